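"""Normalization pipeline and train/validation/test splitting.

Each contact map is normalized in three steps: (1) a natural ``log(x+1)``
transform to tame the dynamic range of contact counts, (2) removal of bins
whose marginal (row-sum) count lies more than ``k_mad`` median absolute
deviations from the median marginal in *any* training map — the same mask is
applied to validation and test maps so no information leaks out of the
training set — and (3) rescaling of every map so its entries sum to a common
total (1e5 by default), removing read-depth differences between experiments.

Experiments are split per assay: the assay's experiments are shuffled once
and assigned cyclically train, test, validation, train, ... so an assay with
only two experiments contributes one training and one test map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BinnedContactMap, ExperimentGrid, ExperimentKey, GridValidationError

__all__ = [
    "BinMask",
    "SplitAssignment",
    "log1p_map",
    "compute_marginals",
    "select_retained_bins",
    "apply_mask",
    "normalize_total",
    "preprocess_grid",
    "split_experiments",
]

SPLIT_CYCLE = ("train", "test", "validation")


@dataclass(frozen=True)
class BinMask:
    """Boolean keep-mask over original bins, derived from training maps only."""

    n_bins_original: int
    keep: np.ndarray

    def __post_init__(self) -> None:
        keep = np.asarray(self.keep, dtype=bool)
        object.__setattr__(self, "keep", keep)
        if keep.size != self.n_bins_original:
            raise GridValidationError("mask length != n_bins_original")
        if keep.sum() < 2:
            raise GridValidationError("mask keeps fewer than 2 bins")

    @property
    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.keep)

    def save(self, path: str) -> None:
        np.savetxt(path, self.kept_indices, fmt="%d")

    @classmethod
    def load(cls, path: str, n_bins_original: int) -> "BinMask":
        kept = np.loadtxt(path, dtype=np.int64, ndmin=1)
        keep = np.zeros(n_bins_original, dtype=bool)
        keep[kept] = True
        return cls(n_bins_original=n_bins_original, keep=keep)


@dataclass
class SplitAssignment:
    """Train/validation/test label for every observed experiment."""

    labels: dict[ExperimentKey, str]
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = {ExperimentKey(*k): v for k, v in self.labels.items()}
        bad = {v for v in self.labels.values()} - set(SPLIT_CYCLE)
        if bad:
            raise GridValidationError(f"unknown split labels: {sorted(bad)}")

    def keys_for(self, split: str) -> list[ExperimentKey]:
        return [k for k, v in self.labels.items() if v == split]

    @property
    def counts(self) -> dict[str, int]:
        out = {s: 0 for s in SPLIT_CYCLE}
        for v in self.labels.values():
            out[v] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k.biosample, k.assay, v) for k, v in self.labels.items()],
            columns=["biosample", "assay", "split"])

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path: str) -> "SplitAssignment":
        df = pd.read_csv(path)
        return cls(labels={ExperimentKey(r.biosample, r.assay): r.split
                           for r in df.itertuples(index=False)})


def log1p_map(cmap: BinnedContactMap) -> BinnedContactMap:
    """Natural ``log(x+1)`` transform of every entry."""
    if cmap.values.size and cmap.values.min() < 0:
        raise GridValidationError("log1p requires non-negative entries")
    return cmap.with_values(np.log1p(cmap.values))


def compute_marginals(cmap: BinnedContactMap) -> np.ndarray:
    """Marginal counts: row sums of the full symmetric matrix."""
    return cmap.values.sum(axis=1)


def _deviation(m: np.ndarray, kind: str) -> tuple[np.ndarray, float]:
    med = np.median(m)
    dev = np.abs(m - med)
    if kind == "median":
        mad = float(np.median(dev))
    elif kind == "mean":
        mad = float(np.mean(dev))
    else:
        raise ValueError(f"mad_kind must be 'median' or 'mean', got {kind!r}")
    return dev, mad


def select_retained_bins(training_maps: list[BinnedContactMap],
                         k_mad: float = 10.0,
                         mad_kind: str = "median") -> BinMask:
    """Mask out bins with outlying marginals in any training map.

    For each training map the marginal vector ``m`` is reduced to its median
    ``M`` and absolute deviation scale ``MAD`` (median-based by default,
    mean-based with ``mad_kind='mean'``); a bin is discarded when
    ``|m[i] - M| > k_mad * MAD`` in any one training map.  When a map's MAD
    is zero (near-uniform marginals) that map discards nothing.  Only
    training maps may be passed here: the mask is reused verbatim on
    validation and test maps to avoid leakage.
    """
    if not training_maps:
        raise GridValidationError("need at least one training map")
    n = training_maps[0].n_bins
    keep = np.ones(n, dtype=bool)
    for cmap in training_maps:
        if cmap.n_bins != n:
            raise GridValidationError("training maps disagree on bin count")
        dev, mad = _deviation(compute_marginals(cmap), mad_kind)
        if mad > 0:
            keep &= dev <= k_mad * mad
    if keep.sum() < 2:
        raise GridValidationError("MAD pruning discarded all bins")
    return BinMask(n_bins_original=n, keep=keep)


def apply_mask(cmap: BinnedContactMap, mask: BinMask) -> BinnedContactMap:
    """Drop the rows/columns of masked-out bins and update bookkeeping."""
    if mask.n_bins_original != cmap.n_bins:
        raise GridValidationError(
            f"mask length {mask.n_bins_original} != map bins {cmap.n_bins}")
    idx = mask.kept_indices
    return BinnedContactMap(
        chrom=cmap.chrom, resolution_bp=cmap.resolution_bp,
        n_bins_original=cmap.n_bins_original,
        retained_bins=cmap.retained_bins[idx],
        values=cmap.values[np.ix_(idx, idx)])


def normalize_total(cmap: BinnedContactMap, total: float = 1e5,
                    triangle: bool = False) -> BinnedContactMap:
    """Scale the map so its entries sum to ``total``.

    The sum runs over the full dense symmetric matrix including the diagonal
    (``triangle=True`` sums the upper triangle instead).  Scaling is exactly
    invariant to the map's original depth: ``normalize_total(c*M)`` equals
    ``normalize_total(M)`` for any ``c > 0``.
    """
    if triangle:
        s = float(np.triu(cmap.values).sum())
    else:
        s = float(cmap.values.sum())
    if s <= 0:
        raise GridValidationError("cannot normalize an all-zero map")
    return cmap.with_values(cmap.values * (total / s))


def preprocess_grid(grid: ExperimentGrid, split: SplitAssignment,
                    k_mad: float = 10.0, total: float = 1e5,
                    mad_kind: str = "median",
                    triangle: bool = False) -> tuple[ExperimentGrid, BinMask]:
    """Full pipeline: log1p, train-derived MAD mask, per-map sum normalization.

    Returns the normalized grid and the bin mask (for reuse on new maps).
    """
    missing = [k for k in grid.maps if k not in split.labels]
    if missing:
        raise GridValidationError(f"split does not cover experiments {missing}")
    logged = grid.transform(log1p_map)
    train_maps = [logged.maps[k] for k in sorted(split.keys_for("train"))
                  if k in logged.maps]
    if not train_maps:
        raise GridValidationError("no training experiments in grid")
    mask = select_retained_bins(train_maps, k_mad=k_mad, mad_kind=mad_kind)
    normalized = logged.transform(
        lambda m: normalize_total(apply_mask(m, mask), total=total,
                                  triangle=triangle))
    return normalized, mask


def split_experiments(grid: ExperimentGrid, seed: int) -> SplitAssignment:
    """Assign every observed experiment to train/test/validation.

    Per assay (processed in sorted label order, one seeded generator
    throughout), that assay's experiments are shuffled and assigned in the
    cyclic order train, test, validation, train, test, validation, ...
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    labels: dict[ExperimentKey, str] = {}
    for assay in sorted(set(grid.assays)):
        keys = sorted(k for k in grid.maps if k.assay == assay)
        order = rng.permutation(len(keys))
        for pos, idx in enumerate(order):
            labels[keys[idx]] = SPLIT_CYCLE[pos % 3]
    return SplitAssignment(labels=labels, seed=seed)
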