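"""Contact-map and experiment-grid I/O.

A contact map is the symmetric matrix of 3D-contact counts between pairs of
fixed-width genomic bins on one chromosome.  Experiments are organised in a
biosample-by-assay grid in which many cells are missing; the imputation task
is to fill those cells.  This module reads and writes single maps in two
plain-text formats (dense TSV and sparse bin-pair triplets), assembles a grid
from a tabular manifest, and prunes the grid so that every biosample and
every assay retains at least two observed experiments.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "BinnedContactMap",
    "ExperimentKey",
    "ExperimentGrid",
    "ContactMapFormatError",
    "GridValidationError",
    "read_contact_map",
    "write_contact_map",
    "assemble_grid",
    "prune_grid",
]

_SYMMETRY_RTOL = 1e-8


class ContactMapFormatError(ValueError):
    """Raised when a contact-map file is malformed or violates invariants."""


class GridValidationError(ValueError):
    """Raised when an experiment grid violates its invariants."""


@dataclass(frozen=True)
class BinnedContactMap:
    """One chromosome's symmetric binned contact matrix plus bin bookkeeping.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    resolution_bp : int
        Bin width in base pairs.  Bins are half-open intervals
        ``[k*resolution_bp, (k+1)*resolution_bp)`` with 0-based index ``k``.
    n_bins_original : int
        Number of bins before any pruning.
    retained_bins : numpy.ndarray
        Strictly increasing original bin indices kept after pruning.
    values : numpy.ndarray
        Square symmetric matrix of finite non-negative reals, indexed by
        ``retained_bins``.
    """

    chrom: str
    resolution_bp: int
    n_bins_original: int
    retained_bins: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "retained_bins",
                           np.asarray(self.retained_bins, dtype=np.int64))
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=np.float64))
        self._validate()

    def _validate(self) -> None:
        if self.resolution_bp <= 0:
            raise GridValidationError("resolution_bp must be positive")
        v = self.values
        rb = self.retained_bins
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise GridValidationError(f"values must be square, got {v.shape}")
        if v.shape[0] != rb.size:
            raise GridValidationError(
                f"values side {v.shape[0]} != retained bin count {rb.size}")
        if rb.size and (rb[0] < 0 or rb[-1] >= self.n_bins_original):
            raise GridValidationError("retained_bins out of range")
        if rb.size > 1 and not np.all(np.diff(rb) > 0):
            raise GridValidationError("retained_bins must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise GridValidationError("contact map contains non-finite entries")
        if v.size and v.min() < 0:
            raise GridValidationError("contact map contains negative entries")
        scale = max(np.abs(v).max(), 1.0) if v.size else 1.0
        if v.size and np.abs(v - v.T).max() > _SYMMETRY_RTOL * scale:
            raise GridValidationError("contact map is not symmetric")

    @property
    def n_bins(self) -> int:
        """Number of currently retained bins (matrix side length)."""
        return int(self.values.shape[0])

    def with_values(self, values: np.ndarray) -> "BinnedContactMap":
        """Copy of this map with ``values`` replaced (bookkeeping kept)."""
        return replace(self, values=np.asarray(values, dtype=np.float64))


class ExperimentKey(NamedTuple):
    """Identifies one experiment: a (biosample, assay) grid cell."""

    biosample: str
    assay: str


@dataclass
class ExperimentGrid:
    """A biosample-by-assay collection of contact maps with missing cells."""

    biosamples: list[str]
    assays: list[str]
    maps: dict[ExperimentKey, BinnedContactMap] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.maps = {ExperimentKey(*k): m for k, m in self.maps.items()}
        self._validate()

    def _validate(self) -> None:
        bset, aset = set(self.biosamples), set(self.assays)
        for key in self.maps:
            if key.biosample not in bset or key.assay not in aset:
                raise GridValidationError(f"key {key} not in grid labels")
        ref = None
        for key, m in self.maps.items():
            if ref is None:
                ref = m
                continue
            if (m.chrom != ref.chrom or m.resolution_bp != ref.resolution_bp
                    or not np.array_equal(m.retained_bins, ref.retained_bins)):
                raise GridValidationError(
                    f"map {key} disagrees with grid chrom/resolution/bins")

    @property
    def observed_keys(self) -> list[ExperimentKey]:
        return list(self.maps)

    @property
    def missing_keys(self) -> list[ExperimentKey]:
        return [ExperimentKey(b, a) for b in self.biosamples for a in self.assays
                if ExperimentKey(b, a) not in self.maps]

    @property
    def n_observed(self) -> int:
        return len(self.maps)

    def biosample_counts(self) -> dict[str, int]:
        counts = {b: 0 for b in self.biosamples}
        for key in self.maps:
            counts[key.biosample] += 1
        return counts

    def assay_counts(self) -> dict[str, int]:
        counts = {a: 0 for a in self.assays}
        for key in self.maps:
            counts[key.assay] += 1
        return counts

    def transform(self, fn) -> "ExperimentGrid":
        """New grid with ``fn`` applied to every observed map."""
        return ExperimentGrid(
            biosamples=list(self.biosamples), assays=list(self.assays),
            maps={k: fn(m) for k, m in self.maps.items()})


def _parse_triplets(path: str, n_bins: int) -> np.ndarray:
    mat = np.zeros((n_bins, n_bins), dtype=np.float64)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise ContactMapFormatError(
                    f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            try:
                i, j = int(parts[0]), int(parts[1])
                c = float(parts[2])
            except ValueError as exc:
                raise ContactMapFormatError(f"{path}:{lineno}: {exc}") from exc
            if not (0 <= i < n_bins and 0 <= j < n_bins):
                raise ContactMapFormatError(
                    f"{path}:{lineno}: bin index out of range [0, {n_bins})")
            if c < 0:
                raise ContactMapFormatError(f"{path}:{lineno}: negative count {c}")
            # accumulate on the unordered pair, then mirror
            mat[i, j] += c
            if i != j:
                mat[j, i] += c
    return mat


def read_contact_map(path: str, fmt: str, n_bins: int, resolution_bp: int,
                     chrom: str) -> BinnedContactMap:
    """Read one contact map from ``path``.

    ``fmt`` is ``"dense-tsv"`` (an ``n_bins`` x ``n_bins`` tab-separated
    matrix, no header) or ``"triplet"`` (``bin1<TAB>bin2<TAB>count`` rows,
    0-based).  Triplet input is symmetrised by mirroring each entry across
    the diagonal; duplicate entries for the same unordered pair are summed;
    unlisted pairs are zero.  Dense input must already be symmetric.
    """
    if fmt == "triplet":
        mat = _parse_triplets(path, n_bins)
    elif fmt == "dense-tsv":
        try:
            mat = np.loadtxt(path, delimiter="\t", dtype=np.float64,
                             ndmin=2)
        except ValueError as exc:
            raise ContactMapFormatError(f"{path}: {exc}") from exc
        if os.path.getsize(path) == 0:
            mat = np.zeros((n_bins, n_bins))
        if mat.shape != (n_bins, n_bins):
            raise ContactMapFormatError(
                f"{path}: expected {n_bins}x{n_bins} matrix, got {mat.shape}")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return BinnedContactMap(chrom=chrom, resolution_bp=resolution_bp,
                            n_bins_original=n_bins,
                            retained_bins=np.arange(n_bins), values=mat)


def write_contact_map(cmap: BinnedContactMap, path: str, fmt: str) -> None:
    """Write ``cmap`` to ``path``.

    Triplet output lists only upper-triangle (including diagonal) nonzeros,
    so a read/write round trip reproduces the matrix exactly.
    """
    if fmt == "triplet":
        iu, ju = np.triu_indices(cmap.n_bins)
        vals = cmap.values[iu, ju]
        nz = vals != 0
        df = pd.DataFrame({"bin1": iu[nz], "bin2": ju[nz], "count": vals[nz]})
        df.to_csv(path, sep="\t", header=False, index=False,
                  float_format="%.17g")
    elif fmt == "dense-tsv":
        np.savetxt(path, cmap.values, delimiter="\t", fmt="%.17g")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def assemble_grid(manifest: "pd.DataFrame | str", n_bins: int,
                  resolution_bp: int, chrom: str) -> ExperimentGrid:
    """Assemble an :class:`ExperimentGrid` from a manifest.

    ``manifest`` is a DataFrame (or path to a CSV) with columns
    ``biosample, assay, path, format``.  Label lists preserve first-appearance
    manifest order.  Relative paths in a CSV manifest are resolved against
    the manifest's directory.
    """
    base = ""
    if isinstance(manifest, (str, os.PathLike)):
        base = os.path.dirname(os.fspath(manifest))
        manifest = pd.read_csv(manifest)
    required = {"biosample", "assay", "path", "format"}
    if not required.issubset(manifest.columns):
        raise GridValidationError(
            f"manifest must have columns {sorted(required)}")
    keys = list(zip(manifest["biosample"], manifest["assay"]))
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise GridValidationError(f"duplicate manifest keys: {dupes}")
    biosamples = list(dict.fromkeys(manifest["biosample"]))
    assays = list(dict.fromkeys(manifest["assay"]))
    maps: dict[ExperimentKey, BinnedContactMap] = {}
    for row in manifest.itertuples(index=False):
        key = ExperimentKey(row.biosample, row.assay)
        path = row.path
        if base and not os.path.isabs(path):
            path = os.path.join(base, path)
        try:
            maps[key] = read_contact_map(path, row.format, n_bins,
                                         resolution_bp, chrom)
        except Exception as exc:
            raise type(exc)(f"experiment {key}: {exc}") from exc
    return ExperimentGrid(biosamples=biosamples, assays=assays, maps=maps)


def prune_grid(grid: ExperimentGrid) -> ExperimentGrid:
    """Iteratively drop biosamples/assays with fewer than two observed maps.

    Removing a label deletes its maps, which can lower other labels' counts,
    so removal repeats to a fixed point.  The fixed point is independent of
    removal order.  Raises :class:`GridValidationError` if nothing survives.
    """
    biosamples = list(grid.biosamples)
    assays = list(grid.assays)
    maps = dict(grid.maps)
    for _ in range(len(biosamples) + len(assays) + 1):
        bc = {b: 0 for b in biosamples}
        ac = {a: 0 for a in assays}
        for key in maps:
            bc[key.biosample] += 1
            ac[key.assay] += 1
        drop_b = {b for b, c in bc.items() if c <= 1}
        drop_a = {a for a, c in ac.items() if c <= 1}
        if not drop_b and not drop_a:
            break
        biosamples = [b for b in biosamples if b not in drop_b]
        assays = [a for a in assays if a not in drop_a]
        maps = {k: m for k, m in maps.items()
                if k.biosample not in drop_b and k.assay not in drop_a}
    if not maps:
        raise GridValidationError("grid pruned to empty: no biosample/assay "
                                  "pair retains two observed experiments")
    return ExperimentGrid(biosamples=biosamples, assays=assays, maps=maps)
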