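"""Evaluation metrics, hyperparameter search, and cross-entity analysis.

The primary performance measure is the mean squared error between an
observed and an imputed map over the off-diagonal upper triangle — the same
quantity the factorization model optimises.  Supporting analyses: Pearson
correlation as a function of genomic distance, ordinary-least-squares
regression of per-map test MSE on the number of shared training experiments,
random hyperparameter search, mean feature-profile correlations between
biosamples (over shared assays) or assays (over shared biosamples), and
average-linkage hierarchical clustering of the resulting correlation
matrices (possible only once imputation has made them complete).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, fields as dataclass_fields

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress, pearsonr

from .features import FEATURES
from .io import BinnedContactMap, ExperimentGrid, ExperimentKey
from .model import Hyperparams, train
from .preprocess import SplitAssignment

__all__ = [
    "CorrelationMatrix",
    "HyperparamSearchResult",
    "map_mse",
    "per_distance_correlation",
    "mse_vs_shared_training",
    "hyperparameter_search",
    "entity_correlation",
    "hierarchical_cluster",
]


def map_mse(predicted: BinnedContactMap, observed: BinnedContactMap,
            include_diagonal: bool = False) -> float:
    """Mean squared error over the upper triangle of two maps."""
    a, b = predicted.values, observed.values
    if a.shape != b.shape or not np.array_equal(
            predicted.retained_bins, observed.retained_bins):
        raise ValueError("maps disagree on shape or retained bins")
    iu, ju = np.triu_indices(a.shape[0], k=0 if include_diagonal else 1)
    return float(np.mean((a[iu, ju] - b[iu, ju]) ** 2))


def per_distance_correlation(predicted: BinnedContactMap,
                             observed: BinnedContactMap) -> np.ndarray:
    """Pearson correlation between the maps along each diagonal.

    Returns a length-``n_bins`` vector indexed by distance; distances with
    fewer than two entries or zero variance in either map are NaN.
    """
    a, b = predicted.values, observed.values
    if a.shape != b.shape:
        raise ValueError("maps disagree on shape")
    n = a.shape[0]
    out = np.full(n, np.nan)
    for d in range(n):
        x, y = np.diagonal(a, d), np.diagonal(b, d)
        if x.size >= 2 and x.std() > 0 and y.std() > 0:
            out[d] = float(np.corrcoef(x, y)[0, 1])
    return out


def mse_vs_shared_training(results: dict[ExperimentKey, float],
                           split: SplitAssignment) -> pd.DataFrame:
    """OLS of per-test-map MSE on the number of shared training experiments.

    For every test map, counts the training experiments sharing its assay,
    its biosample, or either, and fits ordinary least squares of MSE on each
    of the three counts.  Returns one row per predictor with slope,
    intercept and R²; degenerate (zero-variance) predictors yield NaN rows.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 test maps")
    train_keys = split.keys_for("train")
    rows = []
    keys = sorted(results)
    mse = np.array([results[k] for k in keys])
    counts = {
        "shared_assay": [sum(t.assay == k.assay for t in train_keys)
                         for k in keys],
        "shared_biosample": [sum(t.biosample == k.biosample
                                 for t in train_keys) for k in keys],
        "shared_either": [sum(t.assay == k.assay or t.biosample == k.biosample
                              for t in train_keys) for k in keys],
    }
    for name, x in counts.items():
        x = np.asarray(x, dtype=float)
        if np.ptp(x) == 0:
            rows.append((name, np.nan, np.nan, np.nan))
            continue
        fit = linregress(x, mse)
        rows.append((name, fit.slope, fit.intercept, fit.rvalue ** 2))
    return pd.DataFrame(rows, columns=["predictor", "slope", "intercept",
                                       "r_squared"]).set_index("predictor")


@dataclass
class HyperparamSearchResult:
    """Outcome of a random hyperparameter search."""

    table: pd.DataFrame          # one row per configuration
    n_sampled: int
    seed: int

    @property
    def best(self) -> pd.Series:
        return self.table.loc[self.table["best_validation_mse"].idxmin()]

    @property
    def best_hyperparams(self) -> Hyperparams:
        names = {f.name for f in dataclass_fields(Hyperparams)}
        row = self.best
        return Hyperparams(**{k: row[k] for k in row.index if k in names})


def hyperparameter_search(grid_spec: dict[str, list], n_samples: int,
                          grid: ExperimentGrid, split: SplitAssignment,
                          seed: int, base: Hyperparams | None = None,
                          verbose: bool = False) -> HyperparamSearchResult:
    """Random search over a hyperparameter grid.

    ``grid_spec`` maps :class:`Hyperparams` field names to candidate value
    lists.  ``n_samples`` distinct configurations are drawn uniformly
    without replacement (with replacement only if the grid is smaller than
    ``n_samples``); each is trained and its best validation MSE recorded.
    """
    names = list(grid_spec)
    sizes = [len(grid_spec[k]) for k in names]
    if any(s == 0 for s in sizes):
        raise ValueError("every grid dimension must be nonempty")
    total = math.prod(sizes)
    rng = np.random.default_rng(seed)
    if total >= n_samples:
        flat = rng.choice(total, size=n_samples, replace=False)
    else:
        flat = rng.integers(0, total, size=n_samples)
    base = base or Hyperparams()
    rows = []
    for rank, code in enumerate(flat):
        combo = {}
        for name, size in zip(names, sizes):
            combo[name] = grid_spec[name][code % size]
            code //= size
        hp = replace(base, **combo)
        run_seed = int(rng.integers(0, 2 ** 31))
        state = train(grid, split, hp, seed=run_seed)
        rows.append({**combo,
                     "best_validation_mse":
                         float(min(state.history["validation_mse"])),
                     "best_epoch": state.best_epoch,
                     "run_seed": run_seed})
        if verbose:
            print(f"[{rank + 1}/{len(flat)}] {combo} -> "
                  f"{rows[-1]['best_validation_mse']:.5f}")
    return HyperparamSearchResult(table=pd.DataFrame(rows),
                                  n_sampled=len(flat), seed=seed)


@dataclass
class CorrelationMatrix:
    """Mean feature-profile Pearson correlations between entities.

    ``r[c1, c2]`` is the mean, over shared counterpart entities, of the
    Pearson correlation between the two experiments' feature profiles;
    ``n_shared`` counts the experiments that entered each mean.  Entries
    with no shared experiments are NaN, which can only happen on unimputed
    (incomplete) input.
    """

    entities: list[str]
    r: np.ndarray
    n_shared: np.ndarray
    imputed: bool

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.r).any()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.entities, columns=self.entities)

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def entity_correlation(grid: ExperimentGrid, axis: str, feature_kind: str,
                       **feature_kwargs) -> CorrelationMatrix:
    """Mean pairwise feature correlations between biosamples or assays.

    With ``axis='biosample'`` the entities are biosamples and the shared
    counterparts assays (and vice versa).  For every entity pair the feature
    profile correlation is averaged over counterparts where both experiments
    are present; absent experiments are skipped, and feature profiles with
    zero variance contribute nothing (an all-skipped pair is NaN).  On a
    complete (imputed) grid the matrix is complete and flagged ``imputed``.
    """
    if axis == "biosample":
        entities, others = grid.biosamples, grid.assays
        key = lambda e, o: ExperimentKey(e, o)
    elif axis == "assay":
        entities, others = grid.assays, grid.biosamples
        key = lambda e, o: ExperimentKey(o, e)
    else:
        raise ValueError("axis must be 'biosample' or 'assay'")
    feature = FEATURES[feature_kind]
    profiles = {k: feature(m, **feature_kwargs).values
                for k, m in grid.maps.items()}
    ne = len(entities)
    r = np.full((ne, ne), np.nan)
    n_shared = np.zeros((ne, ne), dtype=np.int64)
    for p, e1 in enumerate(entities):
        for q in range(p, ne):
            e2 = entities[q]
            vals = []
            for o in others:
                k1, k2 = key(e1, o), key(e2, o)
                if k1 not in profiles or k2 not in profiles:
                    continue
                v1, v2 = profiles[k1], profiles[k2]
                if v1.std() == 0 or v2.std() == 0:
                    continue
                vals.append(pearsonr(v1, v2).statistic)
            if vals:
                r[p, q] = r[q, p] = float(np.mean(vals))
            n_shared[p, q] = n_shared[q, p] = len(vals)
    return CorrelationMatrix(entities=list(entities), r=r, n_shared=n_shared,
                             imputed=len(grid.missing_keys) == 0)


@dataclass
class Dendrogram:
    """Agglomeration record: entity labels plus a merge list with heights."""

    entities: list[str]
    merges: np.ndarray  # scipy linkage matrix (n-1) x 4

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# entities: " + "\t".join(self.entities) + "\n")
            fh.write("left\tright\theight\tsize\n")
            for a, b, h, s in self.merges:
                fh.write(f"{int(a)}\t{int(b)}\t{h:.10g}\t{int(s)}\n")


def hierarchical_cluster(corr: CorrelationMatrix,
                         method: str = "average") -> Dendrogram:
    """Agglomerative clustering of entities on the distance 1 - r.

    Requires a complete correlation matrix (impute the grid first).
    Entities are processed in lexicographic order, which makes equal-height
    merges deterministic.
    """
    if not corr.is_complete:
        raise ValueError("correlation matrix has missing entries; impute "
                         "the grid before clustering")
    order = np.argsort(np.asarray(corr.entities, dtype=object))
    entities = [corr.entities[k] for k in order]
    dist = 1.0 - corr.r[np.ix_(order, order)]
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0, None)
    merges = linkage(squareform(dist, checks=False), method=method)
    return Dendrogram(entities=entities, merges=merges)
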