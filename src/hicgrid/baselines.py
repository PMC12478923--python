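"""Mean-based imputation baselines.

For a queried (biosample, assay) cell the row mean averages all reference
maps sharing the query's assay, the column mean those sharing its biosample,
and the cross mean the union of both pools.  The query's own map, if
observed, is never in a pool.  When a split is supplied the reference pool is
restricted to training experiments (the comparison the factorization model
is trained under); without a split every observed experiment except the
target qualifies, which is the mode used when imputing a full grid.
"""

from __future__ import annotations

import numpy as np

from .io import BinnedContactMap, ExperimentGrid, ExperimentKey
from .preprocess import SplitAssignment

__all__ = ["row_mean_impute", "column_mean_impute", "cross_mean_impute",
           "NoReferenceError", "BASELINES"]


class NoReferenceError(ValueError):
    """No reference experiments qualify for the requested imputation."""


def _pool(grid: ExperimentGrid, split: SplitAssignment | None,
          key: ExperimentKey, match: str) -> list[ExperimentKey]:
    keys = grid.observed_keys
    if split is not None:
        train = set(split.keys_for("train"))
        keys = [k for k in keys if k in train]
    out = []
    for k in keys:
        if k == key:
            continue
        if match in ("assay", "either") and k.assay == key.assay:
            out.append(k)
        elif match in ("biosample", "either") and k.biosample == key.biosample:
            out.append(k)
    return out


def _mean_of(grid: ExperimentGrid, pool: list[ExperimentKey],
             key: ExperimentKey, kind: str) -> BinnedContactMap:
    if not pool:
        raise NoReferenceError(
            f"no reference experiments for {kind} imputation of {key}")
    stack = np.stack([grid.maps[k].values for k in pool])
    template = grid.maps[pool[0]]
    return template.with_values(stack.mean(axis=0))


def row_mean_impute(grid: ExperimentGrid, split: SplitAssignment | None,
                    key: ExperimentKey) -> BinnedContactMap:
    """Average of reference maps sharing the query's assay."""
    key = ExperimentKey(*key)
    return _mean_of(grid, _pool(grid, split, key, "assay"), key, "row-mean")


def column_mean_impute(grid: ExperimentGrid, split: SplitAssignment | None,
                       key: ExperimentKey) -> BinnedContactMap:
    """Average of reference maps sharing the query's biosample."""
    key = ExperimentKey(*key)
    return _mean_of(grid, _pool(grid, split, key, "biosample"), key,
                    "column-mean")


def cross_mean_impute(grid: ExperimentGrid, split: SplitAssignment | None,
                      key: ExperimentKey) -> BinnedContactMap:
    """Unweighted average over the union of the row and column pools."""
    key = ExperimentKey(*key)
    return _mean_of(grid, _pool(grid, split, key, "either"), key, "cross-mean")


BASELINES = {
    "row": row_mean_impute,
    "column": column_mean_impute,
    "cross": cross_mean_impute,
}
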