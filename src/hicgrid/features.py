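"""One-dimensional summaries of contact maps.

Three standard profiles: the contact decay profile (mean value along each
diagonal, i.e. as a function of genomic distance), the compartment
eigenvector (leading eigenvector of the symmetric map, whose sign pattern
tracks A/B chromatin compartments), and the insulation score (mean of a
sliding diagonal-anchored window, whose dips mark domain boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr  # noqa: F401  (re-exported convenience)

from .io import BinnedContactMap

__all__ = ["FeatureProfile", "contact_decay_profile",
           "compartment_eigenvector", "insulation_score", "FEATURES"]

DEFAULT_INSULATION_WINDOW = 30


@dataclass(frozen=True)
class FeatureProfile:
    """A 1D summary of one contact map."""

    kind: str                 # decay | eigenvector | insulation
    values: np.ndarray
    index_meaning: str        # distance_bins | bin_position | window_start

    def __post_init__(self) -> None:
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=np.float64))

    def save(self, path: str, **params) -> None:
        extra = "".join(f" {k}={v}" for k, v in params.items())
        header = f"kind={self.kind} index={self.index_meaning}{extra}"
        np.savetxt(path, np.column_stack(
            [np.arange(self.values.size), self.values]),
            delimiter="\t", header=header, fmt=["%d", "%.10g"])


def contact_decay_profile(cmap: BinnedContactMap) -> FeatureProfile:
    """Mean contact value along each diagonal: values[d] = mean_i M[i, i+d]."""
    m = cmap.values
    n = m.shape[0]
    vals = np.array([np.mean(np.diagonal(m, d)) for d in range(n)])
    return FeatureProfile(kind="decay", values=vals,
                          index_meaning="distance_bins")


def _fix_sign(vec: np.ndarray, marginals: np.ndarray) -> np.ndarray:
    """Deterministic sign: positive correlation with the marginal vector,
    falling back to a positive first nonzero component on ties."""
    mc = marginals - marginals.mean()
    vc = vec - vec.mean()
    corr = float(vc @ mc)
    if corr < 0:
        return -vec
    if corr == 0:
        nz = np.flatnonzero(vec)
        if nz.size and vec[nz[0]] < 0:
            return -vec
    return vec


def compartment_eigenvector(cmap: BinnedContactMap,
                            oe_correlation: bool = False) -> FeatureProfile:
    """Unit-norm leading eigenvector (largest |eigenvalue|) of the map.

    By default the eigenvector is computed on the normalized map itself.
    ``oe_correlation=True`` first converts the map to its observed/expected
    ratio (dividing each diagonal by its mean) and then to the Pearson
    correlation matrix of that ratio — the conventional A/B-compartment
    pipeline.  The sign is fixed so the vector correlates non-negatively
    with the map's marginals.
    """
    m = np.asarray(cmap.values, dtype=np.float64)
    if np.abs(m - m.T).max() > 1e-8 * max(np.abs(m).max(), 1.0):
        raise ValueError("eigenvector requires a symmetric map")
    marginals = m.sum(axis=1)
    if oe_correlation:
        n = m.shape[0]
        oe = np.array(m, dtype=np.float64)
        for d in range(-(n - 1), n):
            diag = np.diagonal(oe, d)
            mu = diag.mean()
            if mu > 0:
                idx = np.arange(max(0, -d), min(n, n - d))
                oe[idx, idx + d] = diag / mu
        with np.errstate(invalid="ignore"):
            m = np.corrcoef(oe)
        m = np.nan_to_num(m)
    evals, evecs = np.linalg.eigh(m)
    lead = int(np.argmax(np.abs(evals)))
    vec = evecs[:, lead]
    vec = vec / np.linalg.norm(vec)
    return FeatureProfile(kind="eigenvector",
                          values=_fix_sign(vec, marginals),
                          index_meaning="bin_position")


def insulation_score(cmap: BinnedContactMap,
                     window: int = DEFAULT_INSULATION_WINDOW) -> FeatureProfile:
    """Mean of sliding window x window diagonal-anchored submatrices.

    values[s] = mean(M[s:s+window, s:s+window]) for each start s; length is
    n_bins - window + 1.  With window == n_bins this is the global mean.
    """
    m = cmap.values
    n = m.shape[0]
    if window > n:
        raise ValueError(f"window {window} exceeds map size {n}")
    if window < 1:
        raise ValueError("window must be >= 1")
    # O(n^2) via 2D summed-area table
    sat = np.zeros((n + 1, n + 1))
    sat[1:, 1:] = m.cumsum(axis=0).cumsum(axis=1)
    s = np.arange(n - window + 1)
    e = s + window
    block = (sat[e, e] - sat[s, e] - sat[e, s] + sat[s, s])
    return FeatureProfile(kind="insulation", values=block / window ** 2,
                          index_meaning="window_start")


FEATURES = {
    "decay": contact_decay_profile,
    "eigenvector": compartment_eigenvector,
    "insulation": insulation_score,
}
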