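"""Shared fixtures: tiny hand-made maps, small random grids, and the pinned
scaled-down imputation study (generated once per session and reused by the
evaluation-heavy tests)."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import hicgrid as hg
from hicgrid.baselines import cross_mean_impute
from hicgrid.evaluation import map_mse
from hicgrid.io import BinnedContactMap, ExperimentGrid, ExperimentKey
from hicgrid.preprocess import SplitAssignment

# Pinned study conditions: grid seed, training seeds, reduced training scale.
STUDY_SEED = 1
TRAIN_SEEDS = (0, 1, 2)
STUDY_HP = replace(hg.Hyperparams(), batch_size=2000, batches_per_epoch=100,
                   epochs=12)


def make_map(values, chrom="chrT", resolution=100_000):
    values = np.asarray(values, dtype=float)
    return BinnedContactMap(chrom=chrom, resolution_bp=resolution,
                            n_bins_original=values.shape[0],
                            retained_bins=np.arange(values.shape[0]),
                            values=values)


def random_symmetric(rng, n, scale=10.0):
    m = rng.random((n, n)) * scale
    return (m + m.T) / 2


def random_grid(rng, n_biosamples, n_assays, n_bins, p_observed=0.8):
    """Small random grid (plus a split over its observed cells)."""
    biosamples = [f"b{k}" for k in range(n_biosamples)]
    assays = [f"a{k}" for k in range(n_assays)]
    maps = {}
    for b in biosamples:
        for a in assays:
            if rng.random() < p_observed:
                maps[ExperimentKey(b, a)] = make_map(
                    random_symmetric(rng, n_bins))
    grid = ExperimentGrid(biosamples=biosamples, assays=assays, maps=maps)
    labels = {k: ("train", "test", "validation")[rng.integers(0, 3)]
              for k in maps}
    return grid, SplitAssignment(labels=labels)


@pytest.fixture(scope="session")
def study():
    """The pinned synthetic study: grid, truth, split, normalized grid."""
    acc = hg.generate_acceptance_grid(STUDY_SEED)
    norm, mask = hg.preprocess_grid(acc.grid, acc.split)
    return {"acc": acc, "norm": norm, "mask": mask}


@pytest.fixture(scope="session")
def cross_mean_validation_mse(study):
    """Cross-mean baseline MSE on the study's validation maps."""
    norm, split = study["norm"], study["acc"].split
    mses = [map_mse(cross_mean_impute(norm, split, k), norm.maps[k])
            for k in split.keys_for("validation")]
    return float(np.mean(mses))


@pytest.fixture(scope="session")
def trained_full(study):
    """Model trained on the full training set for each pinned seed."""
    norm, split = study["norm"], study["acc"].split
    return {seed: hg.train(norm, split, STUDY_HP, seed=seed)
            for seed in TRAIN_SEEDS}
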