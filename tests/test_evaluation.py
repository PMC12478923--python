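"""MSE, per-distance correlation, regressions, search, entity correlations,
hierarchical clustering."""

import numpy as np
import pandas as pd
import pytest

from hicgrid.evaluation import (entity_correlation, hierarchical_cluster,
                                hyperparameter_search, map_mse,
                                mse_vs_shared_training,
                                per_distance_correlation)
from hicgrid.io import ExperimentGrid, ExperimentKey
from hicgrid.model import Hyperparams
from hicgrid.preprocess import SplitAssignment

from conftest import make_map, random_symmetric
from test_model import TINY_HP, tiny_training_setup


def brute_force_mse(a, b, include_diagonal):
    total, count = 0.0, 0
    n = a.shape[0]
    for i in range(n):
        for j in range(i if include_diagonal else i + 1, n):
            total += (a[i, j] - b[i, j]) ** 2
            count += 1
    return total / count


class TestMapMse:
    def test_identical_maps_zero(self):
        m = make_map(np.eye(4) * 3)
        assert map_mse(m, m) == 0.0

    def test_constant_offset(self):
        a = np.zeros((3, 3))
        b = np.full((3, 3), 2.0)
        np.fill_diagonal(b, 0)
        assert map_mse(make_map(a), make_map(b)) == pytest.approx(4.0)

    @pytest.mark.parametrize("include_diagonal", [False, True])
    def test_matches_brute_force_oracle(self, include_diagonal):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = random_symmetric(rng, 6)
            b = random_symmetric(rng, 6)
            assert map_mse(make_map(a), make_map(b),
                           include_diagonal=include_diagonal) == \
                pytest.approx(brute_force_mse(a, b, include_diagonal),
                              rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            map_mse(make_map(np.zeros((3, 3))), make_map(np.zeros((4, 4))))


class TestPerDistanceCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(2)
        m = make_map(random_symmetric(rng, 8))
        out = per_distance_correlation(m, m)
        for d in range(7):
            assert out[d] == pytest.approx(1.0)
        assert np.isnan(out[7])  # single entry

    def test_reversed_affine_is_minus_one(self):
        rng = np.random.default_rng(3)
        vals = random_symmetric(rng, 6)
        flipped = vals.max() - vals
        flipped = (flipped + flipped.T) / 2
        out = per_distance_correlation(make_map(vals), make_map(flipped))
        assert out[1] == pytest.approx(-1.0)

    def test_constant_diagonal_is_missing(self):
        a = np.ones((4, 4))
        rng = np.random.default_rng(4)
        b = random_symmetric(rng, 4)
        out = per_distance_correlation(make_map(a), make_map(b))
        assert np.isnan(out).all()


class TestMseVsSharedTraining:
    @staticmethod
    def split_with_train(train_cells):
        labels = {ExperimentKey(b, a): "train" for b, a in train_cells}
        return labels

    def test_perfectly_linear_r_squared_one(self):
        # test maps' MSE decreases exactly linearly in shared-assay count
        labels = self.split_with_train(
            [("b1", "a1"), ("b2", "a1"), ("b3", "a1"), ("b4", "a2")])
        results = {}
        for k, (b, a) in enumerate([("t1", "a1"), ("t2", "a2"),
                                    ("t3", "a3")]):
            key = ExperimentKey(b, a)
            labels[key] = "test"
        counts = {"a1": 3, "a2": 1, "a3": 0}
        for b, a in [("t1", "a1"), ("t2", "a2"), ("t3", "a3")]:
            results[ExperimentKey(b, a)] = 10.0 - 2.0 * counts[a]
        fits = mse_vs_shared_training(results, SplitAssignment(labels=labels))
        assert fits.loc["shared_assay", "r_squared"] == pytest.approx(1.0)
        assert fits.loc["shared_assay", "slope"] == pytest.approx(-2.0)
        assert fits.loc["shared_assay", "intercept"] == pytest.approx(10.0)

    def test_constant_response_zero_slope(self):
        labels = self.split_with_train([("b1", "a1"), ("b2", "a2")])
        results = {}
        for b, a in [("t1", "a1"), ("t2", "a2"), ("t3", "a3")]:
            key = ExperimentKey(b, a)
            labels[key] = "test"
            results[key] = 5.0
        fits = mse_vs_shared_training(results, SplitAssignment(labels=labels))
        assert fits.loc["shared_assay", "slope"] == pytest.approx(0.0)

    def test_four_point_ols_matches_normal_equations(self):
        labels = self.split_with_train(
            [("b1", "a1"), ("b2", "a1"), ("b3", "a2"), ("b4", "a2"),
             ("b5", "a2"), ("b6", "a4")])
        cells = [("t1", "a1"), ("t2", "a2"), ("t3", "a3"), ("t4", "a4")]
        mses = [3.0, 1.5, 4.0, 2.5]
        results = {}
        for (b, a), v in zip(cells, mses):
            key = ExperimentKey(b, a)
            labels[key] = "test"
            results[key] = v
        fits = mse_vs_shared_training(results, SplitAssignment(labels=labels))
        x = np.array([2.0, 3.0, 0.0, 1.0])  # shared-assay counts, sorted keys
        keys = sorted(results)
        x = np.array([sum(1 for tb, ta in
                          [("b1", "a1"), ("b2", "a1"), ("b3", "a2"),
                           ("b4", "a2"), ("b5", "a2"), ("b6", "a4")]
                          if ta == k.assay) for k in keys], dtype=float)
        y = np.array([results[k] for k in keys])
        X = np.column_stack([np.ones(4), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fits.loc["shared_assay", "intercept"] == pytest.approx(beta[0])
        assert fits.loc["shared_assay", "slope"] == pytest.approx(beta[1])

    def test_degenerate_predictor_gives_nan(self):
        labels = self.split_with_train([("b1", "a9"), ("b2", "a9")])
        results = {}
        for b, a in [("t1", "a1"), ("t2", "a2"), ("t3", "a3")]:
            key = ExperimentKey(b, a)
            labels[key] = "test"
            results[key] = float(len(b))
        fits = mse_vs_shared_training(results, SplitAssignment(labels=labels))
        assert np.isnan(fits.loc["shared_assay", "slope"])

    def test_too_few_test_maps_rejected(self):
        with pytest.raises(ValueError):
            mse_vs_shared_training({ExperimentKey("a", "b"): 1.0},
                                   SplitAssignment(labels={}))


class TestHyperparameterSearch:
    def run_search(self, n_samples, seed, spec=None):
        norm, split = tiny_training_setup(n_bins=12)
        spec = spec or {"n_nodes": [4, 8], "n_layers": [1, 2],
                        "learning_rate": [1e-3, 3e-3]}
        from dataclasses import replace
        base = replace(TINY_HP, epochs=1, batch_size=50, batches_per_epoch=2)
        return hyperparameter_search(spec, n_samples, norm, split, seed=seed,
                                     base=base)

    def test_argmin_is_table_minimum(self):
        res = self.run_search(4, seed=0)
        assert res.best["best_validation_mse"] == \
            res.table["best_validation_mse"].min()
        assert len(res.table) == 4

    def test_distinct_configurations_without_replacement(self):
        res = self.run_search(6, seed=1)
        combos = res.table[["n_nodes", "n_layers", "learning_rate"]]
        assert not combos.duplicated().any()

    def test_fixed_seed_samples_same_configurations(self):
        a = self.run_search(3, seed=2)
        b = self.run_search(3, seed=2)
        pd.testing.assert_frame_equal(
            a.table[["n_nodes", "n_layers", "learning_rate"]],
            b.table[["n_nodes", "n_layers", "learning_rate"]])

    def test_best_hyperparams_reconstructs_config(self):
        res = self.run_search(2, seed=3)
        hp = res.best_hyperparams
        assert isinstance(hp, Hyperparams)
        assert hp.n_nodes == res.best["n_nodes"]


def feature_grid(cells, profiles):
    """Grid whose decay profiles are fully controlled via diagonal values."""
    biosamples = sorted({b for b, _ in cells})
    assays = sorted({a for _, a in cells})
    maps = {}
    for b, a in cells:
        prof = np.asarray(profiles[(b, a)], dtype=float)
        n = prof.size
        vals = np.zeros((n, n))
        for d in range(n):
            idx = np.arange(n - d)
            vals[idx, idx + d] = prof[d]
            vals[idx + d, idx] = prof[d]
        maps[ExperimentKey(b, a)] = make_map(vals)
    return ExperimentGrid(biosamples=biosamples, assays=assays, maps=maps)


class TestEntityCorrelation:
    def test_diagonal_is_one(self):
        rng = np.random.default_rng(8)
        profiles = {(b, a): rng.random(5)
                    for b in ("b1", "b2") for a in ("a1", "a2")}
        grid = feature_grid(list(profiles), profiles)
        corr = entity_correlation(grid, "biosample", "decay")
        np.testing.assert_allclose(np.diag(corr.r), 1.0)

    def test_identical_shared_maps_correlate_one(self):
        prof = np.array([5.0, 3.0, 2.0, 1.0])
        profiles = {("b1", "a1"): prof, ("b2", "a1"): prof}
        grid = feature_grid(list(profiles), profiles)
        corr = entity_correlation(grid, "biosample", "decay")
        assert corr.r[0, 1] == pytest.approx(1.0)

    def test_mean_of_two_shared_assays_matches_brute_force(self):
        rng = np.random.default_rng(9)
        profs = {(b, a): rng.random(6) for b in ("b1", "b2")
                 for a in ("a1", "a2")}
        grid = feature_grid(list(profs), profs)
        corr = entity_correlation(grid, "biosample", "decay")
        expected = np.mean([np.corrcoef(profs[("b1", a)],
                                        profs[("b2", a)])[0, 1]
                            for a in ("a1", "a2")])
        assert corr.r[0, 1] == pytest.approx(expected)
        assert corr.n_shared[0, 1] == 2

    def test_missing_entries_exactly_where_no_shared(self):
        rng = np.random.default_rng(10)
        cells = [("b1", "a1"), ("b2", "a2")]  # no shared assay
        profs = {c: rng.random(4) for c in cells}
        grid = feature_grid(cells, profs)
        corr = entity_correlation(grid, "biosample", "decay")
        assert np.isnan(corr.r[0, 1])
        assert corr.n_shared[0, 1] == 0
        assert not corr.imputed

    def test_assay_axis_swaps_roles(self):
        rng = np.random.default_rng(11)
        profs = {(b, a): rng.random(5) for b in ("b1", "b2")
                 for a in ("a1", "a2")}
        grid = feature_grid(list(profs), profs)
        corr = entity_correlation(grid, "assay", "decay")
        expected = np.mean([np.corrcoef(profs[(b, "a1")],
                                        profs[(b, "a2")])[0, 1]
                            for b in ("b1", "b2")])
        assert corr.r[0, 1] == pytest.approx(expected)

    def test_partial_agrees_with_complete_where_fully_shared(self):
        """Dropping cells leaves entity pairs whose shared experiments were
        all retained with unchanged correlations."""
        rng = np.random.default_rng(12)
        biosamples = [f"b{k}" for k in range(3)]
        assays = [f"a{k}" for k in range(3)]
        profs = {(b, a): rng.random(6) for b in biosamples for a in assays}
        full = feature_grid(list(profs), profs)
        partial_cells = [c for c in profs if c != ("b2", "a0")]
        partial = feature_grid(partial_cells,
                               {c: profs[c] for c in partial_cells})
        cf = entity_correlation(full, "biosample", "decay")
        cp = entity_correlation(partial, "biosample", "decay")
        # the (b0, b1) pair shares all three assays in both grids
        i0, i1 = cf.entities.index("b0"), cf.entities.index("b1")
        assert cp.n_shared[i0, i1] == cf.n_shared[i0, i1] == 3
        assert cp.r[i0, i1] == pytest.approx(cf.r[i0, i1])


def test_imputation_does_not_increase_correlation_variance():
    """Smoothing property: across 10 simulation seeds, entity correlations
    computed after cross-mean imputation vary no more than the
    sparse-support unimputed correlations."""
    from hicgrid.baselines import cross_mean_impute
    from hicgrid.synthetic import SyntheticSpec, generate_grid

    un_vals, im_vals = [], []
    for seed in range(10):
        spec = SyntheticSpec.random(5, 4, 30, seed=seed,
                                    missing_fraction=0.3, depth=3e4)
        grid, _ = generate_grid(spec)
        maps = dict(grid.maps)
        for key in grid.missing_keys:
            maps[key] = cross_mean_impute(grid, None, key)
        full = ExperimentGrid(biosamples=grid.biosamples,
                              assays=grid.assays, maps=maps)
        un_vals.append(entity_correlation(grid, "biosample", "decay").r)
        im_vals.append(entity_correlation(full, "biosample", "decay").r)
    un = np.array(un_vals)
    im = np.array(im_vals)
    iu = np.triu_indices(5, k=1)
    un_var = np.nanvar(un[:, iu[0], iu[1]], axis=0)
    im_var = np.nanvar(im[:, iu[0], iu[1]], axis=0)
    assert np.nanmean(im_var) <= np.nanmean(un_var)


class TestHierarchicalCluster:
    def corr(self, entities, r):
        from hicgrid.evaluation import CorrelationMatrix
        r = np.asarray(r, dtype=float)
        return CorrelationMatrix(entities=entities, r=r,
                                 n_shared=np.full_like(r, 2, dtype=np.int64),
                                 imputed=True)

    def test_nearest_pair_merges_first(self):
        corr = self.corr(["e1", "e2", "e3"],
                         [[1.0, 0.99, 0.5], [0.99, 1.0, 0.5],
                          [0.5, 0.5, 1.0]])
        dendro = hierarchical_cluster(corr)
        first = set(dendro.merges[0, :2].astype(int))
        assert first == {0, 1}  # e1, e2

    def test_identical_entities_merge_at_zero(self):
        corr = self.corr(["x", "y"], [[1.0, 1.0], [1.0, 1.0]])
        dendro = hierarchical_cluster(corr)
        assert dendro.merges[0, 2] == pytest.approx(0.0)

    def test_four_entity_average_linkage_by_hand(self):
        # distances: d(0,1)=0.1, d(0,2)=0.4, d(0,3)=0.9, d(1,2)=0.5,
        # d(1,3)=0.8, d(2,3)=0.2 -> merges: {0,1}@0.1, {2,3}@0.2,
        # then average linkage height (0.4+0.9+0.5+0.8)/4 = 0.65
        r = 1 - np.array([[0.0, 0.1, 0.4, 0.9], [0.1, 0.0, 0.5, 0.8],
                          [0.4, 0.5, 0.0, 0.2], [0.9, 0.8, 0.2, 0.0]])
        dendro = hierarchical_cluster(self.corr(list("abcd"), r))
        np.testing.assert_allclose(dendro.merges[:, 2], [0.1, 0.2, 0.65])

    def test_missing_entries_rejected(self):
        r = np.array([[1.0, np.nan], [np.nan, 1.0]])
        corr = self.corr(["u", "v"], r)
        corr.imputed = False
        with pytest.raises(ValueError, match="impute"):
            hierarchical_cluster(corr)
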