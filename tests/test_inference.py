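"""Permutation matrix statistics against enumeration and OLS oracles."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix

from conftest import random_distance_matrix
from oracles import (mantel_exhaustive, ols_normal_equations,
                     permanova_exhaustive, permanova_f_definition)

from phylosym.covariates import CovariateSet, covariates_from_metadata
from phylosym.inference import (group_tests, mantel, mrm, pairwise_permanova,
                                partial_mantel, permanova, step_regression,
                                subsample_sensitivity, wilcoxon_rank_sum)
from phylosym.simulate import SimulationConfig, simulate_communities


def _condensed(dm):
    return dm.data[np.triu_indices(len(dm.ids), k=1)]


class TestMantel:
    def test_monotone_transform_perfect_r(self):
        rng = np.random.default_rng(0)
        a = random_distance_matrix(8, rng)
        b = DistanceMatrix(2.0 * a.data, ids=list(a.ids))
        res = mantel(a, b, n_perm=199, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 200)

    @pytest.mark.parametrize("method", ["spearman", "pearson"])
    def test_exhaustive_matches_enumeration_oracle(self, method):
        rng = np.random.default_rng(5)
        for trial in range(4):
            a = random_distance_matrix(4, rng)
            b = random_distance_matrix(4, rng, ids=list(a.ids))
            res = mantel(a, b, method=method, exhaustive=True, seed=0)
            r_oracle, p_oracle = mantel_exhaustive(a.data, b.data, method)
            assert res.r == pytest.approx(r_oracle, abs=1e-10)
            assert res.p == pytest.approx(p_oracle, abs=1e-12)
            assert res.n_perm == 24

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            a = random_distance_matrix(10, rng)
            b = random_distance_matrix(10, rng, ids=list(a.ids))
            if mantel(a, b, n_perm=99, seed=rep).p < 0.05:
                rejections += 1
        assert 0.01 <= rejections / n_rep <= 0.10

    def test_constant_matrix_rejected(self):
        a = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=list("abcd"))
        b = random_distance_matrix(4, np.random.default_rng(0),
                                   ids=list("abcd"))
        with pytest.raises(ValueError, match="constant"):
            mantel(a, b, n_perm=99, seed=0)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        a = random_distance_matrix(5, rng)
        b = random_distance_matrix(5, rng, ids=[f"X{i}" for i in range(5)])
        with pytest.raises(ValueError, match="label"):
            mantel(a, b, n_perm=99, seed=0)


class TestPartialMantel:
    def test_constant_control_equals_simple_mantel(self):
        rng = np.random.default_rng(2)
        a = random_distance_matrix(8, rng)
        b = random_distance_matrix(8, rng, ids=list(a.ids))
        c = DistanceMatrix(0.5 * (np.ones((8, 8)) - np.eye(8)),
                           ids=list(a.ids))
        simple = mantel(a, b, n_perm=199, seed=3)
        with pytest.warns(UserWarning, match="collinear"):
            partial = partial_mantel(a, b, {"c": c}, n_perm=199, seed=3)
        assert partial.r == pytest.approx(simple.r, abs=1e-12)
        assert partial.p == pytest.approx(simple.p, abs=1e-12)

    def test_full_partialling_annihilates(self):
        rng = np.random.default_rng(4)
        a = random_distance_matrix(8, rng)
        res = partial_mantel(a, a, {"c": a}, n_perm=99, seed=0)
        assert res.r == 0.0
        assert res.p == 1.0

    def test_control_absorbs_shared_structure(self):
        """B == C and A independent: calibrated rejection near alpha."""
        rng = np.random.default_rng(21)
        rejections = 0
        n_rep = 150
        for rep in range(n_rep):
            a = random_distance_matrix(10, rng)
            b = random_distance_matrix(10, rng, ids=list(a.ids))
            res = partial_mantel(a, b, {"c": b}, n_perm=99, seed=rep)
            assert abs(res.r) < 1e-8 or res.p > 0.01
            if res.p < 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.10


class TestMRM:
    def test_self_regression_perfect_fit(self):
        rng = np.random.default_rng(6)
        y = random_distance_matrix(8, rng)
        res = mrm(y, {"x": y}, n_perm=99, seed=0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.coefficients["x"] == pytest.approx(1.0)

    def test_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(7)
        y = random_distance_matrix(5, rng)
        x1 = random_distance_matrix(5, rng, ids=list(y.ids))
        x2 = random_distance_matrix(5, rng, ids=list(y.ids))
        res = mrm(y, {"x1": x1, "x2": x2}, n_perm=99, seed=0)
        X = np.column_stack([np.ones(10), _condensed(x1), _condensed(x2)])
        beta = ols_normal_equations(X, _condensed(y))
        assert res.coefficients["intercept"] == pytest.approx(beta[0])
        assert res.coefficients["x1"] == pytest.approx(beta[1])
        assert res.coefficients["x2"] == pytest.approx(beta[2])

    def test_single_predictor_r2_is_squared_pearson(self):
        rng = np.random.default_rng(8)
        y = random_distance_matrix(7, rng)
        x = random_distance_matrix(7, rng, ids=list(y.ids))
        res = mrm(y, {"x": x}, n_perm=99, seed=0)
        r = np.corrcoef(_condensed(y), _condensed(x))[0, 1]
        assert res.r_squared == pytest.approx(r ** 2, abs=1e-12)

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(9)
        y = random_distance_matrix(6, rng)
        x = random_distance_matrix(6, rng, ids=list(y.ids))
        x2 = DistanceMatrix(2.0 * x.data, ids=list(y.ids))
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            mrm(y, {"x": x, "x2": x2}, n_perm=99, seed=0)

    def test_null_calibration(self):
        # the two-sided R-squared statistic is slightly conservative on
        # point-geometry matrices, so the accepted band is wide
        rng = np.random.default_rng(31)
        rejections = 0
        n_rep = 300
        for rep in range(n_rep):
            y = random_distance_matrix(10, rng)
            x = random_distance_matrix(10, rng, ids=list(y.ids))
            if mrm(y, {"x": x}, n_perm=99, seed=rep).p_r_squared < 0.05:
                rejections += 1
        assert 0.005 <= rejections / n_rep <= 0.10


class TestPermanova:
    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(10)
        dm = random_distance_matrix(6, rng)
        groups = dict(zip(dm.ids, ["g1"] * 3 + ["g2"] * 3))
        res = permanova(dm, groups, exhaustive=True, seed=0)
        codes = np.array([0, 0, 0, 1, 1, 1])
        f_oracle, p_oracle = permanova_exhaustive(dm.data, codes)
        assert res.pseudo_f == pytest.approx(f_oracle, abs=1e-10)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)

    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(12)
        dm = random_distance_matrix(9, rng)
        labels = list(dm.ids)
        grouping = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = permanova(dm, dict(zip(labels, grouping)), n_perm=99, seed=0)
        sk = sk_permanova(dm, grouping, permutations=0)
        assert res.pseudo_f == pytest.approx(sk["test statistic"], abs=1e-10)

    def test_perfect_separation(self):
        d = np.ones((6, 6)) - np.eye(6)
        d[:3, :3] = 0
        d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, ids=list("abcdef"))
        groups = dict(zip("abcdef", ["g1"] * 3 + ["g2"] * 3))
        res = permanova(dm, groups, exhaustive=True, seed=0)
        # pseudo-F is maximal (within-group SS is 0) and p is the minimum
        # attainable for 3+3: only the 72/720 partition-preserving
        # relabelings reproduce it
        assert np.isinf(res.pseudo_f)
        assert res.p == pytest.approx(0.1)

    def test_singleton_group_rejected(self):
        rng = np.random.default_rng(13)
        dm = random_distance_matrix(5, rng)
        groups = dict(zip(dm.ids, ["g1", "g1", "g1", "g1", "g2"]))
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(dm, groups, n_perm=99, seed=0)

    def test_pairwise_bh_adjustment(self):
        rng = np.random.default_rng(14)
        dm = random_distance_matrix(9, rng)
        groups = dict(zip(dm.ids, ["a"] * 3 + ["b"] * 3 + ["c"] * 3))
        results = pairwise_permanova(dm, groups, n_perm=99, seed=0)
        assert len(results) == 3
        for r in results:
            assert r.p_adj is not None and r.p_adj >= r.p


@pytest.fixture(scope="module")
def dataset():
    cfg = SimulationConfig(n_populations=5, samples_per_population=4,
                           n_taxa=30, depth=500, sigma_phylo=1.0, seed=77)
    ds = simulate_communities(cfg)
    cov = covariates_from_metadata(list(ds.metadata),
                                   ds.host_tree.tip_tip_distances())
    return ds, cov


class TestSubsampleSensitivity:
    def test_all_samples_degenerate_distribution(self, dataset):
        ds, cov = dataset
        sens = subsample_sensitivity(ds.table, list(ds.metadata), cov,
                                     per_population=4, n_subsamples=5,
                                     n_perm=99, seed=1)
        assert len(sens.statistics) == 5
        assert np.allclose(sens.statistics, sens.statistics[0])

    def test_deterministic_schedule(self, dataset):
        ds, cov = dataset
        a = subsample_sensitivity(ds.table, list(ds.metadata), cov,
                                  per_population=3, n_subsamples=4,
                                  n_perm=99, seed=5)
        b = subsample_sensitivity(ds.table, list(ds.metadata), cov,
                                  per_population=3, n_subsamples=4,
                                  n_perm=99, seed=5)
        assert np.array_equal(a.statistics, b.statistics)
        assert np.array_equal(a.p_values, b.p_values)

    def test_quota_overrides_and_errors(self, dataset):
        ds, cov = dataset
        with pytest.raises(ValueError, match="P01"):
            subsample_sensitivity(ds.table, list(ds.metadata), cov,
                                  per_population=5, n_subsamples=2,
                                  n_perm=99, seed=0)
        sens = subsample_sensitivity(
            ds.table, list(ds.metadata), cov, per_population=3,
            per_population_overrides={"P01": 4}, n_subsamples=2,
            n_perm=99, seed=0)
        assert len(sens.p_values) == 2


class TestStepRegression:
    def test_subset_count_and_monotonicity(self):
        rng = np.random.default_rng(15)
        y = random_distance_matrix(7, rng)
        preds = {f"x{i}": random_distance_matrix(7, rng, ids=list(y.ids))
                 for i in range(4)}
        table = step_regression(y, preds, n_perm=99, seed=0)
        assert len(table) == 15
        full = table[tuple(preds)].r_squared
        for combo, res in table.items():
            assert res.r_squared <= full + 1e-12
        # R2 non-decreasing along every nesting chain
        for combo, res in table.items():
            for other, res2 in table.items():
                if set(combo) < set(other):
                    assert res.r_squared <= res2.r_squared + 1e-12


class TestGroupTests:
    def test_kruskal_matches_hand_ranks(self):
        # groups: [1,2], [3,4], [5,6] -> ranks 1..6, H = 5 exactly? compute
        values = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0, "e": 5.0,
                  "f": 6.0}
        groups = {"a": "g1", "b": "g1", "c": "g2", "d": "g2",
                  "e": "g3", "f": "g3"}
        report = group_tests(values, groups)
        # H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, no ties
        h_hand = 12 / (6 * 7) * (2 * (1.5 - 3.5) ** 2 + 2 * (3.5 - 3.5) ** 2
                                 + 2 * (5.5 - 3.5) ** 2)
        assert report.kruskal_h == pytest.approx(h_hand)
        assert set(report.dunn_p_adj) == {("g1", "g2"), ("g1", "g3"),
                                          ("g2", "g3")}

    def test_all_tied_degenerate(self):
        values = {k: 1.0 for k in "abcd"}
        groups = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        with pytest.warns(UserWarning, match="tied"):
            report = group_tests(values, groups)
        assert report.kruskal_p == 1.0

    def test_wilcoxon_extreme_separation(self):
        stat, p = wilcoxon_rank_sum([1, 2, 3, 4], [10, 11, 12, 13])
        # minimal attainable two-sided p for 4 vs 4: 2/C(8,4) = 1/35
        assert p == pytest.approx(2 / 70, abs=1e-9)

    def test_null_calibration(self):
        rng = np.random.default_rng(41)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            vals = rng.normal(size=12)
            values = {f"s{i}": v for i, v in enumerate(vals)}
            groups = {f"s{i}": f"g{i % 3}" for i in range(12)}
            if group_tests(values, groups).kruskal_p < 0.05:
                rejections += 1
        assert 0.01 <= rejections / n_rep <= 0.09


class TestPermutationPValueBounds:
    def test_p_in_add_one_range(self):
        rng = np.random.default_rng(16)
        for rep in range(10):
            a = random_distance_matrix(8, rng)
            b = random_distance_matrix(8, rng, ids=list(a.ids))
            p = mantel(a, b, n_perm=99, seed=rep).p
            assert 1 / 100 <= p <= 1.0
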