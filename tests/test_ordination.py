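"""Jaccard distances, NMDS, factor fits, distance-based MANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.distance import permanova

from hostscan.ordination import adonis, fit_factor, jaccard_matrix, nmds
from hostscan.synthetic_data import SimConfig, simulate_dominant_markers

from conftest import toy_matrix


def _euclid_dm(X, ids=None):
    ids = ids or [str(i) for i in range(len(X))]
    d = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    return DistanceMatrix(d, ids=ids)


class TestJaccard:
    def test_identical_rows_distance_zero(self):
        m = toy_matrix(np.ones((4, 5), dtype=int))
        d = jaccard_matrix(m)
        assert np.allclose(d.data, 0.0)

    def test_disjoint_presence_sets_distance_one(self):
        calls = np.array([[1, 1, 0, 0], [0, 0, 1, 1]])
        d = jaccard_matrix(toy_matrix(calls, hosts=["glabra", "coriacea"]))
        assert d.data[0, 1] == pytest.approx(1.0)

    def test_hand_computed_overlap(self):
        calls = np.array([[1, 1, 0, 0], [1, 0, 1, 0]])
        d = jaccard_matrix(toy_matrix(calls, hosts=["glabra", "coriacea"]))
        assert d.data[0, 1] == pytest.approx(1 - 1 / 3)

    def test_all_zero_sample_rejected(self):
        calls = np.array([[1, 1], [0, 0]])
        with pytest.raises(ValueError):
            jaccard_matrix(toy_matrix(calls))

    def test_triangle_inequality(self):
        rng = np.random.default_rng(0)
        calls = (rng.random((15, 30)) < 0.4).astype(int)
        calls[:, 0] = 1                      # no empty rows
        d = jaccard_matrix(toy_matrix(calls)).data
        for i, j, k in itertools.permutations(range(10), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestNmds:
    def test_euclidean_configuration_near_zero_stress(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 2))
        res = nmds(_euclid_dm(X), n_restarts=4, seed=0)
        assert res.stress < 1e-6

    def test_scores_centered(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 3))
        res = nmds(_euclid_dm(X), n_restarts=3, seed=1)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-9)

    def test_separated_clusters_stay_separated(self):
        cfg = SimConfig(seed=40, n_locations=1, n_per_group_per_location=15,
                        n_neutral_loci=60, n_outlier_loci=20, miscall_rate=0.0,
                        background_fst=0.05, outlier_fst=0.6, location_fst=0.0)
        m, _ = simulate_dominant_markers(cfg)
        res = nmds(jaccard_matrix(m), n_restarts=8, seed=2)
        meta = m.primary().metadata
        a = res.scores[meta["host"] == "glabra"].to_numpy()
        b = res.scores[meta["host"] == "coriacea"].to_numpy()
        between = np.linalg.norm(a.mean(0) - b.mean(0))
        within = (a.std() + b.std()) / 2
        assert between > within

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nmds(_euclid_dm(np.zeros((3, 2))), k=2)


class TestFitFactor:
    def test_perfect_separation_r2_near_one(self):
        X = np.vstack([np.random.default_rng(3).normal(0, 0.05, (8, 2)),
                       np.random.default_rng(4).normal(5, 0.05, (8, 2))])
        res = nmds(_euclid_dm(X), n_restarts=3, seed=3)
        labels = pd.Series(["a"] * 8 + ["b"] * 8, index=res.scores.index)
        r2, p = fit_factor(res, labels, n_perm=199, seed=0)
        assert r2 > 0.95
        assert p <= 1 / 100

    def test_invariant_to_rotation(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(14, 2))
        res = nmds(_euclid_dm(X), n_restarts=3, seed=4)
        labels = pd.Series(["a"] * 7 + ["b"] * 7, index=res.scores.index)
        r2a, _ = fit_factor(res, labels, n_perm=99, seed=1)
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        import dataclasses
        res2 = dataclasses.replace(
            res, scores=pd.DataFrame(res.scores.to_numpy() @ rot,
                                     index=res.scores.index,
                                     columns=res.scores.columns))
        r2b, _ = fit_factor(res2, labels, n_perm=99, seed=1)
        assert r2a == pytest.approx(r2b, abs=1e-10)

    def test_single_level_rejected(self):
        rng = np.random.default_rng(6)
        res = nmds(_euclid_dm(rng.normal(size=(8, 2))), n_restarts=2, seed=5)
        labels = pd.Series(["a"] * 8, index=res.scores.index)
        with pytest.raises(ValueError):
            fit_factor(res, labels)


class TestAdonis:
    def test_equals_classical_anova_f(self):
        """Euclidean distances on univariate data: pseudo-F == one-way F."""
        rng = np.random.default_rng(7)
        y = np.concatenate([rng.normal(0, 1, 9), rng.normal(0.8, 1, 11)])
        ids = [str(i) for i in range(20)]
        d = DistanceMatrix(np.abs(y[:, None] - y[None, :]), ids=ids)
        meta = pd.DataFrame({"g": ["a"] * 9 + ["b"] * 11}, index=ids)
        out = adonis(d, meta, ["g"], n_perm=99, seed=0)
        f_classic = stats.f_oneway(y[:9], y[9:]).statistic
        assert out.table.loc["g", "pseudo_F"] == pytest.approx(f_classic,
                                                               abs=1e-10)

    def test_matches_projection_oracle_on_six_samples(self):
        """Brute-force Gower/hat-matrix algebra on a printed 6x6 matrix."""
        d_vals = np.array([
            [0.0, 0.3, 0.5, 0.7, 0.8, 0.9],
            [0.3, 0.0, 0.4, 0.6, 0.7, 0.8],
            [0.5, 0.4, 0.0, 0.5, 0.6, 0.7],
            [0.7, 0.6, 0.5, 0.0, 0.3, 0.4],
            [0.8, 0.7, 0.6, 0.3, 0.0, 0.2],
            [0.9, 0.8, 0.7, 0.4, 0.2, 0.0]])
        ids = list("abcdef")
        meta = pd.DataFrame({"g": ["x", "x", "x", "y", "y", "y"]}, index=ids)
        out = adonis(DistanceMatrix(d_vals, ids=ids), meta, ["g"],
                     n_perm=0, seed=0)

        n = 6
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ (d_vals ** 2) @ J
        X = np.column_stack([np.ones(n), (np.array(meta["g"]) == "y")])
        H = X @ np.linalg.pinv(X)
        ss_g = np.trace(H @ G) - np.trace(G) / n * 0  # full-model trace
        ss_mean = np.trace((np.ones((n, n)) / n) @ G)
        ss_term = np.trace(H @ G) - ss_mean
        ss_res = np.trace(G) - np.trace(H @ G)
        f = (ss_term / 1) / (ss_res / (n - 2))
        assert out.table.loc["g", "pseudo_F"] == pytest.approx(f, abs=1e-10)
        assert out.table.loc["g", "SS"] == pytest.approx(ss_term, abs=1e-10)

    def test_matches_skbio_permanova_statistic(self):
        """Independent cross-check against scikit-bio's PERMANOVA."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(16, 4))
        X[8:] += 0.8
        ids = [str(i) for i in range(16)]
        d = DistanceMatrix(np.linalg.norm(X[:, None] - X[None, :], axis=-1),
                           ids=ids)
        meta = pd.DataFrame({"g": ["a"] * 8 + ["b"] * 8}, index=ids)
        ours = adonis(d, meta, ["g"], n_perm=0, seed=0)
        theirs = permanova(d, meta["g"].to_numpy(), permutations=0)
        assert ours.table.loc["g", "pseudo_F"] == pytest.approx(
            theirs["test statistic"], abs=1e-10)

    def test_r2_components_sum_to_one(self):
        cfg = SimConfig(seed=41, n_locations=2, n_per_group_per_location=10,
                        n_neutral_loci=50, n_outlier_loci=5, miscall_rate=0.0)
        m, _ = simulate_dominant_markers(cfg)
        d = jaccard_matrix(m)
        meta = m.primary().metadata
        out = adonis(d, meta, ["location", "location:host"], n_perm=49,
                     seed=1, strata="location")
        assert out.table["R2"].drop("total").sum() == pytest.approx(1.0,
                                                                    abs=1e-12)

    def test_identical_group_compositions_null(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 3))
        ids = [str(i) for i in range(20)]
        d = _euclid_dm(X, ids)
        meta = pd.DataFrame({"g": list(rng.permutation(["a"] * 10 + ["b"] * 10))},
                            index=ids)
        out = adonis(d, meta, ["g"], n_perm=199, seed=2)
        assert out.table.loc["g", "R2"] < 0.15
        assert out.table.loc["g", "p"] > 0.05

    def test_confounded_terms_rejected(self):
        rng = np.random.default_rng(10)
        ids = [str(i) for i in range(8)]
        d = _euclid_dm(rng.normal(size=(8, 2)), ids)
        meta = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4,
                             "h": ["a"] * 4 + ["b"] * 4}, index=ids)
        with pytest.raises(ValueError):
            adonis(d, meta, ["g", "h"], n_perm=0, seed=0)
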