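"""Replicate centering, PERMANOVA, LDA, trend arrow, band correlations."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from venomtherm import multivariate, synthdata
from venomtherm.multivariate import (
    band_trend_correlations,
    arrow_scores,
    center_within_replicates,
    centroid_trend_arrow,
    fit_lda,
    permanova,
)

from conftest import make_matrix


class TestCentering:
    def test_hand_example_four_rows(self):
        # replicate means 2 and 4, grand mean 3 -> shifts +1 / -1
        bm = make_matrix([[1.0], [3.0], [3.0], [5.0]],
                         [20.0, 25.0, 20.0, 25.0], ["r1", "r1", "r2", "r2"])
        out = center_within_replicates(bm)
        assert np.allclose(out.values.ravel(), [2.0, 4.0, 2.0, 4.0])

    def test_already_centered_unchanged(self):
        bm = make_matrix([[1.0, 5.0], [3.0, 7.0], [1.0, 5.0], [3.0, 7.0]],
                         [20.0, 25.0, 20.0, 25.0], ["r1", "r1", "r2", "r2"])
        out = center_within_replicates(bm)
        assert np.allclose(out.values, bm.values)

    def test_replicate_means_equal_grand_mean_exactly(self, default_band_sim):
        _, matrix, _ = default_band_sim
        out = center_within_replicates(matrix)
        grand = out.intensities.mean(axis=0)
        rep_means = out.intensities.groupby(out.meta["replicate"]).mean()
        assert np.max(np.abs(rep_means.to_numpy() - grand.to_numpy())) < 1e-12

    def test_within_replicate_deviations_unchanged(self, small_matrix):
        out = center_within_replicates(small_matrix)
        for rep, idx in small_matrix.meta.groupby("replicate").groups.items():
            before = small_matrix.intensities.loc[idx]
            after = out.intensities.loc[idx]
            assert np.allclose(before - before.mean(), after - after.mean())

    def test_centering_removes_replicate_signal_from_permanova(self):
        spec = synthdata.BandSimSpec(seed=21, replicate_sd=8.0)
        matrix, _ = synthdata.simulate_band_matrix(spec)
        centered = center_within_replicates(matrix)
        tab = permanova(centered, n_permutations=99, seed=0)
        assert tab.r2("replicate") < 0.02


class TestPermanova:
    def test_r2_partition_sums_to_one(self, default_band_sim):
        _, matrix, _ = default_band_sim
        tab = permanova(matrix, n_permutations=99, seed=1)
        r2 = tab.table["r2"]
        assert r2.loc[["temperature", "replicate", "Residual"]].sum() == \
            pytest.approx(1.0, abs=1e-9)
        p = tab.table.loc["temperature", "p_value"]
        assert 1.0 / 100.0 <= p <= 1.0

    def test_r2_deterministic_p_seed_dependent(self, default_band_sim):
        _, matrix, _ = default_band_sim
        t1 = permanova(matrix, n_permutations=199, seed=1)
        t2 = permanova(matrix, n_permutations=199, seed=2)
        assert np.allclose(t1.table["sum_sq"], t2.table["sum_sq"])
        assert np.allclose(t1.table["r2"], t2.table["r2"])

    def test_exhaustive_p_matches_brute_force_oracle(self):
        import itertools

        rng = np.random.default_rng(7)
        vals = rng.normal(size=(6, 3)) * 2 + 5
        bm = make_matrix(vals, [20.0] * 3 + [30.0] * 3, ["r1"] * 6)
        tab = permanova(bm, terms=("temperature",), n_permutations="exhaustive")

        y = vals - vals.mean(0)
        labels = np.array([0, 0, 0, 1, 1, 1])

        def f_stat(y, lab):
            sst = (y**2).sum()
            ssb = sum(len(y[lab == g]) * (y[lab == g].mean(0) ** 2).sum()
                      for g in (0, 1))
            return ssb / ((sst - ssb) / (len(y) - 2))

        f_obs = f_stat(y, labels)
        hits = sum(
            f_stat(y[list(p)], labels) >= f_obs - 1e-12
            for p in itertools.permutations(range(6))
        )
        assert tab.p_value("temperature") == pytest.approx(hits / 720)

    def test_one_way_pseudo_f_matches_skbio(self):
        pytest.importorskip("skbio")
        from scipy.spatial.distance import pdist, squareform
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(3)
        vals = rng.normal(size=(12, 5))
        bm = make_matrix(vals, np.repeat([20.0, 25.0, 30.0], 4), ["r1"] * 12)
        tab = permanova(bm, terms=("temperature",), n_permutations=99, seed=0)
        dm = DistanceMatrix(squareform(pdist(vals)),
                            ids=[f"i{k}" for k in range(12)])
        res = sk_permanova(dm, grouping=list(np.repeat(list("abc"), 4)),
                           permutations=9)
        assert tab.table.loc["temperature", "pseudo_f"] == \
            pytest.approx(res["test statistic"], rel=1e-10)

    def test_sequential_two_factor_matches_vegan_adonis2(self, tmp_path):
        spec = synthdata.BandSimSpec(
            seed=3, n_bands=8, n_replicates=3, n_per_cell=4,
            direct_bands=frozenset({1}), indirect_bands={2: 1},
            direct_signs={1: 1})
        matrix, _ = synthdata.simulate_band_matrix(spec)
        tab = permanova(matrix, n_permutations=99, seed=0)
        path = tmp_path / "m.csv"
        matrix.to_csv(path)
        r_code = f"""
        suppressMessages(library(vegan))
        d <- read.csv("{path}")
        Y <- as.matrix(d[, grep("^band_", names(d))])
        res <- adonis2(Y ~ factor(temperature) + factor(replicate), data=d,
                       method="euclidean", permutations=99, by="terms")
        cat(res$SumOfSqs[1:3], "\n")
        cat(res$F[1:2], "\n")
        """
        out = subprocess.run(["Rscript", "-e", r_code],
                             capture_output=True, text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        ss = [float(x) for x in out.stdout.splitlines()[0].split()]
        fs = [float(x) for x in out.stdout.splitlines()[1].split()]
        mine = tab.table
        assert mine.loc["temperature", "sum_sq"] == pytest.approx(ss[0])
        assert mine.loc["replicate", "sum_sq"] == pytest.approx(ss[1])
        assert mine.loc["Residual", "sum_sq"] == pytest.approx(ss[2])
        assert mine.loc["temperature", "pseudo_f"] == pytest.approx(fs[0])
        assert mine.loc["replicate", "pseudo_f"] == pytest.approx(fs[1])

    def test_constant_matrix_rejected(self):
        bm = make_matrix(np.full((6, 3), 2.0), [20.0] * 3 + [30.0] * 3,
                         ["r1"] * 6)
        with pytest.raises(ValueError, match="constant"):
            permanova(bm, terms=("temperature",), n_permutations=99)

    def test_minimum_permutation_count_enforced(self, small_matrix):
        with pytest.raises(ValueError, match="at least 99"):
            permanova(small_matrix, n_permutations=10)


class TestLDA:
    def test_separation_along_first_band_gives_axis_e1(self):
        rng = np.random.default_rng(0)
        n = 200
        band1 = np.concatenate([rng.normal(0, 1, n), rng.normal(8, 1, n)])
        band2 = rng.normal(0, 1, 2 * n)
        bm = make_matrix(np.column_stack([band1, band2]),
                         [20.0] * n + [30.0] * n, ["r1"] * (2 * n))
        res = fit_lda(bm)
        axis = res.axes["LD1"].to_numpy()
        assert abs(axis[0]) > 0.99
        assert abs(axis[1]) < 0.15

    def test_axes_match_generalized_eigen_oracle(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=(30, 5)) + np.repeat(
            rng.normal(0, 2, size=(3, 5)), 10, axis=0)
        bm = make_matrix(vals, np.repeat([20.0, 25.0, 30.0], 10), ["r1"] * 30)
        res = fit_lda(bm, ridge=1e-8)

        # oracle: explicit inv(Sw) Sb eigendecomposition
        X = vals
        levels = np.repeat([0, 1, 2], 10)
        grand = X.mean(0)
        Sw = np.zeros((5, 5))
        Sb = np.zeros((5, 5))
        for g in range(3):
            sub = X[levels == g]
            mu = sub.mean(0)
            Sw += (sub - mu).T @ (sub - mu)
            Sb += len(sub) * np.outer(mu - grand, mu - grand)
        Sw_r = Sw + 1e-8 * np.trace(Sw) * np.eye(5)
        w, v = np.linalg.eig(np.linalg.inv(Sw_r) @ Sb)
        order = np.argsort(w.real)[::-1][:2]
        for j, col in enumerate(order):
            oracle = v[:, col].real
            oracle /= np.linalg.norm(oracle)
            mine = res.axes.iloc[:, j].to_numpy()
            assert abs(abs(oracle @ mine) - 1.0) < 1e-8
            crit_mine = (mine @ Sb @ mine) / (mine @ Sw_r @ mine)
            crit_oracle = (oracle @ Sb @ oracle) / (oracle @ Sw_r @ oracle)
            assert crit_mine == pytest.approx(crit_oracle, abs=1e-8)

    def test_scores_invariant_to_band_shift(self, small_matrix):
        res1 = fit_lda(small_matrix)
        shifted = small_matrix.with_intensities(small_matrix.values + 100.0)
        res2 = fit_lda(shifted)
        assert np.allclose(res1.scores.to_numpy(), res2.scores.to_numpy(),
                           atol=1e-8)

    def test_singular_scatter_without_ridge_names_the_option(self):
        vals = np.zeros((9, 3))
        vals[:, 0] = np.random.default_rng(1).normal(size=9)
        vals[:, 1] = vals[:, 0]  # duplicated band -> singular scatter
        bm = make_matrix(vals, np.repeat([20.0, 25.0, 30.0], 3), ["r1"] * 9)
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            fit_lda(bm, ridge=None)

    def test_three_groups_give_two_axes_and_ordered_centroids(
            self, default_band_sim):
        _, matrix, _ = default_band_sim
        res = fit_lda(matrix)
        assert res.axes.shape[1] == 2
        assert list(res.centroids.index) == [20.0, 25.0, 30.0]

    def test_strong_groups_are_disjoint_in_score_space(self):
        pytest.importorskip("shapely")
        from shapely.geometry import MultiPoint

        spec = synthdata.BandSimSpec(seed=5, effect_size=8.0, noise_sd=4.0)
        matrix, _ = synthdata.simulate_band_matrix(spec)
        res = fit_lda(center_within_replicates(matrix))
        hulls = []
        temps = matrix.meta["temperature"].to_numpy()
        for t in (20.0, 25.0, 30.0):
            pts = res.scores.to_numpy()[temps == t]
            hulls.append(MultiPoint([tuple(p) for p in pts]).convex_hull)
        for i in range(3):
            for j in range(i + 1, 3):
                assert hulls[i].intersection(hulls[j]).area == pytest.approx(0.0)


class TestTrendArrow:
    def make_centroids(self, pts):
        return pd.DataFrame(pts, index=[20.0, 25.0, 30.0],
                            columns=["LD1", "LD2"])

    def test_hand_ols_three_points(self):
        # symmetric points: slope 0, intercept = mean of the y values = 1/3
        arrow = centroid_trend_arrow(
            self.make_centroids([(0.0, 0.0), (1.0, 1.0), (2.0, 0.0)]))
        assert arrow.slope == pytest.approx(0.0, abs=1e-12)
        assert arrow.intercept == pytest.approx(1.0 / 3.0)

    def test_identity_line_direction(self):
        arrow = centroid_trend_arrow(
            self.make_centroids([(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)]))
        assert np.allclose(arrow.direction, [np.sqrt(2) / 2, np.sqrt(2) / 2])

    def test_collinear_centroids_have_zero_residuals(self):
        c = self.make_centroids([(0.0, 1.0), (1.0, 3.0), (2.0, 5.0)])
        arrow = centroid_trend_arrow(c)
        fitted = arrow.slope * c["LD1"] + arrow.intercept
        assert np.allclose(fitted, c["LD2"])

    def test_orientation_toward_warm_centroid(self):
        arrow = centroid_trend_arrow(
            self.make_centroids([(2.0, 2.0), (1.0, 1.0), (0.0, 0.0)]))
        assert arrow.direction @ np.array([-1.0, -1.0]) > 0

    def test_coincident_centroids_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            centroid_trend_arrow(
                self.make_centroids([(1.0, 1.0)] * 3))


class TestBandTrendCorrelations:
    def test_band_equal_to_score_has_rho_one(self, default_band_sim):
        _, matrix, _ = default_band_sim
        res = fit_lda(matrix)
        arrow = centroid_trend_arrow(res.centroids)
        proj = arrow_scores(res.scores, arrow)
        vals = matrix.intensities.copy()
        vals["band_0"] = proj.to_numpy()
        rigged = matrix.with_intensities(vals)
        table = band_trend_correlations(rigged, arrow, res.scores)
        assert table.loc["band_0", "rho"] == pytest.approx(1.0)

    def test_constant_band_flagged_not_candidate(self, default_band_sim):
        _, matrix, _ = default_band_sim
        res = fit_lda(matrix)
        arrow = centroid_trend_arrow(res.centroids)
        vals = matrix.intensities.copy()
        vals["band_1"] = 7.0
        rigged = matrix.with_intensities(vals)
        table = band_trend_correlations(rigged, arrow, res.scores)
        assert not table.loc["band_1", "defined"]
        assert not table.loc["band_1", "candidate"]

    def test_hand_spearman_value(self):
        # two swapped neighbour pairs: sum d^2 = 4, rho = 1 - 24/120 = 0.8
        rho = stats.spearmanr([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]).statistic
        assert rho == pytest.approx(0.8)

    def test_bonferroni_is_min_one_p_times_n_bands(self, default_band_sim):
        _, matrix, _ = default_band_sim
        res = fit_lda(matrix)
        arrow = centroid_trend_arrow(res.centroids)
        table = band_trend_correlations(matrix, arrow, res.scores)
        ok = table["defined"]
        expected = np.minimum(1.0, table.loc[ok, "p_value"] * matrix.n_bands)
        assert np.allclose(table.loc[ok, "p_bonferroni"], expected)
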