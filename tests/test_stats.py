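"""Unit and property tests of the self-implemented statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from reefexo.stats import (angular_zscore_transform, bh_fdr, congruency_r2,
                           dunnett_many_to_one, dunnett_sf, linear_fit,
                           one_way_anova, pairwise_permanova, pcoa, permanova,
                           tukey_hsd)

# ---------------------------------------------------------------- ANOVA


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        a = one_way_anova([np.array([1., 2., 3.]), np.array([1., 2., 3.])])
        assert a.F == 0.0 and a.p == 1.0

    def test_zero_total_variance_is_degenerate(self):
        a = one_way_anova([np.ones(3), np.ones(4)])
        assert a.degenerate and a.p == 1.0

    def test_two_groups_f_equals_t_squared(self, rng):
        x, y = rng.normal(0, 1, 6), rng.normal(1, 1, 8)
        a = one_way_anova([x, y])
        t, p = sps.ttest_ind(x, y)
        assert a.F == pytest.approx(t**2, rel=1e-10)
        assert a.p == pytest.approx(p, rel=1e-10)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(i * 0.5, 1.0, 5) for i in range(3)]
        a = one_way_anova(groups)
        F, p = sps.f_oneway(*groups)
        assert a.F == pytest.approx(F, rel=1e-10)
        assert a.p == pytest.approx(p, rel=1e-10)


# ---------------------------------------------------------------- Dunnett


class TestDunnett:
    def test_single_comparison_reduces_to_pooled_t(self, rng):
        """With one treatment group the family adjustment is void."""
        c, t1 = rng.normal(0, 1, 5), rng.normal(0.8, 1, 5)
        res = dunnett_many_to_one(c, [t1], sided="two-sided")
        _, p_ref = sps.ttest_ind(t1, c)
        assert res.pvalues[0] == pytest.approx(p_ref, abs=1e-6)

    def test_large_t_gives_tiny_family_p(self):
        c = np.array([0., 0.1, -0.1, 0.05])
        ts = [c + 10.0, c + 10.5]
        res = dunnett_many_to_one(c, ts)
        assert np.all(res.pvalues < 1e-4)

    @pytest.mark.parametrize("sided", ["greater", "two-sided"])
    def test_matches_scipy_dunnett(self, rng, sided):
        """Independent oracle: scipy's QMC implementation (tol ~1e-3)."""
        c = rng.normal(0, 1, 6)
        ts = [rng.normal(0.4 * i, 1, 6) for i in range(1, 5)]
        res = dunnett_many_to_one(c, ts, sided=sided)
        alt = {"greater": "greater", "two-sided": "two-sided"}[sided]
        ref = sps.dunnett(*ts, control=c, alternative=alt)
        assert np.allclose(res.pvalues, ref.pvalue, atol=2e-3)

    def test_adjusted_p_not_below_unadjusted(self, rng):
        c = rng.normal(0, 1, 4)
        ts = [rng.normal(0.5, 1, 4) for _ in range(3)]
        res = dunnett_many_to_one(c, ts, sided="greater")
        raw = sps.t.sf(res.tstats, res.df)
        assert np.all(res.pvalues >= raw - 1e-12)

    def test_monte_carlo_max_t_oracle(self):
        """k=3 balanced: quadrature matches a 2e5-draw max-T simulation."""
        k, n, df = 3, 3, 20
        rng = np.random.default_rng(7)
        z0 = rng.normal(size=200_000)
        zi = rng.normal(size=(200_000, k))
        s = np.sqrt(rng.chisquare(df, size=200_000) / df)
        b = np.sqrt(n / (n + n))
        tmax = ((b * z0[:, None] + np.sqrt(1 - b**2) * zi) / s[:, None]).max(axis=1)
        for t_obs in (1.5, 2.5):
            p_mc = (tmax > t_obs).mean()
            p_quad = dunnett_sf(np.array([t_obs] * k), [n] * k, n, df)[0]
            se = np.sqrt(p_mc * (1 - p_mc) / 200_000)
            assert abs(p_quad - p_mc) < 4 * se

    def test_interpolated_batch_agrees_with_direct(self, rng):
        t = rng.normal(1.0, 1.5, 2000)
        direct = dunnett_sf(t[:100], [3] * 5, 3, 12)
        batch = dunnett_sf(t, [3] * 5, 3, 12)[:100]
        assert np.allclose(direct, batch, atol=1e-5)


# ---------------------------------------------------------------- Tukey


class TestTukey:
    def test_identical_groups_share_one_letter(self):
        g = [np.array([1., 2., 3.])] * 3
        res = tukey_hsd(g)
        assert np.allclose(res.pvalues, 1.0)
        assert len(set(res.letters)) == 1

    def test_two_groups_equal_pooled_t(self, rng):
        """Studentized range with k=2 collapses to |t|*sqrt(2)."""
        x, y = rng.normal(0, 1, 5), rng.normal(1.0, 1, 5)
        res = tukey_hsd([x, y])
        _, p_ref = sps.ttest_ind(x, y)
        assert res.pvalues[0, 1] == pytest.approx(p_ref, abs=1e-6)

    def test_matches_scipy_tukey(self, rng):
        groups = [rng.normal(m, 1.0, 4) for m in (0, 0.5, 2.5)]
        res = tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups)
        assert np.allclose(res.pvalues, ref.pvalue, atol=1e-8)

    def test_separated_groups_get_distinct_letters(self, rng):
        groups = [rng.normal(m, 0.1, 5) for m in (0.0, 5.0, 10.0)]
        res = tukey_hsd(groups)
        assert len({l for l in res.letters}) == 3


# ---------------------------------------------------------------- BH FDR


class TestBH:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_and_equal_p_unchanged(self):
        assert bh_fdr([0.2])[0] == 0.2
        assert np.allclose(bh_fdr([0.3, 0.3, 0.3]), 0.3)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(0, 1, 200)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(p), ref, atol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_monotone_and_dominates_raw(self, ps):
        p = np.array(ps)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)


# ---------------------------------------------------------------- transform


class TestAngularZ:
    def test_known_arcsine_values(self):
        y = np.arcsin(np.sqrt(np.array([0.0, 0.5, 1.0])))
        assert np.allclose(y, [0.0, np.pi / 4, np.pi / 2])

    def test_rows_standardized(self, rng):
        x = rng.uniform(0, 1, (10, 8))
        z = angular_zscore_transform(x)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_constant_row_warns_and_zeroes(self):
        x = np.vstack([np.full(5, 0.3), np.linspace(0.1, 0.9, 5)])
        with pytest.warns(UserWarning):
            z = angular_zscore_transform(x)
        assert np.all(z[0] == 0.0)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            angular_zscore_transform(np.array([[0.5, 1.2]]))


# ---------------------------------------------------------------- PCoA


class TestPcoa:
    def test_recovers_euclidean_configuration(self, rng):
        pts = rng.normal(size=(12, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(d)
        # Procrustes: recovered configuration matches up to rotation
        from scipy.spatial import procrustes
        _, _, disparity = procrustes(pts, res.coordinates[:, :2])
        assert disparity < 1e-12
        assert np.all(res.eigenvalues[:2] > 0)

    def test_collinear_points_have_one_axis(self):
        x = np.array([[0.], [1.], [2.]])
        d = np.abs(x - x.T)
        res = pcoa(d)
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)

    def test_duplicate_points_identical_coordinates(self):
        d = np.array([[0., 0., 1.], [0., 0., 1.], [1., 1., 0.]])
        res = pcoa(d)
        assert np.allclose(res.coordinates[0], res.coordinates[1])

    def test_asymmetric_raises(self):
        with pytest.raises(ValueError):
            pcoa(np.array([[0., 1.], [2., 0.]]))

    def test_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.normal(size=(10, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        res = pcoa(d)
        assert np.allclose(np.sort(res.eigenvalues[res.eigenvalues > 1e-9]),
                           np.sort(ref.eigvals.values[ref.eigvals.values > 1e-9]),
                           atol=1e-8)


# ---------------------------------------------------------------- PERMANOVA


def _two_cluster_distance(n_per=4, sep=1.0):
    labels = np.array(["A"] * n_per + ["B"] * n_per)
    d = np.zeros((2 * n_per, 2 * n_per))
    d[:n_per, n_per:] = sep
    d[n_per:, :n_per] = sep
    return d, labels


class TestPermanova:
    def test_duplicated_clusters_r2_one(self):
        d, labels = _two_cluster_distance()
        res = permanova(d, labels, n_perm=99, seed=0)
        assert res.r2[0] == pytest.approx(1.0, abs=1e-9)
        # minimal p up to permutation ties: partition-preserving
        # relabelings of duplicated points reproduce the statistic
        assert res.p[0] >= 1.0 / 100.0
        assert res.p[0] <= 0.06

    def test_r2_sums_to_one(self, rng):
        pts = rng.normal(size=(24, 5))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        trt = np.repeat(["a", "b", "c"], 8)
        diel = np.tile(np.repeat(["D", "N"], 4), 3)
        res = permanova(d, trt, diel, n_perm=99, seed=1)
        assert res.r2.sum() + res.residual_r2 == pytest.approx(1.0, abs=1e-9)

    def test_p_invariant_to_sample_reordering(self, rng):
        pts = rng.normal(size=(12, 3))
        pts[:6] += 1.0
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = np.array(["x"] * 6 + ["y"] * 6)
        res1 = permanova(d, labels, n_perm=199, seed=3)
        perm = rng.permutation(12)
        res2 = permanova(d[np.ix_(perm, perm)], labels[perm], n_perm=199, seed=3)
        assert res1.r2[0] == pytest.approx(res2.r2[0], abs=1e-9)
        # same permutation distribution up to the generator stream
        assert abs(res1.p[0] - res2.p[0]) <= 0.05

    def test_one_factor_matches_skbio_pseudo_f(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.normal(size=(15, 4))
        pts[:5] += 0.8
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = np.repeat(["a", "b", "c"], 5)
        res = permanova(d, labels, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(skbio.DistanceMatrix(d), labels,
                                             permutations=99)
        assert res.pseudo_f[0] == pytest.approx(ref["test statistic"], rel=1e-8)

    def test_single_level_factor_raises(self):
        d, _ = _two_cluster_distance()
        with pytest.raises(ValueError):
            permanova(d, np.array(["A"] * 8), n_perm=99)

    def test_pairwise_reports_adjusted_p(self, rng):
        pts = rng.normal(size=(18, 3))
        pts[:6] += 3.0
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = np.repeat(["a", "b", "c"], 6)
        rows = pairwise_permanova(d, labels, n_perm=99, seed=0)
        assert len(rows) == 3
        for r in rows:
            assert r["p_adjusted"] >= r["p"] - 1e-12


# ---------------------------------------------------------------- OLS


class TestLinearFit:
    def test_exact_line(self):
        fit = linear_fit([0, 1, 2, 3], [0, 2, 4, 6])
        assert fit.slope == pytest.approx(2.0) and fit.r2 == pytest.approx(1.0)

    def test_three_point_hand_least_squares(self):
        fit = linear_fit([0, 1, 2], [0, 1, 4])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(-1.0 / 3.0)

    def test_zero_x_variance_raises(self):
        with pytest.raises(ValueError):
            linear_fit([1, 1, 1], [0, 1, 2])

    def test_matches_scipy_linregress(self, rng):
        x = rng.normal(size=30)
        y = 1.5 * x + rng.normal(size=30)
        fit = linear_fit(x, y)
        ref = sps.linregress(x, y)
        assert fit.slope == pytest.approx(ref.slope, rel=1e-10)
        assert fit.p == pytest.approx(ref.pvalue, rel=1e-8)


# ---------------------------------------------------------------- congruency


class TestCongruency:
    def test_perfect_mapping_gives_one(self):
        cat = np.repeat(["a", "b", "c"], 10)
        assert congruency_r2(cat, cat).r2 == pytest.approx(1.0)

    def test_closed_form_2x2_diagonal(self):
        cat = np.array(["x"] * 10 + ["y"] * 10)
        res = congruency_r2(cat, cat)
        assert res.g2 == pytest.approx(2 * 20 * np.log(2), rel=1e-12)
        assert res.r2 == pytest.approx(1.0)

    def test_independent_labels_near_zero(self, rng):
        cat = rng.choice(list("abcd"), 10_000)
        cls = rng.choice(list("wxyz"), 10_000)
        assert congruency_r2(cat, cls).r2 < 0.02

    def test_chi2_p_matches_scipy_lr(self, rng):
        import pandas as pd
        cat = rng.choice(list("ab"), 200)
        cls = rng.choice(list("xyz"), 200)
        res = congruency_r2(cat, cls)
        table = pd.crosstab(pd.Series(cat), pd.Series(cls)).to_numpy()
        g2_ref, p_ref, _, _ = sps.chi2_contingency(table, correction=False,
                                                   lambda_="log-likelihood")
        assert res.g2 == pytest.approx(g2_ref, rel=1e-10)
        assert res.p == pytest.approx(p_ref, rel=1e-8)

    def test_single_level_raises(self):
        with pytest.raises(ValueError):
            congruency_r2(["a"] * 5, ["x", "y", "x", "y", "x"])
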