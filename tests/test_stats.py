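import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from microgeo.formats import DistanceMatrix, ValidationError
from microgeo.stats import (correlate, distance_decay, group_compare, mantel,
                            order_terms_by_marginal_r2, permanova_sequential)


def euclid_dm(x, ids=None):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(2))
    ids = ids or [f"s{i}" for i in range(len(x))]
    return DistanceMatrix(ids, d)


class TestPermanova:
    def test_matches_classical_anova_on_univariate_data(self):
        y = np.array([1.2, 0.8, 1.5, 0.9, 3.1, 2.9, 3.4, 2.7, 3.0, 3.3])
        g = pd.Series(["a"] * 4 + ["b"] * 6)
        dm = euclid_dm(y)
        tab = permanova_sequential(dm, pd.DataFrame({"g": g.values},
                                                    index=dm.ids),
                                   n_perm=99, seed=0)
        f_classic = sps.f_oneway(y[:4], y[4:]).statistic
        assert tab.pseudo_f["g"] == pytest.approx(f_classic, rel=1e-10)
        # SS decomposition matches ANOVA exactly
        ss_total = ((y - y.mean()) ** 2).sum()
        assert tab.sum_of_squares["Total"] == pytest.approx(ss_total)

    def test_anova_equivalence_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(8, 15))
            y = rng.normal(size=n)
            g = rng.choice(["a", "b"], size=n)
            if len(set(g)) < 2 or min((g == "a").sum(), (g == "b").sum()) < 2:
                continue
            dm = euclid_dm(y)
            tab = permanova_sequential(dm, pd.DataFrame({"g": g}, index=dm.ids),
                                       n_perm=1, seed=0)
            f = sps.f_oneway(y[g == "a"], y[g == "b"]).statistic
            assert tab.pseudo_f["g"] == pytest.approx(f, rel=1e-8)

    def test_r2_decomposition_sums_to_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 4))
        dm = euclid_dm(x)
        cov = pd.DataFrame({"a": rng.normal(size=20),
                            "b": rng.choice(["u", "v", "w"], 20)},
                           index=dm.ids)
        tab = permanova_sequential(dm, cov, n_perm=19, seed=0)
        total = sum(tab.r_squared[t] for t in tab.terms) + tab.r_squared["Residual"]
        assert total == pytest.approx(1.0, abs=1e-8)
        ss = sum(tab.sum_of_squares[t] for t in tab.terms) \
            + tab.sum_of_squares["Residual"]
        assert ss == pytest.approx(tab.sum_of_squares["Total"], rel=1e-8)

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=15)
        dm = euclid_dm(rng.normal(size=(15, 3)))
        cov = pd.DataFrame({"a": a, "b": 2 * a + 1}, index=dm.ids)
        with pytest.raises(ValidationError, match=r"'b' is collinear with 'a'"):
            permanova_sequential(dm, cov, n_perm=9, seed=0)

    def test_matches_skbio_one_way(self):
        """Cross-check single-factor pseudo-F against an independent package."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as skbio_permanova
        rng = np.random.default_rng(3)
        x = rng.normal(size=(18, 3))
        g = rng.choice(["p", "q"], 18)
        dm = euclid_dm(x)
        tab = permanova_sequential(dm, pd.DataFrame({"g": g}, index=dm.ids),
                                   n_perm=9, seed=0)
        sk = skbio_permanova(skbio.DistanceMatrix(dm.d, ids=dm.ids),
                             grouping=g, permutations=9)
        assert tab.pseudo_f["g"] == pytest.approx(sk["test statistic"],
                                                  rel=1e-8)

    def test_permutation_p_deterministic_and_valid(self):
        rng = np.random.default_rng(4)
        dm = euclid_dm(rng.normal(size=(16, 2)))
        cov = pd.DataFrame({"x": rng.normal(size=16)}, index=dm.ids)
        t1 = permanova_sequential(dm, cov, n_perm=49, seed=9)
        t2 = permanova_sequential(dm, cov, n_perm=49, seed=9)
        assert t1.p_value == t2.p_value
        assert 0 < t1.p_value["x"] <= 1

    def test_n_perm_zero_rejected(self):
        dm = euclid_dm(np.arange(5.0))
        cov = pd.DataFrame({"x": np.arange(5.0)}, index=dm.ids)
        with pytest.raises(ValidationError):
            permanova_sequential(dm, cov, n_perm=0)


class TestOrderTerms:
    def test_signal_candidate_ordered_first(self):
        rng = np.random.default_rng(5)
        signal = rng.normal(size=40)
        dm = euclid_dm(signal + 0.2 * rng.normal(size=40))
        cov = pd.DataFrame({
            "geo": rng.normal(size=40),
            "signal": signal,
            "noise": rng.normal(size=40),
        }, index=dm.ids)
        order = order_terms_by_marginal_r2(dm, "geo", ["noise", "signal"], cov)
        assert order == ["geo", "signal", "noise"]

    def test_single_candidate(self):
        rng = np.random.default_rng(6)
        dm = euclid_dm(rng.normal(size=12))
        cov = pd.DataFrame({"geo": rng.normal(size=12),
                            "x": rng.normal(size=12)}, index=dm.ids)
        assert order_terms_by_marginal_r2(dm, "geo", ["x"], cov) == ["geo", "x"]

    def test_identical_candidates_tie_broken_by_name(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=12)
        dm = euclid_dm(rng.normal(size=12))
        cov = pd.DataFrame({"geo": rng.normal(size=12), "zz": x, "aa": x.copy()},
                           index=dm.ids)
        order = order_terms_by_marginal_r2(dm, "geo", ["zz", "aa"], cov)
        assert order == ["geo", "aa", "zz"]


class TestMantel:
    def test_self_correlation_one(self):
        rng = np.random.default_rng(8)
        dm = euclid_dm(rng.normal(size=(12, 2)))
        res = mantel(dm, dm, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        dm = euclid_dm(rng.normal(size=(10, 2)))
        d2 = DistanceMatrix(dm.ids, 3.0 * dm.d + 0.5 * (dm.d > 0), "affine")
        res = mantel(dm, d2, n_perm=9, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-10)

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import mantel as skbio_mantel
        rng = np.random.default_rng(10)
        d1 = euclid_dm(rng.normal(size=(14, 2)))
        d2 = euclid_dm(rng.normal(size=(14, 2)), ids=d1.ids)
        r_mine = mantel(d1, d2, n_perm=9, seed=0).r
        r_sk, _, _ = skbio_mantel(skbio.DistanceMatrix(d1.d, ids=d1.ids),
                                  skbio.DistanceMatrix(d2.d, ids=d2.ids),
                                  permutations=0)
        assert r_mine == pytest.approx(r_sk, rel=1e-10)

    def test_constant_triangle_rejected(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(list("abcd"), d)
        with pytest.raises(ValidationError, match="constant"):
            mantel(dm, dm, n_perm=9)

    def test_mismatched_ids_rejected(self):
        rng = np.random.default_rng(11)
        d1 = euclid_dm(rng.normal(size=6))
        d2 = euclid_dm(rng.normal(size=6), ids=[f"t{i}" for i in range(6)])
        with pytest.raises(ValidationError, match="matching ids"):
            mantel(d1, d2)


class TestDistanceDecay:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(12)
        pos = rng.uniform(0, 1000, 20)
        geo = euclid_dm(pos)
        c = 2.5e-4
        d = DistanceMatrix(geo.ids, c * geo.d, "scaled")
        transects = pd.Series(["T0"] * 10 + ["T1"] * 10, index=geo.ids)
        res = distance_decay(d, geo, transects)
        assert res.slope_overall == pytest.approx(c, rel=1e-10)
        assert res.intercept_overall == pytest.approx(0.0, abs=1e-12)
        assert res.n_pairs_overall == res.n_pairs_within + res.n_pairs_between

    def test_stratified_slopes_recovered(self):
        """Planted within-transect slope 2c and between-transect slope c."""
        rng = np.random.default_rng(13)
        n = 40
        pos = rng.uniform(0, 1000, n)
        transects = pd.Series(np.repeat(["T0", "T1"], n // 2))
        geo = euclid_dm(pos)
        transects.index = geo.ids
        c = 1e-3
        t = transects.to_numpy()
        same = t[:, None] == t[None, :]
        d = np.where(same, 2 * c * geo.d, c * geo.d)
        np.fill_diagonal(d, 0.0)
        d += rng.normal(0, 0.005, d.shape)
        d = np.abs((d + d.T) / 2)
        np.fill_diagonal(d, 0.0)
        res = distance_decay(DistanceMatrix(geo.ids, d), geo, transects)
        assert res.slope_within == pytest.approx(2 * c, rel=0.1)
        assert res.slope_between == pytest.approx(c, rel=0.1)

    def test_small_stratum_gives_nan(self):
        rng = np.random.default_rng(14)
        geo = euclid_dm(rng.uniform(0, 10, 4))
        d = DistanceMatrix(geo.ids, geo.d * 0.1)
        transects = pd.Series(["T0", "T1", "T2", "T3"], index=geo.ids)
        res = distance_decay(d, geo, transects)
        assert np.isnan(res.slope_within)  # zero same-transect pairs
        assert res.n_pairs_within == 0


class TestGroupCompareAndCorrelate:
    def test_identical_groups_t_zero_p_one(self):
        v = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        lab = pd.Series(["a"] * 3 + ["b"] * 3)
        t, df, p = group_compare(v, lab)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_welch_formula_oracle(self):
        a = np.array([1.1, 2.3, 0.8, 1.9])
        b = np.array([3.2, 4.1, 3.8, 2.9])
        v = pd.Series(np.concatenate([a, b]))
        lab = pd.Series(["x"] * 4 + ["y"] * 4)
        t, df, p = group_compare(v, lab)
        va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va ** 2 / 3 + vb ** 2 / 3)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert df == pytest.approx(df_hand, rel=1e-12)

    def test_small_group_rejected(self):
        v = pd.Series([1.0, 2.0, 3.0])
        lab = pd.Series(["a", "b", "b"])
        with pytest.raises(ValidationError):
            group_compare(v, lab)

    def test_spearman_monotone_map(self):
        rho, _ = correlate([1, 2, 3], [1, 4, 9], method="spearman")
        assert rho == pytest.approx(1.0)

    def test_pearson_matches_scipy(self):
        rng = np.random.default_rng(15)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r, p = correlate(x, y, method="pearson")
        r_sp, p_sp = sps.pearsonr(x, y)
        assert (r, p) == (pytest.approx(r_sp), pytest.approx(p_sp))

    def test_missing_values_rejected(self):
        with pytest.raises(ValidationError):
            correlate([1.0, np.nan], [1.0, 2.0])
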