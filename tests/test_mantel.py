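import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import envscan
from conftest import random_distance_matrix
from envscan import mantel
from envscan.distances import DistanceMatrix


LABELS6 = [f"p{i}" for i in range(6)]


def residual_partial_oracle(Y, X, Z):
    """Independent oracle: correlate the OLS residuals of Y~Z and X~Z over
    the triangle entries."""
    iu = np.triu_indices(len(Y.labels), k=1)
    y, x, z = Y.values[iu], X.values[iu], Z.values[iu]

    def resid(a):
        d = np.column_stack([np.ones_like(z), z])
        return a - d @ np.linalg.lstsq(d, a, rcond=None)[0]

    rp = np.corrcoef(resid(y), resid(x))[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    return rp, (1 - r_yz ** 2) * rp ** 2


class TestMantelR:
    def test_self_correlation_is_one(self, rng):
        A = random_distance_matrix(5, LABELS6[:5], rng)
        assert mantel.mantel_r(A, A) == pytest.approx(1.0)

    def test_affine_rescaling_is_one(self, rng):
        A = random_distance_matrix(5, LABELS6[:5], rng)
        B = DistanceMatrix(A.labels, 2.5 * A.values)
        assert mantel.mantel_r(A, B) == pytest.approx(1.0)

    def test_matches_direct_pearson_over_pairs(self, rng):
        A = random_distance_matrix(4, LABELS6[:4], rng)
        B = random_distance_matrix(4, LABELS6[:4], rng)
        iu = np.triu_indices(4, 1)
        expect = np.corrcoef(A.values[iu], B.values[iu])[0, 1]
        assert mantel.mantel_r(A, B) == pytest.approx(expect, abs=1e-12)

    def test_degenerate_matrix_rejected(self):
        A = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        with pytest.raises(ValueError, match="degenerate"):
            mantel.mantel_r(A, A)


class TestPartialMantel:
    def test_matches_residual_oracle(self, rng):
        for _ in range(200):
            Y = random_distance_matrix(6, LABELS6, rng)
            X = random_distance_matrix(6, LABELS6, rng)
            Z = random_distance_matrix(6, LABELS6, rng)
            rp, r2, ir2 = mantel.partial_mantel(Y, X, Z)
            rp_o, ir2_o = residual_partial_oracle(Y, X, Z)
            assert rp == pytest.approx(rp_o, abs=1e-10)
            assert ir2 == pytest.approx(ir2_o, abs=1e-10)
            assert ir2 == pytest.approx(r2 - mantel.mantel_r(Y, Z) ** 2,
                                        abs=1e-12)
            assert 0.0 <= ir2 <= 1.0 - mantel.mantel_r(Y, Z) ** 2 + 1e-12

    def test_exact_collinearity_rejected(self, rng):
        Y = random_distance_matrix(6, LABELS6, rng)
        X = random_distance_matrix(6, LABELS6, rng)
        with pytest.raises(ValueError, match="collinearity"):
            mantel.partial_mantel(Y, X, X)

    def test_affine_invariance_of_i_r2(self, rng):
        Y = random_distance_matrix(6, LABELS6, rng)
        X = random_distance_matrix(6, LABELS6, rng)
        Z = random_distance_matrix(6, LABELS6, rng)
        base = mantel.partial_mantel(Y, X, Z)[2]
        X2 = DistanceMatrix(X.labels, 3.0 * X.values)
        assert mantel.partial_mantel(Y, X2, Z)[2] == pytest.approx(
            base, abs=1e-12)


class TestStratifiedPermutations:
    def test_invariant_y_gives_p_one(self, rng):
        # Y depends only on the continent pair: every within-stratum
        # permutation leaves it unchanged
        strata = pd.Series(["A"] * 3 + ["B"] * 3, index=LABELS6)
        block = np.array([[0.0, 1.0], [1.0, 0.0]])
        cont = np.repeat([0, 1], 3)
        Y = DistanceMatrix(LABELS6, block[np.ix_(cont, cont)]
                           * (1 - np.eye(6)))
        X = random_distance_matrix(6, LABELS6, rng)
        Z = random_distance_matrix(6, LABELS6, rng)
        p, _, _ = mantel.stratified_perm_p(Y, X, Z, strata, n_perm=200, seed=0)
        assert p == 1.0

    def test_monte_carlo_matches_exhaustive_enumeration(self, rng):
        strata = pd.Series(["A"] * 3 + ["B"] * 3, index=LABELS6)
        Y = random_distance_matrix(6, LABELS6, rng)
        X = random_distance_matrix(6, LABELS6, rng)
        Z = random_distance_matrix(6, LABELS6, rng)
        p_mc, _, obs = mantel.stratified_perm_p(Y, X, Z, strata,
                                                n_perm=5000, seed=3)
        iu = np.triu_indices(6, 1)
        x, z = X.values[iu], Z.values[iu]
        r_xz = np.corrcoef(x, z)[0, 1]
        stats_all = []
        for pa in itertools.permutations(range(3)):
            for pb in itertools.permutations(range(3, 6)):
                ix = np.array(pa + pb)
                y = Y.values[np.ix_(ix, ix)][iu]
                r_xy = np.corrcoef(y, x)[0, 1]
                r_yz = np.corrcoef(y, z)[0, 1]
                rp = (r_xy - r_xz * r_yz) / np.sqrt(
                    (1 - r_xz ** 2) * (1 - r_yz ** 2))
                stats_all.append((1 - r_yz ** 2) * rp ** 2)
        p_exact = np.mean(np.asarray(stats_all) >= obs - 1e-15)
        sd = np.sqrt(p_exact * (1 - p_exact) / 5000)
        assert abs(p_mc - p_exact) <= max(2.6 * sd, 2.0 / 5000)

    def test_all_singleton_strata_rejected(self, rng):
        strata = pd.Series(list("ABCDEF"), index=LABELS6)
        Y = random_distance_matrix(6, LABELS6, rng)
        with pytest.raises(ValueError, match="no permutable structure"):
            mantel.stratified_perm_p(Y, Y, random_distance_matrix(
                6, LABELS6, rng), strata, n_perm=100, seed=0)

    def test_permutations_stay_within_strata(self, rng):
        codes = np.array([0, 0, 0, 1, 1, 2, 2, 2])
        ix = mantel.stratified_permutations(codes, 500, rng)
        for s in range(3):
            pos = np.flatnonzero(codes == s)
            assert (np.sort(ix[:, pos], axis=1) == pos).all()

    def test_too_few_permutations_rejected(self, rng):
        strata = pd.Series(["A"] * 3 + ["B"] * 3, index=LABELS6)
        Y = random_distance_matrix(6, LABELS6, rng)
        with pytest.raises(ValueError, match="n_perm"):
            mantel.stratified_perm_p(Y, Y, Y, strata, n_perm=10, seed=0)


class TestGPD:
    def test_bypass_returns_empirical_p_exactly(self, rng):
        perm = rng.standard_normal(1000)
        obs = np.quantile(perm, 0.8)
        expect = (1 + (perm >= obs).sum()) / (1 + perm.size)
        assert mantel.gpd_tail_p(perm, obs) == expect

    def test_tail_fit_tracks_known_distribution(self):
        ps = []
        for s in range(20):
            r = np.random.default_rng(s)
            perm = stats.genpareto.rvs(0.1, scale=1.0, size=10_000,
                                       random_state=r)
            obs = stats.genpareto.isf(1e-4, 0.1, scale=1.0)
            ps.append(mantel.gpd_tail_p(perm, obs))
        med = np.median(ps)
        assert 0.5e-4 <= med <= 2e-4

    def test_p_is_never_zero(self, rng):
        perm = np.abs(rng.standard_normal(5000))
        p = mantel.gpd_tail_p(perm, 50.0)     # far beyond every statistic
        assert 0.0 < p < 1e-6


class TestFDR:
    def test_single_p_unchanged(self):
        assert mantel.fdr_correct(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_matches_literal_step_up_formula(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        m = 4
        cm = sum(1.0 / i for i in range(1, m + 1))
        raw = np.sort(p) * m * cm / np.arange(1, m + 1)
        expect = np.minimum.accumulate(raw[::-1])[::-1]
        np.testing.assert_allclose(mantel.fdr_correct(p), np.minimum(expect, 1),
                                   atol=1e-12)

    def test_q_at_least_p(self, rng):
        p = rng.uniform(1e-6, 1, 50)
        q = mantel.fdr_correct(p)
        assert (q >= p - 1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            mantel.fdr_correct(np.array([0.0, 0.5]))


class TestGeneScan:
    def test_per_variable_max_equals_category_for_single_variable(
            self, small_selected_panel):
        ft, env, strata, _ = small_selected_panel
        from envscan.containers import EnvironmentTable
        single = EnvironmentTable(env.values[["pathogen_virus"]],
                                  {"pathogen_virus": "pathogen:virus"})
        a = envscan.gene_scan(ft, single, strata, mode="category",
                              categories=("pathogen",), n_perm=199, seed=5)
        b = envscan.gene_scan(ft, single, strata, mode="per-variable-max",
                              categories=("pathogen",), n_perm=199, seed=5)
        merged = a.merge(b, on="gene_id", suffixes=("_cat", "_var"))
        np.testing.assert_allclose(merged["i_r2_cat"], merged["i_r2_var"],
                                   atol=1e-12)
        np.testing.assert_allclose(merged["p_perm_cat"], merged["p_perm_var"])

    def test_selected_genes_rank_first(self, small_selected_panel):
        ft, env, strata, truth = small_selected_panel
        res = envscan.gene_scan(ft, env, strata, categories=("pathogen",),
                                n_perm=499, seed=1)
        auc = envscan.ranking_auc(res, set(truth.selected_gene_ids))
        assert auc >= 0.8

    def test_null_p_values_are_uniform(self, small_null_panel):
        ft, env, strata, _ = small_null_panel
        res = envscan.gene_scan(ft, env, strata, categories=("pathogen",),
                                n_perm=299, seed=2)
        ks = stats.kstest(res["p_perm"], "uniform")
        assert ks.pvalue > 0.01


class TestComparisons:
    def _results(self, values):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(values))],
                             "i_r2": values})

    def test_identical_runs_have_zero_area(self, rng):
        a = self._results(rng.uniform(0, 0.3, 30))
        out = envscan.qq_compare(a, a)
        assert out["signed_area"] == 0.0
        np.testing.assert_allclose(out["table"]["full"],
                                   out["table"]["dropped"])

    def test_halved_run_sits_below_diagonal(self, rng):
        v = rng.uniform(0.01, 0.3, 30)
        a = self._results(v)
        b = self._results(0.5 * v)
        out = envscan.qq_compare(a, b)
        assert out["signed_area"] < 0
        assert (out["table"]["dropped"] <= out["table"]["full"]).all()

    def test_signed_area_matches_trapezoid_oracle(self):
        x = np.array([0.0, 0.1, 0.15, 0.2, 0.3, 0.35, 0.4, 0.55, 0.7, 0.9])
        y = x ** 1.5
        a = self._results(x)
        b = self._results(y)
        out = envscan.qq_compare(a, b)
        xs, ys = np.sort(x), np.sort(y)
        expect = sum((ys[i] - xs[i] + ys[i + 1] - xs[i + 1]) / 2
                     * (xs[i + 1] - xs[i]) for i in range(9))
        assert out["signed_area"] == pytest.approx(expect, abs=1e-12)

    def test_gene_set_mismatch_rejected(self, rng):
        a = self._results(rng.uniform(0, 1, 5))
        b = self._results(rng.uniform(0, 1, 4))
        with pytest.raises(ValueError, match="gene sets"):
            envscan.qq_compare(a, b)

    def test_subset_of_all_genes_recovers_quartiles(self, rng):
        res = pd.DataFrame({"gene_id": [f"g{i}" for i in range(400)],
                            "p_gpd": rng.uniform(1e-4, 1, 400)})
        out = envscan.subset_compare(res, {"all": set(res["gene_id"])})
        np.testing.assert_allclose(out["frequencies"].loc["all"], 0.25,
                                   atol=0.01)

    def test_enriched_subset_detected_by_rank_sum(self, rng):
        p = np.concatenate([rng.uniform(1e-6, 1e-3, 40),
                            rng.uniform(0, 1, 360)])
        res = pd.DataFrame({"gene_id": [f"g{i}" for i in range(400)],
                            "p_gpd": p})
        subsets = {"hot": {f"g{i}" for i in range(40)},
                   "cold": {f"g{i}" for i in range(40, 400)}}
        out = envscan.subset_compare(res, subsets)
        row = out["rank_sum"].query("subset == 'hot' and versus == 'cold'")
        assert float(row["p_greater"].iloc[0]) < 0.01
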