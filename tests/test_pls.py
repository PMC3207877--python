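import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

import envscan
from envscan import pls


def sklearn_loo_q2(y, X, k):
    """Independent explicit leave-one-out loop around sklearn's PLS."""
    n = len(y)
    press = 0.0
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        m = PLSRegression(n_components=k, scale=True).fit(X[tr],
                                                          y[tr].reshape(-1, 1))
        press += float((y[i] - m.predict(X[i:i + 1]).ravel()[0]) ** 2)
    ss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss


class TestPlsFit:
    def test_exact_fit_on_single_informative_predictor(self, rng):
        X = rng.standard_normal((10, 1))
        y = 3.0 * X[:, 0] - 1.0
        m = pls.pls_fit(y, X, n_components=1)
        assert np.linalg.norm(m.residuals(X, y)) < 1e-8

    def test_full_rank_components_reproduce_least_squares(self, rng):
        for _ in range(10):
            n, p = 20, 5
            X = rng.standard_normal((n, p))
            y = rng.standard_normal(n)
            m = pls.pls_fit(y, X, n_components=p)
            # oracle: normal-equations solve on the same standardization
            Xs = (X - X.mean(0)) / X.std(0, ddof=1)
            beta = np.linalg.lstsq(
                np.column_stack([np.ones(n), Xs]), y, rcond=None)[0]
            np.testing.assert_allclose(m.coef, beta[1:], atol=1e-8)

    def test_first_component_direction_is_covariance(self, rng):
        # orthonormal predictors: w1 proportional to M'y
        Q, _ = np.linalg.qr(rng.standard_normal((20, 4)))
        X = Q * np.sqrt(19)          # unit sample variance, orthogonal
        y = rng.standard_normal(20)
        m = pls.pls_fit(y, X, n_components=2)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        direction = Xs.T @ (y - y.mean())
        direction /= np.linalg.norm(direction)
        cos = abs(m.weights[:, 0] @ direction)
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_predictor_dropped(self, rng, caplog):
        X = rng.standard_normal((12, 3))
        X[:, 1] = 2.0
        y = rng.standard_normal(12)
        m = pls.pls_fit(y, X, n_components=2)
        assert m.variables == ["x0", "x2"]

    def test_constant_response_raises(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError, match="constant response"):
            pls.pls_fit(np.ones(10), X, 1)


class TestQ2Loo:
    def test_noiseless_linear_response_predicts_almost_perfectly(self, rng):
        X = rng.standard_normal((10, 1))
        y = 2.0 * X[:, 0] + 5.0
        assert pls.q2_loo(y, X, n_components=1).q2 > 0.999

    def test_equals_explicit_loop_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(8, 25))
            p = int(rng.integers(2, 9))
            X = rng.standard_normal((n, p))
            y = rng.standard_normal(n) + X @ rng.standard_normal(p) * 0.5
            k = int(rng.integers(1, min(3, p) + 1))
            res = pls.q2_loo(y, X, n_components=k)
            assert res.q2 == pytest.approx(sklearn_loo_q2(y, X, k), abs=1e-10)
            assert res.q2 == pytest.approx(1 - res.press / res.ss, abs=1e-12)

    def test_pure_noise_overfits_to_negative_q2(self, rng):
        q2s = []
        for _ in range(50):
            X = rng.standard_normal((15, 5))
            y = rng.standard_normal(15)
            q2s.append(pls.q2_loo(y, X, n_components=2).q2)
        assert np.mean(q2s) <= 0.0

    def test_invariant_to_affine_rescaling_of_predictors(self, rng):
        X = rng.standard_normal((12, 4))
        y = rng.standard_normal(12)
        a = pls.q2_loo(y, X, n_components=2).q2
        X2 = X.copy()
        X2[:, 1] = -3.5 * X2[:, 1] + 7.0
        b = pls.q2_loo(y, X2, n_components=2).q2
        assert a == pytest.approx(b, abs=1e-10)


class TestUVE:
    def test_predictor_identical_to_response_always_retained(self, rng):
        hits = 0
        for s in range(30):
            r = np.random.default_rng(s)
            X = r.standard_normal((20, 5))
            y = X[:, 2].copy()
            kept = pls.uve_filter(y, pd.DataFrame(X, columns=list("abcde")),
                                  n_noise=50, seed=s)
            hits += "c" in kept
        assert hits >= 29

    def test_strong_signal_among_noise_predictors(self, rng):
        # the informative variable must always survive; spurious companions
        # appear with probability <= 13/101 per run (noise symmetry), so the
        # exact singleton is expected in roughly 87% of runs
        exact = 0
        for s in range(40):
            r = np.random.default_rng(1000 + s)
            X = r.standard_normal((25, 14))
            y = 2.0 * X[:, 0] + 0.1 * r.standard_normal(25)
            kept = pls.uve_filter(y, pd.DataFrame(
                X, columns=[f"v{j}" for j in range(14)]), n_noise=100, seed=s)
            assert "v0" in kept
            exact += kept == ["v0"]
        assert exact >= 28

    def test_null_retention_bounded_by_noise_symmetry(self):
        # each variable beats all 100 noise columns with prob <= 1/101
        n_runs, p, n_noise = 200, 8, 100
        retained = 0
        for s in range(n_runs):
            r = np.random.default_rng(5000 + s)
            X = r.standard_normal((18, p))
            y = r.standard_normal(18)
            kept = pls.uve_filter(y, pd.DataFrame(
                X, columns=[f"v{j}" for j in range(p)]), n_noise=n_noise,
                seed=s)
            if len(kept) < p:            # ignore the fall-back-to-all runs
                retained += len(kept)
        frac = retained / (n_runs * p)
        # 3 binomial sds of slack above the symmetry bound
        bound = 1 / (n_noise + 1)
        assert frac <= bound + 3 * np.sqrt(bound / (n_runs * p))

    def test_n_noise_must_cover_variables(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 5)))
        with pytest.raises(ValueError, match="n_noise"):
            pls.uve_filter(rng.standard_normal(10), X, n_noise=3)


class TestScan:
    def test_pathogen_model_uses_exactly_four_predictors(self, small_selected_panel):
        ft, env, *_ = small_selected_panel
        assert len(pls.model_variables(env, "pathogen")) == 4
        scan = pls.scan_all_snps(ft.subset_populations(ft.populations),
                                 env, "pathogen")
        scan = scan[scan["q2"].notna()]          # monomorphic SNPs carry none
        retained = scan["retained_variables"].str.split(";").str.len()
        assert (retained == 4).all()

    def test_identical_snps_get_identical_q2(self, small_selected_panel):
        ft, env, *_ = small_selected_panel
        sub = envscan.FrequencyTable(
            ft.annotations.iloc[[0, 0]].set_axis(["a", "b"]),
            ft.freqs.iloc[[0, 0]].set_axis(["a", "b"]),
            ft.sample_sizes)
        scan = pls.scan_all_snps(sub, env, "pathogen")
        assert scan.loc["a", "q2"] == scan.loc["b", "q2"]

    def test_population_mismatch_reported(self, small_selected_panel):
        ft, env, *_ = small_selected_panel
        bad = envscan.FrequencyTable(
            ft.annotations, ft.freqs.rename(columns={"C1p1": "XX"}),
            ft.sample_sizes.rename({"C1p1": "XX"}))
        with pytest.raises(ValueError, match="XX"):
            pls.scan_all_snps(bad, env, "pathogen")

    def test_missing_subsistence_drops_populations_listwise(self):
        cfg = envscan.SimulationConfig(
            n_continents=3, pops_per_continent=5, n_snps=60,
            n_missing_subsistence=2, seed=9)
        ft, env, *_ = envscan.simulate_panel(cfg)
        full = pls.scan_all_snps(ft, env, "full", apply_uve=False)
        path = pls.scan_all_snps(ft, env, "pathogen")
        assert full["q2"].notna().all() and path["q2"].notna().all()
        # the full model really regressed on 13 populations, pathogen on 15
        y = ft.freqs.iloc[0]
        pops13 = env.complete_populations(pls.model_variables(env, "full"))
        assert len(pops13) == 13
        direct = pls.q2_loo(y[pops13].to_numpy(),
                            env.values.loc[pops13,
                                           pls.model_variables(env, "full")])
        assert full["q2"].iloc[0] == pytest.approx(direct.q2, abs=1e-12)

    def test_driven_snps_prefer_their_category(self, small_selected_panel):
        """SNPs of pathogen-driven genes predict better under the pathogen
        model than under the climate model (paired one-sided test)."""
        from scipy.stats import wilcoxon
        ft, env, strata, truth = small_selected_panel
        sel = ft.annotations["gene_id"].isin(truth.selected_gene_ids).to_numpy()
        qp = pls.scan_all_snps(ft, env, "pathogen")["q2"].to_numpy()[sel]
        qc = pls.scan_all_snps(ft, env, "climate")["q2"].to_numpy()[sel]
        assert wilcoxon(qp, qc, alternative="greater").pvalue < 0.01
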