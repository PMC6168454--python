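import numpy as np
import pandas as pd
import pytest
from scipy.linalg import null_space

from polskit.lmm import (
    Diagonal,
    IndependentMap,
    MixedModelFit,
    ModelSpec,
    Unstructured,
    _block_reml_loglik,
    _fit_from_map,
    _make_blocks,
    _moment_start,
    fit_lm,
    fit_reml,
    fit_univariate_reml,
    wald_f_test,
)
from polskit.simulate import generate_trait_panel

from conftest import bivariate_config, univariate_config


def panel_from_arrays(y, ind, stage=None, trial=None, trait="x", sex=None):
    n = len(y)
    return pd.DataFrame(
        {
            "individual_id": ind,
            "population": "SG",
            "sex": sex if sex is not None else np.zeros(n),
            "age_stage": stage if stage is not None else np.zeros(n),
            "trial": trial if trial is not None else np.zeros(n, dtype=int),
            "trait": trait,
            "value": y,
        }
    )


class TestFitLM:
    def test_noiseless_regression_exact(self):
        x = np.linspace(-0.5, 0.5, 20)
        panel = panel_from_arrays(2.0 * x, [f"i{k}" for k in range(20)], stage=x)
        fit = fit_lm(panel, "x", ["intercept", "age_stage"])
        assert fit.beta[""][1] == pytest.approx(2.0, abs=1e-10)

    def test_two_group_coefficient_is_mean_difference(self):
        rng = np.random.default_rng(0)
        y = np.concatenate([rng.normal(1.0, 1.0, 30), rng.normal(3.0, 1.0, 30)])
        panel = panel_from_arrays(y, [f"i{k}" for k in range(60)])
        panel["population"] = ["FG"] * 30 + ["SG"] * 30
        fit = fit_lm(panel, "x", ["intercept", "population"])
        diff = y[30:].mean() - y[:30].mean()
        assert fit.beta[""][1] == pytest.approx(diff, abs=1e-10)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        beta_true = np.array([0.5, -1.2, 2.0])
        y = X @ beta_true + rng.normal(0, 0.3, 20)
        panel = panel_from_arrays(y, [f"i{k}" for k in range(20)], stage=X[:, 1], sex=X[:, 2])
        fit = fit_lm(panel, "x", ["intercept", "age_stage", "sex"])
        oracle = np.linalg.solve(X.T @ X, X.T @ y)  # direct normal equations
        np.testing.assert_allclose(fit.beta[""], oracle, atol=1e-10)

    def test_rank_deficient_design_names_aliased_columns(self):
        panel = panel_from_arrays(np.arange(10.0), [f"i{k}" for k in range(10)],
                                  stage=np.ones(10))
        with pytest.raises(ValueError, match="aliased"):
            fit_lm(panel, "x", ["intercept", "age_stage"])


class TestUnivariateREML:
    def test_equals_balanced_anova_closed_form(self):
        # classical one-way random-effects solution on a seeded 10 x 2 design
        rng = np.random.default_rng(42)
        n, k = 10, 2
        u = rng.normal(0, np.sqrt(0.4), n)
        y = (u[:, None] + rng.normal(0, np.sqrt(0.6), (n, k))).ravel()
        ind = np.repeat([f"i{j}" for j in range(n)], k)
        panel = panel_from_arrays(y, ind)
        fit = fit_univariate_reml(panel, "x", ["intercept"], compute_se=False)
        ym = y.reshape(n, k)
        msb = k * np.var(ym.mean(axis=1), ddof=1)
        msw = float(np.mean(np.var(ym, axis=1, ddof=1)))
        s2i_oracle = max(0.0, (msb - msw) / k)
        s2r_oracle = msw if s2i_oracle > 0 else np.var(y, ddof=1)
        assert fit.sigma_ind[""][0, 0] == pytest.approx(s2i_oracle, abs=1e-6)
        assert fit.sigma_res[""][0, 0] == pytest.approx(s2r_oracle, abs=1e-6)

    def test_matches_statsmodels_mixedlm(self, study_panel):
        import statsmodels.formula.api as smf

        sub = study_panel[study_panel.population == "SG"]
        fit = fit_univariate_reml(sub, "standard_size", ["intercept", "age_stage", "sex"])
        df = sub[sub.trait == "standard_size"]
        ref = smf.mixedlm(
            "value ~ age_stage + sex", df, groups=df["individual_id"]
        ).fit(reml=True)
        assert fit.sigma_ind[""][0, 0] == pytest.approx(float(ref.cov_re.iloc[0, 0]), abs=1e-4)
        assert fit.sigma_res[""][0, 0] == pytest.approx(ref.scale, abs=1e-4)
        np.testing.assert_allclose(fit.beta[""], ref.fe_params.to_numpy(), atol=1e-5)

    def test_null_variance_sits_at_boundary_about_half_the_time(self):
        at_zero = 0
        reps = 100
        for s in range(reps):
            cfg = univariate_config(0.0, 1.0, n=40, per_stage=2, seed=s)
            panel = generate_trait_panel(cfg)
            fit = fit_univariate_reml(panel, "x", ["intercept", "age_stage"], compute_se=False)
            at_zero += fit.at_boundary
        # asymptotically the REML estimate is truncated at zero w.p. 1/2
        assert 0.35 <= at_zero / reps <= 0.65


class TestMultivariateREML:
    def brute_force_restricted_loglik(self, block, Si, Sr):
        """Independent dense evaluation: the likelihood of K'y for an
        orthonormal basis K of the orthogonal complement of X."""
        rows_X, rows_y, V_blocks = [], [], []
        for pat in block.patterns:
            t = pat.t_idx
            V = Si[np.ix_(t, t)] + np.where(pat.occ_same, Sr[np.ix_(t, t)], 0.0)
            for m in range(pat.X.shape[0]):
                rows_X.append(pat.X[m])
                rows_y.append(pat.y[m])
                V_blocks.append(V)
        X = np.vstack(rows_X)
        y = np.concatenate(rows_y)
        from scipy.linalg import block_diag

        V = block_diag(*V_blocks)
        K = null_space(X.T)
        S = K.T @ V @ K
        r = K.T @ y
        sign, logdet = np.linalg.slogdet(S)
        ll = -0.5 * (len(r) * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(S, r))
        # convert to the |X'V^-1 X| convention: the two differ by 1/2 log|X'X|
        sign2, logdet_xx = np.linalg.slogdet(X.T @ X)
        return ll - 0.5 * logdet_xx

    def test_loglik_matches_dense_brute_force_on_tiny_instance(self):
        cfg = bivariate_config(0.5, n=3, seed=5, per_stage=1)  # 3 ind x 4 = 12 rows
        panel = generate_trait_panel(cfg)
        spec = ModelSpec(
            responses=["a", "b"],
            fixed_terms={"a": ["intercept"], "b": ["intercept"]},
        )
        (block,) = _make_blocks(panel, spec)
        Si = np.array([[0.4, 0.1], [0.1, 0.3]])
        Sr = np.array([[0.8, -0.2], [-0.2, 0.9]])
        ll_engine = _block_reml_loglik(block, Si, Sr)
        ll_oracle = self.brute_force_restricted_loglik(block, Si, Sr)
        assert ll_engine == pytest.approx(ll_oracle, abs=1e-6)

    def test_recovers_among_correlation(self):
        cfg = bivariate_config(0.8, n=200, seed=1)
        panel = generate_trait_panel(cfg)
        spec = ModelSpec(
            responses=["a", "b"],
            fixed_terms={"a": ["intercept", "age_stage", "trial"],
                         "b": ["intercept", "age_stage", "trial"]},
        )
        fit = fit_reml(panel, spec)
        Si = fit.sigma_ind[""]
        r = Si[0, 1] / np.sqrt(Si[0, 0] * Si[1, 1])
        # MC SE of a correlation estimated from ~200 individual effects
        assert r == pytest.approx(0.8, abs=3 * 0.05)

    def test_trait_permutation_invariance(self):
        cfg = bivariate_config(0.5, n=30, seed=2)
        panel = generate_trait_panel(cfg)
        terms = {"a": ["intercept", "age_stage"], "b": ["intercept", "age_stage"]}
        fit_ab = fit_reml(panel, ModelSpec(["a", "b"], terms), n_restarts=1)
        fit_ba = fit_reml(panel, ModelSpec(["b", "a"], terms), n_restarts=1)
        assert fit_ab.reml_loglik == pytest.approx(fit_ba.reml_loglik, abs=1e-4)
        assert fit_ab.sigma_ind[""][0, 1] == pytest.approx(
            fit_ba.sigma_ind[""][1, 0], abs=1e-3
        )
        assert fit_ab.sigma_ind[""][0, 0] == pytest.approx(
            fit_ba.sigma_ind[""][1, 1], abs=1e-3
        )

    def test_equality_constraint_never_increases_loglik(self):
        cfg = bivariate_config(0.6, n=40, seed=3)
        panel = generate_trait_panel(cfg)
        terms = {"a": ["intercept", "age_stage"], "b": ["intercept", "age_stage"]}
        spec = ModelSpec(["a", "b"], terms)
        full = fit_reml(panel, spec)
        blocks = _make_blocks(panel, spec)
        pmap = IndependentMap([(Diagonal(2), Unstructured(2))])
        red = _fit_from_map(blocks, pmap, pmap.init([_moment_start(blocks[0])]), False, 3, 500)
        assert red.reml_loglik <= full.reml_loglik + 1e-6

    def test_serialization_round_trip(self):
        cfg = bivariate_config(0.5, n=30, seed=4)
        panel = generate_trait_panel(cfg)
        spec = ModelSpec(["a", "b"], {"a": ["intercept"], "b": ["intercept"]})
        fit = fit_reml(panel, spec, n_restarts=1)
        back = MixedModelFit.from_dict(__import__("json").loads(fit.to_json()))
        assert back.reml_loglik == fit.reml_loglik
        np.testing.assert_allclose(back.sigma_ind[""], fit.sigma_ind[""])


class TestWaldF:
    def test_single_coefficient_equals_t_squared(self, study_panel):
        sub = study_panel[study_panel.population == "SG"]
        fit = fit_univariate_reml(sub, "hiding_time", ["intercept", "age_stage", "sex", "trial"])
        res = wald_f_test(fit, "sex")
        i = fit.fixed_names[""].index("sex")
        t2 = (fit.beta[""][i] / fit.beta_se[""][i]) ** 2
        assert res["F"] == pytest.approx(t2, rel=1e-10)
        assert res["num_df"] == 1

    def test_huge_effect_is_overwhelmingly_significant(self):
        cfg = univariate_config(0.2, 0.8, n=60, per_stage=2, seed=8,
                                beta={"x": {"age_stage": 10.0}})
        panel = generate_trait_panel(cfg)
        fit = fit_univariate_reml(panel, "x", ["intercept", "age_stage"], compute_se=False)
        res = wald_f_test(fit, "age_stage")
        assert res["p_value"] < 1e-6

    def test_missing_term_raises(self, study_panel):
        sub = study_panel[study_panel.population == "SG"]
        fit = fit_univariate_reml(sub, "smr", ["intercept", "age_stage"], compute_se=False)
        with pytest.raises(ValueError, match="not present"):
            wald_f_test(fit, "sex")

    def test_type_one_error_calibrated_for_within_individual_term(self):
        # null age effect; containment df handles within-individual terms
        rej, reps = 0, 400
        for s in range(reps):
            cfg = univariate_config(0.3, 0.7, n=40, per_stage=2, seed=s)
            panel = generate_trait_panel(cfg)
            fit = fit_univariate_reml(panel, "x", ["intercept", "age_stage"], compute_se=False)
            rej += wald_f_test(fit, "age_stage")["p_value"] < 0.05
        rate = rej / reps
        tol = 3 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < tol


def test_model_spec_from_yaml(tmp_path, study_panel):
    cfg = tmp_path / "model.yaml"
    cfg.write_text(
        "responses: [smr]\n"
        "fixed_terms: [intercept, age_stage, sex]\n"
    )
    spec = ModelSpec.from_yaml(cfg)
    fit = fit_reml(study_panel[study_panel.population == "SG"], spec)
    assert fit.converged
    with pytest.raises(ValueError, match="unknown model-spec"):
        ModelSpec.from_dict({"responses": ["smr"], "bogus": 1})
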