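"""MMRM engine: design construction, REML oracles, LS-mean contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from attrecho import ModelSpec, analyze, build_design, fit_mmrm
from attrecho.mmrm import (
    RankDeficientDesignError,
    _group_by_mask,
    ls_means,
    treatment_contrast,
)
from attrecho.trial import POST_VISITS, simulate_trial, apply_missingness

from conftest import make_config, null_profiles


def saturated_spec(**kw):
    """Arm-by-visit cell means only (no covariates, no tafamidis terms)."""
    return ModelSpec(population="monotherapy", covariates=(), **kw)


@pytest.fixture(scope="module")
def balanced_complete_fit():
    cfg = make_config(n_per_arm=20, seed=17, tafamidis_fraction=0.0)
    ds = simulate_trial(cfg)
    spec = saturated_spec()
    design = build_design(ds, spec)
    return ds, design, fit_mmrm(design)


class TestDesign:
    def test_overall_population_column_count(self, study_like_trial):
        ds, _ = study_like_trial
        design = build_design(ds, ModelSpec(population="overall"))
        # 8 arm-by-visit cell means + baseline + attr + age + taf + trt:taf
        assert design.X.shape[1] == 13
        assert "taf" in design.col_names and "trt:taf" in design.col_names

    def test_monotherapy_drops_tafamidis_terms(self, study_like_trial):
        ds, _ = study_like_trial
        design = build_design(ds, ModelSpec(population="monotherapy"))
        assert design.X.shape[1] == 11
        assert "taf" not in design.col_names

    def test_reference_coding_same_dimension(self, study_like_trial):
        ds, _ = study_like_trial
        design = build_design(ds, ModelSpec(population="overall", coding="reference"))
        assert design.X.shape[1] == 13
        assert "intercept" in design.col_names and "trt" in design.col_names

    def test_patient_missing_one_visit_contributes_three_rows(self, small_complete_trial):
        ds, _ = small_complete_trial
        pid = ds.patients.loc[0, "patient_id"]
        mask = (ds.outcomes["patient_id"] == pid) & (ds.outcomes["visit"] == "m18")
        ds.outcomes.loc[mask, "change_from_baseline"] = np.nan
        ds.outcomes.loc[mask, "observed"] = False
        design = build_design(ds, ModelSpec())
        assert (design.subject_ids == pid).sum() == 3

    def test_duplicated_column_raises_rank_error(self, small_complete_trial):
        ds, _ = small_complete_trial
        ds.patients["attr_type"] = "wild_type"
        ds.patients["age_group"] = "ge75"  # age column becomes all-ones: aliased
        with pytest.raises(RankDeficientDesignError, match="age"):
            build_design(ds, ModelSpec(population="monotherapy", coding="reference",
                                       covariates=("attr_type", "age_group")))


class TestREMLOracles:
    def test_sigma_equals_pooled_within_arm_covariance(self, balanced_complete_fit):
        """Complete balanced saturated model: REML sigma has closed form S/(n-2)."""
        ds, design, fit = balanced_complete_fit
        wide = ds.wide_changes()
        arm = ds.patients.set_index("patient_id").loc[wide.index, "arm"]
        sscp = np.zeros((4, 4))
        n = len(wide)
        for a in ("placebo", "vutrisiran"):
            sub = wide[arm == a].to_numpy()
            dev = sub - sub.mean(axis=0)
            sscp += dev.T @ dev
        sigma_oracle = sscp / (n - 2)
        assert fit.converged
        np.testing.assert_allclose(fit.sigma, sigma_oracle, atol=1e-8)

    def test_beta_equals_cell_means_and_ols(self, balanced_complete_fit):
        ds, design, fit = balanced_complete_fit
        wide = ds.wide_changes()
        arm = ds.patients.set_index("patient_id").loc[wide.index, "arm"]
        cell = {
            (a, v): wide.loc[arm == a, v].mean()
            for a in ("placebo", "vutrisiran")
            for v in POST_VISITS
        }
        beta = dict(zip(fit.col_names, fit.beta))
        for v in POST_VISITS:
            assert beta[f"visit[{v}]"] == pytest.approx(cell[("placebo", v)], abs=1e-8)
            assert beta[f"visit[{v}]"] + beta[f"trt:visit[{v}]"] == pytest.approx(
                cell[("vutrisiran", v)], abs=1e-8
            )
        # complete data: GLS estimate coincides with OLS
        ols, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
        np.testing.assert_allclose(fit.beta, ols, atol=1e-8)

    def test_lsmean_difference_equals_raw_arm_difference(self, balanced_complete_fit):
        ds, design, fit = balanced_complete_fit
        wide = ds.wide_changes()
        arm = ds.patients.set_index("patient_id").loc[wide.index, "arm"]
        raw = wide[arm == "vutrisiran"].mean() - wide[arm == "placebo"].mean()
        for v in POST_VISITS:
            c = treatment_contrast(fit, v)
            assert c.difference == pytest.approx(raw[v], abs=1e-8)
            assert c.ci_low <= c.difference <= c.ci_high
            assert 0.0 <= c.p_value <= 1.0

    def test_single_visit_single_arm_reduces_to_t_test(self):
        cfg = make_config(n_per_arm=15, seed=23, tafamidis_fraction=0.0)
        ds = simulate_trial(cfg)
        # keep placebo patients, month 30 only
        placebo = set(ds.patients.loc[ds.patients["arm"] == "placebo", "patient_id"])
        ds.patients = ds.patients[ds.patients["patient_id"].isin(placebo)].reset_index(drop=True)
        keep = ds.outcomes["patient_id"].isin(placebo) & ds.outcomes["visit"].isin(
            ["baseline", "m30"]
        )
        ds.outcomes = ds.outcomes[keep].reset_index(drop=True)
        design = build_design(ds, saturated_spec())
        fit = fit_mmrm(design)
        y = design.y
        assert fit.sigma.shape == (1, 1)
        assert fit.sigma[0, 0] == pytest.approx(np.var(y, ddof=1), abs=1e-8)
        lsm = ls_means(fit, "m30")
        assert lsm["placebo"][0] == pytest.approx(y.mean(), abs=1e-10)

    def test_loglik_matches_independent_objective(self):
        """Naive per-subject REML objective agrees at the optimum, and a generic
        optimizer of that objective cannot beat the fitted log-likelihood."""
        cfg = make_config(n_per_arm=25, seed=31, tafamidis_fraction=0.0,
                          missingness_mode="mcar", mcar_rate=0.3)
        ds = apply_missingness(simulate_trial(cfg), cfg)
        spec = saturated_spec()
        design = build_design(ds, spec)
        fit = fit_mmrm(design)

        groups = _group_by_mask(design)

        def naive_nll(tril):
            L = np.zeros((4, 4))
            L[np.tril_indices(4)] = tril
            if np.any(np.diag(L) <= 0):
                return np.inf
            sigma = L @ L.T
            logdet, W, Xty = 0.0, 0.0, 0.0
            W = np.zeros((design.X.shape[1],) * 2)
            Xty = np.zeros(design.X.shape[1])
            for grp in groups:
                m = np.array(grp.mask)
                sub = sigma[np.ix_(m, m)]
                sign, ld = np.linalg.slogdet(sub)
                if sign <= 0:
                    return np.inf
                isub = np.linalg.inv(sub)
                for yi, xi in zip(grp.Y, grp.X):
                    logdet += ld
                    W += xi.T @ isub @ xi
                    Xty += xi.T @ isub @ yi
            beta = np.linalg.solve(W, Xty)
            quad = 0.0
            for grp in groups:
                m = np.array(grp.mask)
                isub = np.linalg.inv(sigma[np.ix_(m, m)])
                for yi, xi in zip(grp.Y, grp.X):
                    r = yi - xi @ beta
                    quad += r @ isub @ r
            s, ldW = np.linalg.slogdet(W)
            return 0.5 * (logdet + quad + ldW)

        L_hat = np.linalg.cholesky(fit.sigma)
        at_optimum = -naive_nll(L_hat[np.tril_indices(4)])
        assert at_optimum == pytest.approx(fit.reml_loglik, abs=1e-8)

        start = L_hat[np.tril_indices(4)] * 1.25
        res = optimize.minimize(naive_nll, start, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        assert fit.reml_loglik >= -res.fun - 1e-6


class TestContrastProperties:
    def test_arm_swap_negates_difference(self, study_like_trial):
        ds, _ = study_like_trial
        spec = ModelSpec()
        _, contrasts = analyze(ds, spec)
        swapped = ds.copy()
        swapped.patients["arm"] = swapped.patients["arm"].map(
            {"placebo": "vutrisiran", "vutrisiran": "placebo"}
        )
        _, contrasts_sw = analyze(swapped, spec)
        for c, cs in zip(contrasts, contrasts_sw):
            assert cs.difference == pytest.approx(-c.difference, abs=1e-6)
            assert cs.se == pytest.approx(c.se, rel=1e-6)

    def test_satterthwaite_df_bounded_by_residual_df(self, study_like_trial):
        ds, _ = study_like_trial
        fit, contrasts = analyze(ds, ModelSpec())
        for c in contrasts:
            assert 1.0 <= c.df <= fit.residual_df

    def test_contrast_refused_for_unknown_visit(self, balanced_complete_fit):
        _, _, fit = balanced_complete_fit
        with pytest.raises(ValueError, match="visit"):
            treatment_contrast(fit, "m99")
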