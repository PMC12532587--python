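"""Pattern classification, per-pattern imputers, caps and orchestration."""

import collections

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from attrecho import ModelSpec, TrialConfig, apply_missingness, simulate_trial
from attrecho.echo import PARAMETER_REGISTRY, WorseDirection
from attrecho.imputation import (
    MVNImputationChain,
    UnroutableCellError,
    apply_cap,
    classify_patterns,
    find_retrieved_dropouts,
    impute_retrieved_dropout,
    impute_worst_decile,
    run_pattern_mixture,
    worst_decile_pool,
)
from attrecho.trial import POST_VISITS, VISIT_DAYS

from conftest import make_config


def _set_missing(ds, pid, visits):
    mask = (ds.outcomes["patient_id"] == pid) & ds.outcomes["visit"].isin(visits)
    ds.outcomes.loc[mask, "change_from_baseline"] = np.nan
    ds.outcomes.loc[mask, "observed"] = False


def _patient_idx(ds, pid):
    return ds.patients.index[ds.patients["patient_id"] == pid][0]


class TestClassification:
    def test_death_forces_pattern1(self, small_complete_trial):
        ds, _ = small_complete_trial
        ds = ds.copy()
        pid = ds.patients.loc[0, "patient_id"]
        ds.patients.loc[0, "death_day"] = 700
        _set_missing(ds, pid, ["m24", "m30"])
        patterns = {(a.patient_id, a.visit): a.pattern for a in classify_patterns(ds)}
        assert patterns[(pid, "m24")] == "P1_death"
        assert patterns[(pid, "m30")] == "P1_death"

    def test_window_arithmetic_on_active_arm(self, small_complete_trial):
        ds, _ = small_complete_trial
        ds = ds.copy()
        vut = ds.patients[ds.patients["arm"] == "vutrisiran"]
        pid_in = vut.iloc[0]["patient_id"]
        pid_out = vut.iloc[1]["patient_id"]
        # day 548 visit: last dose 420 -> 128 days... use 430 -> 118 <= 126 (P2)
        ds.patients.loc[_patient_idx(ds, pid_in), "last_dose_day"] = 430
        # last dose 300 -> 248 > 126 (P3)
        ds.patients.loc[_patient_idx(ds, pid_out), "last_dose_day"] = 300
        _set_missing(ds, pid_in, ["m18"])
        _set_missing(ds, pid_out, ["m18"])
        patterns = {(a.patient_id, a.visit): a.pattern for a in classify_patterns(ds)}
        assert patterns[(pid_in, "m18")] == "P2_vutri_on_treatment"
        # no retrieved dropouts in this fixture -> copy reference subtype
        assert patterns[(pid_out, "m18")] == "P3ii_vutri_copy_reference"

    def test_placebo_missing_routes_to_pattern4(self, small_complete_trial):
        ds, _ = small_complete_trial
        ds = ds.copy()
        pid = ds.patients[ds.patients["arm"] == "placebo"].iloc[0]["patient_id"]
        _set_missing(ds, pid, ["m30"])
        patterns = {(a.patient_id, a.visit): a.pattern for a in classify_patterns(ds)}
        assert patterns[(pid, "m30")] == "P4ii_placebo_mar"

    def test_missing_last_dose_day_is_configuration_error(self, small_complete_trial):
        ds, _ = small_complete_trial
        ds = ds.copy()
        vut = ds.patients[ds.patients["arm"] == "vutrisiran"].iloc[0]
        idx = _patient_idx(ds, vut["patient_id"])
        ds.patients.loc[idx, "last_dose_day"] = pd.NA
        _set_missing(ds, vut["patient_id"], ["m30"])
        with pytest.raises(UnroutableCellError, match=vut["patient_id"]):
            classify_patterns(ds)


class TestRetrievedDropouts:
    def _with_dropouts(self, n_qualifying, small):
        ds, _ = small
        ds = ds.copy()
        vut = ds.patients[ds.patients["arm"] == "vutrisiran"]
        taf_false = vut[~vut["baseline_tafamidis"]]
        ids = list(taf_false["patient_id"][:n_qualifying])
        for pid in ids:
            idx = _patient_idx(ds, pid)
            ds.patients.loc[idx, "discontinued"] = True
            ds.patients.loc[idx, "last_dose_day"] = 336  # m30 at 913: 577 days off drug
        return ds, ids

    def test_sufficiency_boundary(self, small_complete_trial):
        ds9, _ = self._with_dropouts(9, small_complete_trial)
        _, sufficient = find_retrieved_dropouts(ds9, "vutrisiran", False)
        assert not sufficient
        ds10, ids = self._with_dropouts(10, small_complete_trial)
        found, sufficient = find_retrieved_dropouts(ds10, "vutrisiran", False)
        assert sufficient and set(found) == set(ids)

    def test_on_treatment_assessment_excluded(self, small_complete_trial):
        ds, ids = self._with_dropouts(1, small_complete_trial)
        idx = _patient_idx(ds, ids[0])
        ds.patients.loc[idx, "last_dose_day"] = 840  # m30 only 73 days after last dose
        found, _ = find_retrieved_dropouts(ds, "vutrisiran", False)
        assert ids[0] not in found


class TestWorstDecile:
    def test_singleton_pool_always_returns_minimum(self):
        pool = np.array([-12.0, -3, -2, -1, 0, 1, 2, 3, 4, 5])
        decile = worst_decile_pool(pool, WorseDirection.DECREASE)
        assert decile.tolist() == [-12.0]

    def test_two_donor_decile_frequencies(self):
        pool = np.arange(20, dtype=float)  # worst two (decrease): 0 and 1
        decile = worst_decile_pool(pool, WorseDirection.DECREASE)
        assert decile.tolist() == [0.0, 1.0]
        rng = np.random.default_rng(2024)
        draws = decile[rng.integers(0, decile.size, size=10_000)]
        freq = np.mean(draws == 0.0)
        assert abs(freq - 0.5) < 0.02

    def test_increase_direction_takes_upper_tail(self):
        pool = np.arange(20, dtype=float)
        decile = worst_decile_pool(pool, WorseDirection.INCREASE)
        assert decile.tolist() == [18.0, 19.0]

    def test_draw_is_capped(self, small_complete_trial):
        ds, _ = small_complete_trial
        ds = ds.copy()
        pid = ds.patients.loc[0, "patient_id"]
        mask = ds.outcomes["patient_id"] == pid
        ds.outcomes.loc[mask, "baseline_value"] = 1.0  # cap at -1
        _set_missing(ds, pid, ["m30"])
        entry = PARAMETER_REGISTRY["stroke_volume"]
        rng = np.random.default_rng(5)
        value, size = impute_worst_decile(ds, pid, "m30", entry, rng)
        assert value >= -1.0
        assert size >= 1


@pytest.mark.parametrize(
    "change,baseline,expected",
    [(-60.0, 55.0, -55.0), (-3.0, 55.0, -3.0), (5.0, 18.0, 5.0)],
)
def test_apply_cap(change, baseline, expected):
    assert apply_cap(change, baseline) == expected


class TestRoutingExhaustiveness:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        death_hazard=st.sampled_from([0.0, 2e-4, 1e-3]),
        disc_hazard=st.sampled_from([0.0, 5e-4, 2e-3]),
        observe=st.sampled_from([0.0, 0.5, 1.0]),
    )
    def test_every_missing_cell_gets_exactly_one_pattern(
        self, seed, death_hazard, disc_hazard, observe
    ):
        cfg = make_config(
            n_per_arm=40, seed=seed, missingness_mode="mcar", mcar_rate=0.2,
            death_hazard=death_hazard, discontinuation_hazard=disc_hazard,
            off_treatment_observe_prob=observe,
        )
        ds = apply_missingness(simulate_trial(cfg), cfg)
        assignments = classify_patterns(ds)
        cells = [(a.patient_id, a.visit) for a in assignments]
        assert len(cells) == len(set(cells))
        missing = ds.post_baseline()
        missing = missing[~missing["observed"]]
        assert set(cells) == set(zip(missing["patient_id"], missing["visit"]))


class TestMVNChain:
    def test_no_missing_cells_is_identity(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(40, 4))
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        chain = MVNImputationChain(Y.copy(), X, rng)
        for _ in chain.run(burn_in=5, n_draws=2, thin=2):
            pass
        np.testing.assert_array_equal(chain.Yc, Y)

    def test_too_small_estimation_sample_aborts(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(6, 4))
        X = np.column_stack([np.ones(6), rng.normal(size=(6, 5))])
        with pytest.raises(ValueError, match="estimation sample too small"):
            MVNImputationChain(Y, X, rng)

    def test_posterior_mean_tracks_conjugate_oracle_single_outcome(self):
        """k=1: data augmentation reduces to Bayesian linear regression; the
        posterior-predictive mean for an all-missing row is x'beta_hat."""
        rng = np.random.default_rng(7)
        n = 200
        x = rng.normal(size=n)
        beta = np.array([1.0, 2.0])
        y = beta[0] + beta[1] * x + rng.normal(scale=0.5, size=n)
        Y = y[:, None].copy()
        miss_rows = np.arange(0, n, 10)
        Y[miss_rows, 0] = np.nan
        X = np.column_stack([np.ones(n), x])
        obs = ~np.isnan(Y[:, 0])
        bhat = np.linalg.lstsq(X[obs], y[obs], rcond=None)[0]
        chain = MVNImputationChain(Y, X, np.random.default_rng(11))
        draws = []
        for B, _ in chain.run(burn_in=50, n_draws=200, thin=2):
            draws.append(X[miss_rows] @ B[:, 0])
        post_mean = np.mean(draws, axis=0)
        np.testing.assert_allclose(post_mean, X[miss_rows] @ bhat, atol=0.2)


class TestRetrievedDropoutImputer:
    def test_degenerate_regression_returns_constant(self, small_complete_trial):
        ds, _ = small_complete_trial
        ds = ds.copy()
        vut = ds.patients[ds.patients["arm"] == "vutrisiran"]
        ids = list(vut["patient_id"][:12])
        for pid in ids:
            idx = _patient_idx(ds, pid)
            ds.patients.loc[idx, "discontinued"] = True
            ds.patients.loc[idx, "last_dose_day"] = 336
            mask = (ds.outcomes["patient_id"] == pid) & (ds.outcomes["visit"] == "m30")
            ds.outcomes.loc[mask, "change_from_baseline"] = -4.0
        target = vut["patient_id"].iloc[15]
        _set_missing(ds, target, ["m30"])
        rng = np.random.default_rng(3)
        value, n_est = impute_retrieved_dropout(ds, target, "m30", ids, rng)
        assert n_est == 12
        assert value == pytest.approx(-4.0, abs=1e-8)


class TestRunPatternMixture:
    def test_no_missingness_gives_identical_copies(self, small_complete_trial):
        ds, _ = small_complete_trial
        run = run_pattern_mixture(ds, m=3, seed=1, burn_in=10, thin=2)
        assert run.provenance.empty
        for comp in run.completed_datasets:
            pd.testing.assert_frame_equal(
                comp.outcomes[ds.outcomes.columns], ds.outcomes
            )

    def test_one_cell_per_pattern_routing(self):
        cfg = make_config(n_per_arm=60, seed=19, tafamidis_fraction=0.0)
        ds = simulate_trial(cfg)
        pts = ds.patients
        vut = list(pts[pts["arm"] == "vutrisiran"]["patient_id"])
        pla = list(pts[pts["arm"] == "placebo"]["patient_id"])
        # P1: death before m30
        ds.patients.loc[_patient_idx(ds, vut[0]), "death_day"] = 600
        _set_missing(ds, vut[0], ["m24", "m30"])
        # P2: active arm, within window
        _set_missing(ds, vut[1], ["m18"])
        # P3i needs >= 10 retrieved dropouts in the active arm
        for pid in vut[2:13]:
            idx = _patient_idx(ds, pid)
            ds.patients.loc[idx, "discontinued"] = True
            ds.patients.loc[idx, "last_dose_day"] = 336
        ds.patients.loc[_patient_idx(ds, vut[14]), "discontinued"] = True
        ds.patients.loc[_patient_idx(ds, vut[14]), "last_dose_day"] = 336
        _set_missing(ds, vut[14], ["m30"])
        # P4i impossible here (no placebo retrieved dropouts): placebo cell -> P4ii
        _set_missing(ds, pla[0], ["m12"])
        run = run_pattern_mixture(ds, m=2, seed=5, burn_in=10, thin=2)
        tags = set(run.provenance["pattern"])
        assert tags == {
            "P1_death", "P2_vutri_on_treatment", "P3i_vutri_retrieved", "P4ii_placebo_mar"
        }

    def test_study_like_run_complete_capped_and_deterministic(self, study_like_trial):
        ds, cfg = study_like_trial
        run = run_pattern_mixture(ds, m=3, seed=9, burn_in=30, thin=5)
        assert collections.Counter(run.provenance["pattern"]).keys() <= set(
            ["P1_death", "P2_vutri_on_treatment", "P3i_vutri_retrieved",
             "P3ii_vutri_copy_reference", "P4i_placebo_retrieved", "P4ii_placebo_mar"]
        )
        base = ds.outcomes.drop_duplicates("patient_id").set_index("patient_id")[
            "baseline_value"
        ]
        originally_missing = ds.post_baseline()
        originally_missing = originally_missing[~originally_missing["observed"]]
        for comp in run.completed_datasets:
            post = comp.post_baseline()
            assert post["change_from_baseline"].notna().all()
            # observed cells never altered
            obs = ds.post_baseline()
            obs = obs[obs["observed"]]
            merged = obs.merge(post, on=["patient_id", "visit"], suffixes=("_in", "_out"))
            np.testing.assert_array_equal(
                merged["change_from_baseline_in"], merged["change_from_baseline_out"]
            )
            # cap invariant on every imputed cell
            imp = post.merge(
                originally_missing[["patient_id", "visit"]], on=["patient_id", "visit"]
            )
            vals = imp["change_from_baseline"].to_numpy()
            bases = base[imp["patient_id"]].to_numpy()
            assert np.all(bases + vals >= -1e-9)
        run2 = run_pattern_mixture(ds, m=3, seed=9, burn_in=30, thin=5)
        for a, b in zip(run.completed_datasets, run2.completed_datasets):
            pd.testing.assert_frame_equal(a.outcomes, b.outcomes)

    def test_copy_reference_tracks_reference_shift(self):
        """When the placebo profile is worse by a margin, copy-reference
        imputations for active-arm dropouts move toward it."""
        base_prof = {"placebo": (-2.0, -4.0, -6.0, -8.0),
                     "vutrisiran": (0.0, 0.0, 0.0, 0.0)}
        cfg = make_config(n_per_arm=150, seed=33, tafamidis_fraction=0.0,
                          mean_profile_by_arm=base_prof)
        ds = simulate_trial(cfg)
        vut = list(ds.patients[ds.patients["arm"] == "vutrisiran"]["patient_id"])
        targets = vut[:30]
        for pid in targets:
            idx = _patient_idx(ds, pid)
            ds.patients.loc[idx, "discontinued"] = True
            ds.patients.loc[idx, "last_dose_day"] = 336
            _set_missing(ds, pid, ["m24", "m30"])
        assignments = classify_patterns(ds)
        assert {a.pattern for a in assignments} == {"P3ii_vutri_copy_reference"}
        run = run_pattern_mixture(ds, m=8, seed=2, burn_in=50, thin=5)
        imputed = []
        for comp in run.completed_datasets:
            post = comp.post_baseline()
            sel = post[(post["visit"] == "m30") & post["patient_id"].isin(targets)]
            imputed.append(sel["change_from_baseline"].mean())
        # reference m30 mean is -8; the active arm's own profile is 0
        assert np.mean(imputed) < -4.0
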