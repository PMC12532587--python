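"""Seeded synthetic two-arm echocardiographic trial generator.

Emulates the data structure of a 30-month placebo-controlled ATTR-CM trial:
~650 patients in two arms, echo assessments at baseline and months 12/18/24/30,
stratification by baseline tafamidis use, ATTR genotype, age group, NYHA class
and NT-proBNP, deaths and treatment discontinuations over follow-up, and
configurable missingness mechanisms (MCAR, MAR dropout driven by the previous
observed change, MNAR driven by the deleted value itself).  Ground-truth
arm-specific mean change profiles are configured directly, so every downstream
estimator can be checked against a known effect.

One parameter is simulated per run; the change-from-baseline trajectory across
the four post-baseline visits is multivariate normal with an unstructured
within-subject covariance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .echo import WorseDirection

__all__ = [
    "VISITS",
    "POST_VISITS",
    "VISIT_DAYS",
    "DOSE_INTERVAL_DAYS",
    "TrialConfig",
    "TrialDataset",
    "simulate_trial",
    "apply_missingness",
    "write_long_csv",
    "read_long_csv",
]

VISITS = ("baseline", "m12", "m18", "m24", "m30")
POST_VISITS = ("m12", "m18", "m24", "m30")
#: Nominal assessment days for the five visits (months 0, 12, 18, 24, 30).
VISIT_DAYS: Mapping[str, int] = {"baseline": 0, "m12": 365, "m18": 548, "m24": 730, "m30": 913}
#: Study-drug dosing interval in days (one subcutaneous dose every 12 weeks).
DOSE_INTERVAL_DAYS = 84
_MONTH30_DAY = VISIT_DAYS["m30"]

ARMS = ("placebo", "vutrisiran")


def _default_profiles() -> Dict[str, tuple]:
    # Stroke-volume-like progressive decline; active arm attenuates it.
    return {
        "placebo": (-1.6, -3.3, -4.9, -6.5),
        "vutrisiran": (-0.6, -1.2, -1.8, -2.4),
    }


def _default_covariance() -> np.ndarray:
    sd = np.array([9.0, 10.5, 12.0, 13.5])
    rho = 0.7
    idx = np.arange(4)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return corr * np.outer(sd, sd)


@dataclass
class TrialConfig:
    """Generator configuration; defaults emulate the target study's conditions.

    ``mean_profile_by_arm`` gives the true mean change from baseline at the
    four post-baseline visits per arm (parameter units); the arm contrast of
    the two profiles is the ground-truth treatment effect.  Hazards are
    per-day exponential rates.  ``missingness_mode`` selects the mechanism
    layered on top of death- and discontinuation-driven missingness.
    """

    parameter: str = "stroke_volume"
    n_per_arm: int = 327
    tafamidis_fraction: float = 0.40
    wild_type_fraction: float = 0.88
    ge75_fraction: float = 0.55
    nyha3_fraction: float = 0.09
    ntprobnp_high_fraction: float = 0.27
    mean_profile_by_arm: Dict[str, Sequence[float]] = field(default_factory=_default_profiles)
    within_subject_covariance: np.ndarray = field(default_factory=_default_covariance)
    baseline_mean: float = 52.0
    baseline_sd: float = 17.5
    baseline_slope: float = -0.1     # change per unit baseline deviation (regression to the mean)
    attr_effect: float = -1.0        # additive shift for variant genotype
    age_effect: float = -1.0         # additive shift for age >= 75
    taf_effect: float = 0.5          # additive shift for baseline tafamidis users
    death_hazard: float = 1.1e-4
    discontinuation_hazard: float = 2.5e-4
    missingness_mode: str = "mar"    # none | mcar | mar | mnar
    mcar_rate: float = 0.1
    mar_intercept: float = -3.0
    mar_slope: float = 0.7
    mnar_intercept: float = -3.0
    mnar_slope: float = 0.7
    off_treatment_observe_prob: float = 0.5
    worse_direction: WorseDirection = WorseDirection.DECREASE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        for name in ("tafamidis_fraction", "wild_type_fraction", "ge75_fraction",
                     "nyha3_fraction", "ntprobnp_high_fraction",
                     "mcar_rate", "off_treatment_observe_prob"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.death_hazard < 0 or self.discontinuation_hazard < 0:
            raise ValueError("hazards must be >= 0")
        if self.missingness_mode not in ("none", "mcar", "mar", "mnar"):
            raise ValueError(f"unknown missingness_mode {self.missingness_mode!r}")
        self.within_subject_covariance = np.asarray(self.within_subject_covariance, dtype=float)
        cov = self.within_subject_covariance
        if cov.shape != (4, 4) or not np.allclose(cov, cov.T):
            raise ValueError("within_subject_covariance must be a symmetric 4x4 matrix")
        if np.linalg.eigvalsh(cov)[0] <= 0:
            raise ValueError("within_subject_covariance is not positive definite")
        for arm in ARMS:
            profile = np.asarray(self.mean_profile_by_arm[arm], dtype=float)
            if profile.shape != (4,):
                raise ValueError(f"mean_profile_by_arm[{arm!r}] must have 4 entries")
        self.worse_direction = WorseDirection(self.worse_direction)

    @property
    def true_effect_by_visit(self) -> np.ndarray:
        """Ground-truth active-minus-placebo contrast at the four visits."""
        a = np.asarray(self.mean_profile_by_arm["vutrisiran"], dtype=float)
        p = np.asarray(self.mean_profile_by_arm["placebo"], dtype=float)
        return a - p

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["within_subject_covariance"] = self.within_subject_covariance.tolist()
        d["mean_profile_by_arm"] = {k: list(map(float, v)) for k, v in self.mean_profile_by_arm.items()}
        d["worse_direction"] = self.worse_direction.value
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrialConfig":
        return cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})


@dataclass
class TrialDataset:
    """Patients x visits outcomes for one echo parameter.

    ``patients`` has one row per patient (arm, strata, death/dosing fields);
    ``outcomes`` is long format with one row per patient-visit, where a
    missing assessment has ``observed == False`` and NaN change.
    """

    patients: pd.DataFrame
    outcomes: pd.DataFrame
    parameter: str
    meta: dict = field(default_factory=dict)

    def copy(self) -> "TrialDataset":
        return TrialDataset(self.patients.copy(), self.outcomes.copy(), self.parameter, dict(self.meta))

    def post_baseline(self) -> pd.DataFrame:
        return self.outcomes[self.outcomes["visit"] != "baseline"]

    def wide_changes(self) -> pd.DataFrame:
        """Pivot to one row per patient with columns m12..m30 (NaN = missing)."""
        post = self.post_baseline()
        wide = post.pivot(index="patient_id", columns="visit", values="change_from_baseline")
        return wide.reindex(columns=list(POST_VISITS))


def _draw_strata(rng: np.random.Generator, n: int, cfg: TrialConfig) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "baseline_tafamidis": rng.random(n) < cfg.tafamidis_fraction,
            "attr_type": np.where(rng.random(n) < cfg.wild_type_fraction, "wild_type", "variant"),
            "age_group": np.where(rng.random(n) < cfg.ge75_fraction, "ge75", "lt75"),
            "nyha": np.where(rng.random(n) < cfg.nyha3_fraction, "III", "I_II"),
            "ntprobnp_high": rng.random(n) < cfg.ntprobnp_high_fraction,
        }
    )


def _exponential_day(rng: np.random.Generator, hazard: float, n: int) -> np.ndarray:
    """Event day for each of n patients, +inf when hazard is zero or event after m30."""
    if hazard <= 0:
        return np.full(n, np.inf)
    days = rng.exponential(1.0 / hazard, size=n)
    return np.where(days < _MONTH30_DAY, np.floor(days), np.inf)


def simulate_trial(config: TrialConfig) -> TrialDataset:
    """Generate a complete (pre-missingness) synthetic trial.

    Deterministic given ``config.seed``.  Each patient receives a baseline
    value and four post-baseline changes drawn from a multivariate normal with
    the arm's mean profile plus small additive stratum effects and a
    regression-to-the-mean term in the baseline deviation.
    """
    rng = np.random.default_rng([config.seed, 11])
    n = 2 * config.n_per_arm
    arm = np.repeat(ARMS, config.n_per_arm)
    patients = _draw_strata(rng, n, config)
    patients.insert(0, "patient_id", [f"P{i:04d}" for i in range(n)])
    patients.insert(1, "arm", arm)

    death_day = _exponential_day(rng, config.death_hazard, n)
    disc_day = _exponential_day(rng, config.discontinuation_hazard, n)
    # Discontinuation only counts if it happens before death and before m30.
    disc_day = np.where(disc_day < np.minimum(death_day, _MONTH30_DAY), disc_day, np.inf)
    end_of_dosing = np.minimum(np.minimum(death_day, disc_day), _MONTH30_DAY)
    last_dose = (np.floor(end_of_dosing / DOSE_INTERVAL_DAYS) * DOSE_INTERVAL_DAYS).astype(float)
    patients["death_day"] = pd.array(
        [int(d) if np.isfinite(d) else pd.NA for d in death_day], dtype="Int64"
    )
    patients["discontinued"] = np.isfinite(disc_day)
    patients["last_dose_day"] = pd.array([int(d) for d in last_dose], dtype="Int64")

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    mean = np.empty((n, 4))
    for a in ARMS:
        mask = arm == a
        mean[mask] = np.asarray(config.mean_profile_by_arm[a], dtype=float)
    mean += config.baseline_slope * (baseline - config.baseline_mean)[:, None]
    mean += np.where(patients["attr_type"] == "variant", config.attr_effect, 0.0)[:, None]
    mean += np.where(patients["age_group"] == "ge75", config.age_effect, 0.0)[:, None]
    mean += np.where(patients["baseline_tafamidis"], config.taf_effect, 0.0)[:, None]
    chol = np.linalg.cholesky(config.within_subject_covariance)
    changes = mean + rng.standard_normal((n, 4)) @ chol.T

    rows = []
    for j, visit in enumerate(VISITS):
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": patients["patient_id"],
                    "visit": visit,
                    "nominal_day": VISIT_DAYS[visit],
                    "parameter": config.parameter,
                    "baseline_value": baseline,
                    "change_from_baseline": 0.0 if visit == "baseline" else changes[:, j - 1],
                    "observed": True,
                }
            )
        )
    outcomes = pd.concat(rows, ignore_index=True)
    outcomes = outcomes.sort_values(["patient_id", "nominal_day"], kind="stable").reset_index(drop=True)
    meta = {"config": config.to_dict(), "true_effect_by_visit": config.true_effect_by_visit.tolist()}
    return TrialDataset(patients, outcomes, config.parameter, meta)


def _worse_sign(direction: WorseDirection) -> float:
    return -1.0 if direction == WorseDirection.DECREASE else 1.0


def apply_missingness(dataset: TrialDataset, config: TrialConfig) -> TrialDataset:
    """Delete assessments according to the configured mechanism.

    Rules, applied in order on post-baseline visits (mode ``none`` leaves the
    dataset untouched):

    1. every visit at or after ``death_day`` is missing;
    2. off-treatment visits of discontinued patients (nominal day more than
       126 days after the last dose) are missing with probability
       ``1 - off_treatment_observe_prob`` — the retained ones are the
       retrieved dropouts;
    3. mode-specific deletion: MCAR coin flips; MAR monotone dropout with a
       per-visit hazard logistic in the previous visit's (observed) change;
       MNAR deletion logistic in the value being deleted.

    MAR/MNAR logits score the change in the parameter's *worse* direction,
    so deteriorating patients are the likelier ones to go missing.
    """
    if config.missingness_mode == "none":
        return dataset.copy()
    rng = np.random.default_rng([config.seed, 23])
    out = dataset.copy()
    patients = out.patients.set_index("patient_id")
    wide = out.wide_changes()
    ids = wide.index.to_numpy()
    values = wide.to_numpy(dtype=float)
    n = len(ids)

    death = patients.loc[ids, "death_day"].to_numpy(dtype=float, na_value=np.inf)
    last_dose = patients.loc[ids, "last_dose_day"].to_numpy(dtype=float, na_value=np.inf)
    discontinued = patients.loc[ids, "discontinued"].to_numpy(dtype=bool)
    days = np.array([VISIT_DAYS[v] for v in POST_VISITS], dtype=float)

    missing = days[None, :] >= death[:, None]
    off_treatment = discontinued[:, None] & ((days[None, :] - last_dose[:, None]) > 126)
    missing |= off_treatment & (rng.random((n, 4)) >= config.off_treatment_observe_prob)

    sign = _worse_sign(config.worse_direction)
    sd = np.sqrt(np.diag(config.within_subject_covariance))
    centre = {a: np.asarray(config.mean_profile_by_arm[a], dtype=float) for a in ARMS}
    arm_centre = np.stack([centre[a] for a in patients.loc[ids, "arm"]])
    z_worse = sign * (values - arm_centre) / sd[None, :]

    if config.missingness_mode == "mcar":
        missing |= rng.random((n, 4)) < config.mcar_rate
    elif config.missingness_mode == "mar":
        dropped = np.zeros(n, dtype=bool)
        z_prev = np.zeros(n)
        for j in range(4):
            hazard = _expit(config.mar_intercept + config.mar_slope * z_prev)
            dropped |= rng.random(n) < hazard
            missing[:, j] |= dropped
            z_prev = np.where(missing[:, j], z_prev, z_worse[:, j])
    elif config.missingness_mode == "mnar":
        prob = _expit(config.mnar_intercept + config.mnar_slope * z_worse)
        missing |= rng.random((n, 4)) < prob

    flat = pd.DataFrame(missing, index=ids, columns=list(POST_VISITS)).stack()
    key = pd.MultiIndex.from_frame(out.outcomes[["patient_id", "visit"]])
    is_missing = flat.reindex(key).to_numpy(dtype=object)
    is_missing = np.array([bool(v) if v is not None and v == v else False for v in is_missing])
    out.outcomes.loc[is_missing, "change_from_baseline"] = np.nan
    out.outcomes.loc[is_missing, "observed"] = False
    return out


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Long-format CSV interchange

_CSV_COLUMNS = [
    "patient_id", "arm", "baseline_tafamidis", "attr_type", "age_group", "nyha",
    "ntprobnp_high", "death_day", "last_dose_day", "discontinued", "visit",
    "nominal_day", "parameter", "baseline_value", "change_from_baseline", "observed",
]


def write_long_csv(dataset: TrialDataset, path: str | Path, meta_path: str | Path | None = None) -> None:
    """Write the dataset as one long-format CSV row per patient-visit."""
    merged = dataset.outcomes.merge(dataset.patients, on="patient_id", how="left")
    merged[_CSV_COLUMNS].to_csv(path, index=False)
    if meta_path is not None:
        Path(meta_path).write_text(json.dumps(dataset.meta, indent=2))


def read_long_csv(path: str | Path, meta_path: str | Path | None = None) -> TrialDataset:
    df = pd.read_csv(
        path,
        dtype={"death_day": "Int64", "last_dose_day": "Int64"},
    )
    missing_cols = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"long-format CSV missing columns: {missing_cols}")
    params = df["parameter"].unique()
    if len(params) != 1:
        raise ValueError(f"expected a single parameter per file, found {sorted(params)}")
    patient_cols = ["patient_id", "arm", "baseline_tafamidis", "attr_type", "age_group",
                    "nyha", "ntprobnp_high", "death_day", "last_dose_day", "discontinued"]
    patients = df[patient_cols].drop_duplicates("patient_id").reset_index(drop=True)
    for col in ("baseline_tafamidis", "ntprobnp_high", "discontinued"):
        patients[col] = patients[col].astype(bool)
    outcome_cols = ["patient_id", "visit", "nominal_day", "parameter",
                    "baseline_value", "change_from_baseline", "observed"]
    outcomes = df[outcome_cols].copy()
    outcomes["observed"] = outcomes["observed"].astype(bool)
    meta = {}
    if meta_path is not None and Path(meta_path).exists():
        meta = json.loads(Path(meta_path).read_text())
    return TrialDataset(patients, outcomes, str(params[0]), meta)
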