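"""Pattern-mixture multiple imputation for missing echo assessments.

Every missing post-baseline change is classified into one of four patterns
and imputed by a pattern-specific rule:

* **Pattern 1 — death** (including transplant / LV assist device before the
  month-30 visit): sample with replacement from the worst 10% of observed
  changes at the same visit, arm and baseline-tafamidis group, where "worst"
  follows the parameter registry's worse direction.
* **Pattern 2 — active arm, missing on treatment** (visit within 126 days of
  the last dose, 1.5 x the 84-day dosing interval): missing at random;
  multivariate-normal multiple imputation estimated from active-arm patients'
  on-treatment data in the same tafamidis group, via Markov-chain Monte Carlo
  data augmentation (handles nonmonotone gaps natively).
* **Pattern 3 — active arm, missing off treatment**: (i) if at least 10
  retrieved dropouts (discontinued but still assessed >126 days after last
  dose) exist at month 30 in the same tafamidis group, impute by Bayesian
  regression estimated on the retrieved dropouts; (ii) otherwise treat as
  missing not at random and impute by *copy reference* — the patient's
  outcome distribution is taken entirely from placebo patients in the same
  tafamidis group, conditioning on the patient's observed changes.
* **Pattern 4 — placebo arm**: (i) retrieved-dropout imputation when
  sufficient, for off-treatment gaps; (ii) otherwise MAR imputation
  estimated from all placebo patients in the same tafamidis group.

Every imputed change, whatever the method, is capped below at
``0 - baseline`` so the imputed post-baseline value never goes negative.
The imputation model covariates are ATTR genotype, NYHA class, age group,
NT-proBNP group and the baseline value.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .echo import PARAMETER_REGISTRY, ParameterRegistryEntry, WorseDirection
from .trial import POST_VISITS, VISIT_DAYS, TrialDataset

__all__ = [
    "WINDOW_DAYS",
    "PatternAssignment",
    "ImputationRun",
    "classify_patterns",
    "find_retrieved_dropouts",
    "impute_worst_decile",
    "apply_cap",
    "MVNImputationChain",
    "impute_mcmc_mar",
    "run_pattern_mixture",
]

#: Off-treatment window: 1.5 x the 84-day dosing interval.
WINDOW_DAYS = 126
_M30_DAY = VISIT_DAYS["m30"]
_RETRIEVED_MIN = 10

PATTERNS = (
    "P1_death",
    "P2_vutri_on_treatment",
    "P3i_vutri_retrieved",
    "P3ii_vutri_copy_reference",
    "P4i_placebo_retrieved",
    "P4ii_placebo_mar",
)

_COVARIATE_COLS = ["attr_type", "nyha", "age_group", "ntprobnp_high"]


@dataclass
class PatternAssignment:
    patient_id: str
    visit: str
    pattern: str
    days_since_last_dose: Optional[int] = None


class UnroutableCellError(ValueError):
    pass


def find_retrieved_dropouts(
    dataset: TrialDataset, arm: str, tafamidis_group: bool, window_days: int = WINDOW_DAYS
) -> Tuple[List[str], bool]:
    """Retrieved dropouts at month 30 for one arm / baseline-tafamidis group.

    A retrieved dropout discontinued study treatment yet has an observed
    month-30 assessment more than ``window_days`` after the last dose.
    Sufficiency means at least 10 of them.
    """
    pts = dataset.patients
    sel = pts[(pts["arm"] == arm) & (pts["baseline_tafamidis"] == tafamidis_group) & pts["discontinued"]]
    if sel.empty:
        return [], False
    m30 = dataset.outcomes[
        (dataset.outcomes["visit"] == "m30") & dataset.outcomes["observed"]
    ]
    observed_m30 = set(m30["patient_id"])
    ids = []
    for _, row in sel.iterrows():
        if row["patient_id"] not in observed_m30 or pd.isna(row["last_dose_day"]):
            continue
        if _M30_DAY - int(row["last_dose_day"]) > window_days:
            ids.append(row["patient_id"])
    return ids, len(ids) >= _RETRIEVED_MIN


def classify_patterns(
    dataset: TrialDataset,
    window_days: int = WINDOW_DAYS,
    pattern1_scope: str = "after_death",
) -> List[PatternAssignment]:
    """Assign exactly one pattern to every missing post-baseline cell.

    ``pattern1_scope`` controls whether death captures only the patient's
    visits at/after the death day (``"after_death"``, default) or all of the
    decedent's missing visits (``"all_missing"``).
    """
    if pattern1_scope not in ("after_death", "all_missing"):
        raise ValueError(f"unknown pattern1_scope {pattern1_scope!r}")
    pts = dataset.patients.set_index("patient_id")
    sufficiency = {
        (arm, taf): find_retrieved_dropouts(dataset, arm, taf, window_days)[1]
        for arm in ("placebo", "vutrisiran")
        for taf in (False, True)
    }
    out: List[PatternAssignment] = []
    missing = dataset.post_baseline()
    missing = missing[~missing["observed"]]
    for _, row in missing.iterrows():
        pid, visit, day = row["patient_id"], row["visit"], int(row["nominal_day"])
        p = pts.loc[pid]
        death = p["death_day"]
        died_before_m30 = pd.notna(death) and int(death) < _M30_DAY
        if died_before_m30 and (pattern1_scope == "all_missing" or day >= int(death)):
            out.append(PatternAssignment(pid, visit, "P1_death"))
            continue
        if pd.isna(p["last_dose_day"]):
            raise UnroutableCellError(
                f"patient {pid}: missing last_dose_day, cannot apply the {window_days}-day window"
            )
        dsld = day - int(p["last_dose_day"])
        taf = bool(p["baseline_tafamidis"])
        if p["arm"] == "vutrisiran":
            if dsld <= window_days:
                out.append(PatternAssignment(pid, visit, "P2_vutri_on_treatment", dsld))
            elif sufficiency[("vutrisiran", taf)]:
                out.append(PatternAssignment(pid, visit, "P3i_vutri_retrieved", dsld))
            else:
                out.append(PatternAssignment(pid, visit, "P3ii_vutri_copy_reference", dsld))
        else:
            if dsld <= window_days:
                out.append(PatternAssignment(pid, visit, "P4ii_placebo_mar", dsld))
            elif sufficiency[("placebo", taf)]:
                out.append(PatternAssignment(pid, visit, "P4i_placebo_retrieved", dsld))
            else:
                out.append(PatternAssignment(pid, visit, "P4ii_placebo_mar", dsld))
    return out


def apply_cap(change: float, baseline_value: float) -> float:
    """Cap an imputed change below at the worst possible change, 0 - baseline."""
    return max(change, 0.0 - baseline_value)


def worst_decile_pool(
    values: np.ndarray, direction: WorseDirection
) -> np.ndarray:
    """The worst ceil(0.1*n) observed changes, per the registry direction."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("empty donor pool")
    n_keep = math.ceil(0.1 * values.size)
    ordered = np.sort(values)
    if direction == WorseDirection.DECREASE:
        return ordered[:n_keep]
    return ordered[-n_keep:]


def impute_worst_decile(
    dataset: TrialDataset,
    patient_id: str,
    visit: str,
    registry_entry: ParameterRegistryEntry,
    rng: np.random.Generator,
) -> Tuple[float, int]:
    """One capped draw from the worst decile of same visit/arm/tafamidis donors.

    Falls back to the arm-level pool (ignoring the tafamidis split) when the
    stratified pool is empty.  Returns (imputed change, decile pool size).
    """
    pts = dataset.patients.set_index("patient_id")
    p = pts.loc[patient_id]
    obs = dataset.outcomes
    obs = obs[(obs["visit"] == visit) & obs["observed"] & obs["change_from_baseline"].notna()]
    obs = obs.merge(dataset.patients[["patient_id", "arm", "baseline_tafamidis"]], on="patient_id")
    same_arm = obs[obs["arm"] == p["arm"]]
    pool = same_arm[same_arm["baseline_tafamidis"] == bool(p["baseline_tafamidis"])]
    if pool.empty:
        pool = same_arm
    if pool.empty:
        raise ValueError(f"no donors for {patient_id}/{visit} even at arm level")
    decile = worst_decile_pool(pool["change_from_baseline"].to_numpy(), registry_entry.worse_direction)
    draw = float(decile[rng.integers(0, decile.size)])
    base = float(dataset.outcomes.loc[
        (dataset.outcomes["patient_id"] == patient_id), "baseline_value"
    ].iloc[0])
    return apply_cap(draw, base), int(decile.size)


def _decile_pool_cache(
    dataset: TrialDataset, entry: ParameterRegistryEntry
) -> Dict[Tuple[str, str, Optional[bool]], np.ndarray]:
    """Worst-decile donor pools per (visit, arm, tafamidis group); None key = arm level."""
    obs = dataset.post_baseline()
    obs = obs[obs["observed"] & obs["change_from_baseline"].notna()].merge(
        dataset.patients[["patient_id", "arm", "baseline_tafamidis"]], on="patient_id"
    )
    pools: Dict[Tuple[str, str, Optional[bool]], np.ndarray] = {}
    for (visit, arm), grp in obs.groupby(["visit", "arm"]):
        pools[(visit, arm, None)] = worst_decile_pool(
            grp["change_from_baseline"].to_numpy(), entry.worse_direction
        )
        for taf, sub in grp.groupby("baseline_tafamidis"):
            pools[(visit, arm, bool(taf))] = worst_decile_pool(
                sub["change_from_baseline"].to_numpy(), entry.worse_direction
            )
    return pools


def _retrieved_estimation(
    dataset: TrialDataset, retrieved_ids: Sequence[str], visit: str, window_days: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Covariate matrix and responses of retrieved dropouts observed at a visit.

    Prefers off-treatment observations (more than ``window_days`` after the
    last dose); widens to any observation at the visit if none qualify.
    """
    pts = dataset.patients.set_index("patient_id")
    obs = dataset.outcomes
    obs = obs[
        (obs["visit"] == visit)
        & obs["observed"]
        & obs["change_from_baseline"].notna()
        & obs["patient_id"].isin(set(retrieved_ids))
    ]
    day = VISIT_DAYS[visit]
    rows = []
    for _, r in obs.iterrows():
        ld = pts.loc[r["patient_id"], "last_dose_day"]
        if pd.notna(ld) and day - int(ld) > window_days:
            rows.append(r)
    if not rows:
        rows = [r for _, r in obs.iterrows()]
    if not rows:
        raise ValueError(f"retrieved dropouts have no observations at visit {visit}")
    ye = np.array([float(r["change_from_baseline"]) for r in rows])
    Xfull = np.stack(
        [_covariate_row(pts.loc[r["patient_id"]], float(r["baseline_value"])) for r in rows]
    )
    return Xfull, ye


def _regression_design_or_fallback(
    Xfull: np.ndarray, x_full: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Full covariate design when estimable, else intercept+baseline, else intercept."""
    n = Xfull.shape[0]
    if n >= Xfull.shape[1] + 2 and np.linalg.matrix_rank(Xfull) == Xfull.shape[1]:
        return Xfull, x_full
    Xe, x_new = Xfull[:, [0, 5]], x_full[[0, 5]]
    if n >= 3 and np.linalg.matrix_rank(Xe) == 2:
        return Xe, x_new
    return Xfull[:, [0]], x_full[[0]]


# ---------------------------------------------------------------------------
# Bayesian multivariate-normal machinery

def _invwishart_bartlett(nu: int, S: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from InverseWishart(nu, S) via the Bartlett decomposition."""
    k = S.shape[0]
    if nu < k:
        raise ValueError(f"inverse-Wishart needs nu >= dimension, got nu={nu}, k={k}")
    try:
        L = np.linalg.cholesky(np.linalg.inv(S))
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(np.linalg.inv(_floor_pd(S, rel=1e-10)))
    T = np.zeros((k, k))
    for i in range(k):
        T[i, i] = math.sqrt(rng.chisquare(nu - i))
        for j in range(i):
            T[i, j] = rng.standard_normal()
    A = L @ T
    W = A @ A.T
    return np.linalg.inv(W)


def _floor_pd(S: np.ndarray, rel: float = 1e-8) -> np.ndarray:
    w, V = np.linalg.eigh(0.5 * (S + S.T))
    floor = rel * max(w.max(), 1e-12)
    return (V * np.maximum(w, floor)) @ V.T


def _chol_or_floor(S: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(_floor_pd(S))


def _conditional_normal(
    mu: np.ndarray, psi: np.ndarray, obs_idx: np.ndarray, mis_idx: np.ndarray, y_obs: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of the missing block given the observed block."""
    if obs_idx.size == 0:
        return mu[mis_idx], psi[np.ix_(mis_idx, mis_idx)]
    poo = psi[np.ix_(obs_idx, obs_idx)]
    pmo = psi[np.ix_(mis_idx, obs_idx)]
    sol = np.linalg.solve(poo, (y_obs - mu[obs_idx]))
    gain = np.linalg.solve(poo, pmo.T).T
    cond_mu = mu[mis_idx] + pmo @ sol
    cond_cov = psi[np.ix_(mis_idx, mis_idx)] - gain @ pmo.T
    return cond_mu, _floor_pd(cond_cov)


class MVNImputationChain:
    """Data-augmentation sampler for a multivariate-normal regression.

    Outcome rows ``Y`` (n x k, NaN = missing for estimation) regress on
    covariates ``X`` (n x q); the chain alternates an I-step (draw missing
    cells from their conditional normal) and a P-step (draw the coefficient
    matrix and covariance from the conjugate posterior under a Jeffreys
    prior).  Nonmonotone missingness needs no special handling.
    """

    def __init__(self, Y: np.ndarray, X: np.ndarray, rng: np.random.Generator):
        self.Y = np.array(Y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.rng = rng
        self.n, self.k = self.Y.shape
        self.q = self.X.shape[1]
        if self.n < self.q + self.k + 1:
            raise ValueError(
                f"estimation sample too small: n={self.n} rows for q={self.q} covariates "
                f"and k={self.k} outcomes"
            )
        self.miss = np.isnan(self.Y)
        self.XtX = self.X.T @ self.X
        self.XtX_inv = np.linalg.inv(self.XtX)
        self.L_xtx_inv = np.linalg.cholesky(_floor_pd(self.XtX_inv))
        # starting values: column-mean fill, then OLS
        Y0 = self.Y.copy()
        col_mean = np.nanmean(np.where(self.miss, np.nan, self.Y), axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        Y0[self.miss] = np.broadcast_to(col_mean, Y0.shape)[self.miss]
        self.Yc = Y0
        self.B = self.XtX_inv @ self.X.T @ self.Yc
        resid = self.Yc - self.X @ self.B
        self.Psi = _floor_pd(resid.T @ resid / max(self.n - self.q, 1), rel=1e-6)
        # group rows by missingness pattern once
        self._patterns: List[Tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        seen: Dict[Tuple[bool, ...], List[int]] = {}
        for i in range(self.n):
            seen.setdefault(tuple(self.miss[i]), []).append(i)
        for patt, rows in seen.items():
            mis = np.flatnonzero(patt)
            if mis.size == 0:
                continue
            obs = np.flatnonzero(~np.array(patt))
            self._patterns.append((np.array(rows), obs, mis))

    def _i_step(self) -> None:
        mu_all = self.X @ self.B
        for rows, obs, mis in self._patterns:
            pmo = self.Psi[np.ix_(mis, obs)]
            pmm = self.Psi[np.ix_(mis, mis)]
            if obs.size:
                poo = self.Psi[np.ix_(obs, obs)]
                gain = np.linalg.solve(poo, pmo.T).T
                cond_cov = pmm - gain @ pmo.T
                resid_obs = self.Yc[np.ix_(rows, obs)] - mu_all[np.ix_(rows, obs)]
                cond_mu = mu_all[np.ix_(rows, mis)] + resid_obs @ gain.T
            else:
                cond_cov = pmm
                cond_mu = mu_all[np.ix_(rows, mis)]
            Lc = _chol_or_floor(cond_cov)
            z = self.rng.standard_normal((rows.size, mis.size))
            self.Yc[np.ix_(rows, mis)] = cond_mu + z @ Lc.T
        # never overwrite observed cells
        self.Yc[~self.miss] = self.Y[~self.miss]

    def _p_step(self) -> None:
        Bhat = self.XtX_inv @ (self.X.T @ self.Yc)
        resid = self.Yc - self.X @ Bhat
        S = resid.T @ resid
        nu = self.n - self.q
        self.Psi = _invwishart_bartlett(nu, S, self.rng)
        Lp = _chol_or_floor(self.Psi)
        Z = self.rng.standard_normal((self.q, self.k))
        self.B = Bhat + self.L_xtx_inv @ Z @ Lp.T

    def run(self, burn_in: int, n_draws: int, thin: int):
        """Yield ``n_draws`` retained (B, Psi) pairs after burn-in, ``thin`` apart."""
        for _ in range(burn_in):
            self._i_step()
            self._p_step()
        for d in range(n_draws):
            steps = 1 if d == 0 else thin
            for _ in range(steps):
                self._i_step()
                self._p_step()
            yield self.B.copy(), self.Psi.copy()


def _covariate_row(patient: pd.Series, baseline: float) -> np.ndarray:
    return np.array(
        [
            1.0,
            1.0 if patient["attr_type"] == "variant" else 0.0,
            1.0 if patient["nyha"] == "III" else 0.0,
            1.0 if patient["age_group"] == "ge75" else 0.0,
            1.0 if patient["ntprobnp_high"] else 0.0,
            baseline,
        ]
    )


def _estimation_matrices(
    dataset: TrialDataset,
    arm: str,
    taf_group: bool,
    on_treatment_only: bool,
    window_days: int,
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Per-group (Y, X, patient ids) for the data-augmentation chain."""
    pts = dataset.patients
    sel = pts[(pts["arm"] == arm) & (pts["baseline_tafamidis"] == taf_group)]
    ids = list(sel["patient_id"])
    wide = dataset.wide_changes().reindex(ids)
    base = (
        dataset.outcomes.drop_duplicates("patient_id")
        .set_index("patient_id")["baseline_value"]
        .reindex(ids)
    )
    Y = wide.to_numpy(dtype=float)
    if on_treatment_only:
        last_dose = sel.set_index("patient_id")["last_dose_day"].reindex(ids)
        days = np.array([VISIT_DAYS[v] for v in POST_VISITS], dtype=float)
        ld = last_dose.to_numpy(dtype=float, na_value=np.inf)
        off = (days[None, :] - ld[:, None]) > window_days
        Y = np.where(off, np.nan, Y)
    X = np.stack(
        [
            _covariate_row(row, float(base[row["patient_id"]]))
            for _, row in sel.iterrows()
        ]
    )
    keep = np.isfinite(X[:, -1])
    return Y[keep], X[keep], [pid for pid, k in zip(ids, keep) if k]


def impute_mcmc_mar(
    dataset: TrialDataset,
    arm: str,
    taf_group: bool,
    target_cells: Sequence[Tuple[str, str]],
    m: int,
    seed: int,
    burn_in: int = 500,
    thin: int = 100,
    on_treatment_only: Optional[bool] = None,
    window_days: int = WINDOW_DAYS,
) -> Tuple[Dict[Tuple[str, str], np.ndarray], int]:
    """MAR multiple imputation for one arm / tafamidis group via MCMC.

    The chain is estimated from the group's observed data (restricted to
    on-treatment assessments for the active arm); each retained posterior
    draw of the regression parameters generates one imputation of the
    ``target_cells`` from the conditional normal given the patient's
    conditioning-eligible observed changes.  Returns per-cell arrays of m
    capped draws and the estimation-sample size.
    """
    if on_treatment_only is None:
        on_treatment_only = arm == "vutrisiran"
    Y, X, est_ids = _estimation_matrices(dataset, arm, taf_group, on_treatment_only, window_days)
    chain_rng = np.random.default_rng([seed & 0x7FFFFFFF, 31, int(taf_group), 0 if arm == "placebo" else 1])
    chain = MVNImputationChain(Y, X, chain_rng)

    draws = {cell: np.empty(m) for cell in target_cells}
    ctx = _patient_context(dataset, {pid for pid, _ in target_cells}, on_treatment_only, window_days)
    visit_pos = {v: i for i, v in enumerate(POST_VISITS)}
    by_patient: Dict[str, List[str]] = {}
    for pid, visit in target_cells:
        by_patient.setdefault(pid, []).append(visit)

    for t, (B, Psi) in enumerate(chain.run(burn_in, m, thin)):
        rng_t = np.random.default_rng([seed & 0x7FFFFFFF, 41, int(taf_group), 0 if arm == "placebo" else 1, t])
        for pid, visits in by_patient.items():
            x, y_row, cond_mask, base = ctx[pid]
            mis = np.array([visit_pos[v] for v in visits])
            obs = np.flatnonzero(cond_mask & ~np.isin(np.arange(4), mis))
            mu = B.T @ x
            cmu, ccov = _conditional_normal(mu, Psi, obs, mis, y_row[obs])
            z = rng_t.standard_normal(mis.size)
            vals = cmu + np.linalg.cholesky(ccov) @ z
            for v, val in zip(visits, vals):
                draws[(pid, v)][t] = apply_cap(float(val), base)
    return draws, len(est_ids)


def _patient_context(
    dataset: TrialDataset,
    patient_ids: set,
    on_treatment_only: bool,
    window_days: int,
) -> Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray, float]]:
    """Per patient: covariate row, wide change row, conditioning mask, baseline."""
    pts = dataset.patients.set_index("patient_id")
    wide = dataset.wide_changes()
    base = dataset.outcomes.drop_duplicates("patient_id").set_index("patient_id")["baseline_value"]
    days = np.array([VISIT_DAYS[v] for v in POST_VISITS], dtype=float)
    out = {}
    for pid in patient_ids:
        p = pts.loc[pid]
        b = float(base[pid])
        y_row = wide.loc[pid].to_numpy(dtype=float)
        observed = np.isfinite(y_row)
        if on_treatment_only and pd.notna(p["last_dose_day"]):
            observed &= (days - float(p["last_dose_day"])) <= window_days
        out[pid] = (_covariate_row(p, b), y_row, observed, b)
    return out


def _bayes_regression_draw(
    Xe: np.ndarray, ye: np.ndarray, x_new: np.ndarray, rng: np.random.Generator
) -> float:
    """One posterior-predictive draw from a normal linear regression (Jeffreys prior)."""
    n, p = Xe.shape
    XtX = Xe.T @ Xe
    bhat = np.linalg.solve(XtX, Xe.T @ ye)
    ssr = float(np.sum((ye - Xe @ bhat) ** 2))
    df = n - p
    sigma2 = ssr / rng.chisquare(df) if ssr > 0 else 0.0
    if sigma2 > 0:
        Lb = np.linalg.cholesky(np.linalg.inv(XtX))
        beta = bhat + math.sqrt(sigma2) * (Lb @ rng.standard_normal(p))
        return float(x_new @ beta + math.sqrt(sigma2) * rng.standard_normal())
    return float(x_new @ bhat)


def impute_retrieved_dropout(
    dataset: TrialDataset,
    patient_id: str,
    visit: str,
    retrieved_ids: Sequence[str],
    rng: np.random.Generator,
    window_days: int = WINDOW_DAYS,
) -> Tuple[float, int]:
    """Capped Bayesian-regression draw anchored on retrieved dropouts.

    The regression of the visit's change on baseline and covariates is
    estimated solely from retrieved dropouts' off-treatment observations at
    that visit; degenerate designs fall back to intercept + baseline.
    Returns (imputed change, estimation rows used).
    """
    if not retrieved_ids:
        raise ValueError("retrieved-dropout imputation requires a nonempty retrieved set")
    pts = dataset.patients.set_index("patient_id")
    Xfull, ye = _retrieved_estimation(dataset, retrieved_ids, visit, window_days)
    base = float(
        dataset.outcomes.loc[dataset.outcomes["patient_id"] == patient_id, "baseline_value"].iloc[0]
    )
    x_full = _covariate_row(pts.loc[patient_id], base)
    Xe, x_new = _regression_design_or_fallback(Xfull, x_full)
    draw = _bayes_regression_draw(Xe, ye, x_new, rng)
    return apply_cap(draw, base), len(ye)


def impute_copy_reference(
    y_row: np.ndarray,
    observed_mask: np.ndarray,
    mis_idx: np.ndarray,
    x_cov: np.ndarray,
    B_ref: np.ndarray,
    Psi_ref: np.ndarray,
    baseline_value: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Copy-reference draw: the patient's joint outcome law is the reference's.

    ``B_ref``/``Psi_ref`` are a posterior draw of the placebo-arm regression
    parameters for the same tafamidis group; the missing cells are drawn from
    the reference conditional normal given the patient's observed
    post-baseline changes and covariates, then capped.
    """
    obs = np.flatnonzero(observed_mask & ~np.isin(np.arange(len(y_row)), mis_idx))
    mu = B_ref.T @ x_cov
    cmu, ccov = _conditional_normal(mu, Psi_ref, obs, mis_idx, y_row[obs])
    vals = cmu + np.linalg.cholesky(ccov) @ rng.standard_normal(mis_idx.size)
    return np.array([apply_cap(float(v), baseline_value) for v in vals])


# ---------------------------------------------------------------------------
# Orchestration

@dataclass
class ImputationRun:
    """m completed datasets plus per-cell provenance."""

    m: int
    seed: int
    completed_datasets: List[TrialDataset]
    provenance: pd.DataFrame     # patient_id, visit, pattern, method, donor_pool_size
    assignments: List[PatternAssignment] = field(default_factory=list)


def run_pattern_mixture(
    dataset: TrialDataset,
    m: int = 100,
    seed: int = 0,
    registry: Mapping[str, ParameterRegistryEntry] = PARAMETER_REGISTRY,
    window_days: int = WINDOW_DAYS,
    burn_in: int = 500,
    thin: int = 100,
    pattern1_scope: str = "after_death",
) -> ImputationRun:
    """Classify, impute per pattern, cap, and emit m completed datasets.

    Deterministic given ``seed``; per-imputation-index draws use separate
    seeded streams.  Observed cells are never altered.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    entry = registry.get(dataset.parameter)
    if entry is None:
        raise KeyError(f"parameter {dataset.parameter!r} not in registry")
    assignments = classify_patterns(dataset, window_days, pattern1_scope)
    seed &= 0x7FFFFFFF

    by_pattern: Dict[str, List[PatternAssignment]] = {p: [] for p in PATTERNS}
    for a in assignments:
        by_pattern[a.pattern].append(a)

    pts = dataset.patients.set_index("patient_id")
    # cell -> (pattern, donor size); draws[cell] -> m values
    draws: Dict[Tuple[str, str], np.ndarray] = {}
    pool_sizes: Dict[Tuple[str, str], int] = {}

    # Pattern 1: worst-decile sampling (donor pools computed once per stratum)
    if by_pattern["P1_death"]:
        pools = _decile_pool_cache(dataset, entry)
        baselines = (
            dataset.outcomes.drop_duplicates("patient_id")
            .set_index("patient_id")["baseline_value"]
        )
        for a in by_pattern["P1_death"]:
            cell = (a.patient_id, a.visit)
            p = pts.loc[a.patient_id]
            decile = pools.get((a.visit, p["arm"], bool(p["baseline_tafamidis"])))
            if decile is None:
                decile = pools.get((a.visit, p["arm"], None))
            if decile is None:
                raise UnroutableCellError(f"no donors for {cell} even at arm level")
            base = float(baselines[a.patient_id])
            rng = np.random.default_rng([seed, 51, _cell_hash(cell)])
            idx = rng.integers(0, decile.size, size=m)
            draws[cell] = np.maximum(decile[idx], 0.0 - base)
            pool_sizes[cell] = int(decile.size)

    # Patterns 2 and 4ii: MAR MCMC MI per arm x tafamidis group
    mar_cells: Dict[Tuple[str, bool], List[Tuple[str, str]]] = {}
    for a in by_pattern["P2_vutri_on_treatment"]:
        taf = bool(pts.loc[a.patient_id, "baseline_tafamidis"])
        mar_cells.setdefault(("vutrisiran", taf), []).append((a.patient_id, a.visit))
    for a in by_pattern["P4ii_placebo_mar"]:
        taf = bool(pts.loc[a.patient_id, "baseline_tafamidis"])
        mar_cells.setdefault(("placebo", taf), []).append((a.patient_id, a.visit))
    for (arm, taf), cells in mar_cells.items():
        got, est_n = impute_mcmc_mar(
            dataset, arm, taf, cells, m, seed, burn_in=burn_in, thin=thin, window_days=window_days
        )
        draws.update(got)
        for cell in cells:
            pool_sizes[cell] = est_n

    # Patterns 3i / 4i: retrieved-dropout regression (estimation rows cached per stratum/visit)
    retrieved_cache: Dict[Tuple[str, bool], List[str]] = {}
    est_cache: Dict[Tuple[str, bool, str], Tuple[np.ndarray, np.ndarray]] = {}
    baselines = (
        dataset.outcomes.drop_duplicates("patient_id").set_index("patient_id")["baseline_value"]
    )
    for pattern, arm in (("P3i_vutri_retrieved", "vutrisiran"), ("P4i_placebo_retrieved", "placebo")):
        for a in by_pattern[pattern]:
            taf = bool(pts.loc[a.patient_id, "baseline_tafamidis"])
            key = (arm, taf)
            if key not in retrieved_cache:
                ids, sufficient = find_retrieved_dropouts(dataset, arm, taf, window_days)
                if not sufficient:
                    raise UnroutableCellError(
                        f"cell {a.patient_id}/{a.visit} routed to retrieved-dropout imputation "
                        f"but {arm}/taf={taf} has <{_RETRIEVED_MIN} retrieved dropouts"
                    )
                retrieved_cache[key] = ids
            ekey = (arm, taf, a.visit)
            if ekey not in est_cache:
                est_cache[ekey] = _retrieved_estimation(
                    dataset, retrieved_cache[key], a.visit, window_days
                )
            Xfull, ye = est_cache[ekey]
            base = float(baselines[a.patient_id])
            x_full = _covariate_row(pts.loc[a.patient_id], base)
            Xe, x_new = _regression_design_or_fallback(Xfull, x_full)
            cell = (a.patient_id, a.visit)
            rng = np.random.default_rng([seed, 61, _cell_hash(cell)])
            vals = np.array(
                [apply_cap(_bayes_regression_draw(Xe, ye, x_new, rng), base) for _ in range(m)]
            )
            draws[cell] = vals
            pool_sizes[cell] = int(len(ye))

    # Pattern 3ii: copy reference from the placebo arm in the same tafamidis group
    cr_by_group: Dict[bool, List[PatternAssignment]] = {}
    for a in by_pattern["P3ii_vutri_copy_reference"]:
        taf = bool(pts.loc[a.patient_id, "baseline_tafamidis"])
        cr_by_group.setdefault(taf, []).append(a)
    visit_pos = {v: i for i, v in enumerate(POST_VISITS)}
    for taf, cells in cr_by_group.items():
        Y, X, est_ids = _estimation_matrices(dataset, "placebo", taf, False, window_days)
        chain = MVNImputationChain(
            Y, X, np.random.default_rng([seed, 71, int(taf)])
        )
        ctx = _patient_context(dataset, {a.patient_id for a in cells}, False, window_days)
        by_patient: Dict[str, List[str]] = {}
        for a in cells:
            by_patient.setdefault(a.patient_id, []).append(a.visit)
        buffers = {(a.patient_id, a.visit): np.empty(m) for a in cells}
        for t, (B, Psi) in enumerate(chain.run(burn_in, m, thin)):
            rng_t = np.random.default_rng([seed, 81, int(taf), t])
            for pid, visits in by_patient.items():
                x, y_row, cond_mask, base = ctx[pid]
                mis = np.array([visit_pos[v] for v in visits])
                vals = impute_copy_reference(y_row, cond_mask, mis, x, B, Psi, base, rng_t)
                for v, val in zip(visits, vals):
                    buffers[(pid, v)][t] = val
        draws.update(buffers)
        for a in cells:
            pool_sizes[(a.patient_id, a.visit)] = len(est_ids)

    unrouted = [
        (a.patient_id, a.visit) for a in assignments if (a.patient_id, a.visit) not in draws
    ]
    if unrouted:
        raise UnroutableCellError(f"cells left unimputed: {unrouted}")

    completed = []
    for t in range(m):
        ds = dataset.copy()
        out = ds.outcomes
        key = list(zip(out["patient_id"], out["visit"]))
        fill = np.array([draws[c][t] if c in draws else np.nan for c in key])
        mask = np.isfinite(fill) & ~out["observed"].to_numpy()
        out.loc[mask, "change_from_baseline"] = fill[mask]
        out.loc[mask, "observed"] = False  # imputed, not observed; analysis uses the value
        ds.meta = dict(ds.meta, imputation_index=t, imputation_seed=seed)
        completed.append(ds)

    method_of = {
        "P1_death": "worst_decile",
        "P2_vutri_on_treatment": "mcmc_mar",
        "P3i_vutri_retrieved": "retrieved_dropout",
        "P3ii_vutri_copy_reference": "copy_reference",
        "P4i_placebo_retrieved": "retrieved_dropout",
        "P4ii_placebo_mar": "mcmc_mar",
    }
    provenance = pd.DataFrame(
        {
            "patient_id": [a.patient_id for a in assignments],
            "visit": [a.visit for a in assignments],
            "pattern": [a.pattern for a in assignments],
            "method": [method_of[a.pattern] for a in assignments],
            "donor_pool_size": [pool_sizes[(a.patient_id, a.visit)] for a in assignments],
        }
    )
    return ImputationRun(m=m, seed=seed, completed_datasets=completed,
                         provenance=provenance, assignments=assignments)


def _cell_hash(cell: Tuple[str, str]) -> int:
    return zlib.crc32(f"{cell[0]}|{cell[1]}".encode()) % (2**31 - 1)
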