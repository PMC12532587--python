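"""Month-30 ANCOVA per imputed dataset and Rubin's-rules pooling.

The sensitivity analysis fits an analysis of covariance to the month-30
change from baseline in each completed dataset (baseline value as covariate;
treatment, baseline tafamidis use, treatment-by-tafamidis interaction, ATTR
genotype and age group as factors; the tafamidis terms are dropped outside
the overall population) and combines the m LS-mean treatment differences by
Rubin's rules with Barnard–Rubin small-sample degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .imputation import ImputationRun
from .mmrm import ModelSpec, RankDeficientDesignError, _population_mask
from .trial import TrialDataset

__all__ = ["AncovaResult", "PooledEstimate", "fit_ancova", "rubin_pool", "sensitivity_report"]


@dataclass
class AncovaResult:
    estimate: float        # LS-mean treatment difference (active - placebo)
    se: float
    df: float              # residual degrees of freedom
    n: int


@dataclass
class PooledEstimate:
    q_bar: float
    u_bar: float           # mean within-imputation variance
    b: float               # between-imputation variance
    total_variance: float  # u_bar + (1 + 1/m) b
    df: float              # Barnard-Rubin
    ci_low: float
    ci_high: float
    p_value: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_variance))


def _ancova_design(dataset: TrialDataset, spec: ModelSpec, visit: str = "m30"):
    patients = dataset.patients
    keep = set(patients.loc[_population_mask(patients, spec.population), "patient_id"])
    rows = dataset.outcomes
    rows = rows[
        (rows["visit"] == visit)
        & rows["patient_id"].isin(keep)
        & rows["change_from_baseline"].notna()
        & rows["baseline_value"].notna()
    ].merge(
        patients[["patient_id", "arm", "baseline_tafamidis", "attr_type", "age_group"]],
        on="patient_id",
    )
    if rows.empty:
        raise ValueError(f"no usable {visit} responses in population {spec.population!r}")
    active = (rows["arm"] == "vutrisiran").to_numpy(dtype=float)
    cols = [np.ones(len(rows)), active]
    names = ["intercept", "trt"]
    if "baseline" in spec.covariates:
        cols.append(rows["baseline_value"].to_numpy(dtype=float))
        names.append("baseline")
    if "attr_type" in spec.covariates:
        cols.append((rows["attr_type"] == "variant").to_numpy(dtype=float))
        names.append("attr[variant]")
    if "age_group" in spec.covariates:
        cols.append((rows["age_group"] == "ge75").to_numpy(dtype=float))
        names.append("age[ge75]")
    if spec.include_tafamidis_terms:
        taf = rows["baseline_tafamidis"].to_numpy(dtype=float)
        cols.append(taf)
        names.append("taf")
        cols.append(taf * active)
        names.append("trt:taf")
    X = np.column_stack(cols)
    y = rows["change_from_baseline"].to_numpy(dtype=float)
    return X, y, names


def fit_ancova(dataset: TrialDataset, spec: ModelSpec, visit: str = "m30") -> AncovaResult:
    """OLS ANCOVA; the estimate is the LS-mean difference with equal factor weights.

    With tafamidis terms in the model the treatment difference averages the
    two tafamidis strata: c = trt + 0.5 * trt:taf.
    """
    X, y, names = _ancova_design(dataset, spec, visit)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"ANCOVA needs more than {p} observations, got {n}")
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(XtX)
    if rank < p:
        raise RankDeficientDesignError(
            f"ANCOVA design rank deficient ({rank} < {p}); terms: {names}"
        )
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    XtX_inv = np.linalg.inv(XtX)
    c = np.zeros(p)
    c[names.index("trt")] = 1.0
    if "trt:taf" in names:
        c[names.index("trt:taf")] = 0.5
    est = float(c @ beta)
    se = float(np.sqrt(sigma2 * (c @ XtX_inv @ c)))
    return AncovaResult(estimate=est, se=se, df=float(df), n=n)


def rubin_pool(
    estimates: np.ndarray,
    ses: np.ndarray,
    alpha: float = 0.05,
    complete_df: Optional[float] = None,
) -> PooledEstimate:
    """Combine m estimates and standard errors by Rubin's rules.

    q_bar = mean(q_i); u_bar = mean(se_i^2); b = var(q_i, ddof=1);
    T = u_bar + (1 + 1/m) b.  Degrees of freedom follow Barnard-Rubin when a
    complete-data df is supplied, otherwise the classic (m-1)/lambda^2.
    """
    q = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if q.ndim != 1 or q.shape != s.shape or q.size < 2:
        raise ValueError("need matching 1-d arrays of >= 2 estimates and ses")
    bad = ~(np.isfinite(q) & np.isfinite(s))
    if bad.any():
        raise ValueError(f"nonfinite inputs at imputation indices {np.flatnonzero(bad).tolist()}")
    m = q.size
    q_bar = float(q.mean())
    u_bar = float(np.mean(s**2))
    b = float(np.sum((q - q_bar) ** 2) / (m - 1))
    T = u_bar + (1.0 + 1.0 / m) * b

    if T <= 0:  # degenerate: all ses zero and no between-variance
        return PooledEstimate(q_bar, u_bar, b, T, np.inf, q_bar, q_bar,
                              0.0 if q_bar != 0 else 1.0, m)
    lam = (1.0 + 1.0 / m) * b / T
    if lam <= 0:
        df = complete_df if complete_df is not None else np.inf
    else:
        nu_old = (m - 1) / lam**2
        if complete_df is None:
            df = nu_old
        else:
            nu_com = float(complete_df)
            nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
            df = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
    se = float(np.sqrt(T))
    tcrit = stats.t.ppf(1 - alpha / 2, df) if np.isfinite(df) else stats.norm.ppf(1 - alpha / 2)
    tstat = q_bar / se
    p = 2 * (stats.t.sf(abs(tstat), df) if np.isfinite(df) else stats.norm.sf(abs(tstat)))
    return PooledEstimate(
        q_bar=q_bar, u_bar=u_bar, b=b, total_variance=T, df=float(df),
        ci_low=q_bar - tcrit * se, ci_high=q_bar + tcrit * se, p_value=float(p), m=m,
    )


def sensitivity_report(
    run: ImputationRun, spec: ModelSpec, visit: str = "m30"
) -> Tuple[PooledEstimate, List[AncovaResult]]:
    """ANCOVA on each completed dataset, pooled by Rubin's rules."""
    fits = [fit_ancova(ds, spec, visit) for ds in run.completed_datasets]
    pooled = rubin_pool(
        np.array([f.estimate for f in fits]),
        np.array([f.se for f in fits]),
        alpha=spec.alpha,
        complete_df=fits[0].df,
    )
    return pooled, fits


def pooled_table(pooled: PooledEstimate, spec: ModelSpec, parameter: str) -> pd.DataFrame:
    """One-row CSV-ready summary comparable to the primary MMRM row."""
    return pd.DataFrame(
        [
            {
                "parameter": parameter,
                "population": spec.population,
                "q_bar": pooled.q_bar,
                "se": pooled.se,
                "ci_low": pooled.ci_low,
                "ci_high": pooled.ci_high,
                "df": pooled.df,
                "p": pooled.p_value,
                "m": pooled.m,
            }
        ]
    )
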