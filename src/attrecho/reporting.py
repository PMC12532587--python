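"""End-to-end orchestration: descriptive tables, primary MMRM run, sensitivity run.

These functions are what the command-line interface wraps: read or simulate a
long-format dataset, fit the repeated-measures model per population, emit a
table of LS-mean changes and placebo-corrected differences per visit, run the
pattern-mixture sensitivity analysis, and record a manifest sufficient to
reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .echo import EchoMeasurementRecord, derive_panel
from .imputation import run_pattern_mixture
from .mmrm import ModelSpec, analyze
from .pooling import pooled_table, sensitivity_report
from .trial import (
    VISIT_DAYS,
    VISITS,
    TrialConfig,
    TrialDataset,
    apply_missingness,
    simulate_trial,
    write_long_csv,
)

logger = logging.getLogger("attrecho")

__all__ = [
    "RunManifest",
    "descriptive_table",
    "derive_long_from_raw",
    "run_primary",
    "run_sensitivity",
    "simulate_to_csv",
]

_PATIENT_COLS = ["patient_id", "arm", "baseline_tafamidis", "attr_type", "age_group",
                 "nyha", "ntprobnp_high", "death_day", "last_dose_day", "discontinued"]


def derive_long_from_raw(
    raw_csv: str | Path,
    parameter: str,
    out_csv: Optional[str | Path] = None,
) -> TrialDataset:
    """Convert a wide per-visit raw-measurement CSV to a long change-from-baseline dataset.

    The input has one row per patient-visit with the patient/stratum columns
    plus raw measurement columns named after
    :class:`~attrecho.echo.EchoMeasurementRecord` fields; each row is run
    through the derivation operations and the requested registry parameter
    is extracted.  Patients without a derivable baseline value are excluded
    and logged.  A visit row that is absent, or whose inputs do not support
    the parameter, yields a missing change.
    """
    import dataclasses as _dc

    df = pd.read_csv(raw_csv, dtype={"death_day": "Int64", "last_dose_day": "Int64"})
    missing_cols = [c for c in _PATIENT_COLS + ["visit"] if c not in df.columns]
    if missing_cols:
        raise ValueError(f"raw CSV missing columns: {missing_cols}")
    scalar_fields = {
        f.name for f in _dc.fields(EchoMeasurementRecord) if not f.name.startswith("disc_")
    }
    meas_cols = [c for c in df.columns if c in scalar_fields]

    values: Dict[str, Dict[str, float]] = {}
    for _, row in df.iterrows():
        kwargs = {
            c: (None if pd.isna(row[c]) else float(row[c])) for c in meas_cols
        }
        panel = derive_panel(EchoMeasurementRecord(**kwargs))
        if parameter in panel:
            values.setdefault(row["patient_id"], {})[row["visit"]] = panel[parameter]

    patients = df[_PATIENT_COLS].drop_duplicates("patient_id").reset_index(drop=True)
    excluded = [
        pid for pid in patients["patient_id"] if "baseline" not in values.get(pid, {})
    ]
    if excluded:
        logger.warning(
            "%d patients excluded for parameter %s (no derivable baseline): %s",
            len(excluded), parameter, excluded[:10],
        )
    patients = patients[~patients["patient_id"].isin(excluded)].reset_index(drop=True)

    rows = []
    for pid in patients["patient_id"]:
        series = values[pid]
        base = series["baseline"]
        for visit in VISITS:
            present = visit in series
            change = 0.0 if visit == "baseline" else (
                series[visit] - base if present else np.nan
            )
            rows.append(
                {
                    "patient_id": pid,
                    "visit": visit,
                    "nominal_day": VISIT_DAYS[visit],
                    "parameter": parameter,
                    "baseline_value": base,
                    "change_from_baseline": change,
                    "observed": bool(present),
                }
            )
    outcomes = pd.DataFrame(rows)
    dataset = TrialDataset(patients, outcomes, parameter,
                           meta={"source": str(raw_csv), "excluded_no_baseline": excluded})
    if out_csv is not None:
        write_long_csv(dataset, out_csv)
    return dataset


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str = __version__
    created: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())
    python: str = field(default_factory=platform.python_version)
    stage_counts: Dict[str, int] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def _config_hash(config: TrialConfig) -> str:
    return hashlib.sha256(json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def descriptive_table(dataset: TrialDataset, populations: tuple = ("overall", "monotherapy")) -> pd.DataFrame:
    """Baseline n / mean / sd per arm and analysis population (observed values only)."""
    rows = []
    base = dataset.outcomes[dataset.outcomes["visit"] == "baseline"].merge(
        dataset.patients[["patient_id", "arm", "baseline_tafamidis"]], on="patient_id"
    )
    for population in populations:
        if population == "monotherapy":
            sub = base[~base["baseline_tafamidis"]]
        elif population == "tafamidis_subgroup":
            sub = base[base["baseline_tafamidis"]]
        else:
            sub = base
        for arm, grp in sub.groupby("arm"):
            values = grp.loc[grp["observed"], "baseline_value"].dropna()
            rows.append(
                {
                    "parameter": dataset.parameter,
                    "population": population,
                    "arm": arm,
                    "n": int(values.size),
                    "mean": float(values.mean()) if values.size else np.nan,
                    "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def run_primary(
    dataset: TrialDataset,
    population: str = "overall",
    alpha: float = 0.05,
    out_dir: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Fit the MMRM and return one row per visit with LS means and the contrast."""
    spec = ModelSpec(parameter=dataset.parameter, population=population, alpha=alpha)
    fit, contrasts = analyze(dataset, spec)
    if not fit.converged:
        raise RuntimeError("MMRM did not converge")
    logger.info(
        "MMRM %s/%s: %d subjects, %d observations, REML loglik %.3f",
        dataset.parameter, population, fit.n_subjects, fit.n_observations, fit.reml_loglik,
    )
    rows = []
    for c in contrasts:
        rows.append(
            {
                "parameter": dataset.parameter,
                "population": population,
                "visit": c.visit,
                "lsmean_placebo": c.ls_mean_by_arm["placebo"][0],
                "sem_placebo": c.ls_mean_by_arm["placebo"][1],
                "lsmean_vutrisiran": c.ls_mean_by_arm["vutrisiran"][0],
                "sem_vutrisiran": c.ls_mean_by_arm["vutrisiran"][1],
                "difference": c.difference,
                "se": c.se,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "df": c.df,
                "p_value": c.p_value,
                "n_subjects": fit.n_subjects,
            }
        )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / f"primary_{dataset.parameter}_{population}.csv", index=False)
        fit_report = {
            "parameter": dataset.parameter,
            "population": population,
            "beta": dict(zip(fit.col_names, map(float, fit.beta))),
            "sigma": fit.sigma.tolist(),
            "visits": fit.design.visits,
            "reml_loglik": fit.reml_loglik,
            "converged": fit.converged,
            "n_iter": fit.n_iter,
            "n_subjects": fit.n_subjects,
            "n_observations": fit.n_observations,
            "contrasts": [
                {"visit": c.visit, "difference": c.difference, "se": c.se,
                 "ci_low": c.ci_low, "ci_high": c.ci_high, "df": c.df,
                 "p_value": c.p_value}
                for c in contrasts
            ],
        }
        (out_dir / f"fit_{dataset.parameter}_{population}.json").write_text(
            json.dumps(fit_report, indent=2)
        )
    return table


def run_sensitivity(
    dataset: TrialDataset,
    population: str = "overall",
    m: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    out_dir: Optional[str | Path] = None,
    burn_in: int = 500,
    thin: int = 100,
) -> pd.DataFrame:
    """Pattern-mixture MI + per-imputation ANCOVA + Rubin pooling at month 30."""
    spec = ModelSpec(parameter=dataset.parameter, population=population, alpha=alpha)
    run = run_pattern_mixture(dataset, m=m, seed=seed, burn_in=burn_in, thin=thin)
    logger.info(
        "pattern mixture: %d missing cells (%s)",
        len(run.assignments),
        dict(run.provenance["pattern"].value_counts()) if len(run.provenance) else {},
    )
    pooled, _ = sensitivity_report(run, spec)
    table = pooled_table(pooled, spec, dataset.parameter)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / f"sensitivity_{dataset.parameter}_{population}.csv", index=False)
        sidecar = run.provenance.copy()
        expanded = pd.concat(
            [sidecar.assign(imputation_index=t) for t in range(run.m)], ignore_index=True
        )[["patient_id", "visit", "imputation_index", "pattern", "donor_pool_size"]]
        expanded.to_csv(out_dir / f"provenance_{dataset.parameter}_{population}.csv", index=False)
    return table


def simulate_to_csv(config: TrialConfig, out_path: str | Path, meta_path: Optional[str | Path] = None) -> TrialDataset:
    """Simulate, apply the configured missingness, and write the long CSV."""
    dataset = apply_missingness(simulate_trial(config), config)
    write_long_csv(dataset, out_path, meta_path)
    manifest = RunManifest(
        config_hash=_config_hash(config),
        seed=config.seed,
        stage_counts={
            "patients": len(dataset.patients),
            "patient_visits": len(dataset.outcomes),
            "missing_post_baseline": int((~dataset.post_baseline()["observed"]).sum()),
        },
    )
    if meta_path is not None:
        manifest.write(str(meta_path) + ".manifest.json")
    return dataset
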