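"""Mixed model for repeated measures (MMRM) with unstructured covariance.

The primary longitudinal model for change from baseline: each patient's
vector of post-baseline changes is Gaussian with a mean given by fixed
effects (visit, treatment-by-visit, baseline covariate, stratification
factors) and a shared unstructured covariance over visits.  Patients
contribute through the submatrix of the covariance matching their observed
visits, so incomplete cases are used without imputation (valid under MAR).

Estimation maximizes the restricted (REML) Gaussian likelihood over a
log-Cholesky parameterization of the covariance using analytic gradients;
the fixed effects are profiled out by generalized least squares.  Treatment
contrasts are least-squares (LS) means: classification factors weighted
equally across levels, the baseline covariate fixed at its analysis-set
mean, with Satterthwaite degrees of freedom by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .trial import ARMS, POST_VISITS, TrialDataset

__all__ = [
    "ModelSpec",
    "MMRMDesign",
    "MMRMFit",
    "LSMeanContrast",
    "build_design",
    "fit_mmrm",
    "ls_means",
    "treatment_contrast",
    "analyze",
]

POPULATIONS = ("overall", "monotherapy", "tafamidis_subgroup")


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: analysis population, covariates, coding and inference options.

    The overall population includes baseline-tafamidis and
    treatment-by-tafamidis fixed effects; the monotherapy and tafamidis
    subgroup populations drop both (the factor is constant there).
    """

    parameter: str = "stroke_volume"
    population: str = "overall"
    alpha: float = 0.05
    covariates: Tuple[str, ...] = ("baseline", "attr_type", "age_group")
    coding: str = "cell_means"          # cell_means | reference
    df_method: str = "satterthwaite"    # satterthwaite | residual

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")
        if self.coding not in ("cell_means", "reference"):
            raise ValueError(f"unknown coding {self.coding!r}")
        if self.df_method not in ("satterthwaite", "residual"):
            raise ValueError(f"unknown df_method {self.df_method!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def include_tafamidis_terms(self) -> bool:
        return self.population == "overall"


@dataclass
class MMRMDesign:
    """Realized design: response, fixed-effect matrix and subject/visit indexing."""

    y: np.ndarray                # (N,) change from baseline
    X: np.ndarray                # (N, p)
    col_names: List[str]
    subject_ids: np.ndarray      # (N,) patient id per row
    visit_idx: np.ndarray        # (N,) index into `visits`
    visits: List[str]
    baseline_mean: float
    n_subjects: int
    spec: ModelSpec

    @property
    def n_visits(self) -> int:
        return len(self.visits)


class RankDeficientDesignError(ValueError):
    pass


def _population_mask(patients: pd.DataFrame, population: str) -> pd.Series:
    if population == "overall":
        return pd.Series(True, index=patients.index)
    if population == "monotherapy":
        return ~patients["baseline_tafamidis"]
    return patients["baseline_tafamidis"]


def build_design(dataset: TrialDataset, spec: ModelSpec) -> MMRMDesign:
    """Assemble response and fixed-effect matrix from observed post-baseline rows.

    Patients outside the analysis population or without a baseline value are
    excluded; missing responses are simply absent rows.  Raises
    :class:`RankDeficientDesignError` naming the aliased columns if the
    realized matrix is rank deficient.
    """
    patients = dataset.patients
    keep_ids = set(patients.loc[_population_mask(patients, spec.population), "patient_id"])
    post = dataset.post_baseline()
    rows = post[
        post["patient_id"].isin(keep_ids)
        & post["observed"]
        & post["change_from_baseline"].notna()
        & post["baseline_value"].notna()
    ].copy()
    if rows.empty:
        raise ValueError("no observed post-baseline responses in the analysis population")

    visits = [v for v in POST_VISITS if v in set(rows["visit"])]
    visit_pos = {v: i for i, v in enumerate(visits)}
    rows["_vidx"] = rows["visit"].map(visit_pos)
    rows = rows.merge(
        patients[["patient_id", "arm", "baseline_tafamidis", "attr_type", "age_group"]],
        on="patient_id",
    )
    rows = rows.sort_values(["patient_id", "_vidx"], kind="stable").reset_index(drop=True)

    active = (rows["arm"] == "vutrisiran").to_numpy(dtype=float)
    baseline = rows["baseline_value"].to_numpy(dtype=float)
    baseline_mean = float(
        rows.drop_duplicates("patient_id")["baseline_value"].mean()
    )

    cols: List[np.ndarray] = []
    names: List[str] = []
    k = len(visits)
    vind = rows["_vidx"].to_numpy()
    if spec.coding == "cell_means":
        for i, v in enumerate(visits):
            cols.append((vind == i).astype(float))
            names.append(f"visit[{v}]")
        for i, v in enumerate(visits):
            cols.append(((vind == i)).astype(float) * active)
            names.append(f"trt:visit[{v}]")
    else:  # reference coding: intercept + visit offsets + trt + trt:visit offsets
        cols.append(np.ones(len(rows)))
        names.append("intercept")
        for i, v in enumerate(visits[1:], start=1):
            cols.append((vind == i).astype(float))
            names.append(f"visit[{v}]")
        cols.append(active.copy())
        names.append("trt")
        for i, v in enumerate(visits[1:], start=1):
            cols.append((vind == i).astype(float) * active)
            names.append(f"trt:visit[{v}]")
    if "baseline" in spec.covariates:
        cols.append(baseline)
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
    # structurally empty columns (an unpopulated arm-by-visit cell or factor
    # level) are dropped rather than flagged as aliasing
    nonzero = np.any(X != 0.0, axis=0)
    X = X[:, nonzero]
    names = [n for n, keep in zip(names, nonzero) if keep]
    _check_full_rank(X, names)
    return MMRMDesign(
        y=rows["change_from_baseline"].to_numpy(dtype=float),
        X=X,
        col_names=names,
        subject_ids=rows["patient_id"].to_numpy(),
        visit_idx=vind,
        visits=visits,
        baseline_mean=baseline_mean,
        n_subjects=rows["patient_id"].nunique(),
        spec=spec,
    )


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [names[j] for j in piv[rank:]]
        raise RankDeficientDesignError(f"design matrix is rank deficient; aliased terms: {aliased}")


# ---------------------------------------------------------------------------
# REML machinery

def _theta_index(k: int) -> List[Tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(i + 1)]


def _theta_to_chol(theta: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((k, k))
    for t, (i, j) in enumerate(_theta_index(k)):
        L[i, j] = np.exp(theta[t]) if i == j else theta[t]
    return L


def _chol_to_theta(L: np.ndarray) -> np.ndarray:
    k = L.shape[0]
    return np.array([np.log(L[i, i]) if i == j else L[i, j] for (i, j) in _theta_index(k)])


def _dsigma_stack(L: np.ndarray) -> np.ndarray:
    """d(LL')/dtheta for every log-Cholesky coordinate, stacked (n_theta, k, k)."""
    k = L.shape[0]
    idx = _theta_index(k)
    out = np.empty((len(idx), k, k))
    for t, (i, j) in enumerate(idx):
        dL = np.zeros((k, k))
        dL[i, j] = L[i, j] if i == j else 1.0
        m = dL @ L.T
        out[t] = m + m.T
    return out


@dataclass
class _MaskGroup:
    mask: Tuple[int, ...]
    Y: np.ndarray   # (g, k_m)
    X: np.ndarray   # (g, k_m, p)


def _group_by_mask(design: MMRMDesign) -> List[_MaskGroup]:
    order = np.argsort(design.subject_ids, kind="stable")
    sids = design.subject_ids[order]
    boundaries = np.flatnonzero(np.r_[True, sids[1:] != sids[:-1]])
    groups: Dict[Tuple[int, ...], List[Tuple[np.ndarray, np.ndarray]]] = {}
    for b, e in zip(boundaries, np.r_[boundaries[1:], len(sids)]):
        rows = order[b:e]
        vi = design.visit_idx[rows]
        sub_order = np.argsort(vi)
        rows = rows[sub_order]
        mask = tuple(design.visit_idx[rows])
        groups.setdefault(mask, []).append((design.y[rows], design.X[rows]))
    return [
        _MaskGroup(mask, np.stack([y for y, _ in items]), np.stack([x for _, x in items]))
        for mask, items in groups.items()
    ]


def _neg_loglik_and_grad(
    theta: np.ndarray, groups: List[_MaskGroup], k: int, p: int, reml: bool
) -> Tuple[float, np.ndarray]:
    L = _theta_to_chol(theta, k)
    sigma = L @ L.T
    dS = _dsigma_stack(L)
    nt = dS.shape[0]

    logdet_sum = 0.0
    W = np.zeros((p, p))
    Xty = np.zeros(p)
    cache = []
    for grp in groups:
        m = np.array(grp.mask)
        sub = sigma[np.ix_(m, m)]
        try:
            c = linalg.cholesky(sub, lower=True)
        except linalg.LinAlgError:
            return np.inf, np.zeros(nt)
        isub = linalg.cho_solve((c, True), np.eye(len(m)))
        g = grp.Y.shape[0]
        logdet_sum += g * 2.0 * np.log(np.diag(c)).sum()
        T = np.einsum("kl,glp->gkp", isub, grp.X)
        W += np.einsum("gkp,gkq->pq", T, grp.X)
        Xty += np.einsum("gkp,gk->p", T, grp.Y)
        cache.append((m, isub, T, g))
    try:
        cW = linalg.cho_factor(W)
    except linalg.LinAlgError:
        return np.inf, np.zeros(nt)
    beta = linalg.cho_solve(cW, Xty)
    Winv = linalg.cho_solve(cW, np.eye(p))
    logdet_W = 2.0 * np.log(np.diag(cW[0])).sum()

    quad = 0.0
    grad = np.zeros(nt)
    for grp, (m, isub, T, g) in zip(groups, cache):
        dS_m = dS[:, m[:, None], m[None, :]]           # (nt, k_m, k_m)
        R = grp.Y - grp.X @ beta                       # (g, k_m)
        Rt = R @ isub                                  # (g, k_m)
        quad += np.einsum("gk,gk->", Rt, R)
        t_trace = g * np.einsum("kl,xkl->x", isub, dS_m)
        r_term = np.einsum("gk,xkl,gl->x", Rt, dS_m, Rt)
        grad += t_trace - r_term
        if reml:
            C = np.einsum("gkp,pq,glq->kl", T, Winv, T)
            grad -= np.einsum("kl,xkl->x", C, dS_m)
    nll = 0.5 * (logdet_sum + quad + (logdet_W if reml else 0.0))
    return float(nll), 0.5 * grad


def _start_theta(design: MMRMDesign) -> np.ndarray:
    """Pairwise-complete covariance of OLS residuals, floored to PD."""
    X, y = design.X, design.y
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    k = design.n_visits
    p_rank = np.linalg.matrix_rank(X)
    dof_adj = max(1.0, p_rank / k)
    S = np.zeros((k, k))
    wide = np.full((design.n_subjects, k), np.nan)
    order = np.argsort(design.subject_ids, kind="stable")
    sids = design.subject_ids[order]
    row_of = {}
    for pos, sid in zip(order, sids):
        row_of.setdefault(sid, len(row_of))
        wide[row_of[sid], design.visit_idx[pos]] = resid[pos]
    for i in range(k):
        for j in range(i + 1):
            both = ~np.isnan(wide[:, i]) & ~np.isnan(wide[:, j])
            n_ij = both.sum()
            if n_ij > dof_adj:
                S[i, j] = S[j, i] = np.sum(wide[both, i] * wide[both, j]) / (n_ij - dof_adj)
    # fall back for empty pairs; floor eigenvalues for PD start
    if not np.all(np.diag(S) > 0):
        v = np.nanvar(wide, axis=0)
        v = np.where(np.isfinite(v) & (v > 0), v, np.nanmean(v[v > 0]) if np.any(v > 0) else 1.0)
        S = S + np.diag(np.where(np.diag(S) > 0, 0.0, v))
    w, V = np.linalg.eigh(S)
    floor = 1e-6 * max(w.max(), 1e-12)
    S = (V * np.maximum(w, floor)) @ V.T
    return _chol_to_theta(np.linalg.cholesky(S))


@dataclass
class MMRMFit:
    """Fitted MMRM: fixed effects, covariance and everything needed for contrasts."""

    beta: np.ndarray
    col_names: List[str]
    sigma: np.ndarray               # (k, k) unstructured covariance over visits
    vcov_beta: np.ndarray           # (p, p) model-based covariance of beta
    reml_loglik: float
    converged: bool
    n_subjects: int
    n_observations: int
    design: MMRMDesign
    theta: np.ndarray
    theta_cov: Optional[np.ndarray] = None
    n_iter: int = 0
    reml: bool = True
    _groups: List[_MaskGroup] = field(default_factory=list, repr=False)

    @property
    def residual_df(self) -> float:
        return float(self.n_observations - len(self.beta))


def fit_mmrm(design: MMRMDesign, reml: bool = True, maxiter: int = 300) -> MMRMFit:
    """Maximize the (restricted) likelihood over the log-Cholesky covariance.

    Quasi-Newton (L-BFGS) with analytic gradients; convergence requires a
    relative objective change below 1e-10 or a gradient norm below 1e-6.
    A fit that fails both is returned with ``converged=False``.
    """
    groups = _group_by_mask(design)
    k, p = design.n_visits, design.X.shape[1]
    theta0 = _start_theta(design)

    res = optimize.minimize(
        _neg_loglik_and_grad,
        theta0,
        args=(groups, k, p, reml),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-8},
    )
    theta = res.x
    _, grad = _neg_loglik_and_grad(theta, groups, k, p, reml)
    converged = bool(res.success or np.linalg.norm(grad) < 1e-6)

    L = _theta_to_chol(theta, k)
    sigma = L @ L.T
    W, Xty = _normal_equations(theta, groups, k, p)
    cW = linalg.cho_factor(W)
    beta = linalg.cho_solve(cW, Xty)
    vcov = linalg.cho_solve(cW, np.eye(p))
    return MMRMFit(
        beta=beta,
        col_names=design.col_names,
        sigma=sigma,
        vcov_beta=vcov,
        reml_loglik=-res.fun,
        converged=converged,
        n_subjects=design.n_subjects,
        n_observations=len(design.y),
        design=design,
        theta=theta,
        n_iter=int(res.nit),
        reml=reml,
        _groups=groups,
    )


def _normal_equations(
    theta: np.ndarray, groups: List[_MaskGroup], k: int, p: int
) -> Tuple[np.ndarray, np.ndarray]:
    L = _theta_to_chol(theta, k)
    sigma = L @ L.T
    W = np.zeros((p, p))
    Xty = np.zeros(p)
    for grp in groups:
        m = np.array(grp.mask)
        sub = sigma[np.ix_(m, m)]
        isub = np.linalg.inv(sub)
        T = np.einsum("kl,glp->gkp", isub, grp.X)
        W += np.einsum("gkp,gkq->pq", T, grp.X)
        Xty += np.einsum("gkp,gk->p", T, grp.Y)
    return W, Xty


def _theta_covariance(fit: MMRMFit) -> np.ndarray:
    """Inverse observed REML information, via finite differences of the analytic score."""
    if fit.theta_cov is not None:
        return fit.theta_cov
    k, p = fit.design.n_visits, fit.design.X.shape[1]
    nt = len(fit.theta)
    H = np.zeros((nt, nt))
    h = 1e-5
    for t in range(nt):
        e = np.zeros(nt)
        e[t] = h
        _, gp = _neg_loglik_and_grad(fit.theta + e, fit._groups, k, p, fit.reml)
        _, gm = _neg_loglik_and_grad(fit.theta - e, fit._groups, k, p, fit.reml)
        H[t] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    fit.theta_cov = np.linalg.pinv(H)
    return fit.theta_cov


def _dW_stack(fit: MMRMFit) -> np.ndarray:
    """dW/dtheta stacked (n_theta, p, p), W = sum_i X_i' V_i^-1 X_i."""
    k, p = fit.design.n_visits, fit.design.X.shape[1]
    L = _theta_to_chol(fit.theta, k)
    sigma = L @ L.T
    dS = _dsigma_stack(L)
    out = np.zeros((dS.shape[0], p, p))
    for grp in fit._groups:
        m = np.array(grp.mask)
        isub = np.linalg.inv(sigma[np.ix_(m, m)])
        T = np.einsum("kl,glp->gkp", isub, grp.X)
        dS_m = dS[:, m[:, None], m[None, :]]
        out -= np.einsum("gkp,xkl,glq->xpq", T, dS_m, T)
    return out


def satterthwaite_df(fit: MMRMFit, contrast: np.ndarray) -> float:
    """Satterthwaite degrees of freedom for a single contrast c'beta."""
    c = np.asarray(contrast, dtype=float)
    v = float(c @ fit.vcov_beta @ c)
    dW = _dW_stack(fit)
    Wc = fit.vcov_beta @ c
    grad_v = -np.einsum("p,xpq,q->x", Wc, dW, Wc)
    A = _theta_covariance(fit)
    denom = float(grad_v @ A @ grad_v)
    if denom <= 0 or not np.isfinite(denom):
        return fit.residual_df
    df = 2.0 * v * v / denom
    return float(np.clip(df, 1.0, fit.residual_df if fit.residual_df > 1 else df))


# ---------------------------------------------------------------------------
# LS means and contrasts

@dataclass
class LSMeanContrast:
    visit: str
    ls_mean_by_arm: Dict[str, Tuple[float, float]]   # arm -> (estimate, se)
    difference: float
    se: float
    ci_low: float
    ci_high: float
    df: float
    p_value: float


def _lsmean_vector(design: MMRMDesign, visit: str, arm: str) -> np.ndarray:
    """Prediction row for the LS mean of `arm` at `visit`.

    Classification factors enter at weight 1/2 per level; the baseline
    covariate at its analysis-set mean.
    """
    if visit not in design.visits:
        raise ValueError(f"visit {visit!r} not in fitted model (visits: {design.visits})")
    active = 1.0 if arm == "vutrisiran" else 0.0
    x = np.zeros(len(design.col_names))
    for j, name in enumerate(design.col_names):
        if name == "intercept":
            x[j] = 1.0
        elif name == f"visit[{visit}]":
            x[j] = 1.0
        elif name == f"trt:visit[{visit}]":
            x[j] = active
        elif name == "trt":
            x[j] = active
        elif name == "baseline":
            x[j] = design.baseline_mean
        elif name in ("attr[variant]", "age[ge75]", "taf"):
            x[j] = 0.5
        elif name == "trt:taf":
            x[j] = 0.5 * active
    return x


def ls_means(fit: MMRMFit, visit: str) -> Dict[str, Tuple[float, float]]:
    """Per-arm LS mean (estimate, SE) at a visit."""
    if not fit.converged:
        raise RuntimeError("fit did not converge; refusing to report LS means")
    out = {}
    for arm in ARMS:
        x = _lsmean_vector(fit.design, visit, arm)
        out[arm] = (float(x @ fit.beta), float(np.sqrt(x @ fit.vcov_beta @ x)))
    return out


def treatment_contrast(fit: MMRMFit, visit: str, alpha: Optional[float] = None) -> LSMeanContrast:
    """Active-minus-placebo LS-mean difference at a visit with CI and p-value."""
    if not fit.converged:
        raise RuntimeError("fit did not converge; refusing to compute contrasts")
    spec = fit.design.spec
    alpha = spec.alpha if alpha is None else alpha
    c = _lsmean_vector(fit.design, visit, "vutrisiran") - _lsmean_vector(fit.design, visit, "placebo")
    diff = float(c @ fit.beta)
    se = float(np.sqrt(c @ fit.vcov_beta @ c))
    if spec.df_method == "satterthwaite":
        df = satterthwaite_df(fit, c)
    else:
        df = fit.residual_df
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    tstat = diff / se if se > 0 else np.inf
    p = 2 * stats.t.sf(abs(tstat), df)
    return LSMeanContrast(
        visit=visit,
        ls_mean_by_arm=ls_means(fit, visit),
        difference=diff,
        se=se,
        ci_low=diff - tcrit * se,
        ci_high=diff + tcrit * se,
        df=float(df),
        p_value=float(p),
    )


def analyze(dataset: TrialDataset, spec: ModelSpec, reml: bool = True) -> Tuple[MMRMFit, List[LSMeanContrast]]:
    """Build the design, fit, and return contrasts at every modeled visit."""
    design = build_design(dataset, spec)
    fit = fit_mmrm(design, reml=reml)
    contrasts = [treatment_contrast(fit, v) for v in design.visits]
    return fit, contrasts
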