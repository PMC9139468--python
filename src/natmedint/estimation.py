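"""Least-squares fitting of the structural models and bootstrap inference.

The workflow mirrors the regression-based estimation of the decomposition:
fit the three linear models by ordinary least squares (identical to
maximum likelihood under Gaussian errors), plug the coefficient estimates
and the unbiased residual-variance estimate of the M1 model into the
closed-form component formulas, and attach percentile bootstrap confidence
intervals from nonparametric case resampling.

The outcome model always contains all two-way and three-way interactions
among exposure and mediators; the M2 model regresses on (A, M1, A*M1, C)
in the sequential scenario and on (A, C) otherwise; the M1 model on
(A, C).  A per-column ``log`` transform directive supports skewed
mediators, with reference levels interpreted on the transformed scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .closed_form import compute_aggregates, decompose_linear
from .sem_model import (
    COMPONENT_FIELDS,
    NONSEQUENTIAL,
    SEQUENTIAL,
    AggregateEffects,
    DecompositionRequest,
    DecompositionResult,
    LinearSEM,
    Scenario,
)

__all__ = [
    "SAMPLE_MEAN",
    "FittedSEM",
    "IntervalReport",
    "fit_sem",
    "estimate_decomposition",
    "bootstrap_decomposition",
    "resolve_request",
]

#: sentinel for "use the sample mean of the (transformed) column"
SAMPLE_MEAN = "sample-mean"

_RCOND = 1e-10


@dataclass(frozen=True)
class FittedSEM:
    """Point estimates of the structural coefficients plus diagnostics.

    ``sem.sigma_m1`` is the square root of the unbiased residual-variance
    estimate (denominator n - p) of the M1 model, as the closed forms
    require; ``model_diagnostics`` carries per-model residual variances and
    coefficient standard errors.
    """

    sem: LinearSEM
    sample_size: int
    model_diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class IntervalReport:
    """Percentile bootstrap intervals for every component and aggregate."""

    estimate: Mapping[str, float]
    lower: Mapping[str, float]
    upper: Mapping[str, float]
    level: float
    n_replicates: int
    n_dropped: int
    seed: Optional[int]
    replicates: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        return {
            name: {
                "estimate": float(self.estimate[name]),
                "lower": float(self.lower[name]),
                "upper": float(self.upper[name]),
            }
            for name in self.estimate
        }


def _prepare(data: pd.DataFrame, column_map: Mapping) -> pd.DataFrame:
    """Select and transform the analysis columns; returns y, m1, m2, a, C."""
    cm = dict(column_map)
    out = {}
    for key in ("y", "m1", "m2", "a"):
        col = cm.get(key, key)
        if col not in data.columns:
            raise ValueError(f"column {col!r} (for {key}) not found in data")
        out[key] = data[col].to_numpy(dtype=float)
    cov_cols = cm.get("covariates", [])
    for col in cov_cols:
        if col not in data.columns:
            raise ValueError(f"covariate column {col!r} not found in data")
    C = (data[list(cov_cols)].to_numpy(dtype=float)
         if cov_cols else np.empty((len(data), 0)))
    frame = pd.DataFrame(out)
    for key, transform in dict(cm.get("transforms", {})).items():
        if transform == "log":
            if key in frame:
                frame[key] = np.log(frame[key])
            else:
                raise ValueError(f"transform for unknown variable {key!r}")
        else:
            raise ValueError(f"unknown transform {transform!r}")
    for i in range(C.shape[1]):
        frame[f"_c{i}"] = C[:, i]
    if not np.all(np.isfinite(frame.to_numpy())):
        raise ValueError("non-finite values in analysis columns (after transforms)")
    return frame


def _design_matrices(frame: pd.DataFrame, scenario: Scenario):
    a = frame["a"].to_numpy()
    m1 = frame["m1"].to_numpy()
    m2 = frame["m2"].to_numpy()
    C = frame[[c for c in frame.columns if c.startswith("_c")]].to_numpy()
    one = np.ones_like(a)
    X_y = np.column_stack(
        [one, a, m1, m2, a * m1, a * m2, m1 * m2, a * m1 * m2, C])
    if scenario == SEQUENTIAL:
        X_m2 = np.column_stack([one, a, m1, a * m1, C])
    else:
        X_m2 = np.column_stack([one, a, C])
    X_m1 = np.column_stack([one, a, C])
    return X_y, X_m2, X_m1


def _check_rank(X: np.ndarray, name: str) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design for the {name} model "
            f"({X.shape[1]} parameters); check for constant or collinear columns")


def fit_sem(data: pd.DataFrame, column_map: Mapping,
            scenario: Scenario = NONSEQUENTIAL) -> FittedSEM:
    """Fit the three structural linear models by least squares."""
    frame = _prepare(data, column_map)
    n = len(frame)
    X_y, X_m2, X_m1 = _design_matrices(frame, scenario)
    if n <= X_y.shape[1]:
        raise ValueError(
            f"n = {n} does not exceed the {X_y.shape[1]} outcome-model parameters")
    for X, name in ((X_y, "outcome"), (X_m2, "M2"), (X_m1, "M1")):
        _check_rank(X, name)

    fit_y = sm.OLS(frame["y"].to_numpy(), X_y).fit()
    fit_m2 = sm.OLS(frame["m2"].to_numpy(), X_m2).fit()
    fit_m1 = sm.OLS(frame["m1"].to_numpy(), X_m1).fit()

    k = X_m1.shape[1] - 2  # covariate dimension
    th = fit_y.params
    b = fit_m2.params
    g = fit_m1.params
    if scenario == SEQUENTIAL:
        beta = dict(beta0=b[0], beta1=b[1], beta2=b[2], beta3=b[3],
                    beta4=b[4:4 + k])
    else:
        beta = dict(beta0=b[0], beta1=b[1], beta2=0.0, beta3=0.0,
                    beta4=b[2:2 + k])
    sem = LinearSEM(
        theta0=th[0], theta1=th[1], theta2=th[2], theta3=th[3],
        theta4=th[4], theta5=th[5], theta6=th[6], theta7=th[7],
        theta8=th[8:8 + k] if k else np.empty(0),
        **beta,
        gamma0=g[0], gamma1=g[1], gamma2=g[2:2 + k],
        sigma_m1=float(np.sqrt(fit_m1.mse_resid)),
        sigma_m2=float(np.sqrt(fit_m2.mse_resid)),
        sigma_y=float(np.sqrt(fit_y.mse_resid)),
    )
    diagnostics = {
        name: {"resid_var": float(f.mse_resid), "bse": f.bse.tolist()}
        for name, f in (("y", fit_y), ("m2", fit_m2), ("m1", fit_m1))
    }
    return FittedSEM(sem=sem, sample_size=n, model_diagnostics=diagnostics)


def resolve_request(
    data: pd.DataFrame,
    column_map: Mapping,
    scenario: Scenario,
    a: float,
    a_star: float,
    m1_star: Union[float, str] = 0.0,
    m2_star: Union[float, str] = 0.0,
    covariate_profile: Union[Sequence[float], str] = SAMPLE_MEAN,
) -> DecompositionRequest:
    """Build a request, resolving ``"sample-mean"`` reference levels.

    Reference levels flagged :data:`SAMPLE_MEAN` are set to the sample
    means of the (transformed) mediator columns; a ``"sample-mean"``
    covariate profile becomes the vector of covariate means.
    """
    frame = _prepare(data, column_map)
    if m1_star == SAMPLE_MEAN:
        m1_star = float(frame["m1"].mean())
    if m2_star == SAMPLE_MEAN:
        m2_star = float(frame["m2"].mean())
    if isinstance(covariate_profile, str):
        if covariate_profile != SAMPLE_MEAN:
            raise ValueError(f"unknown covariate profile {covariate_profile!r}")
        cov_cols = [c for c in frame.columns if c.startswith("_c")]
        covariate_profile = frame[cov_cols].mean().to_numpy()
    return DecompositionRequest(scenario=scenario, a=float(a),
                                a_star=float(a_star), m1_star=float(m1_star),
                                m2_star=float(m2_star),
                                covariate_profile=np.asarray(covariate_profile, float))


def estimate_decomposition(
    data: pd.DataFrame, column_map: Mapping, req: DecompositionRequest,
) -> tuple[DecompositionResult, AggregateEffects, FittedSEM]:
    """Point estimates: fit the SEM, then evaluate the closed forms."""
    fitted = fit_sem(data, column_map, req.scenario)
    result = decompose_linear(fitted.sem, req)
    return result, compute_aggregates(result), fitted


# -- fast weighted least squares for bootstrap replicates -------------------

def _wls_coeffs(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted LS coefficients and unbiased residual variance.

    Multinomial case weights: solving the weighted normal equations is
    identical to OLS on the resampled rows.  Returns None on a (near-)
    singular weighted design.
    """
    Xw = X * w[:, None]
    XtX = X.T @ Xw
    Xty = Xw.T @ y
    try:
        coef = np.linalg.solve(XtX, Xty)
    except np.linalg.LinAlgError:
        return None
    # guard against silently meaningless solutions of an ill-conditioned system
    if not np.all(np.isfinite(coef)) or np.linalg.cond(XtX) > 1 / _RCOND:
        return None
    resid = y - X @ coef
    dof = w.sum() - X.shape[1]
    if dof <= 0:
        return None
    ssr = float(resid @ (w * resid))
    return coef, ssr / dof


def _decompose_from_wls(fits, scenario: Scenario, k: int,
                        req: DecompositionRequest) -> DecompositionResult:
    (th, _), (b, _), (g, var_m1) = fits
    if scenario == SEQUENTIAL:
        beta = dict(beta0=b[0], beta1=b[1], beta2=b[2], beta3=b[3],
                    beta4=b[4:4 + k])
    else:
        beta = dict(beta0=b[0], beta1=b[1], beta2=0.0, beta3=0.0,
                    beta4=b[2:2 + k])
    sem = LinearSEM(
        theta0=th[0], theta1=th[1], theta2=th[2], theta3=th[3],
        theta4=th[4], theta5=th[5], theta6=th[6], theta7=th[7],
        theta8=th[8:8 + k] if k else np.empty(0), **beta,
        gamma0=g[0], gamma1=g[1], gamma2=g[2:2 + k],
        sigma_m1=float(np.sqrt(var_m1)),
    )
    return decompose_linear(sem, req)


def bootstrap_decomposition(
    data: pd.DataFrame,
    column_map: Mapping,
    req: DecompositionRequest,
    B: int = 2000,
    seed: Optional[int] = None,
    level: float = 0.95,
    m1_star: Union[float, str, None] = None,
    m2_star: Union[float, str, None] = None,
    freeze_reference_levels: bool = False,
    keep_replicates: bool = False,
) -> IntervalReport:
    """Percentile bootstrap intervals for all components and aggregates.

    Nonparametric case resampling: each replicate redraws n rows with
    replacement (realized as multinomial case weights), refits the three
    structural models and re-evaluates every component.  Deterministic
    given ``seed``.  When ``m1_star``/``m2_star`` is :data:`SAMPLE_MEAN`,
    the reference level is re-estimated inside each replicate unless
    ``freeze_reference_levels`` is set.  Replicates with a singular design
    are dropped; more than 1% dropped is an error.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    frame = _prepare(data, column_map)
    n = len(frame)
    k = sum(c.startswith("_c") for c in frame.columns)
    m1_col = frame["m1"].to_numpy()
    m2_col = frame["m2"].to_numpy()

    def build_req(m1v, m2v):
        return DecompositionRequest(
            scenario=req.scenario, a=req.a, a_star=req.a_star,
            m1_star=m1v, m2_star=m2v,
            covariate_profile=req.covariate_profile)

    def resolve_refs(weights=None):
        w = np.ones(n) if weights is None else weights
        m1v = (float(np.average(m1_col, weights=w))
               if m1_star == SAMPLE_MEAN else
               float(req.m1_star if m1_star is None else m1_star))
        m2v = (float(np.average(m2_col, weights=w))
               if m2_star == SAMPLE_MEAN else
               float(req.m2_star if m2_star is None else m2_star))
        return m1v, m2v

    X_y, X_m2, X_m1 = _design_matrices(frame, req.scenario)
    y_y = frame["y"].to_numpy()
    y_m2 = frame["m2"].to_numpy()
    y_m1 = frame["m1"].to_numpy()
    for X, name in ((X_y, "outcome"), (X_m2, "M2"), (X_m1, "M1")):
        _check_rank(X, name)

    # full-data point estimates
    full_req = build_req(*resolve_refs())
    point_result, point_agg, _ = estimate_decomposition(data, column_map, full_req)
    point = {**point_result.labels(), **point_agg.labels()}

    rng = np.random.default_rng(seed)
    rows = []
    dropped = 0
    for _ in range(B):
        w = rng.multinomial(n, np.full(n, 1.0 / n)).astype(float)
        fits = tuple(_wls_coeffs(X, y, w) for X, y in
                     ((X_y, y_y), (X_m2, y_m2), (X_m1, y_m1)))
        if any(f is None for f in fits):
            dropped += 1
            continue
        if freeze_reference_levels:
            rep_req = full_req
        else:
            rep_req = build_req(*resolve_refs(w))
        res = _decompose_from_wls(fits, req.scenario, k, rep_req)
        rows.append({**res.labels(), **compute_aggregates(res).labels()})

    if dropped > max(0.01 * B, 0):
        raise RuntimeError(
            f"{dropped}/{B} bootstrap replicates dropped for rank deficiency")
    reps = pd.DataFrame(rows)
    alpha = 1.0 - level
    lower = reps.quantile(alpha / 2).to_dict()
    upper = reps.quantile(1 - alpha / 2).to_dict()
    return IntervalReport(
        estimate=point, lower=lower, upper=upper, level=level,
        n_replicates=B, n_dropped=dropped, seed=seed,
        replicates=reps if keep_replicates else None)
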