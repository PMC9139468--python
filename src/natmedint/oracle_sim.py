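"""Structural simulators and a brute-force counterfactual oracle.

Two generators are provided:

* :func:`simulate_linear` draws observational data from a
  :class:`~natmedint.sem_model.LinearSEM` with Gaussian errors, a Gaussian
  covariate and a confounded Gaussian exposure -- the package's reference
  simulation design (:func:`default_study_sem`);
* :class:`BinarySEM` is the all-binary analogue with Bernoulli mediators,
  whose observational law and counterfactual expectations can be computed
  exactly by enumeration.

The oracle (:func:`oracle_mean`, :func:`oracle_component`) evaluates any
nested counterfactual directly from the structural equations.  Because it
owns the structural model it may evaluate formulas that are not
non-parametrically identifiable from data.  For the linear model it uses
Monte-Carlo integration with *common random numbers*: one set of exogenous
mediator errors is drawn per replicate and reused across every
counterfactual term of a contrast, mirroring the individual-level
definitions (differences within the same unit).  Outcome-model noise has
mean zero and is omitted, which changes no expectation and shrinks the
Monte-Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .sem_model import (
    INHERIT,
    NONSEQUENTIAL,
    SEQUENTIAL,
    CounterfactualAssignment,
    DecompositionRequest,
    LinearSEM,
    ObservationalLaw,
    Scenario,
)

__all__ = [
    "default_study_sem",
    "simulate_linear",
    "BinarySEM",
    "oracle_mean",
    "oracle_component",
    "COMPONENT_TERMS",
]

#: covariate distribution of the reference simulation design
COVARIATE_MEAN = 0.2
COVARIATE_SD = 0.5
#: exposure model A | C ~ Normal(0.3 + 3 c, 0.5) of the reference design
DEFAULT_EXPOSURE_MODEL = (0.3, 3.0, 0.5)


def default_study_sem(sequential: bool = False) -> LinearSEM:
    """The linear SEM of the package's reference simulation design.

    Outcome mean 0.2 + 0.3A + 0.3M1 + 0.4M2 + 0.01AM1 + 0.02AM2 + 0.6M1M2
    + 0.7AM1M2 + 0.2C; both mediator means 0.2 + 0.3A + 0.2C; all error
    standard deviations 0.5.  With ``sequential=True`` a direct M1 -> M2
    link (beta2 = 0.2, beta3 = 0.1) is added for exercising the sequential
    formulas; the non-sequential default is the design used for the
    published true component values.
    """
    beta2, beta3 = (0.2, 0.1) if sequential else (0.0, 0.0)
    return LinearSEM(
        theta0=0.2, theta1=0.3, theta2=0.3, theta3=0.4, theta4=0.01,
        theta5=0.02, theta6=0.6, theta7=0.7, theta8=[0.2],
        beta0=0.2, beta1=0.3, beta2=beta2, beta3=beta3, beta4=[0.2],
        gamma0=0.2, gamma1=0.3, gamma2=[0.2],
        sigma_m1=0.5, sigma_m2=0.5, sigma_y=0.5,
    )


def simulate_linear(
    sem: LinearSEM,
    n: int,
    seed: Optional[int] = None,
    exposure_model: Tuple[float, float, float] = DEFAULT_EXPOSURE_MODEL,
    covariate_mean: float = COVARIATE_MEAN,
    covariate_sd: float = COVARIATE_SD,
) -> pd.DataFrame:
    """Draw ``n`` observations from the structural system.

    ``exposure_model = (alpha0, alpha1, sd)`` gives
    ``A | C ~ Normal(alpha0 + alpha1 * sum(C), sd)``; the default is the
    reference design's confounded exposure.  Deterministic given ``seed``.
    Columns: ``c1..ck, a, m1, m2, y``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    k = sem.covariate_dim
    c = rng.normal(covariate_mean, covariate_sd, size=(n, k))
    a0, a1, asd = exposure_model
    a = rng.normal(a0 + a1 * c.sum(axis=1), asd)
    m1 = sem.gamma0 + sem.gamma1 * a + c @ sem.gamma2 + rng.normal(0, sem.sigma_m1, n)
    m2 = (sem.beta0 + sem.beta1 * a + sem.beta2 * m1 + sem.beta3 * a * m1
          + c @ sem.beta4 + rng.normal(0, sem.sigma_m2, n))
    cov_term = c @ sem.theta8
    y = (sem.theta0 + sem.theta1 * a + sem.theta2 * m1 + sem.theta3 * m2
         + sem.theta4 * a * m1 + sem.theta5 * a * m2 + sem.theta6 * m1 * m2
         + sem.theta7 * a * m1 * m2 + cov_term + rng.normal(0, sem.sigma_y, n))
    data = {f"c{i + 1}": c[:, i] for i in range(k)}
    data.update({"a": a, "m1": m1, "m2": m2, "y": y})
    return pd.DataFrame(data)


@dataclass(frozen=True)
class BinarySEM:
    """All-binary structural system with exact enumerable counterfactuals.

    ``pr_m1[a, s]`` is the success probability of M1 under exposure
    ``a in {0, 1}`` in covariate stratum ``s``; ``pr_m2[a, m1, s]`` that of
    M2; ``mean_y[a, m1, m2, s]`` the outcome mean (no outcome noise model
    is needed for expectations).  The mediators are generated from shared
    uniform noise: ``M1(a) = 1{U1 <= pr_m1[a]}`` and
    ``M2(a, m1) = 1{U2 <= pr_m2[a, m1]}`` with ``U1, U2`` independent, so
    cross-world counterfactuals are comonotonically coupled.
    """

    pr_m1: np.ndarray       # (2, n_strata)
    pr_m2: np.ndarray       # (2, 2, n_strata)
    mean_y: np.ndarray      # (2, 2, 2, n_strata)
    stratum_weights: np.ndarray  # (n_strata,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pr_m1", np.asarray(self.pr_m1, float))
        object.__setattr__(self, "pr_m2", np.asarray(self.pr_m2, float))
        object.__setattr__(self, "mean_y", np.asarray(self.mean_y, float))
        object.__setattr__(
            self, "stratum_weights", np.asarray(self.stratum_weights, float))
        for name in ("pr_m1", "pr_m2"):
            p = getattr(self, name)
            if np.any(p < 0) or np.any(p > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        w = self.stratum_weights
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("stratum_weights must be a probability vector")

    @property
    def n_strata(self) -> int:
        return int(self.stratum_weights.size)

    @classmethod
    def random(cls, rng: np.random.Generator, n_strata: int = 1,
               sequential: bool = True) -> "BinarySEM":
        """A random binary system (uniform probabilities and outcome means)."""
        pr_m1 = rng.uniform(0.05, 0.95, size=(2, n_strata))
        pr_m2 = rng.uniform(0.05, 0.95, size=(2, 2, n_strata))
        if not sequential:
            pr_m2[:, 1, :] = pr_m2[:, 0, :]
        mean_y = rng.uniform(0, 1, size=(2, 2, 2, n_strata))
        w = rng.dirichlet(np.ones(n_strata))
        return cls(pr_m1, pr_m2, mean_y, w)

    def to_law(self) -> ObservationalLaw:
        """Exact observational law implied by the structural system."""
        n_s = self.n_strata
        m1_dist = np.empty((2, 2, n_s))
        m1_dist[:, 1, :] = self.pr_m1
        m1_dist[:, 0, :] = 1.0 - self.pr_m1
        m2_dist = np.empty((2, 2, 2, n_s))
        m2_dist[:, :, 1, :] = self.pr_m2
        m2_dist[:, :, 0, :] = 1.0 - self.pr_m2
        return ObservationalLaw(self.mean_y, m1_dist, m2_dist,
                                a_support=[0, 1], m1_support=[0, 1],
                                m2_support=[0, 1], n_strata=n_s)

    def simulate(self, n: int, seed: Optional[int] = None,
                 pr_a: Union[float, Sequence[float]] = 0.5) -> pd.DataFrame:
        """Draw observational data (Bernoulli outcome with mean ``mean_y``).

        ``pr_a`` may vary by stratum, inducing confounding by the stratum.
        Requires ``mean_y`` within [0, 1].  Columns: ``stratum, a, m1, m2, y``.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        if np.any(self.mean_y < 0) or np.any(self.mean_y > 1):
            raise ValueError("mean_y must lie in [0, 1] to simulate a binary Y")
        rng = np.random.default_rng(seed)
        pr_a = np.broadcast_to(np.asarray(pr_a, float), (self.n_strata,))
        s = rng.choice(self.n_strata, size=n, p=self.stratum_weights)
        a = (rng.random(n) < pr_a[s]).astype(int)
        m1 = (rng.random(n) < self.pr_m1[a, s]).astype(int)
        m2 = (rng.random(n) < self.pr_m2[a, m1, s]).astype(int)
        y = (rng.random(n) < self.mean_y[a, m1, m2, s]).astype(int)
        return pd.DataFrame({"stratum": s, "a": a, "m1": m1, "m2": m2, "y": y})


# ---------------------------------------------------------------------------
# counterfactual oracle
# ---------------------------------------------------------------------------

def _linear_oracle_mean(sem: LinearSEM, assign: CounterfactualAssignment,
                        c, n_draws: int, seed) -> Tuple[float, float]:
    c = np.atleast_1d(np.asarray(c, float))
    rng = np.random.default_rng(seed)
    eps1 = rng.normal(0.0, sem.sigma_m1, n_draws)
    eps2 = rng.normal(0.0, sem.sigma_m2, n_draws)
    values = _linear_term_values(sem, assign, c, eps1, eps2)
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(n_draws))


def _linear_term_values(sem: LinearSEM, assign: CounterfactualAssignment,
                        c: np.ndarray, eps1: np.ndarray,
                        eps2: np.ndarray) -> np.ndarray:
    """Per-draw counterfactual outcome values under shared exogenous noise."""

    def m1_at(a: float) -> np.ndarray:
        return sem.m1_mean(a, c) + eps1

    if assign.m1_override is not None:
        m1_y = np.full_like(eps1, float(assign.m1_override))
    else:
        m1_y = m1_at(assign.a_m1)
    if assign.m2_override is not None:
        m2_y = np.full_like(eps1, float(assign.m2_override))
    else:
        if assign.m2_m1_source is not None:
            m1_for_m2 = m1_at(assign._resolve(assign.m2_m1_source))
        elif assign.m1_override is not None:
            m1_for_m2 = np.full_like(eps1, float(assign.m1_override))
        else:
            m1_for_m2 = m1_y
        m2_y = sem.m2_mean(assign.a_m2, m1_for_m2, c) + eps2
    return sem.outcome_mean(assign.a_y, m1_y, m2_y, c)


def _binary_oracle_mean(bsem: BinarySEM, assign: CounterfactualAssignment,
                        stratum: int) -> float:
    """Exact expectation by enumeration over the shared-noise regions.

    The uniforms U1, U2 are piecewise constant in their effect: cutting
    [0, 1] at the relevant success probabilities yields rectangles on which
    every counterfactual in the system is deterministic.
    """
    s = int(stratum)
    p1 = bsem.pr_m1[:, s]
    p2 = bsem.pr_m2[:, :, s]
    cuts1 = np.unique(np.concatenate(([0.0, 1.0], p1)))
    cuts2 = np.unique(np.concatenate(([0.0, 1.0], p2.ravel())))
    total = 0.0
    for lo1, hi1 in zip(cuts1[:-1], cuts1[1:]):
        u1 = 0.5 * (lo1 + hi1)
        w1 = hi1 - lo1
        if w1 <= 0:
            continue

        def m1_at(a: float) -> int:
            return int(u1 < p1[int(round(a))])

        if assign.m1_override is not None:
            m1_y = int(round(assign.m1_override))
        else:
            m1_y = m1_at(assign.a_m1)
        if assign.m2_override is None:
            if assign.m2_m1_source is not None:
                m1_for_m2 = m1_at(assign._resolve(assign.m2_m1_source))
            elif assign.m1_override is not None:
                m1_for_m2 = int(round(assign.m1_override))
            else:
                m1_for_m2 = m1_y
        for lo2, hi2 in zip(cuts2[:-1], cuts2[1:]):
            u2 = 0.5 * (lo2 + hi2)
            w2 = hi2 - lo2
            if w2 <= 0:
                continue
            if assign.m2_override is not None:
                m2_y = int(round(assign.m2_override))
            else:
                m2_y = int(u2 < p2[int(round(assign.a_m2)), m1_for_m2])
            total += w1 * w2 * bsem.mean_y[int(round(assign.a_y)), m1_y, m2_y, s]
    return float(total)


def oracle_mean(model: Union[LinearSEM, BinarySEM],
                assign: CounterfactualAssignment,
                c=None, stratum: int = 0,
                n_draws: int = 100_000, seed: Optional[int] = None):
    """Expectation of a nested counterfactual outcome.

    For a :class:`BinarySEM` the value is exact (enumeration; returns a
    float).  For a :class:`LinearSEM` it is a shared-noise Monte-Carlo mean
    (returns ``(value, standard_error)``).
    """
    if isinstance(model, BinarySEM):
        return _binary_oracle_mean(model, assign, stratum)
    if c is None:
        c = np.zeros(model.covariate_dim)
    return _linear_oracle_mean(model, assign, c, n_draws, seed)


# ---------------------------------------------------------------------------
# component definitions as signed counterfactual terms
# ---------------------------------------------------------------------------

# Term notation: (sign, ay, m1, m2) with
#   ay in {"a", "a*"};
#   m1 in {"M1(a)", "M1(a*)", "m1*"};
#   m2 in {"M2(a)", "M2(a*)", "m2*"} for the non-sequential scenario, or
#         "M2(x,M1(y))" / "M2(x,m1*)" forms for the sequential scenario.
# The same table drives the Monte-Carlo and the enumeration oracle.

def _t(sign, ay, m1, m2):
    return (sign, ay, m1, m2)


_NONSEQ = {
    "cde": [_t(+1, "a", "m1*", "m2*"), _t(-1, "a*", "m1*", "m2*")],
    "intref_am1": [
        _t(+1, "a", "M1(a*)", "m2*"), _t(-1, "a*", "M1(a*)", "m2*"),
        _t(-1, "a", "m1*", "m2*"), _t(+1, "a*", "m1*", "m2*")],
    "intref_am2": [
        _t(+1, "a", "m1*", "M2(a*)"), _t(-1, "a*", "m1*", "M2(a*)"),
        _t(-1, "a", "m1*", "m2*"), _t(+1, "a*", "m1*", "m2*")],
    "intref_am1m2": [
        _t(+1, "a", "M1(a*)", "M2(a*)"), _t(-1, "a*", "M1(a*)", "M2(a*)"),
        _t(-1, "a", "m1*", "M2(a*)"), _t(+1, "a*", "m1*", "M2(a*)"),
        _t(-1, "a", "M1(a*)", "m2*"), _t(+1, "a*", "M1(a*)", "m2*"),
        _t(+1, "a", "m1*", "m2*"), _t(-1, "a*", "m1*", "m2*")],
    "natint_am1": [
        _t(+1, "a", "M1(a)", "M2(a*)"), _t(-1, "a*", "M1(a)", "M2(a*)"),
        _t(-1, "a", "M1(a*)", "M2(a*)"), _t(+1, "a*", "M1(a*)", "M2(a*)")],
    "natint_am2": [
        _t(+1, "a", "M1(a*)", "M2(a)"), _t(-1, "a*", "M1(a*)", "M2(a)"),
        _t(-1, "a", "M1(a*)", "M2(a*)"), _t(+1, "a*", "M1(a*)", "M2(a*)")],
    "natint_m1m2": [
        _t(+1, "a*", "M1(a)", "M2(a)"), _t(-1, "a*", "M1(a*)", "M2(a)"),
        _t(-1, "a*", "M1(a)", "M2(a*)"), _t(+1, "a*", "M1(a*)", "M2(a*)")],
    "natint_am1m2": [
        _t(+1, "a", "M1(a)", "M2(a)"), _t(-1, "a*", "M1(a)", "M2(a)"),
        _t(-1, "a", "M1(a*)", "M2(a)"), _t(+1, "a*", "M1(a*)", "M2(a)"),
        _t(-1, "a", "M1(a)", "M2(a*)"), _t(+1, "a*", "M1(a)", "M2(a*)"),
        _t(+1, "a", "M1(a*)", "M2(a*)"), _t(-1, "a*", "M1(a*)", "M2(a*)")],
    "pie_m1": [
        _t(+1, "a*", "M1(a)", "M2(a*)"), _t(-1, "a*", "M1(a*)", "M2(a*)")],
    "ie_m2": [
        _t(+1, "a*", "M1(a*)", "M2(a)"), _t(-1, "a*", "M1(a*)", "M2(a*)")],
}

_SEQ = {
    "cde": _NONSEQ["cde"],
    "intref_am1": _NONSEQ["intref_am1"],
    "intref_am2": [
        _t(+1, "a", "m1*", "M2(a*,m1*)"), _t(-1, "a*", "m1*", "M2(a*,m1*)"),
        _t(-1, "a", "m1*", "m2*"), _t(+1, "a*", "m1*", "m2*")],
    "intref_am1m2": [
        _t(+1, "a", "M1(a*)", "M2(a*,M1(a*))"),
        _t(-1, "a*", "M1(a*)", "M2(a*,M1(a*))"),
        _t(-1, "a", "m1*", "M2(a*,m1*)"), _t(+1, "a*", "m1*", "M2(a*,m1*)"),
        _t(-1, "a", "M1(a*)", "m2*"), _t(+1, "a*", "M1(a*)", "m2*"),
        _t(+1, "a", "m1*", "m2*"), _t(-1, "a*", "m1*", "m2*")],
    "natint_am1": [
        _t(+1, "a", "M1(a)", "M2(a*,M1(a))"),
        _t(-1, "a*", "M1(a)", "M2(a*,M1(a))"),
        _t(-1, "a", "M1(a*)", "M2(a*,M1(a*))"),
        _t(+1, "a*", "M1(a*)", "M2(a*,M1(a*))")],
    "natint_am2": [
        _t(+1, "a", "M1(a*)", "M2(a,M1(a*))"),
        _t(-1, "a*", "M1(a*)", "M2(a,M1(a*))"),
        _t(-1, "a", "M1(a*)", "M2(a*,M1(a*))"),
        _t(+1, "a*", "M1(a*)", "M2(a*,M1(a*))")],
    "natint_m1m2": [
        _t(+1, "a*", "M1(a)", "M2(a,M1(a))"),
        _t(-1, "a*", "M1(a*)", "M2(a,M1(a*))"),
        _t(-1, "a*", "M1(a)", "M2(a*,M1(a))"),
        _t(+1, "a*", "M1(a*)", "M2(a*,M1(a*))")],
    "natint_am1m2": [
        _t(+1, "a", "M1(a)", "M2(a,M1(a))"),
        _t(-1, "a*", "M1(a)", "M2(a,M1(a))"),
        _t(-1, "a", "M1(a*)", "M2(a,M1(a*))"),
        _t(+1, "a*", "M1(a*)", "M2(a,M1(a*))"),
        _t(-1, "a", "M1(a)", "M2(a*,M1(a))"),
        _t(+1, "a*", "M1(a)", "M2(a*,M1(a))"),
        _t(+1, "a", "M1(a*)", "M2(a*,M1(a*))"),
        _t(-1, "a*", "M1(a*)", "M2(a*,M1(a*))")],
    "pie_m1": [
        _t(+1, "a*", "M1(a)", "M2(a*,M1(a))"),
        _t(-1, "a*", "M1(a*)", "M2(a*,M1(a*))")],
    "ie_m2": [
        _t(+1, "a*", "M1(a*)", "M2(a,M1(a*))"),
        _t(-1, "a*", "M1(a*)", "M2(a*,M1(a*))")],
}

# Bellavia--Valeri mediated effects (non-sequential only): product contrasts
# against the fixed reference corner (m1*, m2*).
_BELLAVIA = {
    "intmed_am1": [
        _t(+1, "a", "M1(a)", "m2*"), _t(-1, "a*", "M1(a)", "m2*"),
        _t(-1, "a", "M1(a*)", "m2*"), _t(+1, "a*", "M1(a*)", "m2*")],
    "intmed_am2": [
        _t(+1, "a", "m1*", "M2(a)"), _t(-1, "a*", "m1*", "M2(a)"),
        _t(-1, "a", "m1*", "M2(a*)"), _t(+1, "a*", "m1*", "M2(a*)")],
    "intmed_am1m2": [
        # three-way contrast at natural (M1(a), M2(a)) ...
        _t(+1, "a", "M1(a)", "M2(a)"), _t(-1, "a*", "M1(a)", "M2(a)"),
        _t(-1, "a", "m1*", "M2(a)"), _t(+1, "a*", "m1*", "M2(a)"),
        _t(-1, "a", "M1(a)", "m2*"), _t(+1, "a*", "M1(a)", "m2*"),
        _t(+1, "a", "m1*", "m2*"), _t(-1, "a*", "m1*", "m2*"),
        # ... minus the same at (M1(a*), M2(a*))
        _t(-1, "a", "M1(a*)", "M2(a*)"), _t(+1, "a*", "M1(a*)", "M2(a*)"),
        _t(+1, "a", "m1*", "M2(a*)"), _t(-1, "a*", "m1*", "M2(a*)"),
        _t(+1, "a", "M1(a*)", "m2*"), _t(-1, "a*", "M1(a*)", "m2*"),
        _t(-1, "a", "m1*", "m2*"), _t(+1, "a*", "m1*", "m2*")],
    "pnie_m1m2": [
        _t(+1, "a*", "M1(a)", "M2(a)"), _t(-1, "a*", "m1*", "M2(a)"),
        _t(-1, "a*", "M1(a)", "m2*"), _t(+1, "a*", "m1*", "m2*"),
        _t(-1, "a*", "M1(a*)", "M2(a*)"), _t(+1, "a*", "m1*", "M2(a*)"),
        _t(+1, "a*", "M1(a*)", "m2*"), _t(-1, "a*", "m1*", "m2*")],
    "pnie_m1": [
        _t(+1, "a*", "M1(a)", "m2*"), _t(-1, "a*", "M1(a*)", "m2*")],
    "pnie_m2": [
        _t(+1, "a*", "m1*", "M2(a)"), _t(-1, "a*", "m1*", "M2(a*)")],
}

# Aggregates expressed directly as counterfactual contrasts (not sums of
# components), usable as an independent route for the traditional effects.
_AGGREGATES = {
    "te": [_t(+1, "a", "M1(a)", "M2(a,M1(a))"),
           _t(-1, "a*", "M1(a*)", "M2(a*,M1(a*))")],
    "pde": [_t(+1, "a", "M1(a*)", "M2(a*,M1(a*))"),
            _t(-1, "a*", "M1(a*)", "M2(a*,M1(a*))")],
    "tde": [_t(+1, "a", "M1(a)", "M2(a,M1(a))"),
            _t(-1, "a*", "M1(a)", "M2(a,M1(a))")],
    "tie": [_t(+1, "a", "M1(a)", "M2(a,M1(a))"),
            _t(-1, "a", "M1(a*)", "M2(a*,M1(a*))")],
    "nie_m1": [_t(+1, "a*", "M1(a)", "M2(a,M1(a))"),
               _t(-1, "a*", "M1(a*)", "M2(a,M1(a*))")],
}

COMPONENT_TERMS = {
    SEQUENTIAL: {**_SEQ, **_AGGREGATES},
    NONSEQUENTIAL: {**_NONSEQ, **_BELLAVIA,
                    **{k: v for k, v in _AGGREGATES.items()}},
}


def _term_to_assignment(term, req: DecompositionRequest) -> CounterfactualAssignment:
    sign, ay, m1, m2 = term
    level = {"a": float(req.a), "a*": float(req.a_star)}
    kwargs = dict(exposure_for_y=level[ay])
    if m1 == "m1*":
        kwargs["m1_override"] = float(req.m1_star)
    else:  # "M1(x)"
        kwargs["exposure_for_m1"] = level[m1[3:-1]]
    if m2 == "m2*":
        kwargs["m2_override"] = float(req.m2_star)
    else:
        inner = m2[3:-1]          # e.g. "a*,M1(a)" or "a" or "a*,m1*"
        parts = inner.split(",", 1)
        kwargs["exposure_for_m2"] = level[parts[0]]
        if len(parts) == 2:
            src = parts[1]
            if src == "m1*":
                # M2 receives the fixed reference level of M1
                kwargs.setdefault("m1_override", float(req.m1_star))
            else:  # "M1(x)"
                kwargs["m2_m1_source"] = level[src[3:-1]]
    return CounterfactualAssignment(**kwargs)


def component_assignments(component_id: str, req: DecompositionRequest):
    """Signed counterfactual assignments defining a component."""
    try:
        terms = COMPONENT_TERMS[req.scenario][component_id]
    except KeyError:
        raise KeyError(
            f"unknown component {component_id!r} for scenario {req.scenario!r}"
        ) from None
    return [(sign, _term_to_assignment(term, req))
            for term in terms for sign in [term[0]]]


def oracle_component(model: Union[LinearSEM, BinarySEM], component_id: str,
                     req: DecompositionRequest, c=None, stratum: int = 0,
                     n_draws: int = 100_000, seed: Optional[int] = None):
    """Brute-force value of a decomposition component.

    Linear combination of counterfactual means per the component's
    definition.  For a :class:`BinarySEM` the result is exact (float); for
    a :class:`LinearSEM` it is ``(estimate, standard_error)`` with all
    terms sharing one set of exogenous error draws.
    """
    signed = component_assignments(component_id, req)
    if isinstance(model, BinarySEM):
        return float(sum(s * _binary_oracle_mean(model, asg, stratum)
                         for s, asg in signed))
    if c is None:
        c = np.zeros(model.covariate_dim)
    c = np.atleast_1d(np.asarray(c, float))
    rng = np.random.default_rng(seed)
    eps1 = rng.normal(0.0, model.sigma_m1, n_draws)
    eps2 = rng.normal(0.0, model.sigma_m2, n_draws)
    contrast = np.zeros(n_draws)
    for s, asg in signed:
        contrast += s * _linear_term_values(model, asg, c, eps1, eps2)
    return float(contrast.mean()), float(contrast.std(ddof=1) / np.sqrt(n_draws))
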