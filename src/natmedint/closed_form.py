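"""Exact regression-based formulas for the ten-way decomposition.

Every function here evaluates a polynomial in the structural coefficients
at a point covariate profile ``c``; nothing is estimated.  The sequential
formulas involve the error variance of the M1 model (``sigma_m1**2``)
because M2 is a quadratic function of M1 inside the interaction terms; the
non-sequential formulas are the special case ``beta2 = beta3 = 0``, in
which the variance terms drop out.

Notation used throughout (all conditional on ``c``):

* ``g0 = gamma0 + gamma2'c``            -- M1 intercept at the profile
* ``g_star = g0 + gamma1 * a_star``     -- E[M1(a*) | c]
* ``b_star = beta0 + beta1*a_star + beta4'c`` -- exposure part of E[M2(a*, .)]
* ``q_star = beta2 + beta3 * a_star``   -- M1 slope of M2 at a*
* ``s = sigma_m1 ** 2``
"""

from __future__ import annotations

from .sem_model import (
    NONSEQUENTIAL,
    SEQUENTIAL,
    AggregateEffects,
    BellaviaComponents,
    DecompositionRequest,
    DecompositionResult,
    LinearSEM,
    validate_request,
)

__all__ = [
    "decompose_linear",
    "closed_form_te",
    "bellavia_components",
    "compute_aggregates",
]


def decompose_linear(sem: LinearSEM, req: DecompositionRequest) -> DecompositionResult:
    """Evaluate all ten decomposition components of the total effect.

    Returns a :class:`DecompositionResult` whose ``ie_m2`` field is the
    seminatural indirect effect through M2 in the sequential scenario and
    the pure indirect effect through M2 in the non-sequential scenario.
    ``te`` is the sum of the ten components (the sum telescopes to
    ``E[Y(a)|c] - E[Y(a*)|c]``).
    """
    validate_request(sem, req)
    t = sem
    a, a_star = float(req.a), float(req.a_star)
    m1s, m2s = float(req.m1_star), float(req.m2_star)
    c = req.covariate_profile

    if req.scenario == NONSEQUENTIAL:
        sem = t = sem.as_nonsequential()

    da = a - a_star
    da2 = a * a - a_star * a_star          # a^2 - a*^2
    asum = a + a_star
    g0 = t.gamma0 + float(t.gamma2 @ c)
    g_star = g0 + t.gamma1 * a_star
    b_star = t.beta0 + t.beta1 * a_star + float(t.beta4 @ c)
    q_star = t.beta2 + t.beta3 * a_star
    s = t.sigma_m1 ** 2

    cde = (t.theta1 + t.theta4 * m1s + t.theta5 * m2s + t.theta7 * m1s * m2s) * da

    intref_am1 = (g_star - m1s) * (t.theta4 + t.theta7 * m2s) * da

    intref_am2 = (t.theta5 + t.theta7 * m1s) * (
        b_star + t.beta2 * m1s + t.beta3 * a_star * m1s - m2s) * da

    intref_am1m2 = (
        t.theta1
        + t.theta7 * b_star * g_star
        + t.theta5 * q_star * g_star
        + t.theta7 * q_star * (s + g_star ** 2)
        - (t.theta1 + t.theta5 * m2s)
        - t.theta7 * m2s * g_star
        - t.theta5 * (t.beta2 * m1s + t.beta3 * a_star * m1s - m2s)
        - t.theta7 * m1s * (b_star + t.beta2 * m1s + t.beta3 * a_star * m1s - m2s)
    ) * da

    natint_am1 = (
        t.theta4 * t.gamma1
        + t.theta7 * t.gamma1 * b_star
        + t.theta5 * t.gamma1 * q_star
        + 2 * t.theta7 * t.gamma1 * q_star * g0
        + t.theta7 * t.gamma1 ** 2 * q_star * asum
    ) * da * da

    natint_am2 = (
        t.theta5 * t.beta1
        + t.theta7 * t.beta1 * g_star
        + t.theta5 * t.beta3 * g_star
        + t.theta7 * t.beta3 * (s + g_star ** 2)
    ) * da * da

    natint_am1m2 = (
        t.theta7 * t.beta1 * t.gamma1
        + t.theta5 * t.beta3 * t.gamma1
        + 2 * t.theta7 * t.beta3 * t.gamma1 * g0
        + t.theta7 * t.beta3 * t.gamma1 ** 2 * asum
    ) * da ** 3

    th6a = t.theta6 + t.theta7 * a_star   # M1*M2 slope of Y at a*
    th3a = t.theta3 + t.theta5 * a_star   # M2 slope of Y at a*

    natint_m1m2 = (
        t.beta1 * t.gamma1 * th6a
        + t.beta3 * t.gamma1 * th3a
        + 2 * t.beta3 * t.gamma1 * th6a * g0
        + t.beta3 * t.gamma1 ** 2 * th6a * asum
    ) * da * da

    pie_m1 = (
        t.gamma1 * (t.theta2 + t.theta4 * a_star)
        + t.gamma1 * th6a * b_star
        + t.gamma1 * th3a * q_star
        + 2 * t.gamma1 * th6a * q_star * g0
        + t.gamma1 ** 2 * th6a * q_star * asum
    ) * da

    ie_m2 = (
        t.beta1 * th3a
        + t.beta1 * th6a * g_star
        + t.beta3 * th3a * g_star
        + t.beta3 * th6a * (s + g_star ** 2)
    ) * da

    components = (cde, intref_am1, intref_am2, intref_am1m2, natint_am1,
                  natint_am2, natint_am1m2, natint_m1m2, pie_m1, ie_m2)
    return DecompositionResult(*(float(v) for v in components),
                               te=float(sum(components)),
                               scenario=req.scenario)


def closed_form_te(sem: LinearSEM, req: DecompositionRequest) -> float:
    """Total effect from the explicit quartic polynomial in (a, a*).

    This is an independent derivation of ``E[Y(a)|c] - E[Y(a*)|c]``,
    expanded in the power differences ``a^k - a*^k``; it never touches the
    component formulas and serves as their cross-check.
    """
    validate_request(sem, req)
    t = sem if req.scenario == SEQUENTIAL else sem.as_nonsequential()
    a, a_star = float(req.a), float(req.a_star)
    c = req.covariate_profile
    g0 = t.gamma0 + float(t.gamma2 @ c)
    b0 = t.beta0 + float(t.beta4 @ c)
    s = t.sigma_m1 ** 2
    th = t

    lin = (
        th.theta1 + th.theta5 * b0 + th.beta1 * th.theta3 + th.theta4 * g0
        + th.gamma1 * th.theta2 + th.theta7 * b0 * g0
        + th.beta1 * th.theta6 * g0 + th.gamma1 * th.theta6 * b0
        + th.theta5 * th.beta2 * g0 + th.theta3 * th.beta3 * g0
        + th.theta3 * th.beta2 * th.gamma1
        + th.theta7 * th.beta2 * s + th.theta6 * th.beta3 * s
        + th.theta7 * th.beta2 * g0 ** 2 + th.theta6 * th.beta3 * g0 ** 2
        + 2 * th.gamma1 * th.theta6 * th.beta2 * g0
    )
    quad = (
        th.beta1 * th.theta5 + th.gamma1 * th.theta4
        + th.beta1 * th.theta7 * g0 + th.gamma1 * th.theta7 * b0
        + th.gamma1 * th.beta1 * th.theta6
        + th.theta5 * th.beta3 * g0 + th.theta5 * th.beta2 * th.gamma1
        + th.theta3 * th.beta3 * th.gamma1
        + th.theta7 * th.beta3 * s + th.theta7 * th.beta3 * g0 ** 2
        + 2 * th.gamma1 * th.theta7 * th.beta2 * g0
        + 2 * th.gamma1 * th.theta6 * th.beta3 * g0
        + th.theta6 * th.beta2 * th.gamma1 ** 2
    )
    cub = (
        th.gamma1 * th.beta1 * th.theta7 + th.theta5 * th.beta3 * th.gamma1
        + 2 * th.gamma1 * th.theta7 * th.beta3 * g0
        + th.theta7 * th.beta2 * th.gamma1 ** 2
        + th.theta6 * th.beta3 * th.gamma1 ** 2
    )
    quart = th.theta7 * th.beta3 * th.gamma1 ** 2

    return float(
        lin * (a - a_star)
        + quad * (a ** 2 - a_star ** 2)
        + cub * (a ** 3 - a_star ** 3)
        + quart * (a ** 4 - a_star ** 4)
    )


def bellavia_components(sem: LinearSEM, req: DecompositionRequest) -> BellaviaComponents:
    """Mediated effects of the Bellavia--Valeri decomposition.

    These condition on fixed reference values ``M1(a*) = m1*`` and/or
    ``M2(a*) = m2*`` instead of averaging over the potential mediator
    values.  The comparison exists only for non-sequential mediators: with
    a direct M1 -> M2 link, fixing M2 at a constant would sever the causal
    relationship between the mediators.
    """
    if req.scenario != NONSEQUENTIAL or not sem.is_nonsequential:
        raise ValueError(
            "Bellavia-Valeri mediated effects are defined only for the "
            "non-sequential scenario (beta2 = beta3 = 0)")
    validate_request(sem, req)
    t = sem
    a, a_star = float(req.a), float(req.a_star)
    m1s, m2s = float(req.m1_star), float(req.m2_star)
    c = req.covariate_profile
    g0 = t.gamma0 + float(t.gamma2 @ c)
    b0 = t.beta0 + float(t.beta4 @ c)
    g_star = g0 + t.gamma1 * a_star
    b_star = b0 + t.beta1 * a_star
    da = a - a_star
    th6a = t.theta6 + t.theta7 * a_star

    intmed_am1 = (t.theta4 + t.theta7 * m2s) * t.gamma1 * da * da
    intmed_am2 = (t.theta5 + t.theta7 * m1s) * t.beta1 * da * da
    intmed_am1m2 = (
        t.beta1 * (g0 - m1s) + t.gamma1 * (b0 - m2s)
        + t.beta1 * t.gamma1 * (a + a_star)
    ) * t.theta7 * da * da
    pnie_m1m2 = (
        t.gamma1 * b0 + t.beta1 * g0 - t.gamma1 * m2s - t.beta1 * m1s
        + t.gamma1 * t.beta1 * (a + a_star)
    ) * th6a * da
    pnie_m1 = (t.theta2 + t.theta4 * a_star + th6a * m2s) * t.gamma1 * da
    pnie_m2 = (t.theta3 + t.theta5 * a_star + th6a * m1s) * t.beta1 * da
    return BellaviaComponents(
        intmed_am1=float(intmed_am1),
        intmed_am2=float(intmed_am2),
        intmed_am1m2=float(intmed_am1m2),
        pnie_m1m2=float(pnie_m1m2),
        pnie_m1=float(pnie_m1),
        pnie_m2=float(pnie_m2),
    )


def compute_aggregates(result: DecompositionResult) -> AggregateEffects:
    """Traditional summary effects, obtained purely by summing components."""
    r = result
    pde = r.cde + r.intref_am1 + r.intref_am2 + r.intref_am1m2
    tde = pde + r.natint_am1 + r.natint_am2 + r.natint_am1m2
    tie = r.te - pde
    pe = r.te - r.cde
    pai = (r.intref_am1 + r.intref_am2 + r.intref_am1m2
           + r.natint_am1 + r.natint_am2 + r.natint_am1m2 + r.natint_m1m2)
    nie_m1 = r.natint_m1m2 + r.pie_m1
    return AggregateEffects(pde=float(pde), tde=float(tde), tie=float(tie),
                            pe=float(pe), pai=float(pai), nie_m1=float(nie_m1))
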