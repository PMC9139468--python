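"""Shared fixtures: the reference study design and deterministic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from natmedint import (
    DecompositionRequest,
    LinearSEM,
    default_study_sem,
)

#: true component values of the reference (non-sequential) study design at
#: a=1, a*=0, m1*=m2*=0, c=0.2 -- exact closed-form evaluations, which also
#: match the published values of the originating simulation design
STUDY_TRUTH = {
    "CDE": 0.3000,
    "INTref-AM1": 0.0024,
    "INTref-AM2": 0.0048,
    "INTref-AM1M2": 0.0403,
    "NatINT-AM1": 0.0534,
    "NatINT-AM2": 0.0564,
    "NatINT-AM1M2": 0.0630,
    "NatINT-M1M2": 0.0540,
    "PIE-M1": 0.1332,
    "PIE-M2": 0.1632,
    "PDE": 0.3475,
    "TE": 0.8707,
}

STUDY_BELLAVIA_TRUTH = {
    "INTmed-AM1": 0.0030,
    "INTmed-AM2": 0.0060,
    "INTmed-AM1M2": 0.1638,
    "PNIE-M1M2": 0.1404,
    "PNIE-M1": 0.0900,
    "PNIE-M2": 0.1200,
}


@pytest.fixture(scope="session")
def study_sem() -> LinearSEM:
    return default_study_sem()


@pytest.fixture(scope="session")
def study_seq_sem() -> LinearSEM:
    return default_study_sem(sequential=True)


@pytest.fixture(scope="session")
def study_req() -> DecompositionRequest:
    return DecompositionRequest("nonsequential", 1.0, 0.0, 0.0, 0.0, [0.2])


@pytest.fixture(scope="session")
def column_map() -> dict:
    return {"y": "y", "m1": "m1", "m2": "m2", "a": "a", "covariates": ["c1"]}


def random_sem(rng: np.random.Generator, sequential: bool = True,
               cov_dim: int = 1) -> LinearSEM:
    """A random linear SEM with coefficients uniform in [-1, 1]."""
    u = lambda size=None: rng.uniform(-1, 1, size)
    beta2, beta3 = (u(), u()) if sequential else (0.0, 0.0)
    return LinearSEM(
        *(u() for _ in range(8)), theta8=u(cov_dim),
        beta0=u(), beta1=u(), beta2=beta2, beta3=beta3, beta4=u(cov_dim),
        gamma0=u(), gamma1=u(), gamma2=u(cov_dim),
        sigma_m1=rng.uniform(0, 1),
    )


def noiseless_dataset(sem: LinearSEM, n: int = 64,
                      seed: int = 0) -> pd.DataFrame:
    """Deterministic data from which every coefficient is exactly recoverable.

    All three regression equations hold without error.  The mediators get
    exogenous deviations orthogonal to their regression designs, so the
    outcome design has full rank (with zero structural mediator noise the
    mediators would be exact linear functions of A and C and the outcome
    coefficients would be unidentifiable) while the mediator-model OLS fits
    still interpolate the structural coefficients exactly.
    """
    if sem.covariate_dim != 1:
        raise ValueError("helper supports one covariate")
    rng = np.random.default_rng(seed)
    reps = n // 4
    a = np.tile([0.0, 1.0, 2.0, 3.0], reps)
    c = np.repeat(np.linspace(-1.0, 1.0, reps), 4)
    X = np.column_stack([np.ones(a.size), a, c])
    proj = X @ np.linalg.pinv(X)
    resid = lambda v: v - proj @ v
    e1 = resid(rng.normal(size=a.size))
    m1 = sem.gamma0 + sem.gamma1 * a + sem.gamma2[0] * c + e1
    if sem.is_nonsequential:
        X2 = X
        m2_mean = sem.beta0 + sem.beta1 * a + sem.beta4[0] * c
    else:
        X2 = np.column_stack([np.ones(a.size), a, m1, a * m1, c])
        m2_mean = (sem.beta0 + sem.beta1 * a + sem.beta2 * m1
                   + sem.beta3 * a * m1 + sem.beta4[0] * c)
    e2 = rng.normal(size=a.size)
    e2 = e2 - X2 @ np.linalg.pinv(X2) @ e2
    m2 = m2_mean + e2
    y = sem.outcome_mean(a, m1, m2, c[:, None])
    return pd.DataFrame({"a": a, "c1": c, "m1": m1, "m2": m2, "y": y})
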