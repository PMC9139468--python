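"""Iterated-conditional-expectation estimators for categorical mediators.

Given the observational conditional law of the system -- the conditional
outcome mean ``p_{a m1 m2 c} = E[Y | A=a, M1=m1, M2=m2, C=c]`` and the
mediator distributions ``Pr(M1 | a, c)`` and ``Pr(M2 | a, m1, c)`` over
finite supports -- each decomposition component is a finite weighted sum
of outcome-mean contrasts.  The formulas are written for the sequential
structure; a non-sequential system is the special case where the M2 law
is constant in m1 (see :meth:`ObservationalLaw.from_nonsequential`), so
one code path serves both scenarios.

Covariates enter as discrete strata: every quantity here is conditional on
one stratum.  No smoothing is applied when estimating the law from data;
an empty cell is a hard error.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .sem_model import (
    DecompositionRequest,
    DecompositionResult,
    ObservationalLaw,
)

__all__ = [
    "empirical_decompose",
    "gformula_mean",
    "law_from_data",
    "law_to_csv",
    "law_from_csv",
]


def empirical_decompose(law: ObservationalLaw, req: DecompositionRequest,
                        stratum: int = 0) -> DecompositionResult:
    """All ten component expectations for one covariate stratum.

    ``req.a``, ``req.a_star`` and the mediator reference levels must lie in
    the law's declared supports.  The ten values sum to the g-formula total
    effect exactly (an algebraic identity of the plug-in estimators).
    """
    law.validate()
    s = int(stratum)
    ia = law.index_of("a", req.a)
    ja = law.index_of("a", req.a_star)
    i1 = law.index_of("m1", req.m1_star)
    i2 = law.index_of("m2", req.m2_star)

    p_a = law.outcome_mean[ia, :, :, s]      # (n_m1, n_m2)
    p_s = law.outcome_mean[ja, :, :, s]
    P1a = law.m1_dist[ia, :, s]              # (n_m1,)
    P1s = law.m1_dist[ja, :, s]
    P2a = law.m2_dist[ia, :, :, s]           # (n_m1, n_m2)
    P2s = law.m2_dist[ja, :, :, s]
    d1 = P1a - P1s
    d2 = P2a - P2s
    dp = p_a - p_s

    cde = p_a[i1, i2] - p_s[i1, i2]

    intref_am1 = float(
        ((p_a[:, i2] - p_a[i1, i2]) - (p_s[:, i2] - p_s[i1, i2])) @ P1s)

    intref_am2 = float(np.sum(
        ((p_a[i1, :] - p_s[i1, :]) * P2s[i1, :])[None, :] * P1s[:, None]
        + (-p_a[i1, i2] + p_s[i1, i2]) * P2s * P1s[:, None]))

    intref_am1m2 = float(np.sum(
        ((dp - dp[:, i2][:, None] + dp[i1, i2]) * P2s
         - (dp[i1, :] * P2s[i1, :])[None, :]) * P1s[:, None]))

    natint_am1 = float(np.sum(dp * P2s * d1[:, None]))
    natint_am2 = float(np.sum(dp * P1s[:, None] * d2))
    natint_am1m2 = float(np.sum(dp * d1[:, None] * d2))
    natint_m1m2 = float(np.sum(p_s * d1[:, None] * d2))
    pie_m1 = float(np.sum(p_s * P2s * d1[:, None]))
    ie_m2 = float(np.sum(p_s * P1s[:, None] * d2))

    components = (float(cde), intref_am1, intref_am2, intref_am1m2,
                  natint_am1, natint_am2, natint_am1m2, natint_m1m2,
                  pie_m1, ie_m2)
    return DecompositionResult(*components, te=float(sum(components)),
                               scenario=req.scenario)


def gformula_mean(law: ObservationalLaw, exposure_value: float,
                  stratum: int = 0) -> float:
    """Standard g-formula mean ``E[Y(a) | c]`` for one stratum.

    ``sum_{m1,m2} p(a, m1, m2, c) Pr(M2=m2 | a, m1, c) Pr(M1=m1 | a, c)``.
    """
    law.validate()
    s = int(stratum)
    ia = law.index_of("a", exposure_value)
    return float(np.sum(
        law.outcome_mean[ia, :, :, s] * law.m2_dist[ia, :, :, s]
        * law.m1_dist[ia, :, s][:, None]))


def law_from_data(
    data: pd.DataFrame,
    a_support: Optional[Sequence[float]] = None,
    m1_support: Optional[Sequence[float]] = None,
    m2_support: Optional[Sequence[float]] = None,
    stratum_col: Optional[str] = None,
    columns: Mapping[str, str] = None,
    allow_unreachable: bool = False,
) -> ObservationalLaw:
    """Nonparametric plug-in law from categorical data.

    Outcome means are within-cell sample means; mediator distributions are
    within-cell sample frequencies.  Supports default to the sorted unique
    values observed.  Any empty ``(a, m1, m2, stratum)`` cell raises with
    the offending cell named -- there is no smoothing.  With
    ``allow_unreachable=True`` an empty outcome cell whose plug-in
    probability is exactly zero (e.g. a deterministic M2 given M1) is
    tolerated and its outcome mean set to 0; such cells carry zero weight
    in every mediator-averaged term, but fixed reference levels must not
    point at them.
    """
    cols = {"a": "a", "m1": "m1", "m2": "m2", "y": "y"}
    if columns:
        cols.update(columns)
    a_col, m1_col, m2_col, y_col = cols["a"], cols["m1"], cols["m2"], cols["y"]
    for c in (a_col, m1_col, m2_col, y_col):
        if c not in data.columns:
            raise ValueError(f"column {c!r} not found in data")

    a_support = sorted(data[a_col].unique()) if a_support is None else list(a_support)
    m1_support = sorted(data[m1_col].unique()) if m1_support is None else list(m1_support)
    m2_support = sorted(data[m2_col].unique()) if m2_support is None else list(m2_support)
    if stratum_col is None:
        strata = np.zeros(len(data), dtype=int)
        n_strata = 1
    else:
        stratum_values = sorted(data[stratum_col].unique())
        lookup = {v: i for i, v in enumerate(stratum_values)}
        strata = data[stratum_col].map(lookup).to_numpy()
        n_strata = len(stratum_values)

    na, n1, n2 = len(a_support), len(m1_support), len(m2_support)
    shape = (na, n1, n2, n_strata)
    sums = np.zeros(shape)
    counts = np.zeros(shape)
    ia = pd.Categorical(data[a_col], categories=a_support).codes
    i1 = pd.Categorical(data[m1_col], categories=m1_support).codes
    i2 = pd.Categorical(data[m2_col], categories=m2_support).codes
    if min(ia.min(), i1.min(), i2.min()) < 0:
        raise ValueError("data contains values outside the declared supports")
    np.add.at(sums, (ia, i1, i2, strata), data[y_col].to_numpy(dtype=float))
    np.add.at(counts, (ia, i1, i2, strata), 1.0)

    empty = counts == 0
    if empty.any() and not allow_unreachable:
        j = np.argwhere(empty)[0]
        raise ValueError(
            f"empty cell: a={a_support[j[0]]}, m1={m1_support[j[1]]}, "
            f"m2={m2_support[j[2]]}, stratum={j[3]} has no observations")

    with np.errstate(invalid="ignore"):
        outcome_mean = np.where(empty, 0.0, sums / np.where(empty, 1.0, counts))
    n_am1 = counts.sum(axis=2)                   # (na, n1, n_strata)
    if np.any(n_am1 == 0):
        j = np.argwhere(n_am1 == 0)[0]
        raise ValueError(
            f"empty cell: a={a_support[j[0]]}, m1={m1_support[j[1]]}, "
            f"stratum={j[2]} has no observations")
    n_a = n_am1.sum(axis=1)                      # (na, n_strata)
    m1_dist = n_am1 / n_a[:, None, :]
    m2_dist = counts / n_am1[:, :, None, :]
    return ObservationalLaw(outcome_mean, m1_dist, m2_dist,
                            a_support, m1_support, m2_support, n_strata)


def law_to_csv(law: ObservationalLaw, path) -> None:
    """Serialize a law to one long-format CSV.

    Rows carry a ``table`` tag: ``outcome_mean`` rows hold
    ``E[Y | a, m1, m2, stratum]``, ``pr_m1`` rows ``Pr(M1=m1 | a, stratum)``
    (m2 blank), ``pr_m2`` rows ``Pr(M2=m2 | a, m1, stratum)``.
    """
    rows = []
    for i, a in enumerate(law.a_support):
        for s in range(law.n_strata):
            for j, m1 in enumerate(law.m1_support):
                rows.append(("pr_m1", a, m1, np.nan, s, law.m1_dist[i, j, s]))
                for k, m2 in enumerate(law.m2_support):
                    rows.append(("outcome_mean", a, m1, m2, s,
                                 law.outcome_mean[i, j, k, s]))
                    rows.append(("pr_m2", a, m1, m2, s, law.m2_dist[i, j, k, s]))
    pd.DataFrame(rows, columns=["table", "a", "m1", "m2", "stratum", "value"]
                 ).to_csv(path, index=False)


def law_from_csv(path) -> ObservationalLaw:
    df = pd.read_csv(path)
    required = {"table", "a", "m1", "m2", "stratum", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"law CSV must have columns {sorted(required)}")
    a_support = sorted(df["a"].unique())
    m1_support = sorted(df.loc[df.table == "pr_m1", "m1"].unique())
    m2_support = sorted(df.loc[df.table == "pr_m2", "m2"].unique())
    n_strata = int(df["stratum"].max()) + 1
    na, n1, n2 = len(a_support), len(m1_support), len(m2_support)
    outcome_mean = np.full((na, n1, n2, n_strata), np.nan)
    m1_dist = np.full((na, n1, n_strata), np.nan)
    m2_dist = np.full((na, n1, n2, n_strata), np.nan)
    a_idx = {v: i for i, v in enumerate(a_support)}
    m1_idx = {v: i for i, v in enumerate(m1_support)}
    m2_idx = {v: i for i, v in enumerate(m2_support)}
    for row in df.itertuples(index=False):
        i, j, s = a_idx[row.a], m1_idx[row.m1], int(row.stratum)
        if row.table == "pr_m1":
            m1_dist[i, j, s] = row.value
        elif row.table == "outcome_mean":
            outcome_mean[i, j, m2_idx[row.m2], s] = row.value
        elif row.table == "pr_m2":
            m2_dist[i, j, m2_idx[row.m2], s] = row.value
        else:
            raise ValueError(f"unknown table tag {row.table!r}")
    if np.isnan(outcome_mean).any() or np.isnan(m1_dist).any() or np.isnan(m2_dist).any():
        raise ValueError("law CSV is missing entries for some cells")
    return ObservationalLaw(outcome_mean, m1_dist, m2_dist,
                            a_support, m1_support, m2_support, n_strata)
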