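"""Shared domain types for two-mediator effect decompositions.

The causal system has an exposure ``A``, two mediators ``M1`` and ``M2``,
an outcome ``Y`` and a covariate vector ``C``.  Two causal structures are
supported:

* **non-sequential** -- no causal link between the mediators;
* **sequential** -- a direct link ``M1 -> M2``, so the structural equation
  of ``M2`` takes ``M1`` as an input.

All closed-form machinery works on a linear structural equation model

.. math::

    E[Y | A, M_1, M_2, C] &= \\theta_0 + \\theta_1 A + \\theta_2 M_1
        + \\theta_3 M_2 + \\theta_4 A M_1 + \\theta_5 A M_2
        + \\theta_6 M_1 M_2 + \\theta_7 A M_1 M_2 + \\theta_8' C \\\\
    E[M_2 | A, M_1, C] &= \\beta_0 + \\beta_1 A + \\beta_2 M_1
        + \\beta_3 A M_1 + \\beta_4' C \\\\
    E[M_1 | A, C] &= \\gamma_0 + \\gamma_1 A + \\gamma_2' C

A non-sequential model is exactly the special case ``beta2 = beta3 = 0``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "Scenario",
    "SEQUENTIAL",
    "NONSEQUENTIAL",
    "LinearSEM",
    "DecompositionRequest",
    "DecompositionResult",
    "AggregateEffects",
    "BellaviaComponents",
    "ObservationalLaw",
    "CounterfactualAssignment",
    "INHERIT",
    "validate_request",
    "is_identifiable",
    "COMPONENT_FIELDS",
]

Scenario = Literal["sequential", "nonsequential"]
SEQUENTIAL: Scenario = "sequential"
NONSEQUENTIAL: Scenario = "nonsequential"

#: order of the ten component fields in every decomposition result
COMPONENT_FIELDS = (
    "cde",
    "intref_am1",
    "intref_am2",
    "intref_am1m2",
    "natint_am1",
    "natint_am2",
    "natint_am1m2",
    "natint_m1m2",
    "pie_m1",
    "ie_m2",
)

# identity tolerances: all closed forms are polynomial, so agreement should
# be near machine precision
RTOL = 1e-9
ATOL = 1e-12


def _as_vector(x) -> np.ndarray:
    v = np.atleast_1d(np.asarray(x, dtype=float))
    if v.ndim != 1:
        raise ValueError("covariate coefficient vectors must be 1-D")
    return v


def _check_scenario(scenario: str) -> Scenario:
    if scenario not in (SEQUENTIAL, NONSEQUENTIAL):
        raise ValueError(
            f"unknown scenario {scenario!r}; expected 'sequential' or 'nonsequential'"
        )
    return scenario  # type: ignore[return-value]


@dataclass(frozen=True)
class LinearSEM:
    """Coefficients and error scales of the three structural linear models.

    ``theta0..theta7`` parametrize the outcome model (intercept, A, M1, M2,
    A*M1, A*M2, M1*M2, A*M1*M2); ``theta8`` holds covariate coefficients.
    ``beta0..beta3`` parametrize the M2 model (intercept, A, M1, A*M1) with
    covariate coefficients ``beta4``; ``gamma0, gamma1`` the M1 model with
    covariate coefficients ``gamma2``.  ``sigma_m1`` is the error standard
    deviation of the M1 model; its square enters the sequential closed
    forms.  ``sigma_m2`` and ``sigma_y`` are used only for simulation.
    """

    theta0: float
    theta1: float
    theta2: float
    theta3: float
    theta4: float
    theta5: float
    theta6: float
    theta7: float
    theta8: np.ndarray
    beta0: float
    beta1: float
    beta2: float
    beta3: float
    beta4: np.ndarray
    gamma0: float
    gamma1: float
    gamma2: np.ndarray
    sigma_m1: float = 0.5
    sigma_m2: float = 0.5
    sigma_y: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta8", _as_vector(self.theta8))
        object.__setattr__(self, "beta4", _as_vector(self.beta4))
        object.__setattr__(self, "gamma2", _as_vector(self.gamma2))
        dims = {self.theta8.size, self.beta4.size, self.gamma2.size}
        if len(dims) != 1:
            raise ValueError(
                "covariate coefficient vectors theta8, beta4, gamma2 must have "
                f"equal length, got sizes {sorted(dims)}"
            )
        for name in ("sigma_m1", "sigma_m2", "sigma_y"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        scalars = [getattr(self, f"theta{i}") for i in range(8)]
        scalars += [self.beta0, self.beta1, self.beta2, self.beta3,
                    self.gamma0, self.gamma1,
                    self.sigma_m1, self.sigma_m2, self.sigma_y]
        if not all(math.isfinite(float(s)) for s in scalars):
            raise ValueError("all SEM coefficients must be finite")

    @property
    def covariate_dim(self) -> int:
        return int(self.theta8.size)

    @property
    def is_nonsequential(self) -> bool:
        """True when M2's structural equation does not depend on M1."""
        return self.beta2 == 0.0 and self.beta3 == 0.0

    def theta(self) -> np.ndarray:
        return np.array([getattr(self, f"theta{i}") for i in range(8)])

    def outcome_mean(self, a, m1, m2, c) -> np.ndarray:
        """Structural mean of Y given exposure, mediators and covariates."""
        t = self
        return (t.theta0 + t.theta1 * a + t.theta2 * m1 + t.theta3 * m2
                + t.theta4 * a * m1 + t.theta5 * a * m2 + t.theta6 * m1 * m2
                + t.theta7 * a * m1 * m2 + np.dot(np.asarray(c, float), t.theta8))

    def m2_mean(self, a, m1, c) -> np.ndarray:
        return (self.beta0 + self.beta1 * a + self.beta2 * m1
                + self.beta3 * a * m1 + np.dot(np.asarray(c, float), self.beta4))

    def m1_mean(self, a, c) -> np.ndarray:
        return self.gamma0 + self.gamma1 * a + np.dot(np.asarray(c, float), self.gamma2)

    def as_nonsequential(self) -> "LinearSEM":
        return replace(self, beta2=0.0, beta3=0.0)

    # -- flat key/value serialization -------------------------------------

    def to_dict(self) -> dict:
        d = {f"theta{i}": float(getattr(self, f"theta{i}")) for i in range(8)}
        d["theta8"] = [float(x) for x in self.theta8]
        d.update({f"beta{i}": float(getattr(self, f"beta{i}")) for i in range(4)})
        d["beta4"] = [float(x) for x in self.beta4]
        d["gamma0"] = float(self.gamma0)
        d["gamma1"] = float(self.gamma1)
        d["gamma2"] = [float(x) for x in self.gamma2]
        d["sigma_m1"] = float(self.sigma_m1)
        d["sigma_m2"] = float(self.sigma_m2)
        d["sigma_y"] = float(self.sigma_y)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinearSEM":
        kwargs = dict(d)
        unknown = set(kwargs) - {
            *(f"theta{i}" for i in range(9)),
            *(f"beta{i}" for i in range(5)),
            "gamma0", "gamma1", "gamma2",
            "sigma_m1", "sigma_m2", "sigma_y",
        }
        if unknown:
            raise ValueError(f"unknown SEM coefficient keys: {sorted(unknown)}")
        return cls(**kwargs)  # type: ignore[arg-type]

    def to_file(self, path: Union[str, Path]) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "LinearSEM":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class DecompositionRequest:
    """What contrast to decompose, and at which reference levels.

    ``a`` and ``a_star`` are the treatment and reference exposure levels,
    ``m1_star``/``m2_star`` the fixed mediator reference levels entering the
    controlled direct effect and reference interactions, and
    ``covariate_profile`` the point ``c`` at which every effect is
    conditioned.
    """

    scenario: Scenario
    a: float
    a_star: float
    m1_star: float = 0.0
    m2_star: float = 0.0
    covariate_profile: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self) -> None:
        _check_scenario(self.scenario)
        object.__setattr__(
            self, "covariate_profile", _as_vector(self.covariate_profile)
        )


@dataclass(frozen=True)
class DecompositionResult:
    """The ten components of the total-effect decomposition.

    ``ie_m2`` is the pure indirect effect through M2 in the non-sequential
    scenario and the seminatural indirect effect through M2 in the
    sequential scenario (only the path A -> M2 -> Y is identifiable there).
    """

    cde: float
    intref_am1: float
    intref_am2: float
    intref_am1m2: float
    natint_am1: float
    natint_am2: float
    natint_am1m2: float
    natint_m1m2: float
    pie_m1: float
    ie_m2: float
    te: float
    scenario: Scenario = NONSEQUENTIAL

    def components(self) -> dict:
        return {name: getattr(self, name) for name in COMPONENT_FIELDS}

    def component_sum(self) -> float:
        return float(sum(self.components().values()))

    def labels(self) -> dict:
        """Flat report keyed by the field-standard component labels."""
        ie_label = "SNIE-M2" if self.scenario == SEQUENTIAL else "PIE-M2"
        names = ("CDE", "INTref-AM1", "INTref-AM2", "INTref-AM1M2",
                 "NatINT-AM1", "NatINT-AM2", "NatINT-AM1M2", "NatINT-M1M2",
                 "PIE-M1", ie_label)
        out = {lab: float(getattr(self, f)) for lab, f in zip(names, COMPONENT_FIELDS)}
        out["TE"] = float(self.te)
        return out


@dataclass(frozen=True)
class AggregateEffects:
    """Traditional summary effects recovered by summing components.

    pde:    pure direct effect      = CDE + the three INTref terms
    tde:    total direct effect     = PDE + the three exposure NatINT terms
    tie:    total indirect effect   = TE - PDE
    pe:     portion eliminated      = TE - CDE
    pai:    portion attributable to interaction = INTrefs + NatINTs
    nie_m1: natural indirect effect through M1 = NatINT-M1M2 + PIE-M1
    """

    pde: float
    tde: float
    tie: float
    pe: float
    pai: float
    nie_m1: float

    def labels(self) -> dict:
        return {
            "PDE": float(self.pde),
            "TDE": float(self.tde),
            "TIE": float(self.tie),
            "PE": float(self.pe),
            "PAI": float(self.pai),
            "NIE-M1": float(self.nie_m1),
        }


@dataclass(frozen=True)
class BellaviaComponents:
    """Mediated effects of the Bellavia--Valeri ten-way decomposition.

    Their mediated-interaction and pure natural indirect effects condition
    on arbitrarily fixed values ``M1(a*) = m1*`` and/or ``M2(a*) = m2*``,
    in contrast to the natural mediated interactions which average over the
    potential mediator values.  Defined only for non-sequential mediators.
    """

    intmed_am1: float
    intmed_am2: float
    intmed_am1m2: float
    pnie_m1m2: float
    pnie_m1: float
    pnie_m2: float

    def labels(self) -> dict:
        return {
            "INTmed-AM1": float(self.intmed_am1),
            "INTmed-AM2": float(self.intmed_am2),
            "INTmed-AM1M2": float(self.intmed_am1m2),
            "PNIE-M1M2": float(self.pnie_m1m2),
            "PNIE-M1": float(self.pnie_m1),
            "PNIE-M2": float(self.pnie_m2),
        }

    def total(self) -> float:
        return float(self.intmed_am1 + self.intmed_am2 + self.intmed_am1m2
                     + self.pnie_m1m2 + self.pnie_m1 + self.pnie_m2)


class ObservationalLaw:
    """Discrete conditional laws over finite supports.

    Holds the conditional outcome mean ``p[a, m1, m2, c] = E[Y | a, m1, m2, c]``
    and the conditional mediator distributions ``Pr(M1 = m1 | a, c)`` and
    ``Pr(M2 = m2 | a, m1, c)`` as dense arrays indexed by position in the
    declared supports.  Covariates enter as a discrete stratum index.

    Parameters
    ----------
    outcome_mean : array (n_a, n_m1, n_m2, n_strata)
    m1_dist : array (n_a, n_m1, n_strata)
    m2_dist : array (n_a, n_m1, n_m2, n_strata)
        For a non-sequential system this table is constant in its m1 axis;
        use :meth:`from_nonsequential` to broadcast a (n_a, n_m2, n_strata)
        table.
    a_support, m1_support, m2_support : sequences of support values
    n_strata : int
    """

    def __init__(self, outcome_mean, m1_dist, m2_dist,
                 a_support: Sequence[float], m1_support: Sequence[float],
                 m2_support: Sequence[float], n_strata: int = 1) -> None:
        self.outcome_mean = np.asarray(outcome_mean, dtype=float)
        self.m1_dist = np.asarray(m1_dist, dtype=float)
        self.m2_dist = np.asarray(m2_dist, dtype=float)
        self.a_support = [float(v) for v in a_support]
        self.m1_support = [float(v) for v in m1_support]
        self.m2_support = [float(v) for v in m2_support]
        self.n_strata = int(n_strata)
        self.validate()

    @classmethod
    def from_nonsequential(cls, outcome_mean, m1_dist, m2_marginal,
                           a_support, m1_support, m2_support,
                           n_strata: int = 1) -> "ObservationalLaw":
        """Build a law whose M2 distribution does not depend on M1."""
        m2_marginal = np.asarray(m2_marginal, dtype=float)
        m2_dist = np.broadcast_to(
            m2_marginal[:, None, :, :],
            (len(a_support), len(m1_support), len(m2_support), n_strata),
        ).copy()
        return cls(outcome_mean, m1_dist, m2_dist,
                   a_support, m1_support, m2_support, n_strata)

    def validate(self) -> None:
        shape = (len(self.a_support), len(self.m1_support),
                 len(self.m2_support), self.n_strata)
        if self.outcome_mean.shape != shape:
            raise ValueError(
                f"outcome_mean shape {self.outcome_mean.shape} != {shape}")
        if self.m1_dist.shape != (shape[0], shape[1], shape[3]):
            raise ValueError("m1_dist shape mismatch")
        if self.m2_dist.shape != shape:
            raise ValueError("m2_dist shape mismatch")
        for name, arr, axis in (("m1_dist", self.m1_dist, 1),
                                ("m2_dist", self.m2_dist, 2)):
            if np.any(arr < -1e-15) or np.any(arr > 1 + 1e-15):
                raise ValueError(f"{name} has probabilities outside [0, 1]")
            sums = arr.sum(axis=axis)
            if not np.allclose(sums, 1.0, rtol=0, atol=1e-12):
                raise ValueError(
                    f"{name} does not sum to 1 over its mediator support "
                    f"(max deviation {np.abs(sums - 1).max():.3g})")
        if not np.all(np.isfinite(self.outcome_mean)):
            raise ValueError("outcome_mean contains non-finite entries")

    def index_of(self, which: str, value: float) -> int:
        support = getattr(self, f"{which}_support")
        for i, v in enumerate(support):
            if v == value or abs(v - value) <= 1e-12:
                return i
        raise ValueError(f"value {value} not in {which} support {support}")


#: sentinel meaning "use the exposure value assigned to the outcome"
INHERIT = "inherit"


@dataclass(frozen=True)
class CounterfactualAssignment:
    """Specification of which exposure value feeds each structural input.

    Determines a unique nested counterfactual such as
    ``Y(a, M1(a*), M2(a**, M1(a***)))``:

    * ``exposure_for_y`` -- exposure entering Y's structural equation;
    * ``exposure_for_m1`` -- exposure activating M1 (or :data:`INHERIT`);
      ignored when ``m1_override`` fixes M1 at a constant level;
    * ``exposure_for_m2`` -- exposure activating M2 (or :data:`INHERIT`);
      ignored when ``m2_override`` is set;
    * ``m2_m1_source`` -- in the sequential structure, which exposure value
      generates the M1 fed into M2's equation.  ``None`` means: feed
      ``m1_override`` if set, otherwise the same M1 that feeds Y.
    """

    exposure_for_y: float
    exposure_for_m1: Union[float, str] = INHERIT
    exposure_for_m2: Union[float, str] = INHERIT
    m1_override: Union[float, None] = None
    m2_override: Union[float, None] = None
    m2_m1_source: Union[float, str, None] = None

    def _resolve(self, value) -> float:
        return float(self.exposure_for_y) if value == INHERIT else float(value)

    @property
    def a_y(self) -> float:
        return float(self.exposure_for_y)

    @property
    def a_m1(self) -> float:
        return self._resolve(self.exposure_for_m1)

    @property
    def a_m2(self) -> float:
        return self._resolve(self.exposure_for_m2)

    def m1_activation_values(self, scenario: Scenario) -> list:
        """Exposure values at which a counterfactual M1 is activated."""
        values = []
        if self.m1_override is None:
            values.append(self.a_m1)
        if scenario == SEQUENTIAL and self.m2_override is None:
            if self.m2_m1_source is None:
                if self.m1_override is None:
                    values.append(self.a_m1)
            else:
                values.append(self._resolve(self.m2_m1_source))
        return values


def validate_request(sem: LinearSEM, req: DecompositionRequest) -> DecompositionRequest:
    """Check that a request is compatible with a model; return it unchanged.

    A degenerate contrast ``a == a*`` is legal and yields all-zero effects.
    """
    if req.covariate_profile.size != sem.covariate_dim:
        raise ValueError(
            f"covariate_profile has length {req.covariate_profile.size} but the "
            f"SEM has {sem.covariate_dim} covariate coefficient(s)")
    values = [req.a, req.a_star, req.m1_star, req.m2_star,
              *req.covariate_profile.tolist()]
    if not all(math.isfinite(float(v)) for v in values):
        raise ValueError("request contains non-finite values")
    if req.scenario == NONSEQUENTIAL and not sem.is_nonsequential:
        raise ValueError(
            "non-sequential request paired with a SEM whose M2 model depends "
            "on M1 (beta2 or beta3 nonzero)")
    return req


def is_identifiable(assign: CounterfactualAssignment,
                    scenario: Scenario) -> tuple[bool, str]:
    """Avin-style identifiability check for a nested counterfactual.

    In the sequential structure a counterfactual mean is non-parametrically
    identifiable only if M1 is not activated at two distinct exposure values
    at once -- neither via two counterfactual activations (directly for Y
    and through M2's M1 input), nor by fixing M1 at a constant for Y while
    M2 receives a counterfactual M1.
    """
    _check_scenario(scenario)
    if scenario == NONSEQUENTIAL:
        return True, "M2 takes no M1 input; M1 is activated at most once"
    m2_gets_counterfactual_m1 = (
        assign.m2_override is None and assign.m2_m1_source is not None
    )
    if assign.m1_override is not None and m2_gets_counterfactual_m1:
        return False, (
            "M1 is fixed at a constant for Y while a counterfactual M1 feeds "
            "M2: M1 takes two values at once")
    activations = set(assign.m1_activation_values(scenario))
    if len(activations) > 1:
        return False, (
            f"M1 is activated at two distinct exposure values {sorted(activations)}")
    return True, "M1 is activated at a single exposure value"
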