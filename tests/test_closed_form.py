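"""Closed-form component formulas: reference values and algebraic identities."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from natmedint import (
    DecompositionRequest,
    bellavia_components,
    closed_form_te,
    compute_aggregates,
    decompose_linear,
)

from conftest import STUDY_BELLAVIA_TRUTH, STUDY_TRUTH, random_sem

coef = st.floats(-1, 1, allow_nan=False)


def sem_strategy(sequential=True):
    n = 17 if sequential else 15
    return st.tuples(
        st.lists(coef, min_size=n, max_size=n),
        st.floats(0, 1, allow_nan=False),
    ).map(lambda t: _build_sem(t[0], t[1], sequential))


def _build_sem(v, sigma, sequential):
    from natmedint import LinearSEM

    it = iter(v)
    nx = lambda: next(it)
    theta = [nx() for _ in range(8)]
    beta = [nx(), nx()] + ([nx(), nx()] if sequential else [0.0, 0.0])
    return LinearSEM(*theta, theta8=[nx()], beta0=beta[0], beta1=beta[1],
                     beta2=beta[2], beta3=beta[3], beta4=[nx()],
                     gamma0=nx(), gamma1=nx(), gamma2=[nx()],
                     sigma_m1=sigma)


req_strategy = st.tuples(coef, coef, coef, coef, coef)


class TestStudyDesignTruths:
    """The reference design reproduces its known component values."""

    def test_ten_components_and_te(self, study_sem, study_req):
        result = decompose_linear(study_sem, study_req)
        labels = result.labels()
        for name, expected in STUDY_TRUTH.items():
            if name == "PDE":
                continue
            assert labels[name] == pytest.approx(expected, abs=5e-5), name

    def test_pde_aggregate(self, study_sem, study_req):
        agg = compute_aggregates(decompose_linear(study_sem, study_req))
        assert agg.pde == pytest.approx(STUDY_TRUTH["PDE"], abs=5e-5)
        assert agg.tie == pytest.approx(
            STUDY_TRUTH["TE"] - STUDY_TRUTH["PDE"], abs=1e-4)

    def test_te_polynomial_agrees(self, study_sem, study_req):
        assert closed_form_te(study_sem, study_req) == pytest.approx(
            STUDY_TRUTH["TE"], abs=5e-5)

    def test_bellavia_values(self, study_sem, study_req):
        labels = bellavia_components(study_sem, study_req).labels()
        for name, expected in STUDY_BELLAVIA_TRUTH.items():
            assert labels[name] == pytest.approx(expected, abs=5e-5), name


class TestInteractionFreeModel:
    """Without interaction coefficients the decomposition collapses to
    product-of-coefficients mediation formulas."""

    @pytest.fixture()
    def plain_sem(self, study_sem):
        return dataclasses.replace(
            study_sem, theta4=0.0, theta5=0.0, theta6=0.0, theta7=0.0)

    def test_all_interaction_components_vanish(self, plain_sem, study_req):
        r = decompose_linear(plain_sem, study_req)
        for name in ("intref_am1", "intref_am2", "intref_am1m2",
                     "natint_am1", "natint_am2", "natint_am1m2",
                     "natint_m1m2"):
            assert getattr(r, name) == 0.0, name

    def test_product_of_coefficients(self, plain_sem, study_req):
        r = decompose_linear(plain_sem, study_req)
        da = study_req.a - study_req.a_star
        assert r.cde == pytest.approx(plain_sem.theta1 * da)
        assert r.pie_m1 == pytest.approx(
            plain_sem.theta2 * plain_sem.gamma1 * da)
        assert r.ie_m2 == pytest.approx(
            plain_sem.theta3 * plain_sem.beta1 * da)


class TestAlgebraicIdentities:
    @settings(derandomize=True, max_examples=100)
    @given(sem_strategy(sequential=True), req_strategy)
    def test_components_sum_to_te_polynomial(self, sem, reqvals):
        """Ten components sum to the independently derived quartic TE."""
        a, a_star, m1s, m2s, c = reqvals
        for scenario, model in (("sequential", sem),
                                ("nonsequential", sem.as_nonsequential())):
            req = DecompositionRequest(scenario, 2 * a, -1 + a_star,
                                       m1s, m2s, [c])
            result = decompose_linear(model, req)
            te = closed_form_te(model, req)
            assert result.component_sum() == pytest.approx(
                te, rel=1e-9, abs=1e-12)
            assert result.te == pytest.approx(te, rel=1e-9, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(sem_strategy(sequential=False), req_strategy)
    def test_bellavia_sum_identity(self, sem, reqvals):
        """CDE + INTrefs + the six comparison mediated effects = TE for any
        choice of the fixed reference levels."""
        a, a_star, m1s, m2s, c = reqvals
        req = DecompositionRequest("nonsequential", a + 1, a_star - 1,
                                   m1s, m2s, [c])
        r = decompose_linear(sem, req)
        b = bellavia_components(sem, req)
        total = (r.cde + r.intref_am1 + r.intref_am2 + r.intref_am1m2
                 + b.total())
        assert total == pytest.approx(r.te, rel=1e-9, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(sem_strategy(sequential=True), req_strategy, coef)
    def test_theta_scaling(self, sem, reqvals, k):
        """Every component is linear in the outcome coefficients."""
        a, a_star, m1s, m2s, c = reqvals
        req = DecompositionRequest("sequential", a + 1, a_star - 1, m1s, m2s, [c])
        scaled = dataclasses.replace(
            sem, **{f"theta{i}": k * getattr(sem, f"theta{i}") for i in range(8)},
            theta8=k * sem.theta8)
        base = decompose_linear(sem, req).components()
        top = decompose_linear(scaled, req).components()
        for name in base:
            assert top[name] == pytest.approx(k * base[name],
                                              rel=1e-9, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(sem_strategy(sequential=True), req_strategy, coef, coef)
    def test_reference_level_invariance(self, sem, reqvals, alt1, alt2):
        """te, the NatINTs and the indirect effects are free of m1*, m2*;
        only CDE and the reference interactions depend on them."""
        a, a_star, m1s, m2s, c = reqvals
        r1 = decompose_linear(sem, DecompositionRequest(
            "sequential", a + 1, a_star - 1, m1s, m2s, [c]))
        r2 = decompose_linear(sem, DecompositionRequest(
            "sequential", a + 1, a_star - 1, alt1, alt2, [c]))
        for name in ("natint_am1", "natint_am2", "natint_am1m2",
                     "natint_m1m2", "pie_m1", "ie_m2"):
            assert getattr(r1, name) == getattr(r2, name), name
        assert r1.te == pytest.approx(r2.te, rel=1e-9, abs=1e-12)

    def test_degenerate_contrast_all_zero(self, study_sem):
        req = DecompositionRequest("nonsequential", 0.7, 0.7, 0.3, -0.2, [0.2])
        r = decompose_linear(study_sem, req)
        assert all(v == 0.0 for v in r.components().values())
        assert closed_form_te(study_sem, req) == 0.0


class TestScenarioLimits:
    def test_sequential_formulas_reduce_to_nonsequential(self, study_sem):
        """With beta2 = beta3 = 0 both scenario code paths agree exactly."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            sem = random_sem(rng, sequential=False)
            a, a_star = rng.uniform(-2, 2, 2)
            m1s, m2s, c = rng.uniform(-1, 1, 3)
            seq = decompose_linear(sem, DecompositionRequest(
                "sequential", a, a_star, m1s, m2s, [c]))
            nonseq = decompose_linear(sem, DecompositionRequest(
                "nonsequential", a, a_star, m1s, m2s, [c]))
            for name, v in seq.components().items():
                assert abs(v - getattr(nonseq, name)) <= 1e-12, name

    def test_m2_inert_reduces_to_single_mediator_four_way(self):
        """Silencing M2 recovers the classical four-way decomposition:
        CDE = (th1 + th4 m1*)(a - a*), INTref = th4 (E[M1(a*)] - m1*)(a - a*),
        INTmed = th4 g1 (a - a*)^2, PIE = (th2 + th4 a*) g1 (a - a*)."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            sem = random_sem(rng, sequential=False)
            sem = dataclasses.replace(sem, beta1=0.0, theta3=0.0,
                                      theta5=0.0, theta6=0.0, theta7=0.0)
            a, a_star = rng.uniform(-2, 2, 2)
            m1s, c = rng.uniform(-1, 1, 2)
            req = DecompositionRequest("nonsequential", a, a_star, m1s, 0.0, [c])
            r = decompose_linear(sem, req)
            da = a - a_star
            em1_star = sem.gamma0 + sem.gamma1 * a_star + sem.gamma2[0] * c
            assert r.cde == pytest.approx((sem.theta1 + sem.theta4 * m1s) * da)
            assert r.intref_am1 == pytest.approx(
                sem.theta4 * (em1_star - m1s) * da)
            assert r.natint_am1 == pytest.approx(
                sem.theta4 * sem.gamma1 * da * da)
            assert r.pie_m1 == pytest.approx(
                (sem.theta2 + sem.theta4 * a_star) * sem.gamma1 * da)
            for name in ("intref_am2", "intref_am1m2", "natint_am2",
                         "natint_am1m2", "natint_m1m2", "ie_m2"):
                assert getattr(r, name) == pytest.approx(0.0, abs=1e-15), name


class TestBellavia:
    def test_rejects_sequential_model(self, study_seq_sem):
        req = DecompositionRequest("sequential", 1, 0, covariate_profile=[0.2])
        with pytest.raises(ValueError, match="non-sequential"):
            bellavia_components(study_seq_sem, req)

    def test_coincides_with_natural_effects_at_model_implied_means(
            self, study_sem):
        """Fixing the reference levels at the model-implied mediator means
        under the reference exposure makes the two-way comparison mediated
        effects equal the natural mediated interactions."""
        c = 0.2
        a, a_star = 1.0, 0.0
        m2s = study_sem.beta0 + study_sem.beta1 * a_star + study_sem.beta4[0] * c
        m1s = study_sem.gamma0 + study_sem.gamma1 * a_star + study_sem.gamma2[0] * c
        req = DecompositionRequest("nonsequential", a, a_star, m1s, m2s, [c])
        b = bellavia_components(study_sem, req)
        r = decompose_linear(study_sem, req)
        assert b.intmed_am1 == pytest.approx(r.natint_am1, rel=1e-12)
        assert b.intmed_am2 == pytest.approx(r.natint_am2, rel=1e-12)

    def test_without_three_way_interaction_intmed_am1_ignores_m2_ref(
            self, study_sem):
        sem = dataclasses.replace(study_sem, theta7=0.0)
        da2 = 1.0
        for m2s in (-3.0, 0.0, 5.0):
            req = DecompositionRequest("nonsequential", 1, 0, 0.0, m2s, [0.2])
            b = bellavia_components(sem, req)
            assert b.intmed_am1 == pytest.approx(
                sem.theta4 * sem.gamma1 * da2)


class TestAggregates:
    def test_four_way_regrouping(self, study_sem):
        """CDE + PAI + PIE-M1 + PIE-M2 regroups to the total effect."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            sem = random_sem(rng, sequential=True)
            req = DecompositionRequest(
                "sequential", *rng.uniform(-2, 2, 2), *rng.uniform(-1, 1, 2),
                [rng.uniform(-1, 1)])
            r = decompose_linear(sem, req)
            agg = compute_aggregates(r)
            assert agg.pai + r.cde + r.pie_m1 + r.ie_m2 == pytest.approx(
                r.te, rel=1e-9, abs=1e-12)
            assert agg.tde == pytest.approx(
                agg.pde + r.natint_am1 + r.natint_am2 + r.natint_am1m2)
            assert agg.nie_m1 == pytest.approx(r.natint_m1m2 + r.pie_m1)

    def test_zero_components_zero_aggregates(self):
        from natmedint import DecompositionResult

        zero = DecompositionResult(*([0.0] * 10), te=0.0)
        agg = compute_aggregates(zero)
        assert all(v == 0.0 for v in agg.labels().values())
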