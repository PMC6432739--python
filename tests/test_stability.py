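"""Jacobians, characteristic polynomials, Routh-Hurwitz, classification, Dulac."""

import numpy as np
import pytest

import chemoviro as cv
from chemoviro.stability import jacobian_fd
from conftest import random_nondim


def _state(coords, columns, label="test"):
    return cv.SteadyState(coords=np.asarray(coords, float), columns=columns, label=label)


class TestJacobian:
    def test_logistic_slope_at_capacity(self, nd):
        J = cv.jacobian("none", [1.0], nd)
        assert J[0, 0] == pytest.approx(-nd.alpha)

    def test_drug_row_is_decoupled_decay(self, nd):
        spec = cv.InfusionSpec("constant", phi=nd.phi)
        J = cv.jacobian("full", [0.0, 0.0, 0.0, nd.phi / nd.psi], nd, spec)
        assert J[3, 3] == pytest.approx(-nd.psi)
        assert J[3, :3] == pytest.approx([0, 0, 0])

    @pytest.mark.parametrize("model,dim", [("chemo", 2), ("viro", 3), ("full", 4)])
    def test_matches_central_differences(self, model, dim, rng, nd):
        spec = cv.InfusionSpec("constant", phi=nd.phi)
        rhs = cv.make_rhs(model, nd, spec)
        for _ in range(5):
            y = rng.uniform(0.05, 1.0, size=dim)
            J = cv.jacobian(model, y, nd, spec)
            J_fd = jacobian_fd(lambda v: rhs(0.0, v), y)
            assert np.max(np.abs(J - J_fd)) < 1e-6

    def test_autonomized_exponential_matches_central_differences(self, nd, rng):
        from chemoviro.equilibria import autonomized_rhs
        spec = cv.InfusionSpec("exponential", phi=nd.phi, a=0.7)
        rhs, _ = autonomized_rhs("full", nd, spec)
        y = rng.uniform(0.05, 1.0, size=5)
        J = cv.jacobian("full", y, nd, spec)
        assert np.max(np.abs(J - jacobian_fd(lambda v: rhs(0.0, v), y))) < 1e-6


class TestCharacteristicPolynomial:
    def test_diagonal_example(self):
        cp = cv.characteristic_polynomial(np.diag([-1.0, -2.0]))
        assert cp.coeffs == pytest.approx([1.0, 3.0, 2.0])

    def test_viro_infection_free_factorization(self, rng):
        # (lambda + alpha)(lambda^2 + lambda(1 + beta + gamma) + beta + gamma - b beta)
        for _ in range(5):
            p = random_nondim(rng)
            J = cv.jacobian("viro", [1.0, 0.0, 0.0], p)
            cp = cv.characteristic_polynomial(J)
            expected = np.polymul(
                [1.0, p.alpha],
                [1.0, 1.0 + p.beta + p.gamma, p.beta + p.gamma - p.b * p.beta],
            )
            assert cp.coeffs == pytest.approx(tuple(expected), rel=1e-10, abs=1e-10)

    def test_chemo_tumor_free_quadratic(self, rng):
        # lambda^2 + (psi - alpha + delta0 phi/psi) lambda + delta0 phi - alpha psi
        for _ in range(5):
            p = random_nondim(rng, viro_active=False)
            spec = cv.InfusionSpec("constant", phi=p.phi)
            J = cv.jacobian("chemo", [0.0, p.phi / p.psi], p, spec)
            cp = cv.characteristic_polynomial(J)
            expected = (1.0, p.psi - p.alpha + p.delta0 * p.phi / p.psi,
                        p.delta0 * p.phi - p.alpha * p.psi)
            assert cp.coeffs == pytest.approx(expected, rel=1e-10, abs=1e-10)

    def test_coefficients_match_eigen_decomposition(self, rng):
        # oracle: rebuild the monic polynomial from numeric eigenvalues
        for _ in range(5):
            J = rng.standard_normal((3, 3))
            cp = cv.characteristic_polynomial(J)
            rebuilt = np.real(np.poly(np.linalg.eigvals(J)))
            assert cp.coeffs == pytest.approx(tuple(rebuilt), rel=1e-8, abs=1e-8)


class TestRouthHurwitz:
    def test_known_stable_cubic(self):
        # roots {-1,-2,-3} -> (a2,a1,a0) = (6,11,6)
        assert cv.routh_hurwitz_cubic(6.0, 11.0, 6.0) == "stable"

    def test_product_condition_violated(self):
        assert cv.routh_hurwitz_cubic(1.0, 1.0, 2.0) == "unstable"

    def test_equality_is_marginal(self):
        assert cv.routh_hurwitz_cubic(2.0, 1.0, 2.0) == "marginal"

    def test_verdict_matches_root_finder_on_random_cubics(self, rng):
        agree = 0
        for _ in range(200):
            a2, a1, a0 = rng.uniform(-3, 3, size=3)
            verdict = cv.routh_hurwitz_cubic(a2, a1, a0)
            max_re = np.max(np.roots([1.0, a2, a1, a0]).real)
            if verdict == "marginal":
                agree += 1  # equality boundary, sign not asserted
            elif verdict == "stable":
                agree += max_re < 0
            else:
                agree += max_re > 0
        assert agree == 200


class TestClassify:
    def test_chemo_tumor_free_stable_when_drug_dominates(self):
        p = cv.NondimParams(alpha=0.2, beta=0, delta0=0.5, delta1=0, b=0,
                            gamma=0, phi=4.0, psi=2.0, a=1)  # delta0 phi > alpha psi
        spec = cv.InfusionSpec("constant", phi=4.0)
        tf = [s for s in cv.equilibria_chemo(p, spec) if s.label == "tumor-free"][0]
        rep = cv.classify(tf, "chemo", p, spec)
        assert rep.classification == "stable"
        assert rep.conditions["delta0*phi > alpha*psi"]
        # closed-form quadratic roots match numeric eigenvalues
        roots = np.sort(np.roots([1.0, p.psi - p.alpha + p.delta0 * p.phi / p.psi,
                                  p.delta0 * p.phi - p.alpha * p.psi]))
        assert np.sort(rep.eigenvalues.real) == pytest.approx(roots, rel=1e-10)

    def test_viro_extinction_state_spectrum(self, rng):
        # eigenvalues {alpha, -1, -gamma}: always unstable
        for _ in range(5):
            p = random_nondim(rng)
            tf = [s for s in cv.equilibria_viro(p) if s.label == "tumor-free"][0]
            rep = cv.classify(tf, "viro", p)
            assert rep.classification == "unstable"
            assert np.sort(rep.eigenvalues.real) == pytest.approx(
                np.sort([p.alpha, -1.0, -p.gamma]), rel=1e-10, abs=1e-12)
            assert rep.routh_hurwitz == "unstable"

    def test_full_tumor_free_closed_form_spectrum(self, rng):
        # four closed-form eigenvalues of the constant-infusion tumor-free state
        for _ in range(5):
            p = random_nondim(rng)
            spec = cv.InfusionSpec("constant", phi=p.phi)
            tf = [s for s in cv.equilibria_full(p, spec) if s.label == "tumor-free"][0]
            rep = cv.classify(tf, "full", p, spec)
            expected = np.sort([
                p.alpha - p.delta0 * p.phi / p.psi,
                -1.0 - p.delta1 * p.phi / p.psi,
                -p.gamma,
                -p.psi,
            ])
            assert np.sort(rep.eigenvalues.real) == pytest.approx(expected, rel=1e-10, abs=1e-10)
            assert np.max(np.abs(rep.eigenvalues.imag)) < 1e-12

    def test_nonexistent_state_rejected(self, nd):
        ghost = cv.SteadyState(coords=np.full(4, np.nan), columns=("U", "I", "V", "C"),
                               label="tumor-dormant", exists=False)
        with pytest.raises(cv.InvalidParameterError):
            cv.classify(ghost, "full", nd, cv.InfusionSpec("constant", phi=nd.phi))


class TestDulac:
    def test_hand_value(self):
        p = cv.NondimParams(alpha=1.0, beta=0, delta0=0.1, delta1=0, b=0,
                            gamma=0, phi=1.0, psi=1.0, a=1)
        spec = cv.InfusionSpec("constant", phi=1.0)
        assert cv.dulac_divergence(1.0, 1.0, p, spec) == pytest.approx(-2.0)

    def test_negative_on_positive_quadrant(self, rng):
        for _ in range(10):
            p = random_nondim(rng, viro_active=False)
            spec = cv.InfusionSpec("constant", phi=p.phi)
            U, C = np.meshgrid(np.linspace(0.1, 10, 40), np.linspace(0.1, 10, 40))
            assert np.all(cv.dulac_divergence(U, C, p, spec) < 0)

    def test_matches_finite_difference_divergence(self, rng, nd):
        spec = cv.InfusionSpec("constant", phi=nd.phi)
        for _ in range(100):
            U, C = rng.uniform(0.2, 8.0, size=2)
            assert cv.dulac_divergence(U, C, nd, spec) == pytest.approx(
                cv.dulac_divergence_fd(U, C, nd, spec), abs=1e-5)

    def test_domain_errors(self, nd):
        spec = cv.InfusionSpec("constant", phi=nd.phi)
        with pytest.raises(cv.DomainError):
            cv.dulac_divergence(0.0, 1.0, nd, spec)
        with pytest.raises(cv.InvalidParameterError):
            cv.dulac_divergence(1.0, 1.0, nd, cv.InfusionSpec("exponential", phi=1, a=1))


class TestVerifyBySimulation:
    def test_stable_chemo_node_attracts(self):
        p = cv.NondimParams(alpha=0.2, beta=0, delta0=0.5, delta1=0, b=0,
                            gamma=0, phi=4.0, psi=2.0, a=1)
        spec = cv.InfusionSpec("constant", phi=4.0)
        tf = [s for s in cv.equilibria_chemo(p, spec) if s.label == "tumor-free"][0]
        rep = cv.classify(tf, "chemo", p, spec)
        assert rep.classification == "stable"
        assert cv.verify_by_simulation(rep, p, spec) is True

    def test_unstable_infection_free_state_departs(self):
        p = cv.NondimParams(alpha=0.4, beta=0.5, delta0=0, delta1=0, b=10,
                            gamma=0.1, phi=0, psi=1, a=1)  # b beta > beta + gamma
        itf = [s for s in cv.equilibria_viro(p) if s.label == "infected-tumor-free"][0]
        rep = cv.classify(itf, "viro", p)
        assert rep.classification == "unstable"
        assert cv.verify_by_simulation(rep, p) is True

    def test_marginal_state_skipped(self, nd):
        # zero eigenvalue: logistic at U=0 with alpha artificially 0
        p = cv.NondimParams(alpha=0.0, beta=0, delta0=0, delta1=0, b=0,
                            gamma=0, phi=0, psi=1, a=1)
        s = _state([0.0, 0.0], ("U", "C"))
        rep = cv.classify(s, "chemo", p, cv.InfusionSpec("none"))
        assert cv.verify_by_simulation(rep, p, cv.InfusionSpec("none")) is None
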