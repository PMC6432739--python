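"""Method-of-steps DDE integration and delay-induced stability machinery."""

import math
from math import factorial

import numpy as np
import pytest

import chemoviro as cv
from conftest import random_nondim


def scalar_dde_exact(t, tau=0.5):
    """Exact method-of-steps solution of x'(t) = -x(t - tau), x = 1 on [-tau, 0].

    Piecewise polynomial: x(t) = sum_k (-1)^k (t - (k-1) tau)^k / k!.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t)
    for i, tt in enumerate(t):
        s = 0.0
        for k in range(int(tt / tau) + 2):
            if k > 0 and tt < (k - 1) * tau:
                break
            s += (-1) ** k * (tt - (k - 1) * tau) ** k / factorial(k)
        out[i] = s
    return out


class TestIntegrateDde:
    def test_scalar_test_problem_matches_exact_solution(self):
        traj = cv.integrate_dde(lambda t, y, lags: -lags[0], (0.5,), [1.0],
                                (0.0, 2.0), 0.01, policy=None)
        assert np.max(np.abs(traj.y[:, 0] - scalar_dde_exact(traj.t))) < 1e-8

    def test_fourth_order_convergence(self):
        errs = []
        for h in (0.05, 0.025):
            traj = cv.integrate_dde(lambda t, y, lags: -lags[0], (0.5,), [1.0],
                                    (0.0, 6.0), h, policy=None)
            errs.append(np.max(np.abs(traj.y[:, 0] - scalar_dde_exact(traj.t))))
        assert math.log2(errs[0] / errs[1]) > 3.7

    def test_zero_delay_reduces_to_ode_path(self, nd):
        spec = cv.InfusionSpec("constant", phi=nd.phi)
        y0 = np.array([1.0, 0.0, 0.1, 0.1])
        dde = cv.simulate_dde("full", nd, spec, cv.DelaySpec(0.0, 0.0), y0, (0.0, 5.0), 1e-3)
        ode = cv.integrate(cv.make_rhs("full", nd, spec), y0, (0.0, 5.0), 1e-3, model="full")
        assert np.max(np.abs(dde.y - ode.y)) < 1e-6

    def test_step_capped_at_half_the_smallest_delay(self):
        traj = cv.integrate_dde(lambda t, y, lags: -lags[0], (0.1,), [1.0],
                                (0.0, 1.0), 0.5, policy=None)
        assert traj.meta["h"] <= 0.05 + 1e-15

    def test_mixed_zero_and_positive_delays(self, nd):
        # tau1 = 0 passes the current state through; only tau2 lags
        spec = cv.InfusionSpec("constant", phi=nd.phi)
        y0 = np.array([0.9, 0.0, 0.1, 0.1])
        traj = cv.simulate_dde("full", nd, spec, cv.DelaySpec(0.0, 0.05), y0, (0.0, 1.0), 1e-3)
        assert np.all(np.isfinite(traj.y))

    def test_invalid_arguments(self):
        f = lambda t, y, lags: -lags[0]
        with pytest.raises(cv.InvalidParameterError):
            cv.integrate_dde(f, (-0.1,), [1.0], (0, 1), 0.01)
        with pytest.raises(cv.InvalidParameterError):
            cv.DelaySpec(tau1=-1.0)


class TestCharChemoDelay:
    def test_zero_delay_reduces_to_ode_quadratic(self, rng):
        for _ in range(5):
            p = random_nondim(rng, viro_active=False)
            spec = cv.InfusionSpec("constant", phi=p.phi)
            cf = cv.char_chemo_delay(p, spec, 0.0)
            roots = np.roots(cf.poly_at_zero)
            for r in roots:
                assert abs(cf(complex(r))) < 1e-9
            assert set(np.round(np.sort(roots.real), 9)) == set(
                np.round(np.sort([-p.psi, p.alpha - p.delta0 * p.phi / p.psi]), 9))

    def test_explicit_drug_factor_root(self, nd):
        spec = cv.InfusionSpec("constant", phi=nd.phi)
        for tau2 in (0.0, 0.1, 1.0, 5.0):
            cf = cv.char_chemo_delay(nd, spec, tau2)
            assert abs(cf(-nd.psi)) < 1e-12

    def test_continued_root_satisfies_equation(self, nd):
        # follow the ODE root to small tau2 by Newton; residual stays tiny
        spec = cv.InfusionSpec("constant", phi=nd.phi)
        cf = cv.char_chemo_delay(nd, spec, 0.05)
        from chemoviro.delay import _newton_polish
        z0 = nd.alpha - nd.delta0 * nd.phi / nd.psi
        root = _newton_polish(cf.reduced, complex(z0), tol=1e-10)
        assert root is not None
        assert abs(cf.reduced(root)) < 1e-10


class TestHopf:
    def test_boundary_case_flagged(self):
        p = cv.NondimParams(alpha=0.5, beta=0, delta0=1.0, delta1=0, b=0,
                            gamma=0, phi=1.0, psi=2.0, a=1)  # delta0 phi / psi == alpha
        res = cv.hopf_frequency(p, cv.InfusionSpec("constant", phi=1.0))
        assert not res.exists and res.boundary

    def test_three_four_five_triple(self):
        # delta0 phi / psi = 5, alpha = 3 -> omega = 4
        p = cv.NondimParams(alpha=3.0, beta=0, delta0=1.0, delta1=0, b=0,
                            gamma=0, phi=5.0, psi=1.0, a=1)
        res = cv.hopf_frequency(p, cv.InfusionSpec("constant", phi=5.0))
        assert res.exists
        assert res.omega == pytest.approx(4.0)

    def test_critical_delays_are_exact_roots(self, rng):
        # substitution oracle: |g(i omega)| = 0 at every catalogued tau2k
        for _ in range(10):
            alpha = rng.uniform(0.2, 0.6)
            ratio = rng.uniform(1.3, 3.0)
            psi = rng.uniform(1.0, 5.0)
            delta0 = rng.uniform(0.1, 1.0)
            phi = alpha * ratio * psi / delta0
            p = cv.NondimParams(alpha=alpha, beta=0, delta0=delta0, delta1=0, b=0,
                                gamma=0, phi=phi, psi=psi, a=1)
            spec = cv.InfusionSpec("constant", phi=phi)
            res = cv.hopf_frequency(p, spec)
            assert res.exists
            for k in range(3):
                cf = cv.char_chemo_delay(p, spec, res.tau_crit(k))
                assert abs(cf.reduced(1j * res.omega)) < 1e-9

    def test_no_crossing_without_drug_dominance(self, nd):
        res = cv.hopf_frequency(nd, cv.InfusionSpec("constant", phi=nd.phi))
        assert not res.exists
        with pytest.raises(cv.DomainError):
            res.tau_crit(0)


class TestCharViroDelay:
    def test_zero_delay_matches_ode_cubic(self, rng):
        for _ in range(5):
            p = random_nondim(rng)
            cf = cv.char_viro_delay(p, 0.0)
            J = cv.jacobian("viro", [1.0, 0.0, 0.0], p)
            ode = cv.characteristic_polynomial(J)
            assert cf.poly_at_zero == pytest.approx(ode.coeffs, rel=1e-10, abs=1e-10)

    def test_explicit_logistic_factor_root(self, nd):
        for tau1 in (0.0, 0.01, 0.5):
            cf = cv.char_viro_delay(nd, tau1)
            assert abs(cf(-nd.alpha)) < 1e-12

    def test_rightmost_root_sign_matches_simulation(self):
        # supercritical infection: (1,0,0) unstable; perturbation grows
        p = cv.NondimParams(alpha=0.4, beta=0.5, delta0=0, delta1=0, b=10,
                            gamma=0.1, phi=0, psi=1, a=1)
        tau1 = 0.05
        cf = cv.char_viro_delay(p, tau1)
        roots = cv.rightmost_root_scan(cf.reduced, (-1.5, 3.0), (-4.0, 4.0))
        assert roots and roots[0].real > 0

        from chemoviro.delay import integrate_dde

        def viro_delayed(t, y, lags):
            U, I, V = y
            L1 = lags[0]
            inf = p.beta * L1[0] * L1[2]
            return np.array([
                p.alpha * U * (1 - U - I) - inf,
                inf - I,
                p.b * I - inf - p.gamma * V,
            ])

        y0 = np.array([1.0, 0.0, 1e-4])
        traj = integrate_dde(viro_delayed, (tau1,), y0, (0.0, 20.0), 0.01,
                             columns=("U", "I", "V"))
        assert np.max(traj.column("I")) > 1e-2  # infection took off (and resolved)


class TestRightmostRootScan:
    def test_polynomial_roots_located(self):
        roots = cv.rightmost_root_scan(lambda z: z * z - 1.0, (-2, 2), (-1, 1))
        assert np.sort([r.real for r in roots]) == pytest.approx([-1.0, 1.0], abs=1e-9)
        assert roots[0].real > roots[-1].real  # sorted rightmost-first

    def test_zero_delay_factor_recovers_ode_roots(self, nd):
        spec = cv.InfusionSpec("constant", phi=nd.phi)
        cf = cv.char_chemo_delay(nd, spec, 0.0)
        roots = cv.rightmost_root_scan(cf, (-10.0, 2.0), (-2.0, 2.0))
        expected = np.sort(np.roots(cf.poly_at_zero).real)
        assert np.sort([r.real for r in roots]) == pytest.approx(expected, abs=1e-9)

    def test_crossing_appears_just_above_critical_delay(self):
        p = cv.NondimParams(alpha=0.4, beta=0, delta0=0.5, delta1=0, b=0,
                            gamma=0, phi=4.0, psi=2.0, a=1)
        spec = cv.InfusionSpec("constant", phi=4.0)
        res = cv.hopf_frequency(p, spec)
        below = cv.rightmost_real_part(p, spec, res.tau_crit(0) * 0.9)
        above = cv.rightmost_real_part(p, spec, res.tau_crit(0) * 1.1)
        assert below is None or below < 0
        assert above is not None and above > 0

    def test_scan_locates_crossing_near_closed_form(self):
        p = cv.NondimParams(alpha=0.4, beta=0, delta0=0.5, delta1=0, b=0,
                            gamma=0, phi=4.0, psi=2.0, a=1)
        spec = cv.InfusionSpec("constant", phi=4.0)
        res = cv.hopf_frequency(p, spec)
        found = cv.critical_delay_scan(p, spec)
        assert found == pytest.approx(res.tau_crit(0), abs=1e-3)
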