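"""Local stability machinery: Jacobians, characteristic polynomials,
Routh-Hurwitz tests, eigenvalue classification and the Dulac test.

Eigenvalues are always computed numerically from the analytic Jacobian; the
published closed-form polynomials and conditions are evaluated alongside as
cross-checks (several printed formulas carry typos, so the numeric spectrum
is authoritative).  Classification uses the signed real parts with a
marginal band of 1e-9: nothing inside the band is asserted stable or
unstable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._numdiff import fd_jacobian
from .dynamics import integrate, make_rhs, NegativityPolicy
from .equilibria import SteadyState, _frozen_w_rhs, autonomized_rhs
from .errors import DomainError, InvalidParameterError
from .infusion import InfusionSpec
from .params import NondimParams

MARGINAL_BAND = 1e-9

#: central-difference Jacobian, exposed as the independent cross-check for
#: the analytic Jacobians
jacobian_fd = fd_jacobian


# ---------------------------------------------------------------------------
# Jacobians
# ---------------------------------------------------------------------------

def jacobian(model: str, state, p: NondimParams, spec: InfusionSpec | None = None) -> np.ndarray:
    """Analytic Jacobian of a model variant at a state.

    For exponential schedules the state is the autonomized one (with W,
    rows C' = W - psi*C and W' = -a*W).  For sinusoidal schedules the
    autonomized W-equation is non-smooth at its equilibria, so the Jacobian
    is taken over the smooth compartments with W frozen; pass the state
    without its W coordinate (or with it -- it is dropped).
    """
    y = np.asarray(state, dtype=float)
    kind = spec.kind if spec is not None else "none"
    if model == "none":
        U = y[0]
        return np.array([[p.alpha * (1.0 - 2.0 * U)]])
    if model == "chemo":
        if kind == "exponential" and y.size == 3:
            U, C, W = y
            return np.array(
                [
                    [p.alpha * (1.0 - 2.0 * U) - p.delta0 * C, -p.delta0 * U, 0.0],
                    [0.0, -p.psi, 1.0],
                    [0.0, 0.0, -spec.a],
                ]
            )
        U, C = y[0], y[1]
        return np.array(
            [
                [p.alpha * (1.0 - 2.0 * U) - p.delta0 * C, -p.delta0 * U],
                [0.0, -p.psi],
            ]
        )
    if model == "viro":
        U, I, V = y
        return np.array(
            [
                [p.alpha * (1.0 - 2.0 * U - I) - p.beta * V, -p.alpha * U, -p.beta * U],
                [p.beta * V, -1.0, p.beta * U],
                [-p.beta * V, p.b, -p.beta * U - p.gamma],
            ]
        )
    if model == "full":
        U, I, V, C = y[0], y[1], y[2], y[3]
        J4 = np.array(
            [
                [
                    p.alpha * (1.0 - 2.0 * U - I) - p.beta * V - p.delta0 * C,
                    -p.alpha * U,
                    -p.beta * U,
                    -p.delta0 * U,
                ],
                [p.beta * V, -1.0 - p.delta1 * C, p.beta * U, -p.delta1 * I],
                [-p.beta * V, p.b, -p.beta * U - p.gamma, 0.0],
                [0.0, 0.0, 0.0, -p.psi],
            ]
        )
        if kind == "exponential" and y.size == 5:
            J5 = np.zeros((5, 5))
            J5[:4, :4] = J4
            J5[3, 4] = 1.0
            J5[4, 4] = -spec.a
            return J5
        return J4
    raise InvalidParameterError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Characteristic polynomial and Routh-Hurwitz
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CharPoly:
    """Monic characteristic polynomial, coefficients in descending degree."""

    coeffs: tuple

    @property
    def degree(self) -> int:
        return len(self.coeffs) - 1

    def __call__(self, lam):
        return np.polyval(self.coeffs, lam)

    def roots(self) -> np.ndarray:
        return np.roots(self.coeffs)

    @property
    def cubic_a(self) -> tuple:
        """(a2, a1, a0) for a cubic lambda^3 + a2 l^2 + a1 l + a0."""
        if self.degree != 3:
            raise InvalidParameterError("cubic coefficients requested for a non-cubic")
        return self.coeffs[1], self.coeffs[2], self.coeffs[3]


def characteristic_polynomial(J: np.ndarray) -> CharPoly:
    """Monic characteristic polynomial of a square matrix."""
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise InvalidParameterError("Jacobian must be a square matrix")
    c = np.poly(J)
    return CharPoly(coeffs=tuple(float(v) for v in c))


def routh_hurwitz_cubic(a2: float, a1: float, a0: float, tol: float = 1e-12) -> str:
    """Routh-Hurwitz verdict for lambda^3 + a2 l^2 + a1 l + a0.

    All roots have negative real parts iff a0, a1, a2 > 0 and a1*a2 > a0.
    Equalities within ``tol`` are reported as 'marginal'.
    """
    vals = (a0, a1, a2, a1 * a2 - a0)
    if any(abs(v) <= tol for v in vals):
        return "marginal"
    return "stable" if all(v > 0 for v in vals) else "unstable"


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    """Eigenvalue-based classification of one equilibrium."""

    state: SteadyState
    model: str
    eigenvalues: np.ndarray
    classification: str
    char_poly: CharPoly
    routh_hurwitz: str | None = None
    conditions: dict = field(default_factory=dict)
    notes: str = ""

    @property
    def max_real_part(self) -> float:
        return float(np.max(self.eigenvalues.real))

    def as_dict(self) -> dict:
        return {
            "state": self.state.as_dict(),
            "model": self.model,
            "eigenvalues": [{"re": float(l.real), "im": float(l.imag)} for l in self.eigenvalues],
            "classification": self.classification,
            "char_poly": list(self.char_poly.coeffs),
            "routh_hurwitz": self.routh_hurwitz,
            "conditions": {k: bool(v) for k, v in self.conditions.items()},
            "notes": self.notes,
        }


def _classify_spectrum(eigs: np.ndarray) -> str:
    m = float(np.max(eigs.real))
    if m > MARGINAL_BAND:
        return "unstable"
    if m < -MARGINAL_BAND:
        return "stable"
    return "marginal"


def _printed_conditions(state: SteadyState, model: str, p: NondimParams,
                        spec: InfusionSpec | None) -> dict:
    """Evaluate the closed-form stability/existence conditions reported
    alongside the numeric spectrum."""
    cond: dict[str, bool] = {}
    kind = spec.kind if spec is not None else "none"
    phi = spec.phi if spec is not None else 0.0
    a = spec.a if spec is not None else 1.0
    if model in ("chemo", "full"):
        if kind == "constant":
            cond["delta0*phi > alpha*psi"] = p.delta0 * phi > p.alpha * p.psi
            if state.label == "tumor-dormant" and model == "chemo":
                # printed condition, kept for side-by-side comparison
                cond["delta0*phi + alpha*psi > 2*delta0*phi*psi^2 (printed)"] = (
                    p.delta0 * phi + p.alpha * p.psi > 2.0 * p.delta0 * phi * p.psi**2
                )
                cond["alpha*psi > delta0*phi"] = p.alpha * p.psi > p.delta0 * phi
        elif kind == "sinusoidal":
            cond["delta0*phi > a*alpha*psi"] = p.delta0 * phi > a * p.alpha * p.psi
            cond["phi < 1"] = phi < 1.0
    if model in ("viro", "full"):
        cond["b*beta > beta + gamma"] = p.b * p.beta > p.beta + p.gamma
        cond["b > 1"] = p.b > 1.0
    return cond


def classify(state: SteadyState, model: str, p: NondimParams,
             spec: InfusionSpec | None = None) -> StabilityReport:
    """Numeric eigenvalue classification of a catalogued equilibrium.

    Exponential schedules are classified in the autonomized system; for
    sinusoidal schedules the frozen-W smooth sub-system is used (the
    autonomized W-equation is non-smooth at its fixed points).
    """
    if not state.exists:
        raise InvalidParameterError(
            f"state {state.label!r} does not exist at these parameters"
        )
    kind = spec.kind if spec is not None else "none"
    notes = ""
    if kind == "sinusoidal" and "W" in state.columns:
        w_star = state.coord("W")
        coords = state.coords[:-1]
        J = jacobian(model, coords, p, InfusionSpec("constant", phi=w_star))
        notes = "frozen-W sub-Jacobian (sinusoidal autonomization is non-smooth at W*)"
    else:
        J = jacobian(model, state.coords, p, spec)
    eigs = np.linalg.eigvals(J)
    order = np.argsort(-eigs.real)
    eigs = eigs[order]
    cp = characteristic_polynomial(J)
    rh = None
    if cp.degree == 3:
        a2, a1, a0 = cp.cubic_a
        rh = routh_hurwitz_cubic(a2, a1, a0)
    return StabilityReport(
        state=state,
        model=model,
        eigenvalues=eigs,
        classification=_classify_spectrum(eigs),
        char_poly=cp,
        routh_hurwitz=rh,
        conditions=_printed_conditions(state, model, p, spec),
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Dulac periodic-orbit exclusion (chemo-only, constant infusion)
# ---------------------------------------------------------------------------

def dulac_divergence(U, C, p: NondimParams, spec: InfusionSpec):
    """Divergence of g*f with the Dulac weight g = 1/(U C).

    For the planar chemotherapy system with constant infusion phi the
    weighted divergence is -alpha/C - phi/(U C^2) < 0 on the open positive
    quadrant, so the system has no periodic orbits there.
    """
    if spec.kind != "constant":
        raise InvalidParameterError("the Dulac weight 1/(UC) applies to the constant schedule")
    U_arr = np.asarray(U, dtype=float)
    C_arr = np.asarray(C, dtype=float)
    if np.any(U_arr <= 0) or np.any(C_arr <= 0):
        raise DomainError("Dulac divergence requires U > 0 and C > 0")
    out = -p.alpha / C_arr - spec.phi / (U_arr * C_arr**2)
    if np.isscalar(U) and np.isscalar(C):
        return float(out)
    return out


def dulac_divergence_fd(U: float, C: float, p: NondimParams, spec: InfusionSpec,
                        eps: float = 1e-6) -> float:
    """Finite-difference divergence of g*f (independent cross-check)."""
    rhs = make_rhs("chemo", p, spec)

    def gf(u, c):
        f = rhs(0.0, np.array([u, c]))
        return f / (u * c)

    dU = (gf(U + eps, C)[0] - gf(U - eps, C)[0]) / (2.0 * eps)
    dC = (gf(U, C + eps)[1] - gf(U, C - eps)[1]) / (2.0 * eps)
    return float(dU + dC)


# ---------------------------------------------------------------------------
# Simulation cross-check
# ---------------------------------------------------------------------------

def _rhs_for_report(report: StabilityReport, p: NondimParams,
                    spec: InfusionSpec | None):
    kind = spec.kind if spec is not None else "none"
    state = report.state
    if kind == "sinusoidal" and "W" in state.columns:
        f, _ = _frozen_w_rhs(report.model, p, state.coord("W"))
        return f, state.coords[:-1]
    if kind == "exponential" and "W" in state.columns:
        f, _ = autonomized_rhs(report.model, p, spec)
        return f, state.coords
    if report.model == "viro":
        return make_rhs("viro", p), state.coords
    return make_rhs(report.model, p, spec), state.coords


def verify_by_simulation(
    report: StabilityReport,
    p: NondimParams,
    spec: InfusionSpec | None = None,
    rhs=None,
    pert: float = 1e-4,
    n_directions: int = 2,
    rng=None,
    max_time: float = 300.0,
    hyperbolic_tol: float = 1e-6,
) -> bool | None:
    """Check an eigenvalue classification against perturbed simulations.

    Perturbs the equilibrium by ``pert`` in random directions (kept on the
    nonnegative cone), integrates, and checks that stable states attract the
    perturbation while unstable states repel it.  Returns True/False for
    agreement, or None when the equilibrium is non-hyperbolic (marginal) and
    the check is skipped.
    """
    lam = report.max_real_part
    if abs(lam) <= hyperbolic_tol or report.classification == "marginal":
        return None
    T = 8.0 / abs(lam)
    if T > max_time:
        # too weakly hyperbolic to resolve within the simulation horizon
        return None
    if rng is None:
        rng = np.random.default_rng(0)
    if rhs is None:
        rhs, y_star = _rhs_for_report(report, p, spec)
    else:
        y_star = report.state.coords
    y_star = np.asarray(y_star, dtype=float)
    fastest = float(np.max(np.abs(report.eigenvalues.real)) + np.max(np.abs(report.eigenvalues.imag)))
    h = min(0.02, 0.2 / max(fastest, 1.0))
    policy = NegativityPolicy(clip_tol=1e-300, fail_below=1.0)
    stable = report.classification == "stable"
    for _ in range(n_directions):
        d = rng.standard_normal(y_star.size)
        d[y_star <= 1e-12] = np.abs(d[y_star <= 1e-12])  # stay on the cone
        d /= np.linalg.norm(d)
        traj = integrate(rhs, y_star + pert * d, (0.0, T), h, policy=policy)
        dist = np.linalg.norm(traj.y - y_star, axis=1)
        if stable:
            if dist[-1] > 0.5 * pert:
                return False
        else:
            if np.max(dist) < 10.0 * pert:
                return False
    return True
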