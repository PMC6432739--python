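"""Delay-differential extension: method-of-steps integration and the
transcendental stability analysis of the delayed model.

The delays are tau1 (time the virus needs to mount an infection after
meeting a tumor cell) and tau2 (the drug-response lag).  Integration uses a
method-of-steps RK4: delayed state lookups interpolate the already-computed
solution with cubic Hermite polynomials (the step is kept at or below half
the smallest positive delay, so every lookup lies in stored history).
Linearizing about the tumor-free states gives transcendental characteristic
equations whose purely-imaginary roots mark delay-induced loss of stability;
the critical delays are computed in closed form and cross-checked by an
argument-principle root scan.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np

from .dynamics import (
    DEFAULT_POLICY,
    MODEL_COLUMNS,
    NegativityPolicy,
    Trajectory,
    integrate,
)
from .errors import DomainError, IntegrationFailure, InvalidParameterError
from .infusion import InfusionSpec, scalar_infusion
from .params import NondimParams


#: In the delayed model the lysis/consumption terms depend on the *lagged*
#: state, not the current one, so a nearly-extinct compartment is genuinely
#: pushed below zero by O(step x lagged rate) before the lag catches up.
#: Per-step projection back onto the cone discretizes the clamped dynamics;
#: the failure threshold is therefore wider than the ODE default.
DDE_POLICY = NegativityPolicy(clip_tol=1e-12, fail_below=0.05)


@dataclass(frozen=True)
class DelaySpec:
    """Virus-infection delay tau1 and drug-response delay tau2 (nondimensional)."""

    tau1: float = 0.0
    tau2: float = 0.0

    def __post_init__(self):
        if self.tau1 < 0 or self.tau2 < 0:
            raise InvalidParameterError("delays must be >= 0")

    @property
    def max_delay(self) -> float:
        return max(self.tau1, self.tau2)

    def to_dict(self) -> dict:
        return {"tau1": self.tau1, "tau2": self.tau2}


# ---------------------------------------------------------------------------
# Method-of-steps integration
# ---------------------------------------------------------------------------

class _History:
    """Uniform-grid solution store with cubic Hermite lookup."""

    __slots__ = ("t0", "h", "ys", "fs", "n", "y_init")

    def __init__(self, t0: float, h: float, n_max: int, y_init: np.ndarray):
        self.t0 = t0
        self.h = h
        self.ys = np.empty((n_max + 1, y_init.size))
        self.fs = np.empty((n_max + 1, y_init.size))
        self.n = 0
        self.y_init = y_init

    def push(self, y: np.ndarray, f: np.ndarray) -> None:
        self.ys[self.n] = y
        self.fs[self.n] = f
        self.n += 1

    def eval(self, s: float) -> np.ndarray:
        """State at time s <= last stored node (constant history before t0)."""
        if s <= self.t0:
            return self.y_init
        x = (s - self.t0) / self.h
        j = int(x)
        last = self.n - 1
        if j >= last:
            j = last - 1 if last > 0 else 0
        theta = x - j
        if theta <= 1e-13:
            return self.ys[j]
        y0, y1 = self.ys[j], self.ys[j + 1]
        f0, f1 = self.fs[j], self.fs[j + 1]
        t2 = theta * theta
        t3 = t2 * theta
        h00 = 2.0 * t3 - 3.0 * t2 + 1.0
        h10 = t3 - 2.0 * t2 + theta
        h01 = -2.0 * t3 + 3.0 * t2
        h11 = t3 - t2
        return h00 * y0 + self.h * h10 * f0 + h01 * y1 + self.h * h11 * f1


def integrate_dde(
    rhs,
    delays,
    y0,
    t_span,
    h: float,
    policy: NegativityPolicy | None = DEFAULT_POLICY,
    columns: tuple | None = None,
    model: str = "custom",
    meta: dict | None = None,
) -> Trajectory:
    """Method-of-steps RK4 for y'(t) = rhs(t, y(t), (y(t - tau_i), ...)).

    ``delays`` is a sequence of lags; ``rhs(t, y, lags)`` receives the
    delayed states in the same order (a zero lag passes the current stage
    state through, so zero delays reproduce the plain RK4 path exactly).
    The history is the constant function y(t) = y0 on [-max(delays), t0].
    The step is capped at half the smallest positive delay so that every
    delayed lookup falls inside the stored solution.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if h <= 0:
        raise InvalidParameterError(f"step h must be > 0, got {h}")
    if t1 <= t0:
        raise InvalidParameterError(f"t_span must be increasing, got {t_span}")
    delays = [float(d) for d in delays]
    if any(d < 0 for d in delays):
        raise InvalidParameterError("delays must be >= 0")
    y = np.atleast_1d(np.asarray(y0, dtype=float)).copy()
    d_dim = y.size
    if columns is None:
        columns = MODEL_COLUMNS.get(model, tuple(f"y{i}" for i in range(d_dim)))

    positive = [d for d in delays if d > 0.0]
    if not positive:
        f_ode = lambda t, yy: rhs(t, yy, tuple(yy for _ in delays))
        return integrate(f_ode, y, (t0, t1), h, policy=policy, columns=columns,
                         model=model, meta=meta)

    h_eff = min(h, min(positive) / 2.0)
    n = max(1, int(math.ceil((t1 - t0) / h_eff - 1e-9)))
    h_eff = (t1 - t0) / n  # uniform grid hitting t1 exactly
    hist = _History(t0, h_eff, n, y.copy())

    def lags_at(t: float, y_stage: np.ndarray):
        return tuple(y_stage if d == 0.0 else hist.eval(t - d) for d in delays)

    def f(t: float, y_stage: np.ndarray) -> np.ndarray:
        return np.asarray(rhs(t, y_stage, lags_at(t, y_stage)), dtype=float)

    ts = t0 + h_eff * np.arange(n + 1)
    out = np.empty((n + 1, d_dim))
    if policy is not None:
        y = policy.apply(y, t0)
    out[0] = y
    half = 0.5 * h_eff
    sixth = h_eff / 6.0
    for i in range(n):
        t = ts[i]
        k1 = f(t, y)
        hist.push(y, k1)
        k2 = f(t + half, y + half * k1)
        k3 = f(t + half, y + half * k2)
        k4 = f(t + h_eff, y + h_eff * k3)
        y = y + sixth * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if policy is not None:
            y = policy.apply(y, ts[i + 1])
        elif not np.all(np.isfinite(y)):
            raise IntegrationFailure(
                f"non-finite state at t={ts[i + 1]:.6g}", last_valid_time=ts[i]
            )
        out[i + 1] = y
    m = dict(meta or {})
    m.setdefault("h", h_eff)
    m.setdefault("delays", list(delays))
    return Trajectory(t=ts, y=out, columns=tuple(columns), model=model, meta=m)


def rhs_full_delayed(p: NondimParams, spec: InfusionSpec):
    """Delayed RHS of the full model; lags arrive as (state at t-tau1, at t-tau2)."""
    xi = scalar_infusion(spec)
    alpha, beta, delta0, delta1, b, gamma, psi = (
        p.alpha, p.beta, p.delta0, p.delta1, p.b, p.gamma, p.psi)

    def f(t, y, lags):
        U, I, V, C = y
        L1, L2 = lags
        inf_term = beta * L1[0] * L1[2]  # beta * U(t-tau1) * V(t-tau1)
        return np.array(
            [
                alpha * U * (1.0 - U - I) - inf_term - delta0 * L2[0] * L2[3],
                inf_term - I - delta1 * L2[1] * L2[3],
                b * I - inf_term - gamma * V,
                xi(t) - psi * C,
            ]
        )

    return f


def rhs_chemo_delayed(p: NondimParams, spec: InfusionSpec):
    """Delayed RHS of the chemotherapy-only model; single lag tau2."""

    xi = scalar_infusion(spec)

    def f(t, y, lags):
        U, C = y
        (L2,) = lags
        return np.array(
            [
                p.alpha * U * (1.0 - U) - p.delta0 * L2[0] * L2[1],
                xi(t) - p.psi * C,
            ]
        )

    return f


def simulate_dde(
    model: str,
    p: NondimParams,
    spec: InfusionSpec,
    delays: DelaySpec,
    y0,
    t_span,
    h: float,
    policy: NegativityPolicy | None = DDE_POLICY,
    meta: dict | None = None,
) -> Trajectory:
    """Integrate the delayed chemo or full model from a constant history y0."""
    m = dict(meta or {})
    m.setdefault("time_unit_days", p.time_unit_days)
    if model == "full":
        return integrate_dde(
            rhs_full_delayed(p, spec), (delays.tau1, delays.tau2), y0, t_span, h,
            policy=policy, model="full", meta=m,
        )
    if model == "chemo":
        return integrate_dde(
            rhs_chemo_delayed(p, spec), (delays.tau2,), y0, t_span, h,
            policy=policy, model="chemo", meta=m,
        )
    raise InvalidParameterError(f"no delayed variant for model {model!r}")


# ---------------------------------------------------------------------------
# Transcendental characteristic functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CharFunction:
    """Characteristic function f(lambda) of a linearized delay model.

    ``reduced`` is the nontrivial transcendental factor once explicit linear
    factors are peeled off; ``poly_at_zero`` are the monic polynomial
    coefficients the function reduces to at zero delay.
    """

    f: callable
    label: str
    tau: float
    reduced: callable | None = None
    poly_at_zero: tuple = ()

    def __call__(self, lam):
        return self.f(lam)


def char_chemo_delay(p: NondimParams, spec: InfusionSpec, tau2: float) -> CharFunction:
    """Characteristic function at the tumor-free state of the delayed
    chemotherapy model: f(l) = (l + psi) (l - alpha + e^{-l tau2} delta0 phi / psi)."""
    if tau2 < 0:
        raise InvalidParameterError("tau2 must be >= 0")
    B = p.delta0 * spec.phi / p.psi

    def g(lam):
        return lam - p.alpha + B * cmath.exp(-lam * tau2)

    def f(lam):
        return (lam + p.psi) * g(lam)

    return CharFunction(
        f=f,
        label="chemo-delay tumor-free",
        tau=tau2,
        reduced=g,
        poly_at_zero=(1.0, p.psi - p.alpha + B, p.delta0 * spec.phi - p.alpha * p.psi),
    )


def char_viro_delay(p: NondimParams, tau1: float) -> CharFunction:
    """Characteristic function at the infection-free state (1, 0, 0) of the
    delayed virotherapy model:
    f(l) = (l + alpha) [ (l + 1)(l + gamma + beta e^{-l tau1}) - b beta e^{-l tau1} ]."""
    if tau1 < 0:
        raise InvalidParameterError("tau1 must be >= 0")

    def g(lam):
        e = cmath.exp(-lam * tau1)
        return (lam + 1.0) * (lam + p.gamma + p.beta * e) - p.b * p.beta * e

    def f(lam):
        return (lam + p.alpha) * g(lam)

    return CharFunction(
        f=f,
        label="viro-delay infection-free",
        tau=tau1,
        reduced=g,
        poly_at_zero=(
            1.0,
            p.alpha + 1.0 + p.beta + p.gamma,
            p.alpha * (1.0 + p.beta + p.gamma) + p.beta + p.gamma - p.b * p.beta,
            p.alpha * (p.beta + p.gamma - p.b * p.beta),
        ),
    )


# ---------------------------------------------------------------------------
# Hopf frequency and critical delays
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HopfResult:
    """Purely-imaginary-root data of the reduced chemo-delay factor.

    A pair +-i omega exists iff delta0*phi/psi > alpha, with
    omega = sqrt((delta0 phi/psi)^2 - alpha^2); the delay first destroys
    stability at tau2 = tau_crit(0) and again at every tau_crit(k).
    """

    exists: bool
    condition: str
    omega: float = 0.0
    boundary: bool = False

    def tau_crit(self, k: int = 0) -> float:
        if not self.exists or self.omega == 0.0:
            raise DomainError("no imaginary-root crossing exists at these parameters")
        return (self._arccos + 2.0 * math.pi * k) / self.omega

    @property
    def tau2k(self) -> list:
        """First three critical delays."""
        return [self.tau_crit(k) for k in range(3)]

    _arccos: float = 0.0


def hopf_frequency(p: NondimParams, spec: InfusionSpec) -> HopfResult:
    """Crossing frequency and critical delays of the tumor-free chemo state."""
    if p.psi <= 0:
        raise InvalidParameterError("psi must be > 0")
    B = p.delta0 * spec.phi / p.psi
    condition = "delta0*phi/psi > alpha"
    if B < p.alpha:
        return HopfResult(exists=False, condition=condition)
    if B == p.alpha:
        return HopfResult(exists=False, condition=condition, boundary=True)
    omega = math.sqrt(B * B - p.alpha * p.alpha)
    return HopfResult(
        exists=True,
        condition=condition,
        omega=omega,
        _arccos=math.acos(p.alpha / B),
    )


# ---------------------------------------------------------------------------
# Argument-principle root location
# ---------------------------------------------------------------------------

def _winding_number(f, re_lo, re_hi, im_lo, im_hi, n_edge):
    corners = [
        complex(re_lo, im_lo),
        complex(re_hi, im_lo),
        complex(re_hi, im_hi),
        complex(re_lo, im_hi),
        complex(re_lo, im_lo),
    ]
    pts = []
    for z0, z1 in zip(corners[:-1], corners[1:]):
        s = np.linspace(0.0, 1.0, n_edge, endpoint=False)
        pts.append(z0 + (z1 - z0) * s)
    zs = np.concatenate(pts)
    vals = np.array([f(z) for z in zs])
    mags = np.abs(vals)
    if np.min(mags) < 1e-12 * max(1.0, np.max(mags)):
        raise _ContourHitsRoot
    ang = np.angle(vals)
    d = np.diff(np.concatenate([ang, ang[:1]]))
    d = (d + np.pi) % (2.0 * np.pi) - np.pi
    return int(round(float(np.sum(d)) / (2.0 * np.pi)))


class _ContourHitsRoot(Exception):
    pass


def _newton_polish(f, z0, tol=1e-11, max_iter=60):
    z = complex(z0)
    for _ in range(max_iter):
        fz = f(z)
        if abs(fz) < tol:
            return z
        eps = 1e-7 * (1.0 + abs(z))
        df = (f(z + eps) - f(z - eps)) / (2.0 * eps)
        if df == 0:
            return None
        step = fz / df
        if not (cmath.isfinite(step.real) and cmath.isfinite(step.imag)):
            return None
        z = z - step
    return z if abs(f(z)) < tol else None


def rightmost_root_scan(
    f,
    re_window,
    im_window,
    grid: int = 48,
    tol: float = 1e-9,
    min_box: float = 0.02,
    _jitter: int = 0,
) -> list:
    """Roots of an analytic f inside a rectangular window.

    Counts zeros with the argument principle on the boundary, recursively
    subdivides boxes that contain roots, and polishes with complex Newton.
    If the contour passes (numerically) through a root the window is
    jittered slightly and the scan retried.  Roots are returned sorted by
    descending real part, each satisfying \\|f(root)\\| < tol.
    """
    re_lo, re_hi = float(re_window[0]), float(re_window[1])
    im_lo, im_hi = float(im_window[0]), float(im_window[1])
    if not (re_hi > re_lo and im_hi > im_lo):
        raise InvalidParameterError("windows must be nonempty intervals")
    try:
        roots = _scan_box(f, re_lo, re_hi, im_lo, im_hi, grid, tol, min_box)
    except _ContourHitsRoot:
        if _jitter >= 5:
            raise IntegrationFailure("root scan: contour keeps hitting a root")
        pad = 1e-3 * (1.0 + _jitter) * max(re_hi - re_lo, im_hi - im_lo)
        return rightmost_root_scan(
            f, (re_lo - pad, re_hi + pad), (im_lo - pad, im_hi + pad),
            grid=grid, tol=tol, min_box=min_box, _jitter=_jitter + 1,
        )
    uniq: list[complex] = []
    for r in sorted(roots, key=lambda z: -z.real):
        if all(abs(r - u) > 1e-6 * (1.0 + abs(u)) for u in uniq):
            uniq.append(r)
    return uniq


def _scan_box(f, re_lo, re_hi, im_lo, im_hi, grid, tol, min_box):
    width = re_hi - re_lo
    height = im_hi - im_lo
    n_edge = max(grid, int(8 * max(width, height)))
    count = _winding_number(f, re_lo, re_hi, im_lo, im_hi, n_edge)
    if count == 0:
        return []
    if max(width, height) <= min_box or count <= 1:
        center = complex(0.5 * (re_lo + re_hi), 0.5 * (im_lo + im_hi))
        found = []
        starts = [center]
        if max(width, height) > min_box:
            starts += [
                complex(re_lo + 0.25 * width, im_lo + 0.25 * height),
                complex(re_lo + 0.75 * width, im_lo + 0.75 * height),
                complex(re_lo + 0.25 * width, im_lo + 0.75 * height),
                complex(re_lo + 0.75 * width, im_lo + 0.25 * height),
            ]
        for z0 in starts:
            r = _newton_polish(f, z0, tol=tol)
            if (
                r is not None
                and re_lo - 1e-9 <= r.real <= re_hi + 1e-9
                and im_lo - 1e-9 <= r.imag <= im_hi + 1e-9
                and all(abs(r - u) > 1e-6 * (1.0 + abs(u)) for u in found)
            ):
                found.append(r)
            if len(found) >= count:
                break
        return found
    if width >= height:
        mid = 0.5 * (re_lo + re_hi)
        return _scan_box(f, re_lo, mid, im_lo, im_hi, grid, tol, min_box) + _scan_box(
            f, mid, re_hi, im_lo, im_hi, grid, tol, min_box
        )
    mid = 0.5 * (im_lo + im_hi)
    return _scan_box(f, re_lo, re_hi, im_lo, mid, grid, tol, min_box) + _scan_box(
        f, re_lo, re_hi, mid, im_hi, grid, tol, min_box
    )


def rightmost_real_part(
    p: NondimParams,
    spec: InfusionSpec,
    tau2: float,
    re_window=(-0.35, 0.35),
    im_pad: float = 2.0,
) -> float | None:
    """Largest real part among near-axis roots of the reduced chemo-delay factor.

    Scans a strip around the imaginary axis wide enough to contain every
    root with real part in ``re_window`` (the modulus bound
    \\|lambda - alpha\\| = B e^{-Re lambda tau} confines them).  Returns None when
    the strip holds no root (all roots lie left of the strip).
    """
    B = p.delta0 * spec.phi / p.psi
    cf = char_chemo_delay(p, spec, tau2)
    im_max = p.alpha + B * math.exp(-re_window[0] * tau2) + im_pad
    roots = rightmost_root_scan(cf.reduced, re_window, (-im_max, im_max))
    if not roots:
        return None
    return max(r.real for r in roots)


def critical_delay_scan(
    p: NondimParams,
    spec: InfusionSpec,
    tau_max: float = 60.0,
    tol: float = 1e-3,
) -> float | None:
    """Locate the delay at which the tumor-free chemo state loses stability.

    Brackets the first sign change of the rightmost near-axis root's real
    part by doubling tau2, then bisects to ``tol``.  Independent of the
    closed-form critical delay, which it serves to verify.
    """
    def max_re(tau):
        r = rightmost_real_part(p, spec, tau)
        return -1.0 if r is None else r

    lo = 1e-4
    if max_re(lo) >= 0:
        return lo
    hi = 0.05
    while hi <= tau_max:
        if max_re(hi) > 0:
            break
        lo = hi
        hi *= 2.0
    else:
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if max_re(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
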