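"""Model right-hand sides, a fixed-step RK4 integrator, and trajectory metrics.

The nondimensional state is (U, I, V, C): uninfected tumor fraction, infected
tumor fraction, free virus and drug level.  Sub-models drop compartments:
``chemo`` keeps (U, C), ``viro`` keeps (U, I, V), ``none`` keeps U alone
(pure logistic growth, solved exactly by :func:`logistic_solution`).

Integration uses the classical fixed-step fourth-order Runge-Kutta scheme.
A negativity policy keeps trajectories on the biologically admissible cone:
tiny values are zeroed (numerical extinction), moderate negative excursions
are projected back to 0, and large violations abort the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, IntegrationFailure, InvalidParameterError
from .infusion import InfusionSpec, infusion_value, scalar_infusion
from .params import NondimParams

MODEL_COLUMNS = {
    "none": ("U",),
    "chemo": ("U", "C"),
    "viro": ("U", "I", "V"),
    "full": ("U", "I", "V", "C"),
}


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------

def rhs_full(t: float, y, p: NondimParams, spec: InfusionSpec) -> np.ndarray:
    """Four-compartment chemovirotherapy model."""
    U, I, V, C = y
    xi = infusion_value(spec, t)
    bUV = p.beta * U * V
    return np.array(
        [
            p.alpha * U * (1.0 - U - I) - bUV - p.delta0 * U * C,
            bUV - I - p.delta1 * I * C,
            p.b * I - bUV - p.gamma * V,
            xi - p.psi * C,
        ]
    )


def rhs_chemo(t: float, y, p: NondimParams, spec: InfusionSpec) -> np.ndarray:
    """Chemotherapy-only model (virus absent): state (U, C)."""
    U, C = y
    xi = infusion_value(spec, t)
    return np.array(
        [
            p.alpha * U * (1.0 - U) - p.delta0 * U * C,
            xi - p.psi * C,
        ]
    )


def rhs_viro(t: float, y, p: NondimParams) -> np.ndarray:
    """Virotherapy-only model (no drug): state (U, I, V)."""
    U, I, V = y
    bUV = p.beta * U * V
    return np.array(
        [
            p.alpha * U * (1.0 - U - I) - bUV,
            bUV - I,
            p.b * I - bUV - p.gamma * V,
        ]
    )


def rhs_none(t: float, y, p: NondimParams) -> np.ndarray:
    """No-treatment logistic growth: state (U,)."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    U = y[0]
    return np.array([p.alpha * U * (1.0 - U)])


def make_rhs(model: str, p: NondimParams, spec: InfusionSpec | None = None):
    """Bind a model's RHS to (params, schedule); returns f(t, y) -> ndarray.

    The bound closures evaluate the schedule through a scalar fast path so
    that fixed-step runs with 1e5-1e6 steps stay cheap.
    """
    if model == "full":
        xi = scalar_infusion(spec if spec is not None else InfusionSpec("none"))
        alpha, beta, delta0, delta1, b, gamma, psi = (
            p.alpha, p.beta, p.delta0, p.delta1, p.b, p.gamma, p.psi)

        def f_full(t, y):
            U, I, V, C = y
            bUV = beta * U * V
            return np.array([
                alpha * U * (1.0 - U - I) - bUV - delta0 * U * C,
                bUV - I - delta1 * I * C,
                b * I - bUV - gamma * V,
                xi(t) - psi * C,
            ])

        return f_full
    if model == "chemo":
        xi = scalar_infusion(spec if spec is not None else InfusionSpec("none"))
        alpha, delta0, psi = p.alpha, p.delta0, p.psi

        def f_chemo(t, y):
            U, C = y
            return np.array([
                alpha * U * (1.0 - U) - delta0 * U * C,
                xi(t) - psi * C,
            ])

        return f_chemo
    if model == "viro":
        return lambda t, y: rhs_viro(t, y, p)
    if model == "none":
        return lambda t, y: rhs_none(t, y, p)
    raise InvalidParameterError(f"unknown model {model!r}")


def logistic_solution(U0: float, alpha: float, t):
    """Exact solution U(t) = U0 / ((1-U0) e^{-alpha t} + U0) of U' = alpha U (1-U).

    Requires 0 <= U0 <= 1; tends to 1 as t -> infinity whenever U0 > 0.
    """
    if not 0.0 <= U0 <= 1.0:
        raise DomainError(f"U0 must lie in [0, 1], got {U0}")
    t_arr = np.asarray(t, dtype=float)
    out = U0 / ((1.0 - U0) * np.exp(-alpha * t_arr) + U0)
    return out.item() if np.isscalar(t) or t_arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NegativityPolicy:
    """Keeps integrated states on the admissible cone.

    ``clip_tol``: values with \\|x\\| below this are set to 0 (numerical
    extinction; also prevents spurious revival of underflowed compartments).
    ``fail_below``: a component more negative than this aborts the run --
    the trajectory has left the model's domain of validity.
    Negative values in between are projected to 0.
    """

    clip_tol: float = 1e-12
    fail_below: float = 1e-3

    def apply(self, y: np.ndarray, t: float) -> np.ndarray:
        if not np.all(np.isfinite(y)):
            raise IntegrationFailure(f"non-finite state at t={t:.6g}", last_valid_time=t)
        if np.any(y < -self.fail_below):
            raise IntegrationFailure(
                f"state component below -{self.fail_below:g} at t={t:.6g}: {y}",
                last_valid_time=t,
            )
        y = y.copy()
        y[np.abs(y) < self.clip_tol] = 0.0
        y[y < 0.0] = 0.0
        return y


DEFAULT_POLICY = NegativityPolicy()


@dataclass
class Trajectory:
    """A uniform-grid trajectory: times, state matrix and provenance."""

    t: np.ndarray
    y: np.ndarray
    columns: tuple
    model: str = "custom"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape[0] != self.t.shape[0]:
            raise InvalidParameterError("state matrix rows must match the time grid")
        if self.y.ndim != 2 or self.y.shape[1] != len(self.columns):
            raise InvalidParameterError("state matrix columns must match the column labels")

    def column(self, name: str) -> np.ndarray:
        return self.y[:, self.columns.index(name)]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.column(name)

    @property
    def final_state(self) -> np.ndarray:
        return self.y[-1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(self.columns))
        df.insert(0, "t", self.t)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def integrate(
    rhs,
    y0,
    t_span,
    h: float,
    policy: NegativityPolicy | None = DEFAULT_POLICY,
    columns: tuple | None = None,
    model: str = "custom",
    meta: dict | None = None,
) -> Trajectory:
    """Fixed-step classical RK4 integration of y' = rhs(t, y).

    The grid is uniform with step ``h``; the final node is the first grid
    point at or beyond ``t_span[1]``.  ``policy=None`` disables state
    post-processing (useful for non-population test problems).
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if h <= 0:
        raise InvalidParameterError(f"step h must be > 0, got {h}")
    if t1 <= t0:
        raise InvalidParameterError(f"t_span must be increasing, got {t_span}")
    y = np.atleast_1d(np.asarray(y0, dtype=float)).copy()
    n = max(1, int(math.ceil((t1 - t0) / h - 1e-9)))
    d = y.shape[0]
    if columns is None:
        columns = MODEL_COLUMNS.get(model, tuple(f"y{i}" for i in range(d)))
    out = np.empty((n + 1, d))
    ts = t0 + h * np.arange(n + 1)
    if policy is not None:
        y = policy.apply(y, t0)
    out[0] = y
    half = 0.5 * h
    sixth = h / 6.0
    for i in range(n):
        t = ts[i]
        k1 = rhs(t, y)
        k2 = rhs(t + half, y + half * k1)
        k3 = rhs(t + half, y + half * k2)
        k4 = rhs(t + h, y + h * k3)
        y = y + sixth * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if policy is not None:
            y = policy.apply(y, ts[i + 1])
        elif not np.all(np.isfinite(y)):
            raise IntegrationFailure(
                f"non-finite state at t={ts[i + 1]:.6g}", last_valid_time=ts[i]
            )
        out[i + 1] = y
    m = dict(meta or {})
    m.setdefault("h", h)
    return Trajectory(t=ts, y=out, columns=tuple(columns), model=model, meta=m)


# ---------------------------------------------------------------------------
# Trajectory metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Clearance:
    """First time the tumor burden U+I falls -- and stays -- below threshold."""

    time: float
    time_days: float | None
    threshold: float
    index: int


def clearance_time(
    traj: Trajectory,
    threshold: float = 1e-3,
    time_unit_days: float | None = None,
) -> Clearance | None:
    """Tumor clearance time of a trajectory, or None if never cleared.

    The burden is the sum of the tumor compartments present (U and, if
    simulated, I).  The crossing must persist: the first grid time after
    which the burden never rises back above the threshold is reported, which
    makes the metric robust to transient dips and delay-induced oscillation.
    """
    if threshold <= 0:
        raise InvalidParameterError(f"threshold must be > 0, got {threshold}")
    if traj.t.size == 0:
        raise InvalidParameterError("empty trajectory")
    cols = [c for c in ("U", "I") if c in traj.columns]
    if not cols:
        raise InvalidParameterError("trajectory has no tumor compartments (U, I)")
    burden = sum(traj.column(c) for c in cols)
    below = burden < threshold
    # suffix_all[i] is True when the burden stays below threshold from i on
    suffix_all = np.flip(np.logical_and.accumulate(np.flip(below)))
    idx = np.nonzero(suffix_all)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    if time_unit_days is None:
        time_unit_days = traj.meta.get("time_unit_days")
    t = float(traj.t[i])
    days = t * time_unit_days if time_unit_days is not None else None
    return Clearance(time=t, time_days=days, threshold=threshold, index=i)
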