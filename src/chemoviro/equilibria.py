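"""Steady-state catalogues for every model variant and infusion schedule.

Coordinates are derived in closed form from the fixed-point equations (the
published expressions suffer typesetting damage, so the algebra is redone
from the model itself), then verified by the residual of the right-hand side
and polished by a damped Newton step.  Refined coordinates are authoritative;
a refinement that moves a candidate by more than 10% flags a transcription
or derivation error instead of silently accepting it.

For the exponential and sinusoidal schedules the nonautonomous system is
first autonomized by adjoining W(t) = xi(t): W' = -a W (exponential) or
W' = 2a sqrt(W (phi - W)) (sinusoidal, rising branch).  The sinusoidal
autonomization is non-smooth and is used only to catalogue equilibria --
simulation always integrates the nonautonomous schedule directly.  Its
printed fixed points (W* = phi/a) coincide with true equilibria of the
W-equation exactly when a = 1; the catalogue records a consistency flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._numdiff import fd_jacobian
from .dynamics import make_rhs
from .errors import InvalidParameterError, RefinementFailure
from .infusion import InfusionSpec
from .params import NondimParams

CLOSED_FORM = "closed-form"
NUMERIC_REFINED = "numeric-refined"


@dataclass
class SteadyState:
    """An equilibrium: coordinates, existence, label and verification data."""

    coords: np.ndarray
    columns: tuple
    label: str
    exists: bool = True
    condition: str = ""
    provenance: str = CLOSED_FORM
    residual: float | None = None
    notes: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)

    def coord(self, name: str) -> float:
        return float(self.coords[self.columns.index(name)])

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "coordinates": {c: float(v) for c, v in zip(self.columns, self.coords)},
            "exists": bool(self.exists),
            "condition": self.condition,
            "provenance": self.provenance,
            "residual": None if self.residual is None else float(self.residual),
            "notes": self.notes,
        }


# ---------------------------------------------------------------------------
# Autonomized right-hand sides
# ---------------------------------------------------------------------------

def autonomized_rhs(model: str, p: NondimParams, spec: InfusionSpec):
    """RHS and column labels of the (autonomized, if needed) system.

    constant / none schedules need no extra state; exponential and
    sinusoidal schedules gain the infusion variable W.
    """
    if model not in ("chemo", "full"):
        if model == "viro":
            return make_rhs("viro", p), ("U", "I", "V")
        raise InvalidParameterError(f"no autonomization for model {model!r}")

    base_cols = ("U", "C") if model == "chemo" else ("U", "I", "V", "C")
    if spec.kind in ("constant", "none"):
        return make_rhs(model, p, spec), base_cols

    a, phi = spec.a, spec.phi

    def w_rate(W):
        if spec.kind == "exponential":
            return -a * W
        return 2.0 * a * np.sqrt(max(W * (phi - W), 0.0))

    if model == "chemo":
        def f(t, y):
            U, C, W = y
            return np.array(
                [
                    p.alpha * U * (1.0 - U) - p.delta0 * U * C,
                    W - p.psi * C,
                    w_rate(W),
                ]
            )

        return f, ("U", "C", "W")

    def f(t, y):
        U, I, V, C, W = y
        bUV = p.beta * U * V
        return np.array(
            [
                p.alpha * U * (1.0 - U - I) - bUV - p.delta0 * U * C,
                bUV - I - p.delta1 * I * C,
                p.b * I - bUV - p.gamma * V,
                W - p.psi * C,
                w_rate(W),
            ]
        )

    return f, ("U", "I", "V", "C", "W")


def _frozen_w_rhs(model: str, p: NondimParams, w_star: float):
    """Smooth sub-system with the infusion variable frozen at W*.

    Used to refine and classify sinusoidal autonomized states, where the
    sqrt W-equation is non-smooth at its equilibria.
    """
    frozen = InfusionSpec("constant", phi=w_star)
    return make_rhs(model, p, frozen), (("U", "C") if model == "chemo" else ("U", "I", "V", "C"))


def _residual(state: SteadyState, rhs) -> float:
    return float(np.max(np.abs(rhs(0.0, state.coords))))


# ---------------------------------------------------------------------------
# Refinement
# ---------------------------------------------------------------------------

def refine(state: SteadyState, rhs, tol: float = 1e-12, max_iter: int = 50,
           max_move: float = 0.1) -> SteadyState:
    """Damped-Newton polish of a steady-state candidate against rhs = 0.

    Raises :class:`RefinementFailure` if Newton stalls or if the refined
    point moves by more than ``max_move`` (10%) in any coordinate --
    a move that large signals an error in the closed form, not roundoff.
    Coordinates that start at (numerically) zero are held to an absolute
    move budget instead of a relative one.
    """
    y0 = state.coords.copy()
    y = y0.copy()
    f = lambda v: np.asarray(rhs(0.0, v), dtype=float)
    r = f(y)
    best = float(np.max(np.abs(r)))
    for _ in range(max_iter):
        if best < tol:
            break
        J = fd_jacobian(f, y)
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(J, -r, rcond=None)
        lam = 1.0
        improved = False
        for _ in range(25):
            y_new = y + lam * step
            r_new = f(y_new)
            n_new = float(np.max(np.abs(r_new)))
            if np.all(np.isfinite(r_new)) and n_new < best:
                y, r, best = y_new, r_new, n_new
                improved = True
                break
            lam *= 0.5
        if not improved:
            break
    if best > 1e-9:
        raise RefinementFailure(
            f"Newton refinement stalled at residual {best:.3e} for state {state.label!r}"
        )
    move = np.abs(y - y0)
    scale = np.where(np.abs(y0) > 1e-8, np.abs(y0), 0.1)
    if np.any(move > max_move * scale):
        raise RefinementFailure(
            f"refined state moved by {move} from candidate {y0} "
            f"(limit {max_move:.0%}); the closed form looks wrong"
        )
    out = SteadyState(
        coords=y,
        columns=state.columns,
        label=state.label,
        exists=state.exists,
        condition=state.condition,
        provenance=NUMERIC_REFINED,
        residual=best,
        notes=state.notes,
        meta=dict(state.meta),
    )
    return out


def _finalize(states, rhs, refine_existing: bool = True):
    """Attach residuals and refine each existing state in a catalogue."""
    out = []
    for s in states:
        s.residual = _residual(s, rhs)
        if refine_existing and s.exists and s.meta.get("refinable", True):
            out.append(refine(s, rhs))
        else:
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# Closed-form building blocks
# ---------------------------------------------------------------------------

def _viro_dormant(p: NondimParams):
    """Coexistence state of the virotherapy-only model.

    From the fixed-point equations with drug level 0:
    U* = gamma/(beta (b-1)), then (I*, V*) solve the remaining linear pair.
    Exists when b*beta > beta + gamma (equivalently U* <= 1) and b > 1.
    """
    if p.beta <= 0 or p.b <= 1:
        return None
    U = p.gamma / (p.beta * (p.b - 1.0))
    num = p.alpha * (1.0 - U)
    den = p.beta + p.alpha * (p.beta * U + p.gamma) / p.b
    V = num / den
    I = V * (p.beta * U + p.gamma) / p.b
    if U > 1.0 or V < 0.0:
        return None
    return U, I, V


def _full_dormant(p: NondimParams, C_star: float):
    """Coexistence state of the full model at a fixed drug level C*.

    The infected-cell equation gives beta*U*b = (beta*U + gamma) * D with
    D = 1 + delta1*C*, hence U* = gamma*D / (beta*(b - D)); the remaining
    linear pair yields (I*, V*).
    """
    D = 1.0 + p.delta1 * C_star
    if p.beta <= 0 or p.b <= D:
        return None
    U = p.gamma * D / (p.beta * (p.b - D))
    num = p.alpha * (1.0 - U) - p.delta0 * C_star
    den = p.beta + p.alpha * (p.beta * U + p.gamma) / p.b
    V = num / den
    I = V * (p.beta * U + p.gamma) / p.b
    if U > 1.0 or V < 0.0:
        return None
    return U, I, V


# ---------------------------------------------------------------------------
# Catalogues
# ---------------------------------------------------------------------------

def equilibria_chemo(p: NondimParams, spec: InfusionSpec, do_refine: bool = True):
    """Steady states of the chemotherapy-only model for a schedule."""
    states: list[SteadyState] = []
    if spec.kind in ("constant", "none"):
        phi = spec.phi if spec.kind == "constant" else 0.0
        eff = InfusionSpec("constant", phi=phi)
        cols = ("U", "C")
        Cs = phi / p.psi if p.psi > 0 else 0.0
        states.append(
            SteadyState([0.0, Cs], cols, "tumor-free", condition="always exists")
        )
        dormant_exists = p.alpha * p.psi >= p.delta0 * phi and p.alpha > 0
        U = 1.0 - p.delta0 * phi / (p.alpha * p.psi) if p.alpha > 0 else 1.0
        states.append(
            SteadyState(
                [U, Cs],
                cols,
                "tumor-dormant",
                exists=dormant_exists,
                condition="alpha*psi >= delta0*phi",
                notes="drug coordinate phi/psi (algebraic necessity; "
                "the printed C = 0 cannot satisfy C' = 0)",
            )
        )
        rhs = make_rhs("chemo", p, eff)
        return _finalize(states, rhs, do_refine)

    rhs, cols = autonomized_rhs("chemo", p, spec)
    if spec.kind == "exponential":
        states.append(SteadyState([0.0, 0.0, 0.0], cols, "tumor-free", condition="always exists"))
        states.append(
            SteadyState([1.0, 0.0, 0.0], cols, "carrying-capacity", condition="always exists")
        )
        return _finalize(states, rhs, do_refine)

    # sinusoidal autonomization; printed W* = phi/a matches an equilibrium of
    # the sqrt W-equation exactly when a = 1
    a, phi = spec.a, spec.phi
    Cs = phi / (a * p.psi)
    Ws = phi / a
    consistent = abs(a - 1.0) < 1e-12 or phi == 0.0
    note = "" if consistent else "printed W* = phi/a is not a fixed point of the autonomized W-equation for a != 1"
    common = dict(meta={"refinable": False, "autonomization_consistent": consistent})
    states.append(
        SteadyState([0.0, 0.0, 0.0], cols, "tumor-free", condition="always exists",
                    meta={"refinable": False, "autonomization_consistent": True})
    )
    states.append(
        SteadyState([1.0, 0.0, 0.0], cols, "carrying-capacity", condition="always exists",
                    notes="drug coordinate corrected to 0 (printed C = 1 cannot satisfy C' = 0)",
                    meta={"refinable": False, "autonomization_consistent": True})
    )
    dorm_exists = p.alpha > 0 and a * p.alpha * p.psi >= p.delta0 * phi
    U = 1.0 - p.delta0 * phi / (a * p.alpha * p.psi) if p.alpha > 0 else 1.0
    states.append(
        SteadyState([U, Cs, Ws], cols, "tumor-dormant", exists=dorm_exists,
                    condition="a*alpha*psi >= delta0*phi", notes=note, **common)
    )
    states.append(
        SteadyState([0.0, Cs, Ws], cols, "tumor-free", condition="always exists",
                    notes=note, **common)
    )
    states = _finalize(states, rhs, refine_existing=False)
    if do_refine:
        states = [_refine_frozen_w(s, "chemo", p) if s.meta.get("refinable") is False and len(s.coords) == 3
                  else s for s in states]
    return states


def _refine_frozen_w(state: SteadyState, model: str, p: NondimParams) -> SteadyState:
    """Refine a sinusoidal autonomized state in its smooth frozen-W subsystem."""
    w_star = state.coords[-1]
    sub_rhs, _ = _frozen_w_rhs(model, p, w_star)
    sub = SteadyState(
        coords=state.coords[:-1],
        columns=state.columns[:-1],
        label=state.label,
        exists=state.exists,
        condition=state.condition,
        notes=state.notes,
        meta=dict(state.meta),
    )
    if not sub.exists:
        sub.residual = _residual(sub, sub_rhs)
        refined = sub
    else:
        refined = refine(sub, sub_rhs)
    out = SteadyState(
        coords=np.append(refined.coords, w_star),
        columns=state.columns,
        label=state.label,
        exists=state.exists,
        condition=state.condition,
        provenance=refined.provenance,
        residual=refined.residual,
        notes=state.notes,
        meta=dict(state.meta),
    )
    return out


def equilibria_viro(p: NondimParams, do_refine: bool = True):
    """Steady states of the virotherapy-only model."""
    cols = ("U", "I", "V")
    states = [
        SteadyState([0.0, 0.0, 0.0], cols, "tumor-free", condition="always exists"),
        SteadyState([1.0, 0.0, 0.0], cols, "infected-tumor-free", condition="always exists"),
    ]
    dorm = _viro_dormant(p)
    cond = "b*beta > beta + gamma and b > 1"
    if dorm is not None:
        states.append(SteadyState(list(dorm), cols, "tumor-dormant", condition=cond))
    else:
        states.append(
            SteadyState([np.nan, np.nan, np.nan], cols, "tumor-dormant",
                        exists=False, condition=cond, meta={"refinable": False})
        )
    rhs = make_rhs("viro", p)
    return _finalize([s for s in states if s.exists], rhs, do_refine) + [
        s for s in states if not s.exists
    ]


def equilibria_full(p: NondimParams, spec: InfusionSpec, do_refine: bool = True):
    """Steady states of the full chemovirotherapy model for a schedule."""
    states: list[SteadyState] = []
    if spec.kind in ("constant", "none"):
        phi = spec.phi if spec.kind == "constant" else 0.0
        cols = ("U", "I", "V", "C")
        Cs = phi / p.psi if p.psi > 0 else 0.0
        eff = InfusionSpec("constant", phi=phi)
        states.append(
            SteadyState([0.0, 0.0, 0.0, Cs], cols, "tumor-free", condition="always exists")
        )
        itf_exists = p.alpha > 0 and p.alpha * p.psi >= p.delta0 * phi
        U = 1.0 - p.delta0 * phi / (p.alpha * p.psi) if p.alpha > 0 else 1.0
        states.append(
            SteadyState([U, 0.0, 0.0, Cs], cols, "infected-tumor-free",
                        exists=itf_exists, condition="alpha*psi >= delta0*phi")
        )
        dorm = _full_dormant(p, Cs)
        cond = "b > 1 + delta1*phi/psi and alpha*(1-U*) > delta0*phi/psi"
        if dorm is not None:
            states.append(SteadyState([*dorm, Cs], cols, "tumor-dormant", condition=cond))
        else:
            states.append(
                SteadyState([np.nan] * 4, cols, "tumor-dormant", exists=False,
                            condition=cond, meta={"refinable": False})
            )
        rhs = make_rhs("full", p, eff)
        return _finalize([s for s in states if s.exists], rhs, do_refine) + [
            s for s in states if not s.exists
        ]

    rhs, cols = autonomized_rhs("full", p, spec)
    if spec.kind == "exponential":
        states.append(SteadyState([0.0] * 5, cols, "tumor-free", condition="always exists"))
        states.append(
            SteadyState([1.0, 0.0, 0.0, 0.0, 0.0], cols, "carrying-capacity",
                        condition="always exists")
        )
        dorm = _viro_dormant(p)
        cond = "b*beta > beta + gamma and b > 1"
        if dorm is not None:
            states.append(SteadyState([*dorm, 0.0, 0.0], cols, "drug-free", condition=cond))
        else:
            states.append(SteadyState([np.nan] * 5, cols, "drug-free", exists=False,
                                      condition=cond, meta={"refinable": False}))
        return _finalize([s for s in states if s.exists], rhs, do_refine) + [
            s for s in states if not s.exists
        ]

    # sinusoidal
    a, phi = spec.a, spec.phi
    Cs = phi / (a * p.psi)
    Ws = phi / a
    consistent = abs(a - 1.0) < 1e-12 or phi == 0.0
    note = "" if consistent else "printed W* = phi/a is not a fixed point of the autonomized W-equation for a != 1"
    meta = {"refinable": False, "autonomization_consistent": consistent}
    states.append(SteadyState([0.0] * 5, cols, "tumor-free", condition="always exists",
                              meta={"refinable": False, "autonomization_consistent": True}))
    states.append(
        SteadyState([1.0, 0.0, 0.0, 0.0, 0.0], cols, "carrying-capacity",
                    condition="always exists",
                    notes="drug coordinate corrected to 0 (printed C = 1 cannot satisfy C' = 0)",
                    meta={"refinable": False, "autonomization_consistent": True})
    )
    states.append(
        SteadyState([0.0, 0.0, 0.0, Cs, Ws], cols, "tumor-free",
                    condition="always exists", notes=note, meta=dict(meta))
    )
    itf_exists = p.alpha > 0 and a * p.alpha * p.psi >= p.delta0 * phi
    U = 1.0 - p.delta0 * phi / (a * p.alpha * p.psi) if p.alpha > 0 else 1.0
    states.append(
        SteadyState([U, 0.0, 0.0, Cs, Ws], cols, "infected-tumor-free", exists=itf_exists,
                    condition="a*alpha*psi >= delta0*phi", notes=note, meta=dict(meta))
    )
    dormv = _viro_dormant(p)
    if dormv is not None:
        states.append(
            SteadyState([*dormv, 0.0, 0.0], cols, "drug-free",
                        condition="b*beta > beta + gamma and b > 1",
                        meta={"refinable": False, "autonomization_consistent": True})
        )
    else:
        states.append(SteadyState([np.nan] * 5, cols, "drug-free", exists=False,
                                  condition="b*beta > beta + gamma and b > 1",
                                  meta={"refinable": False}))
    dorm = _full_dormant(p, Cs)
    cond = "b > 1 + delta1*phi/(a*psi) and alpha*(1-U*) > delta0*phi/(a*psi)"
    if dorm is not None:
        states.append(SteadyState([*dorm, Cs, Ws], cols, "tumor-dormant",
                                  condition=cond, notes=note, meta=dict(meta)))
    else:
        states.append(SteadyState([np.nan] * 5, cols, "tumor-dormant", exists=False,
                                  condition=cond, meta={"refinable": False}))
    states = _finalize([s for s in states if s.exists], rhs, refine_existing=False) + [
        s for s in states if not s.exists
    ]
    if do_refine:
        refined = []
        for s in states:
            if s.exists and len(s.coords) == 5:
                refined.append(_refine_frozen_w(s, "full", p))
            else:
                refined.append(s)
        states = refined
    return states


def equilibria(model: str, p: NondimParams, spec: InfusionSpec | None = None,
               do_refine: bool = True):
    """Dispatch to the catalogue of a model variant."""
    if model == "chemo":
        return equilibria_chemo(p, spec or InfusionSpec("none"), do_refine)
    if model == "viro":
        return equilibria_viro(p, do_refine)
    if model == "full":
        return equilibria_full(p, spec or InfusionSpec("none"), do_refine)
    if model == "none":
        cols = ("U",)
        rhs = make_rhs("none", p)
        return _finalize(
            [
                SteadyState([0.0], cols, "tumor-free", condition="always exists"),
                SteadyState([1.0], cols, "carrying-capacity", condition="always exists"),
            ],
            rhs,
            do_refine,
        )
    raise InvalidParameterError(f"unknown model {model!r}")
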