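"""Drug-infusion schedules and the chemotherapy-only drug closed forms.

Three clinically motivated schedules drive the nondimensional drug equation
``C' = xi(t) - psi*C``:

* constant:     xi(t) = phi            (protracted intravenous infusion)
* exponential:  xi(t) = phi*exp(-a*t)  (single bolus, decaying source)
* sinusoidal:   xi(t) = phi*sin^2(a*t) (periodic clinic visits)

plus ``none`` (xi = 0).  The linear drug equation is solved in closed form
for every schedule; the long-time behaviour is a constant level phi/psi
(constant), total washout (exponential / none), or a periodic attractor with
mean phi/(2*psi) (sinusoidal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InvalidParameterError

KINDS = ("constant", "exponential", "sinusoidal", "none")


@dataclass(frozen=True)
class InfusionSpec:
    """A drug-infusion schedule: kind plus the dimensionless (phi, a)."""

    kind: str = "none"
    phi: float = 0.0
    a: float = 1.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise InvalidParameterError(f"infusion kind must be one of {KINDS}, got {self.kind!r}")
        if self.phi < 0:
            raise InvalidParameterError(f"infusion rate phi must be >= 0, got {self.phi}")
        if self.kind in ("exponential", "sinusoidal") and self.a <= 0:
            raise InvalidParameterError(f"shape constant a must be > 0 for {self.kind} infusion")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "phi": self.phi, "a": self.a}

    @classmethod
    def from_dict(cls, d: dict) -> "InfusionSpec":
        return cls(kind=d.get("kind", "none"), phi=d.get("phi", 0.0), a=d.get("a", 1.0))


def infusion_value(spec: InfusionSpec, t):
    """Evaluate xi(t) for the schedule; accepts scalars or arrays, t >= 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("infusion schedules are defined for t >= 0")
    if spec.kind == "constant":
        out = np.full_like(t_arr, spec.phi)
    elif spec.kind == "exponential":
        out = spec.phi * np.exp(-spec.a * t_arr)
    elif spec.kind == "sinusoidal":
        out = spec.phi * np.sin(spec.a * t_arr) ** 2
    else:
        out = np.zeros_like(t_arr)
    return out.item() if np.isscalar(t) or t_arr.ndim == 0 else out


def scalar_infusion(spec: InfusionSpec):
    """Fast scalar-time evaluator of xi(t) for integrator inner loops.

    Same values as :func:`infusion_value` without array plumbing or the
    t >= 0 domain check (integrators only evaluate at grid times >= 0).
    """
    phi, a = spec.phi, spec.a
    if spec.kind == "constant":
        return lambda t: phi
    if spec.kind == "exponential":
        return lambda t: phi * math.exp(-a * t)
    if spec.kind == "sinusoidal":
        return lambda t: phi * math.sin(a * t) ** 2
    return lambda t: 0.0


@dataclass(frozen=True)
class DrugClosedForm:
    """Callable closed-form solution of C' = xi(t) - psi*C with C(0) = C0.

    ``hom_coeff`` multiplies the homogeneous mode exp(-psi*t); for the
    exponential schedule it plays the role of the integration constant
    c = C0 - phi/(psi - a), and for the sinusoidal schedule of the constant R
    fixing C(0) = C0 against the particular solution.
    """

    kind: str
    C0: float
    phi: float
    psi: float
    a: float
    hom_coeff: float
    degenerate: bool = False  # exponential schedule with a == psi

    def particular(self, t):
        """Particular (forced) part of the solution."""
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            return np.full_like(t, self.phi / self.psi)
        if self.kind == "exponential":
            if self.degenerate:
                return self.phi * t * np.exp(-self.psi * t)
            return self.phi / (self.psi - self.a) * np.exp(-self.a * t)
        if self.kind == "sinusoidal":
            denom = self.psi**2 + 4.0 * self.a**2
            return self.phi / (2.0 * self.psi) - (
                self.phi / 2.0
            ) * (self.psi * np.cos(2.0 * self.a * t) + 2.0 * self.a * np.sin(2.0 * self.a * t)) / denom
        return np.zeros_like(t)

    def __call__(self, t):
        t_arr = np.asarray(t, dtype=float)
        out = self.hom_coeff * np.exp(-self.psi * t_arr) + self.particular(t_arr)
        return out.item() if np.isscalar(t) or t_arr.ndim == 0 else out


def drug_closed_form(spec: InfusionSpec, C0: float, psi: float) -> DrugClosedForm:
    """Build the closed-form drug solution for a schedule.

    The exponential schedule with a == psi hits the resonant case; its limit
    form (C0 + phi*t)*exp(-psi*t) is used there.
    """
    if psi <= 0:
        raise InvalidParameterError(f"drug decay rate psi must be > 0, got {psi}")
    if spec.kind == "constant":
        hom = C0 - spec.phi / psi
        return DrugClosedForm(spec.kind, C0, spec.phi, psi, spec.a, hom)
    if spec.kind == "exponential":
        if abs(spec.a - psi) < 1e-12 * max(1.0, psi):
            return DrugClosedForm(spec.kind, C0, spec.phi, psi, spec.a, C0, degenerate=True)
        hom = C0 - spec.phi / (psi - spec.a)
        return DrugClosedForm(spec.kind, C0, spec.phi, psi, spec.a, hom)
    if spec.kind == "sinusoidal":
        denom = psi**2 + 4.0 * spec.a**2
        part0 = spec.phi / (2.0 * psi) - spec.phi * psi / (2.0 * denom)
        return DrugClosedForm(spec.kind, C0, spec.phi, psi, spec.a, C0 - part0)
    return DrugClosedForm(spec.kind, C0, 0.0, psi, spec.a, C0)


def drug_solution(spec: InfusionSpec, C0: float, psi: float, t):
    """Closed-form drug level C(t); scalar or array t."""
    return drug_closed_form(spec, C0, psi)(t)


@dataclass(frozen=True)
class DrugLimit:
    """Asymptotic description of the drug level.

    For constant/exponential/none schedules the limit is a single ``value``.
    The sinusoidal schedule settles onto a periodic attractor described by
    its ``mean``, its oscillation ``amplitude`` and its ``period`` (the
    forcing sin^2(a t) has period pi/a).
    """

    kind: str
    value: float | None = None
    mean: float | None = None
    amplitude: float | None = None
    period: float | None = None

    @property
    def is_periodic(self) -> bool:
        return self.kind == "sinusoidal"


def drug_limit(spec: InfusionSpec, psi: float) -> DrugLimit:
    """Long-time behaviour of C(t) under a schedule."""
    if psi <= 0:
        raise InvalidParameterError(f"drug decay rate psi must be > 0, got {psi}")
    if spec.kind == "constant":
        return DrugLimit("constant", value=spec.phi / psi)
    if spec.kind in ("exponential", "none"):
        return DrugLimit(spec.kind, value=0.0)
    amp = spec.phi / (2.0 * math.sqrt(psi**2 + 4.0 * spec.a**2))
    return DrugLimit(
        "sinusoidal",
        mean=spec.phi / (2.0 * psi),
        amplitude=amp,
        period=math.pi / spec.a,
    )


def cumulative_infusion(spec: InfusionSpec, T: float) -> float:
    """Total drug delivered on [0, T]: the exact integral of xi(t)."""
    if T < 0:
        raise DomainError("T must be >= 0")
    if spec.kind == "constant":
        return spec.phi * T
    if spec.kind == "exponential":
        return spec.phi * (1.0 - math.exp(-spec.a * T)) / spec.a
    if spec.kind == "sinusoidal":
        return spec.phi * (T / 2.0 - math.sin(2.0 * spec.a * T) / (4.0 * spec.a))
    return 0.0
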