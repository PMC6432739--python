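"""Dimensional and nondimensional parameter sets for the chemovirotherapy model.

The dimensional model tracks uninfected tumor cells U, virus-infected tumor
cells I, free virions V and a chemotherapeutic drug C in a tumor nodule of
carrying capacity K.  All analysis is done on the rescaled (nondimensional)
system obtained by measuring cell populations in units of K, time in units of
the infected-cell lifetime 1/delta, and the virus/drug levels against
configurable scales.

Two conventions are supported for the virus replication rate ``beta``, whose
published unit is "per day per 10^6 cells or viruses":

``per-1e6-cells``
    State variables are measured in units of 10^6 cells, so the rescaled rate
    is ``beta/delta``.  This is the default.
``per-cell``
    The printed number is read as a per-cell rate, so the rescaled rate is
    ``beta * virus_scale / delta`` (a factor K larger when virus_scale = K).
    This is the reading under which the simulation-scale behaviour of the
    model (clearance within days for beta = 1e-3..1e-6) is reproduced.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

from .errors import InvalidParameterError

BETA_PER_1E6 = "per-1e6-cells"
BETA_PER_CELL = "per-cell"
_BETA_CONVENTIONS = (BETA_PER_1E6, BETA_PER_CELL)


@dataclass(frozen=True)
class DimParams:
    """Dimensional parameters (rates per day, populations in cells).

    Fields
    ------
    K : carrying capacity of the tumor nodule (cells)
    alpha : intrinsic tumor growth rate (/day)
    beta : virus replication rate (/day per 10^6 cells-or-virions)
    delta : infected-cell death rate (/day)
    gamma : virus clearance rate (/day); virus lifespan is 1/gamma
    b : burst size (virions released per lysed cell)
    q : drug infusion rate (concentration/day)
    lam : drug decay rate (/day)
    delta0, delta1 : drug-induced lysis rates of uninfected / infected cells
        (/day per unit drug)
    a : infusion shape constant (/day); exponential decay rate of a bolus, or
        angular rate of the periodic schedule
    U0, I0, V0, C0 : initial concentrations (cells / virions / drug units)
    """

    K: float = 1.0e6
    alpha: float = 0.0
    beta: float = 0.0
    delta: float = 1.0
    gamma: float = 0.0
    b: float = 0.0
    q: float = 0.0
    lam: float = 0.0
    delta0: float = 0.0
    delta1: float = 0.0
    a: float = 1.0
    U0: float = 1.0e6
    I0: float = 0.0
    V0: float = 1.0e5
    C0: float = 0.1

    def __post_init__(self):
        if self.K <= 0:
            raise InvalidParameterError(f"carrying capacity K must be > 0, got {self.K}")
        if self.delta <= 0:
            raise InvalidParameterError(f"infected-cell death rate delta must be > 0, got {self.delta}")
        for name in ("alpha", "beta", "gamma", "b", "q", "lam", "delta0", "delta1", "a"):
            v = getattr(self, name)
            if v < 0:
                raise InvalidParameterError(f"rate {name} must be >= 0, got {v}")
        if 0 < self.b <= 1 and self.beta > 0:
            warnings.warn(
                "burst size b <= 1: the virotherapy dormant state requires b > 1",
                stacklevel=2,
            )

    def replace(self, **kw) -> "DimParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DimParams":
        return cls(**d)


@dataclass(frozen=True)
class NondimParams:
    """Nondimensional parameter vector of the rescaled model.

    ``alpha, beta, delta0, delta1, b, gamma, phi, psi, a`` are all
    dimensionless; ``time_unit_days`` (= 1/delta) converts one nondimensional
    time unit back to days.
    """

    alpha: float
    beta: float
    delta0: float
    delta1: float
    b: float
    gamma: float
    phi: float
    psi: float
    a: float
    time_unit_days: float = 1.0

    def __post_init__(self):
        for name in ("alpha", "beta", "delta0", "delta1", "b", "gamma", "phi", "psi", "a"):
            v = getattr(self, name)
            if v < 0:
                raise InvalidParameterError(f"nondimensional {name} must be >= 0, got {v}")

    def replace(self, **kw) -> "NondimParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NondimParams":
        return cls(**d)


def table1() -> DimParams:
    """Published dimensional parameter set (mouse-fitted virotherapy data).

    The shape constant ``a`` has no published value; it is set to ``delta``
    so that its nondimensional counterpart is 1 (a documented convention).
    Initial concentrations correspond to the nondimensional simulation state
    (U, I, V, C) = (1, 0, 0.1, 0.1).
    """
    return DimParams(
        K=1.0e6,
        alpha=0.206,
        beta=0.001,
        delta=0.5115,
        gamma=0.001,
        b=10.0,
        q=5.0,
        lam=4.16,
        delta0=0.005,
        delta1=0.006,
        a=0.5115,
        U0=1.0e6,
        I0=0.0,
        V0=1.0e5,
        C0=0.1,
    )


# Backwards-compatible alias used by the CLI ("--params table1").
table1_fixture = table1


def nondimensionalize(
    dim: DimParams,
    virus_scale: float | None = None,
    drug_scale: float = 1.0,
    beta_convention: str = BETA_PER_1E6,
) -> NondimParams:
    """Rescale a dimensional parameter set.

    Time is measured in units of 1/delta, cell populations in units of K,
    the virus in units of ``virus_scale`` (defaults to K) and the drug in
    units of ``drug_scale``.  Returns the dimensionless rates

        alpha/delta, beta_hat/delta, delta0*drug_scale/delta,
        delta1*drug_scale/delta, b*K/virus_scale, gamma/delta,
        q/(delta*drug_scale), lam/delta, a/delta

    where ``beta_hat`` depends on ``beta_convention`` (see module docstring).
    """
    if dim.delta <= 0:
        raise InvalidParameterError("delta must be > 0 to nondimensionalize")
    if virus_scale is None:
        virus_scale = dim.K
    if virus_scale <= 0 or drug_scale <= 0:
        raise InvalidParameterError("virus_scale and drug_scale must be > 0")
    if beta_convention not in _BETA_CONVENTIONS:
        raise InvalidParameterError(
            f"beta_convention must be one of {_BETA_CONVENTIONS}, got {beta_convention!r}"
        )
    d = dim.delta
    if beta_convention == BETA_PER_1E6:
        beta_bar = dim.beta * virus_scale / (1.0e6 * d)
    else:
        beta_bar = dim.beta * virus_scale / d
    return NondimParams(
        alpha=dim.alpha / d,
        beta=beta_bar,
        delta0=dim.delta0 * drug_scale / d,
        delta1=dim.delta1 * drug_scale / d,
        b=dim.b * dim.K / virus_scale,
        gamma=dim.gamma / d,
        phi=dim.q / (d * drug_scale),
        psi=dim.lam / d,
        a=dim.a / d,
        time_unit_days=1.0 / d,
    )


def redimensionalize(
    nd: NondimParams,
    K: float,
    virus_scale: float | None = None,
    drug_scale: float = 1.0,
    beta_convention: str = BETA_PER_1E6,
) -> DimParams:
    """Inverse of :func:`nondimensionalize` (up to the initial conditions)."""
    if nd.time_unit_days <= 0:
        raise InvalidParameterError("time_unit_days must be > 0")
    if virus_scale is None:
        virus_scale = K
    d = 1.0 / nd.time_unit_days
    if beta_convention == BETA_PER_1E6:
        beta = nd.beta * 1.0e6 * d / virus_scale
    elif beta_convention == BETA_PER_CELL:
        beta = nd.beta * d / virus_scale
    else:
        raise InvalidParameterError(
            f"beta_convention must be one of {_BETA_CONVENTIONS}, got {beta_convention!r}"
        )
    return DimParams(
        K=K,
        alpha=nd.alpha * d,
        beta=beta,
        delta=d,
        gamma=nd.gamma * d,
        b=nd.b * virus_scale / K,
        q=nd.phi * d * drug_scale,
        lam=nd.psi * d,
        delta0=nd.delta0 * d / drug_scale,
        delta1=nd.delta1 * d / drug_scale,
        a=nd.a * d,
    )


def table1_nondim(
    drug_scale: float = 1.0, beta_convention: str = BETA_PER_1E6
) -> NondimParams:
    """Nondimensional version of the published parameter set."""
    return nondimensionalize(table1(), drug_scale=drug_scale, beta_convention=beta_convention)
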