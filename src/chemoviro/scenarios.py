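"""Config-driven experiment runner reproducing the published figure settings.

Every scenario is a complete, deterministic run configuration: model
variant, infusion schedule, delays, initial state, parameter overrides and
integration settings.  The catalogue covers the chemotherapy-only panels
(fig1a-c), the virotherapy burst-size / replication-rate panels (fig2a-d),
the combination-treatment panels (fig3*, shipped in both the caption's
b = 2, 5 and the text's b = 15, 25 parameterizations), and the delay panels
(fig4a-d).

Figure-scale runs use the per-cell reading of the virus replication rate
(beta_bar = beta*K/delta): under the per-1e6 reading the published beta
values give a subcritical infection that never clears the tumor, which
contradicts the figures.  Both conventions remain available on every entry
point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .delay import DelaySpec, simulate_dde
from .dynamics import Trajectory, clearance_time, integrate, make_rhs
from .equilibria import equilibria
from .errors import IntegrationFailure, InvalidParameterError
from .infusion import InfusionSpec, cumulative_infusion
from .params import BETA_PER_CELL, NondimParams, nondimensionalize, table1
from .stability import classify

#: nondimensional initial state used throughout the numerical experiments
DEFAULT_IC = {"U": 1.0, "I": 0.0, "V": 0.1, "C": 0.1}


@dataclass(frozen=True)
class Scenario:
    """One runnable experiment configuration."""

    id: str
    model: str  # none | chemo | viro | full
    infusion: InfusionSpec = InfusionSpec("none")
    delays: DelaySpec | None = None
    ic: dict = field(default_factory=lambda: dict(DEFAULT_IC))
    dim_overrides: dict = field(default_factory=dict)
    beta_convention: str = BETA_PER_CELL
    drug_scale: float = 1.0
    t_max: float = 12.0
    h: float = 1e-3
    clearance_threshold: float = 1e-3
    description: str = ""

    def params(self) -> NondimParams:
        dim = table1()
        if self.dim_overrides:
            dim = dim.replace(**self.dim_overrides)
        return nondimensionalize(
            dim, drug_scale=self.drug_scale, beta_convention=self.beta_convention
        )

    def initial_state(self) -> np.ndarray:
        cols = {"none": ("U",), "chemo": ("U", "C"), "viro": ("U", "I", "V"),
                "full": ("U", "I", "V", "C")}[self.model]
        return np.array([self.ic.get(c, DEFAULT_IC[c]) for c in cols])

    def to_config(self) -> dict:
        return {
            "id": self.id,
            "model": self.model,
            "infusion": self.infusion.to_dict(),
            "delays": self.delays.to_dict() if self.delays else None,
            "ic": dict(self.ic),
            "dim_overrides": dict(self.dim_overrides),
            "beta_convention": self.beta_convention,
            "drug_scale": self.drug_scale,
            "t_max": self.t_max,
            "h": self.h,
            "clearance_threshold": self.clearance_threshold,
            "description": self.description,
        }


def _build_registry() -> dict:
    reg: dict[str, Scenario] = {}

    def add(s: Scenario):
        if s.id in reg:
            raise InvalidParameterError(f"duplicate scenario id {s.id!r}")
        reg[s.id] = s

    p_table = table1()
    phi = p_table.q / p_table.delta  # nondimensional constant-rate dose

    # Fig 1: chemotherapy only, three schedules, ICs (U, C) = (0.8, 0.2)
    for panel, kind in (("a", "constant"), ("b", "exponential"), ("c", "sinusoidal")):
        add(
            Scenario(
                id=f"fig1{panel}",
                model="chemo",
                infusion=InfusionSpec(kind, phi=phi, a=1.0),
                ic={"U": 0.8, "C": 0.2},
                t_max=30.0,
                h=1e-3,
                description=f"chemotherapy only, {kind} infusion; tumor is not cleared",
            )
        )

    # Fig 2: virotherapy only; replication-rate and burst-size panels
    fig2 = {
        "a": {"beta": 1e-6, "b": 10.0},
        "b": {"beta": 1e-3, "b": 10.0},
        "c": {"beta": 1e-6, "b": 10.0},
        "d": {"beta": 1e-6, "b": 100.0},
    }
    for panel, ov in fig2.items():
        stiff = ov["beta"] >= 1e-3
        add(
            Scenario(
                id=f"fig2{panel}",
                model="viro",
                dim_overrides=ov,
                t_max=14.0,
                h=5e-5 if stiff else 1e-3,
                description=f"virotherapy only, beta={ov['beta']:g}, b={ov['b']:g}",
            )
        )

    # Fig 3: combination treatment; caption (b=2,5) and text (b=15,25) readings
    for panel, kind in (("a", "constant"), ("b", "exponential"), ("c", "sinusoidal")):
        for tag, bursts in (("caption", (2.0, 5.0)), ("text", (15.0, 25.0))):
            for b in bursts:
                add(
                    Scenario(
                        id=f"fig3{panel}-{tag}-b{int(b)}",
                        model="full",
                        infusion=InfusionSpec(kind, phi=phi, a=1.0),
                        dim_overrides={"b": b},
                        t_max=14.0,
                        h=5e-5,
                        description=f"combination treatment, {kind} infusion, b={b:g}",
                    )
                )

    # Fig 4: delayed combination treatment, constant infusion
    fig4 = {
        "a": (0.001, 0.1),
        "b": (0.01, 0.1),
        "c": (0.001, 0.001),
        "d": (0.001, 0.3),
    }
    for panel, (tau1, tau2) in fig4.items():
        add(
            Scenario(
                id=f"fig4{panel}",
                model="full",
                infusion=InfusionSpec("constant", phi=phi),
                delays=DelaySpec(tau1=tau1, tau2=tau2),
                t_max=12.0,
                h=5e-5,
                description=f"delayed combination treatment, tau1={tau1}, tau2={tau2}",
            )
        )

    return reg


SCENARIOS = _build_registry()


def list_scenarios() -> list:
    return sorted(SCENARIOS)


def get_scenario(scenario_id: str) -> Scenario:
    try:
        return SCENARIOS[scenario_id]
    except KeyError:
        raise InvalidParameterError(
            f"unknown scenario {scenario_id!r}; known ids: {', '.join(sorted(SCENARIOS))}"
        ) from None


@dataclass
class ScenarioResult:
    """Bundle produced by one scenario run."""

    scenario: Scenario
    trajectory: Trajectory
    metrics: dict
    equilibria: list
    stability: list

    def save(self, out_dir) -> Path:
        d = Path(out_dir) / self.scenario.id
        d.mkdir(parents=True, exist_ok=True)
        self.trajectory.to_csv(d / "traj.csv")
        (d / "metrics.json").write_text(json.dumps(self.metrics, indent=2))
        (d / "stability.json").write_text(
            json.dumps([r.as_dict() for r in self.stability], indent=2)
        )
        (d / "config.json").write_text(json.dumps(self.scenario.to_config(), indent=2))
        return d


def run_scenario(s: Scenario, with_reports: bool = True) -> ScenarioResult:
    """Integrate a scenario and collect its metrics and analysis reports."""
    p = s.params()
    y0 = s.initial_state()
    meta = {"time_unit_days": p.time_unit_days, "scenario": s.id}
    try:
        if s.delays is not None and s.delays.max_delay > 0:
            traj = simulate_dde(s.model, p, s.infusion, s.delays, y0,
                                (0.0, s.t_max), s.h, meta=meta)
        else:
            rhs = make_rhs(s.model, p, s.infusion)
            traj = integrate(rhs, y0, (0.0, s.t_max), s.h, model=s.model, meta=meta)
    except IntegrationFailure as err:
        raise IntegrationFailure(
            f"scenario {s.id!r}: {err}", last_valid_time=err.last_valid_time
        ) from err

    cl = None
    if s.model != "none":
        cl = clearance_time(traj, threshold=s.clearance_threshold)
    burden_cols = [c for c in ("U", "I") if c in traj.columns]
    terminal_burden = float(sum(traj.column(c)[-1] for c in burden_cols))
    metrics = {
        "clearance_time": None if cl is None else cl.time,
        "clearance_time_days": None if cl is None else cl.time_days,
        "clearance_threshold": s.clearance_threshold,
        "terminal_burden": terminal_burden,
        "terminal_state": {c: float(v) for c, v in zip(traj.columns, traj.final_state)},
        "cumulative_drug": cumulative_infusion(s.infusion, s.t_max),
        "t_max": s.t_max,
        "h": traj.meta.get("h", s.h),
        "time_unit_days": p.time_unit_days,
    }

    eq_states: list = []
    reports: list = []
    if with_reports and s.model != "none":
        eq_states = equilibria(s.model, p, s.infusion)
        for st in eq_states:
            if st.exists:
                reports.append(classify(st, s.model, p, s.infusion))
    return ScenarioResult(scenario=s, trajectory=traj, metrics=metrics,
                          equilibria=eq_states, stability=reports)


def compare_infusions(base: Scenario, with_reports: bool = False) -> dict:
    """Run the three schedules at equal phi and rank them.

    Ranking is by terminal tumor burden (best = smallest); clearance times
    and the cumulative delivered drug are reported alongside.
    """
    if base.model != "full":
        raise InvalidParameterError("infusion comparison is defined for the full model")
    phi, a = base.infusion.phi, base.infusion.a
    out = {}
    for kind in ("constant", "exponential", "sinusoidal"):
        s = replace(base, id=f"{base.id}-{kind}", infusion=InfusionSpec(kind, phi=phi, a=a))
        res = run_scenario(s, with_reports=with_reports)
        out[kind] = {
            "clearance_time": res.metrics["clearance_time"],
            "clearance_time_days": res.metrics["clearance_time_days"],
            "terminal_burden": res.metrics["terminal_burden"],
            "cumulative_drug": res.metrics["cumulative_drug"],
        }
    ranking = sorted(out, key=lambda k: out[k]["terminal_burden"])
    return {"schedules": out, "ranking_by_terminal_burden": ranking,
            "worst": ranking[-1], "best": ranking[0]}


def plot_trajectory(traj: Trajectory, path) -> None:
    """Optional plot artifact (PNG/SVG by extension); never used by metrics."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for c in traj.columns:
        ax.plot(traj.t, traj.column(c), label=c)
    ax.set_xlabel("nondimensional time")
    ax.set_ylabel("fractional concentration")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
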