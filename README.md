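# chemoviro

Simulation and stability analysis of **chemovirotherapy** — cancer
treatment that combines a chemotherapeutic drug with an oncolytic
(tumor-lysing) virus — for researchers in mathematical oncology who want a
tested, scriptable implementation of the standard four-compartment
tumor–virus–drug model and its delay extension.

## The model

The nondimensional state is the uninfected tumor fraction *U*, the
virus-infected fraction *I*, the free virus level *V* and the drug level
*C* (populations measured against the carrying capacity *K*, time in units
of the infected-cell lifetime 1/δ):

```
U' = α U (1 − U − I) − β U V − δ₀ U C
I' = β U V − I − δ₁ I C
V' = b I − β U V − γ V
C' = ξ(t) − ψ C
```

with burst size *b*, virus replication rate *β*, virus clearance *γ*,
drug-induced lysis rates *δ₀*, *δ₁*, drug decay *ψ*, and a drug-infusion
schedule ξ(t) that is **constant** (ϕ), a **single bolus** (ϕ·e^(−at)) or
**periodic** (ϕ·sin²(at)).  Sub-models drop compartments: chemotherapy
only (*U*, *C*), virotherapy only (*U*, *I*, *V*), no treatment (logistic
growth of *U*, solved exactly).  A delay extension lags the infection
terms by τ₁ (virus response) and the drug-kill terms by τ₂ (drug
response).

The package provides, per module:

* **params** — the published dimensional parameter set and the rescaling
  to dimensionless rates (both readings of the ambiguous β unit are
  supported, see `docs/methods.md`);
* **infusion** — the three schedules, closed-form drug solutions of
  C' = ξ(t) − ψC and their long-time limits;
* **dynamics** — model right-hand sides, a fixed-step RK4 integrator with
  a positivity policy, and the tumor clearance-time metric;
* **equilibria** — closed-form steady-state catalogues for every
  model/schedule combination, residual-verified and Newton-refined;
* **stability** — analytic Jacobians, characteristic polynomials,
  Routh–Hurwitz verdicts, numeric eigenvalue classification, perturbation
  cross-checks, and the Dulac test excluding periodic chemotherapy orbits;
* **delay** — method-of-steps RK4 with cubic-Hermite history lookup, the
  transcendental characteristic equations, Hopf crossing frequency ω and
  critical delays τ₂ₖ, and an argument-principle root scan;
* **scenarios** — deterministic, config-driven reproductions of the
  published figure settings (`fig1a` … `fig4d`) plus an infusion-schedule
  comparison.

## Worked example

Simulate the combination treatment with a low virus replication rate
(β = 10⁻⁶ per cell per day, burst size 10) under constant infusion:

```sh
$ chemoviro simulate --model full --beta-convention per-cell \
      --set beta=1e-6 --t-max 14 --step 0.001 --out traj.csv
wrote traj.csv; tumor cleared at t=7.964 units (15.57 days)
```

The tumor burden *U + I* falls below 10⁻³ of carrying capacity after about
8 nondimensional units (one unit ≈ 1.955 days ≈ 2 days).  Virotherapy
alone at the same virus parameters needs 8.066 units — the drug shortens
the treatment.  Chemotherapy alone never clears this tumor: its dormant
state retains U ≈ 0.97 because the drug condition δ₀ϕ > αψ fails for the
published rates.

Stability of the chemotherapy-only model with a strong drug
(δ₀ = 0.5) — the tumor-free state becomes attracting:

```sh
$ chemoviro stability --model chemo --infusion constant --set delta0=0.5
[
  {
    "state": {"label": "tumor-free", "coordinates": {"U": 0.0, "C": 1.2019...}, ...},
    "eigenvalues": [{"re": -0.7721..., "im": 0.0}, {"re": -8.1329..., "im": 0.0}],
    "classification": "stable",
    ...
```

and its delay-induced loss of stability — the drug-response delay at which
a pair of characteristic roots crosses the imaginary axis:

```sh
$ chemoviro delay-stability --infusion constant --set delta0=0.5
{
  "condition": "delta0*phi/psi > alpha",
  "exists": true,
  "omega": 1.1037181461003318,
  "tau2k": [1.1061859234983407, 6.798930334179094, 12.491674744859846]
}
```

Here ω is the crossing frequency and τ₂ₖ the critical delays: the
tumor-free state is stable for τ₂ below τ₂₀ ≈ 1.106 and unstable beyond.

Catalogued figure scenarios run with one command:

```sh
chemoviro list-scenarios
chemoviro run --scenario fig2d --out-dir results/
```

## Layout

```
src/chemoviro/     library (params, infusion, dynamics, equilibria,
                   stability, delay, scenarios, cli)
tests/             pytest suite (unit, property and end-to-end checks)
scripts/           acceptance script
docs/methods.md    modelling and numerical-methods note
```
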