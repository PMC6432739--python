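# Methods

## Model

The package implements a compartmental model of chemovirotherapy in an
avascular tumor nodule.  Uninfected tumor cells U grow logistically
(intrinsic rate α per day, carrying capacity K cells) and are lost to virus
infection (mass action βUV) and to drug-induced lysis (δ₀UC).  Infected
cells I die at rate δ per day and are additionally lysed by the drug
(δ₁IC); each dying infected cell releases b virions, so virus production is
bδI.  Free virus V is consumed by infection and cleared at rate γ; the drug
C enters through an infusion schedule g(t) and decays at rate λ.

All analysis is done on the rescaled system: populations measured in units
of K, the virus against a configurable scale (default K), the drug against a
configurable scale (default 1), and time in units of the infected-cell
lifetime 1/δ.  With the shipped parameter set 1/δ = 1.955 days, i.e. one
nondimensional unit is about two days.  The model assumes a well-mixed
nodule (no space), perfect virus specificity for tumor cells, no immune
response, and drug action that is linear in the drug level.

Two typesetting defects of the source equations are corrected to the
evidently intended forms: the logistic bracket is 1 − U − I (total tumor
burden competes for the carrying capacity), and the nondimensional infected
death term is −I.

## Parameters

The shipped dimensional set (fitted mouse virotherapy data plus
pharmacokinetic rates) is

| symbol | value | meaning |
|---|---|---|
| K | 10⁶ cells | carrying capacity |
| α | 0.206 /day | tumor growth rate |
| β | 0.001 /day per 10⁶ cells-or-virions | virus replication rate |
| δ | 0.5115 /day | infected-cell death rate |
| γ | 0.001 /day | virus clearance rate |
| b | 10 | burst size |
| q | 5 /day | drug infusion rate |
| λ | 4.16 /day | drug decay rate |
| δ₀ | 0.005, δ₁ = 0.006 /day per unit drug | drug-induced lysis |

Three quantities the source leaves open are fixed as package conventions:

* **Drug scale.**  The dimensional initial drug concentration entering the
  rescaling ϕ = q/(δ·C₀) is never stated; the default drug scale is 1, so
  ϕ = q/δ = 9.775.  It is exposed as `drug_scale` on every entry point.
* **β unit.**  "Per day per 10⁶ cells" admits two readings.  Under
  `per-1e6-cells` (default) state variables are taken to be measured in
  units of 10⁶ cells, giving β̄ = β/δ ≈ 0.00196.  Under `per-cell` the
  printed number is a per-cell rate, giving β̄ = βK/δ ≈ 1955.  The default
  keeps desk-scale eigenvalue analysis in a moderate range; the figure
  scenarios pin `per-cell`, because it is the only reading under which the
  published simulation behaviour (tumor cleared within days for
  β = 10⁻⁶…10⁻³) occurs — under the per-1e6 reading the infection is
  subcritical (bβ̄ < β̄ + γ̄ at β = 10⁻⁶) or too slow and the tumor never
  clears.  Both readings run everywhere via `beta_convention`.
* **Shape constant a.**  No dimensional value is published for the
  bolus-decay / periodicity constant; the fixture sets a = δ so that the
  nondimensional a = 1.

Nondimensionalization is exactly invertible (`redimensionalize`), and
homogeneity in δ (doubling δ halves every rate-type output) is
property-tested.

## Drug schedules and closed forms

The drug equation C' = ξ(t) − ψC is linear and solved in closed form for
all three schedules.  For the bolus the resonant case a = ψ uses the limit
form (C₀ + ϕt)e^(−ψt).  The periodic schedule is solved through
sin²(at) = (1 − cos 2at)/2, giving the particular solution
ϕ/(2ψ) − (ϕ/2)(ψ·cos 2at + 2a·sin 2at)/(ψ² + 4a²); the printed source
expression for this case is typographically damaged and is not
transcribed — the derived form is verified against high-accuracy
quadrature (sup-norm < 10⁻⁸ on [0, 20] over random parameter draws).

Long-time behaviour: constant → ϕ/ψ; bolus → 0; periodic → a **periodic
attractor**, not a constant: mean ϕ/(2ψ), oscillation amplitude
ϕ/(2√(ψ² + 4a²)), period π/a, approached at rate e^(−ψt).  A constant
limit is sometimes quoted for this case; the package reports the attractor
because that is the mathematically correct ω-limit (and the testable one).

## Steady states

Steady-state coordinates are **re-derived from the fixed-point equations**
rather than transcribed: the printed coexistence-state expressions carry
typesetting damage that cannot be parsed unambiguously.  The derivation is
elementary — e.g. for the full model at drug level C*, the infected-cell
balance gives U* = γD/(β(b − D)) with D = 1 + δ₁C*, and (I*, V*) then solve
a linear pair.  Guard rails keep the catalogue honest: every catalogued
state is residual-checked against the right-hand side and polished by a
damped Newton iteration that **fails loudly if the refined point moves by
more than 10%** in any coordinate (such a move signals an error in the
closed form, not roundoff).  Non-existing states (existence condition
violated, e.g. negative coordinates) are reported as such, never raised.

Two printed coordinates are corrected by algebraic necessity, with the
correction noted on the state: a drug coordinate of 0 (or 1) cannot satisfy
C' = ϕ − ψC = 0 for ϕ > 0, so the dormant chemotherapy state carries
C* = ϕ/ψ (its U-coordinate 1 − δ₀ϕ/(αψ) is unchanged).

**Autonomization.**  For the non-constant schedules the catalogue adjoins
W(t) = ξ(t): W' = −aW for the bolus (smooth), and W' = 2a√(W(ϕ−W)) for the
periodic schedule.  The latter is non-smooth and non-unique at its fixed
points W ∈ {0, ϕ}; it is used **only to catalogue equilibria** — the
simulator always integrates the nonautonomous ξ(t) directly.  The
catalogued periodic-schedule states carry W* = ϕ/a as printed, which is an
exact fixed point of the W-equation precisely when a = 1 (the default); for
a ≠ 1 the states carry a consistency flag instead of a fake residual.
Refinement and classification of these states use the smooth frozen-W
subsystem (W held at W*, i.e. a constant schedule at rate W*).

## Local stability

Classification is **numeric-first**: eigenvalues of the analytic Jacobian
(cross-checked against central differences), with the printed closed-form
polynomials and conditions evaluated alongside as cross-checks — several
printed formulas contain typos, so the numeric spectrum is authoritative.
A marginal band |Re λ| ≤ 10⁻⁹ is never asserted stable or unstable.  For
cubics the Routh–Hurwitz verdict (a₀, a₁, a₂ > 0 and a₁a₂ > a₀) is
reported and property-tested against a root-finder on random cubics.

Every verdict can be cross-checked by `verify_by_simulation`: the
equilibrium is perturbed by 10⁻⁴ along random directions (kept on the
nonnegative cone), integrated for a horizon set by the rightmost
eigenvalue (8/|Re λ|, capped), and required to return (stable) or depart
(unstable).  Equilibria too weakly hyperbolic to resolve within the capped
horizon are skipped with a `None`, not guessed.

The planar chemotherapy system with constant infusion has no periodic
orbits: with the Dulac weight g = 1/(UC) the weighted divergence is
−α/C − ϕ/(UC²) < 0 on the open positive quadrant.  Both the analytic form
and a finite-difference divergence are exposed and tested against each
other.

## Delay model

Virus infection responds after a lag τ₁ and the drug after τ₂: the
infection terms use U(t−τ₁)V(t−τ₁) and the kill terms use the state at
t−τ₂.  Histories are constant (equal to the initial state), matching the
simulation setup of the source; general histories are a configuration
extension point.

**Integration** is method-of-steps RK4: delayed lookups interpolate the
stored solution with cubic Hermite polynomials (O(h⁴), preserving the
global fourth order, verified on the scalar test problem x' = −x(t−τ)
against its exact piecewise-polynomial solution).  The step is capped at
half the smallest positive delay so that all stage lookups lie in stored
history; zero delays pass the current stage state through, so τ = 0
reproduces the ODE path exactly.

**Positivity.**  Because the delayed lysis/consumption terms are *not*
proportional to the current compartment, a nearly-extinct compartment is
genuinely pushed below zero by O(h × lagged rate) within each step before
the lag catches up (the continuous DDE itself leaves the positive cone).
The integrator therefore projects the state back onto the cone after every
step — the discretization of the clamped dynamics — and aborts only if an
excursion exceeds 5% of carrying capacity.  The ODE policy is stricter
(projection with failure beyond 10⁻³); both also zero values below 10⁻¹²
(numerical extinction, which prevents spurious revival of underflowed
compartments in stiff runs).

**Stability.**  Linearizing the delayed chemotherapy model about its
tumor-free state gives f(λ) = (λ+ψ)(λ − α + e^(−λτ₂)·δ₀ϕ/ψ).  Purely
imaginary roots ±iω of the reduced factor exist iff δ₀ϕ/ψ > α, with
ω = √((δ₀ϕ/ψ)² − α²) and critical delays
τ₂ₖ = (arccos(αψ/(δ₀ϕ)) + 2kπ)/ω — the standard crossing form, validated
by direct substitution (the printed variant "1/ω + arccos(…)" fails that
test, as does the printed existence inequality, which contradicts the
algebra that produces ω).  The delayed virotherapy model's infection-free
state yields f(λ) = (λ+α)[(λ+1)(λ+γ+βe^(−λτ₁)) − bβe^(−λτ₁)]; both reduce
to the ODE characteristic polynomials at zero delay (tested to 10⁻¹²).

Roots are located independently of the closed forms by
`rightmost_root_scan`: argument-principle winding counts on rectangle
boundaries, recursive subdivision, complex-Newton polish, and window
jitter when the contour grazes a root.  `critical_delay_scan` brackets the
first stability loss by doubling τ₂ and bisects the rightmost near-axis
real part to 10⁻³, agreeing with the closed-form τ₂₀ on random
drug-dominated parameter draws.  The scan strip (Re ∈ [−0.35, 0.35] with
an imaginary half-width α + (δ₀ϕ/ψ)e^(0.35τ) + 2) contains every root with
real part in the strip by the modulus bound |λ − α| = (δ₀ϕ/ψ)e^(−τ·Re λ);
an empty strip is reported as "all roots further left".

## Clearance metric

Clearance time is the first grid time at which the tumor burden U + I
falls below a threshold **and stays below it** for the rest of the run;
the persistence requirement makes the metric robust to transient dips and
to delay-induced oscillation.  The default threshold is 10⁻³ of carrying
capacity (10³ cells — "reduced to zero" is never formally defined in this
literature, so the knob is documented and exposed).  Times are reported in
nondimensional units and in days (exact factor 1/δ = 1.955; the "≈ 2
days" approximation appears only in prose).

## Scenario problem sizes

Figure scenarios are deterministic (no randomness anywhere; reruns are
byte-identical).  Step sizes are chosen per scenario from the fastest rate
present: h = 10⁻³ suffices for the chemotherapy panels and the
low-replication virotherapy panels (fastest rates ≲ 10²), while runs with
the per-cell reading of β = 10⁻³ (β̄ ≈ 1955) use h = 5×10⁻⁵ to keep
h·β̄V inside the RK4 stability region; delayed runs additionally cap h at
τ_min/2.  Clearance-time values at h = 5×10⁻⁵ agree with h = 2.5×10⁻⁵ to
about 10⁻⁴ time units.  Horizons (12–30 units) cover clearance or dormancy
with margin.

## What the tests do and do not show

The suite verifies the implementation against *independent* oracles:
closed forms against quadrature, RK4 and the method of steps against exact
solutions and order counts, catalogued equilibria against residuals and
Newton basins, eigenvalue verdicts against perturbation simulations and
Routh–Hurwitz against root finders, crossing delays against substitution
and against the argument-principle scan.  Passing them shows the machinery
is faithful to the model — not that the model is faithful to tumors: the
generator emulates a well-mixed nodule with constant-history delays and
linear drug action, and none of the clinical variability, immune response,
resistance, or spatial structure of real disease.

One model property deserves flagging because it runs against the source's
qualitative narrative and is computed by the acceptance suite: with the
shipped parameters (per-cell β reading), raising the drug-response delay
τ₂ from 0.001 to 0.3 *shortens* the clearance time slightly (6.886 →
6.859 units).  Mechanism: the delayed kill terms δ₀U(t−τ₂)C(t−τ₂) and
δ₁I(t−τ₂)C(t−τ₂) evaluate the tumor at an earlier, larger state while the
tumor is collapsing, so a longer lag delivers a stronger kill.  The
opposite (delay slows clearance) requires the drug ramp-up from C₀ = 0.1
toward ϕ/ψ to be rate-limiting, i.e. much weaker virotherapy.  The virus
delay τ₁ does lengthen clearance across its published range (6.886 →
7.504 units for τ₁ = 0.001 → 0.01).

## Known limitations

* Fixed-step RK4 only (the source's method); no adaptive or stiff
  solvers, so very stiff parameterizations need small steps.
* Delay histories are constant; no distributed or state-dependent delays;
  no Hopf normal-form coefficients (direction/stability of the bifurcating
  orbits).
* The periodic-schedule equilibrium catalogue is exact only at a = 1 (see
  autonomization note); classification there uses the frozen-W subsystem.
* No parameter fitting: the shipped values are literature constants, not
  estimated from data by this package.
* No global bifurcation continuation and no spatial (PDE) extension.
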