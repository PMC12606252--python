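# Methods

## Model and assumptions

The package models a flat road stage as two tracked positions: the front of
the peloton and one "special" rider who may attack. Forces on a rider are
propulsive power (power meters, not pedal forces, are what riders monitor)
against aerodynamic drag; rolling resistance and drivetrain losses are folded
into the effective power, and all riders share one frontal area. The drag
coefficient decays exponentially with drafting depth,
`Ĉd(ζ) = Ĉd_min + (Ĉd_max − Ĉd_min) e^{−λζ/d}` behind the front and
`Ĉd_max` at or ahead of it, with representative values `Ĉd_max = 0.9`,
`Ĉd_min = 0.05`, `λ = 0.25` per axle spacing `d ≈ 4 m`.

Nondimensionalizing by course length `L`, initial mean peloton power
`⟨P̂(0)⟩` and the peloton-mean drag `⟨Ĉd⟩` makes the peloton cover a unit
course in unit time with unit mean energy; the rider's equation of motion is
`ε x″ = P/x′ − Cd x′²` with `ε = 2⟨m⟩/(L⟨Ĉd⟩ρA)`. For `ρ = 1.225 kg/m³`,
`⟨m⟩ = 70 kg`, `L = 100 km` and `⟨Cd⟩A = 0.4 m²` this gives
`ε = 140/49000 ≈ 2.9×10⁻³`; the scales are always computed from the supplied
inputs, never hard-coded. Because `ε ≪ 1`, the working model is the
quasi-steady limit `v = (P/Cd)^{1/3}`: power changes produce effectively
instantaneous speed changes on the race time scale. The inertial ODE is kept
solely to validate that limit (Radau with finish-line event detection,
rtol 1e-8 / atol 1e-10; the finish-time error decays roughly linearly
in `ε`).

Two drag conventions coexist in the literature on the discrete peloton: the
geometric definition puts the front rider at depth 0 (`i − 1` spacings for
position `i`), while the canonical dimensionless pair
`(C_{d,1}, C_{d,5}) = (1.43, 0.46)` with `⟨Ĉd⟩ = 0.9/1.43` is consistent
with depth `i`. Both are implemented behind `OffsetConvention`, with
`EXPONENT_I` the default so the canonical values are reproduced; the
dimensionless drags can also simply be supplied directly, which is how the
default scenario is defined. The row-layout average behind `⟨Ĉd⟩` is offered
(`DragProfile.from_row_layout`) but no specific layout is canonical.

## Crash model

A crash starts at position `k` with uniform probability `1/N` and sweeps up
rider `i ≥ k` with probability `e^{−ω(i−k)}`; riders ahead are spared. The
law of total probability gives the closed form
`H(i; ω) = (1/N)(1−e^{−ωi})/(1−e^{−ω})`, nondecreasing in `i` and equal to
`1/N` at the front. Integrating `H(i(x); ω)` against a constant crash
density `ℙ(C)` over the course yields the crash measure `P` — an *expected
involvement count*, not a probability, so `P` may exceed 1 at high crash
rates; the objective is linear in it either way. The default `ℙ(C) = 2` per
stage reflects typical Grand Tour crash frequencies (one crash every
50–100 km). Non-uniform start distributions and arbitrary propagation
matrices plug in through `CrashKernel`; a Monte-Carlo simulator
(Poisson crash count, uniform locations, kernel-Bernoulli involvement,
single-seed reproducible) serves as an independent oracle for the analytic
measures.

Failed escapes need a convention: a rider who attacks before the earliest
feasible position lacks the power to pull clear, drifts back, and finishes
with the peloton. Their exposure is taken as full-race lurking at position
`i` — the brief excursion is ignored. This matches the discontinuity of the
objective at `x_a^min`: attacking exactly there drops the exposure of the
solo stretch discontinuously. A rider off the front carries the same
exposure as the front of the peloton (`H(1; ω)`).

## Constant-power optimization

With `Δt(x_a)` and `P(x_a)` closed-form, the stationarity condition of
`M = −βΔt + (1−β)P` is a depressed cubic in
`η = √((1−x_a)/(E* − C_{d,i}x_a))`. The cubic is solved in closed form
(trigonometric three-real-root formula, hyperbolic/Cardano otherwise) rather
than iteratively, to be robust near the discriminant; roots are filtered to
`η > 0` with `x_a ∈ [x_a^min, 1)` and confirmed as minima by a centred
second difference (step 1e-5). Because `η` solves an equation free of `E*`,
the interior attack power `P_a† = 1/(√C_{d,1} η³)` is budget-independent and
`x_a†(E*)` is affine — both are asserted to 1e-9 in the tests. The global
optimum compares the interior candidate with the boundary `x_a^min`
(labelled `START_LINE` when the budget `E* ≥ C_{d,1}` puts `x_a^min = 0`);
ties break toward the smaller attack position. `β = 0` is handled exactly
(no interior stationary point; pure exposure minimization selects
`x_a^min`), avoiding a `0·∞` ambiguity in the cubic coefficients.

The critical risk `β* = a/(a+b)`, with
`a = (ℙ(C)/N)((1−e^{−ωi})/(1−e^{−ω}) − 1)` and
`b = (1−C_{d,i}/C_{d,1})/2`, separates the two winning regimes and makes the
minimum winning budget a step function: `C_{d,1}` below `β*`, `C_{d,i}`
above. At exactly `β = β*` the right-continuous value `C_{d,i}` is returned
(a documented choice; the step's location, not its value at the step, is
what matters downstream). The inverse map, minimum risk versus budget, is
undefined at or below `C_{d,i}` and raises rather than guessing.

The energy constraint behaves singularly as `x_a → 1` (finite energy in
vanishing time means unbounded power), so attack positions within 1e-6 of
the line are rejected, and the fatigue optimizer accepts an optional peak
power cap for the same reason.

## Fatigue model

After attacking at `t_a = x_a`, power decays as
`P_a(t) = (P_max − P_s)e^{−μ(t−t_a)} + P_s`; by default the sustainable
power `P_s` equals the lurking power `C_{d,i}`. Energy and the
budget-exhausting `P_max(x_a, t_f)` are closed-form; the position integral
and finish time are not, so the finish condition `x_i(t_f) = 1` is solved by
adaptive quadrature (rtol 1e-9) inside bracketed root finding (xtol 1e-12).
`μ = 0` is handled by analytic limits throughout — no `1/μ` is ever
evaluated — and `μ ≤ 1e-3` demonstrably reproduces the constant-power
optimum to 1e-3.

The three-variable constrained optimum is computed two ways: SLSQP on
`(x_a, t_f, P_max)` with the two equality constraints, multi-started from 16
fixed attack positions with `(t_f, P_max)` repaired to feasibility at each
start; and a 1-D scan over `x_a` with the constraints eliminated pointwise
(200-point grid plus golden-section refinement), which serves as the oracle.
Both are deterministic; no seeds are involved. Returned optima satisfy both
constraints to better than 1e-8. As `μ` grows the optimal attack moves
toward the line, margins shrink, and `P_max` scales like `O(μ)` (a finite
energy parcel must be deposited in a `1/μ` window) — all asserted as
monotone trends rather than point values, since the optimum's location is
the model's prediction, not a calibrated quantity.

## Scenario fixtures and what tests show

The canonical scenario (`i = 5`, `C_{d,5} = 0.46`, `C_{d,1} = 1.43`,
`ω = 0.5`, `ℙ(C) = 2`, `N = 75`, `E* = 1.2`) is the default `RaceScenario`.
The fixture generator adds edge cases (`β ∈ {0,1}`, budgets at `C_{d,i}` and
`C_{d,1}`) and seed-reproducible random variants drawn from realistic
flat-stage ranges: solo drag 1.1–2, lurking drag 0.2 up to the solo value,
`ω ∈ [0.1, 1]`, crash rate 0–4 per stage, budgets 0.5–2, the full risk
range, pelotons of 20–200. These variants exercise the mathematics across
the parameter space; they do not emulate features the model itself omits —
peloton chase response, wind and echelons, variable terrain, multi-rider
breaks, velocity-dependent crash risk — so passing tests validate the
strategy calculus, not those race dynamics.

## Numerical summary

- Quadrature: adaptive, rtol 1e-8 (energy) and 1e-9 (position).
- ODE: Radau, rtol 1e-8, atol 1e-10, event detection for the line.
- Cubic: closed-form; residuals checked at 1e-10 in tests.
- Grid oracle: vectorized objective on a 1e-4 grid plus the exact candidate
  points `{0, x_a^min}`; analytic and brute-force optima agree within one
  grid step on 400 random scenarios.
- Monte-Carlo validation: 1e5 trials, agreement within 3 standard errors.
- Problem sizes: batteries of 400 (grid oracle) and 200 (fixture
  validation) scenarios, 200-point fatigue scans — sizes at which the whole
  suite runs in well under a minute while covering the parameter space.

## Known limitations

The peloton neither reacts to the attack nor varies its pace (`t_p = 1` by
construction); crash probability is independent of speed and terrain; the
energy budget is a single scalar rather than a multi-compartment ("tank")
physiology; and conclusions near `x_a → 1` should not be trusted, as the
implied powers exceed what any sprinter can produce.
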