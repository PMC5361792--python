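# Methods

## Model structure and assumptions

`chemoresist` integrates a compartment model of tumor–normal ("conjoint")
growth under chemotherapy. All compartments grow logistically; the three
tumor compartments — wild `T`, mutated `T_M`, resistant `T_R` — compete for a
single niche through their summed burden `B = T + T_R + T_M` in each
logistic factor, while normal cells `N` have their own capacity and feel the
tumor only through the interaction term `κ·B·(1 − B/T*)`, which stimulates
normal tissue below the critical tumor size `T*` and suppresses it above.
Nothing feeds back from `N` into the tumor equations, so normal-side
parameters (`r_N`, `K_N`, `κ`, `T*`, `a_N`) never affect tumor-side results.

Drug action is the saturating response `a·(1 − e^{−M·C})`: linear in `C` for
weak exposure, capped at the compartment's induced death rate `a` (day⁻¹).
Resistance is modeled two ways:

* **intrinsic** — wild cells convert directly to resistant at rate `τ`
  (intrinsic model) or `τ₁` (extended model), drug or no drug;
* **drug-induced** — wild cells first acquire a convertible mutation at rate
  `τ₂`; mutated cells are then converted to resistant at the drug-driven
  rate `τ_{M→R}·(1 − e^{−M·C₁})`, so conversion only happens while drug 1 is
  present.

Transitions are first-order (no density dependence in the flux), gates are
hard 0/1 switches closed on the left (a term is fully active from its
on-time), and cell counts are continuous — the model has no demographic
stochasticity, so "one cell" is a bookkeeping unit, not a discrete birth.

## Parameters

| symbol | meaning | unit | default |
|---|---|---|---|
| `r_T, r_R, r_M` | tumor per-capita growth rates | day⁻¹ | 0.25 |
| `r_N` | normal-cell growth rate | day⁻¹ | 0.5 |
| `K_T, K_R, K_M, K_N` | carrying capacities | cells | 10⁶ |
| `κ` | tumor→normal coupling | day⁻¹ | 0.0124 |
| `T*` | critical tumor size | cells | 3×10⁵ |
| `τ₂` | wild→mutated mutation rate | day⁻¹ | 10⁻³ (presets) |
| `τ_{M→R}` | drug-driven conversion rate | day⁻¹ | 10⁻⁴ (presets) |
| `τ₁` (`τ`) | wild→resistant mutation rate | day⁻¹ | 0 (10⁻⁴ in preset d) |
| `M` | drug efficiency coefficient | m²·mg⁻¹ | 1 |
| `a_T, a_TM, a_N` | drug-1 induced death rates | day⁻¹ | 0.15 |
| `a_TR` | drug-2 induced death rate | day⁻¹ | 0.15 (preset d) |
| `C₁` | drug-1 concentration | mg·m⁻² | 0.2, constant or ×e^{−0.001·t} |
| `C₂` | drug-2 concentration | mg·m⁻² | 0.6 (preset d) |
| detection threshold | clinically detectable burden | cells | 2×10⁵ |
| extinction ε | "died out" bound | cells | 1 |

Both drugs start on day 50 in the presets; τ₂ is active from day 0 and the
conversion gate opens on day 50 (day 150 in preset b). `a_TM` defaults to
`a_T`: mutated cells are biologically drug-responsive, and setting their kill
rate to zero instead makes the mutated clone take over the niche and prevents
resistant cells from ever becoming detectable, which contradicts every
qualitative behavior the scenarios are meant to show. `a_N` likewise defaults
to `a_T`; being normal-side only, it cannot influence tumor results. The
decaying-drug clock runs on absolute simulation time (`C₀·e^{−λt}`), matching
the printed form of the schedule; a `decay_from_start` switch measures decay
from the therapy start instead.

## Numerics

Integration uses `scipy.integrate.solve_ivp` with LSODA, rtol 1e−8 and
atol 1e−6 cells. The right-hand side is discontinuous at therapy starts and
gate on-times, so the solver is restarted at each such time and never steps
across a jump. Dense output is sampled every 0.5 day (1001 points over the
500-day horizon); event times (threshold crossings, extinctions) are located
by linear interpolation between grid points, which at this spacing is stable
to far below the one-day precision at which detection times are quoted —
halving both solver tolerances moves the scenario-a detection time by much
less than half a day (asserted in the tests). Solver noise can leave counts a
hair below zero; output values are clamped to 0 (observed pre-clamp minima
are ≥ −10⁻⁶ cells) while the state handed between segments is untouched.
Dominance ties are broken in the fixed order `T` > `T_M` > `T_R`.

## Initial conditions and calibration

The bundled scenarios start from `T(0) = 10⁴` wild cells, no resistant or
mutated cells (both arise only through the modeled transitions), and normal
tissue at capacity. `calibrate_initial_conditions` bisects `T(0)` so that the
resistant clone's detection time hits a target, and raises a
`CalibrationError` when the residual cannot change sign over the bracket.

For the preset parameter set that calibration is provably inert, and this is
worth understanding rather than papering over: because `r_T = r_R = r_M` and
all tumor compartments share one carrying capacity, the *fractions*
`T_i / B` obey an autonomous system — the common logistic factor cancels —
and start at `(1, 0, 0)` regardless of `T(0)`. The total `B` saturates near
`K` within ~60 days for any `T(0) ≥ 1`, long before detection, so the
detection time of `T_R` is the time at which a scale-free fraction crosses
`2×10⁵/K`: numerically it varies by under 10⁻⁴ days as `T(0)` sweeps 1 to
10⁶. Scenario a detects at ≈364.0 days and scenario c (identical except for
the 10⁻³ day⁻¹ concentration decay) at ≈437.1 days, for **any** initial
wild-cell count. Calibration to a target a few days away from these values
therefore fails by construction; the self-consistency of the bisection is
instead exercised on a configuration with a strong intrinsic conversion and
no drug, where detection happens during the growth phase and is genuinely
`T(0)`-sensitive.

## What the scenarios do and do not show

On a linear axis scaled to the 10⁶-cell niche, the scenario endpoints read as
clean qualitative stories: under the constant drug (a) the wild and mutated
clones collapse to a few percent of the niche and the resistant clone owns
the tumor; delaying the conversion (b) or letting the dose decay (c) delays
resistant takeover beyond the horizon; combination therapy (d) pins the
resistant clone at ~10⁻³ of the niche. Under the strict analytics defaults,
however, several of these are *not* extinctions or subordinations: the
maximum kill rate at `C₁ = 0.2` is `0.15·(1 − e^{−0.2}) ≈ 0.027` day⁻¹, so a
clone can shrink by at most a factor of ~e^{−12} over the whole horizon and
wild cells in (a) still number ~5×10⁴ at day 500; in (d) the resistant clone
sits in a quasi-steady balance between the τ₁ influx and drug-2 kill at
~1.2×10³ cells rather than dying out; and in (b) and (c) the resistant clone,
while below `N`, is already the largest *tumor* compartment at day 500. The
qualitative-regression test asserts the strict readings and its failures are
reported as such; users wanting the "visually zero" reading can raise the
extinction ε.

## Limitations

Well-mixed, non-spatial growth; no immune compartment, toxicity constraint,
pharmacokinetic absorption/clearance beyond the single exponential decay, or
periodic dosing; mutation rates are constant rather than exposure-dependent;
and continuous counts mean late-time "die-out" questions sit below the
resolution at which a deterministic model is meaningful (a birth–death
formulation would be the honest tool there). The normal-cell coupling term is
an external forcing on `N`: for tumor burdens above `T*` it is negative and
independent of `N`, so it could in principle drive `N` below zero; with the
default parameters `N` stays near capacity and the clamp never engages beyond
solver noise.
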