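# Methods

## The problem

A point source (an industrial stack) releases a tracer gas into the
boundary layer; a network of ground-level sensors reports hourly
concentrations.  Gaussian dispersion models predict those concentrations
cheaply, but their dispersion coefficients — the power-law widths
σ\_y = a₁·x^b₁, σ\_z = a₂·x^b₂ of the concentration profile — depend on
atmospheric stability, terrain and insolation, cannot be measured
directly, and drift over a day.  `plumetrack` treats the coefficient
vector X = (a₁, b₁, a₂, b₂) as the state of a state-space model,
X\_{k+1} = X\_k + n\_k, and estimates it sequentially from the sensor data
with a particle filter.  Alongside the concentrations it propagates an
integer *relative-error exponent* through every arithmetic operation, so
each computed concentration carries a machine-checkable statement of how
many binary digits of relative accuracy survive the measurement errors
and the computation.

## Forward models

**Plume.**  For a steady release of q kg/s at effective height H under
wind speed v, the ground-reflected Gaussian plume in the frame whose
x-axis points downwind:

    c(x, y, z) = D(t) q / (2π v σy σz) · exp(−y²/2σy²)
                 · [exp(−(z−H)²/2σz²) + exp(−(z+H)²/2σz²)]

Bearings are meteorological (degrees clockwise from north, naming where
the wind blows *from*); the plume axis points toward (θ+180°) mod 360.
This convention is fixed by the scenario itself: a wind from 210° must
put the high concentrations to the north-north-east.  The plume is
defined as zero at non-positive downwind distance (no upwind diffusion),
which also keeps the power laws in their domain.

**Puff.**  An instantaneous release of mass q is a Gaussian kernel
advected by the wind, with σ\_x = σ\_y = a₁·d^b₁ and σ\_z = a₂·d^b₂
functions of the *travelled distance* d = ∫v(τ)dτ.  Wind series are
piecewise-constant (previous sample holds — the scenario samples wind
hourly), and the travel integral is evaluated exactly under that rule.
A puff at d = 0 returns 0 (point-mass guard).  The kernel is reflected
at the ground; its integral over the half-space z ≥ 0 is exactly q·D(t),
which the tests verify by 40-point Gauss–Legendre product quadrature.

**Multi-puff merging.**  A continuous release is approximated by a train
of puffs emitted every `dt_release` seconds, each carrying
rate(t\_start)·dt\_release of mass, summed at the receptor.  With constant
wind and rate, `dt_release ≤ 10 s` and an established plume
(3σ\_x < v·(t−t₀)), the train matches the analytic plume to well under
10 % at centerline ground receptors (measured ≈ 0.7 % at 2 km).

**Decay.**  D(t) = exp(−λt) with λ configurable and 0 by default: the
emulated tracer, SF₆, is inert.

**Units.**  SI internally (kg, m, s; concentrations kg/m³).  Sensor
tables are compared in a configurable observation unit; the default,
ppt (10⁻¹² mole fraction), converts with the SF₆ molar mass
0.14606 kg/mol and a configurable air molar volume (default
0.02445 m³/mol, ≈25 °C at 1 atm).

## The particle filter

The state is a bounded random walk inside the legal coefficient box
a₁∈(0.1,0.5), b₁∈(0.8,1.0), a₂∈(0.9,1.1), b₂∈(0.4,0.6).  Per-step
process noise is Gaussian with sd = `noise_fraction` × range width
(default 2 %), and states are reflected — not clipped — back into the
box, which preserves the perturbation distribution near the edges.  The
observation operator is the plume equation (or the multi-puff sum)
evaluated at the batch's sensors; the observation error is independent
Gaussian, either a single absolute sd or a relative sd floored at the
instrument resolution.

With ~160 sensors per batch and ~1 % noise the joint batch likelihood is
many orders of magnitude sharper than any finite particle cloud: a plain
bootstrap update collapses the effective sample size to 1 at every step
and degenerates into an unreliable greedy search.  The default update is
therefore *annealed*: the batch log-likelihood is raised to an
increasing sequence of powers β₁ < β₂ < … ≤ 1, each increment chosen by
bisection so the stage ESS stays near `anneal_target`·N (default 0.5),
with a systematic resample and a small reflected roughening move
(`move_fraction`, default 0.5 % of range width) between stages.  This is
the standard tempered/resample-move construction for sharp likelihoods;
`anneal=False` restores the plain sequential-importance-resampling path
with ESS-triggered systematic resampling (threshold 0.5), which remains
implemented and tested.  The per-batch estimate is the posterior
(weighted) mean, clipped to the box; the reported uncertainty is the
ensemble weighted sd.  The recorded ESS diagnostic is the effective
sample size the *untempered* batch likelihood would have produced.

All randomness flows from one `numpy` generator seeded by the config, so
runs are bitwise reproducible.

### Parameter defaults that matter

| parameter            | default | why |
|----------------------|---------|-----|
| `n_particles`        | 1000    | resolves ~1 % of a 4-D box; doubles as the twin-experiment size |
| `noise_fraction`     | 0.02    | tracking jitter for slowly varying conditions; raise to ≈ the expected drift rate per batch (the drifting-truth harness uses 0.10) |
| `obs_noise_sd`       | 1.0 ppt | the assumed sensor error = instrument resolution |
| `anneal_target`      | 0.5     | keeps half the ensemble alive per tempering stage |
| `move_fraction`      | 0.005   | roughening only; large values blur the posterior |
| `dt_release`         | 60 s    | puff-train discretisation; 10 s for convergence checks, 120 s in the 20-seed comparison harness for speed |

## Error propagation

Every tracked scalar carries r = ⌊log₂ Δx⌋, the integer exponent of its
relative error.  Initialisation takes the maximum of the measurement
contribution ⌊log₂ Δε⌋ and the representation class (−20 single, −50
double precision).  The propagation rules are worst-case first-order:

    add:   r(x+y)   = max(eₓ+rₓ, e_y+r_y) − e(x+y)
    mul:   r(xy)    = max(rₓ, r_y, rₓ+r_y)
    inv:   r(1/x)   = rₓ
    exp:   r(eˣ)    = eₓ + rₓ
    sqrt:  r(√x)    = rₓ − 1
    sin:   r(sin x) = e(cos(x)·x/sin(x)) + rₓ

with e(·) = ⌊log₂|·|⌋.  Three extensions, derived by the same
first-order method, are needed by the dispersion equations and are
flagged as extensions: x^b (exact b) gives r = ⌊log₂|b|⌋ + rₓ (with
b = ½ this reproduces the square-root rule exactly), cos mirrors sin
with amplification −sin(x)·x/cos(x), and negation/subtraction reduce to
the rules above.

Degenerate cases are saturated rather than silently wrong: ⌊log₂ 0⌋ is
the sentinel −1075 (below the smallest subnormal double), an exact zero
sum or a vanishing sin/cos reports the ceiling r = +64, and everything
is clamped to [−1075, +64].  The sign of the tracked value never enters
the rules (the magnitude exponent uses |x|).

**Accuracy of the calculus.**  The rules are bounds, not estimates.
Against the propagated worst-case first-order error — (|Δ̂x|+|Δ̂y|)/|x+y|
for addition, Δx+Δy+ΔxΔy for multiplication, evaluated without floors —
the integer rules sit within ±3 exponents on 10⁴ random cases (two
input floors, one output floor, and a factor-2 triangle slack; measured
maximum deviation 1).  The *signed* first-order error |Δ̂x+Δ̂y|/|x+y| can
be arbitrarily smaller under sign cancellation, so no finite band
against it can hold; the calculus intentionally reports the worst case.
Note also the documented one-exponent slack: r(√x·√x) = rₓ−1, not rₓ.

**Error maps.**  `tracked_field` evaluates the plume (or the multi-puff
sum) entirely in tracked arithmetic on a grid, with input specs
defaulting to the emulated study's assumptions: wind-speed resolution
0.01 m/s, wind-direction error 1°, and — because a bearing is a value on
a 360° circle — the direction's relative error is the *constant* 1/360
(exponent −9), not 1/θ.  Upwind points, where the plume is identically
zero, report the saturation ceiling: a zero concentration has no
meaningful relative accuracy.  Downwind/crosswind points come out
around −4 … −7 with these specs.  The maps are integer-valued and
deterministic, and because every batch re-wraps its inputs freshly, the
filter accumulates no error history: at a filter fixed point the
assimilated and static maps are identical.

## The synthetic scenario generator

`make_default_scenario` emulates the study conditions the package is
aimed at: one elevated point source (stack height 83.8 m, constant
4.65 g/s release), 160 ground-level sensors on eight arcs from 250 m to
12 km spread over a 120° sector centred downwind, eight hourly
observation batches, hourly wind samples jittered uniformly ±0.2 m/s and
±10° around a stable mean of 1.85 m/s from 210°, and additive Gaussian
sensor noise of 1 ppt clipped at zero.  The true coefficients drift
linearly across their ranges during the day (default from the 10 % to
the 90 % point of each range) — an invented, configurable stand-in for
the real environmental nonstationarity that makes static-coefficient
models fail; `drift=(f, f)` gives constant truth for twin experiments.

What the generator does *not* emulate: plume rise, terrain and building
wakes, sensor dropouts, non-Gaussian instrument error, and
within-the-hour wind variability.  Passing tests therefore demonstrate
the estimator's correctness and its behaviour under the stated noise
model, not field-data skill.

## Problem sizes used by the shipped experiments

The twin-recovery experiment uses N = 1000 particles, 160 sensors and
8 hourly batches with 1 % relative observation noise; recovery across
seeds is 0.3–3.2 % of range width per coefficient.  The
assimilated-vs-static comparison runs 20 seeded replicates of the
drifting-truth day with N = 300 (plume) and N = 80 (multi-puff,
dt\_release = 120 s) particles — sizes chosen so the full four-variant
table stays cheap while the ordering (assimilated MSE below static MSE
for both families) is decisive.  The mass-conservation check uses
40-point Gauss–Legendre quadrature per axis over ±8σ (10σ vertically).

## Known limitations

* The plume observation operator assumes within-batch steady wind; the
  multi-puff operator relaxes this but pays ~100× the cost.
* The annealed filter targets the *filtering* posterior under an
  assumed-Gaussian observation error; it provides no smoothing pass.
* The error calculus is a worst-case significance arithmetic: it can
  overstate the error of deep sums (each addition takes the max), and it
  ignores correlation between operands entirely.
* Coefficient pairs (a, b) are only jointly identified through the
  sensor geometry's span of downwind distances; a narrow network would
  leave a ridge the filter cannot resolve.
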