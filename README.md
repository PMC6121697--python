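# plumetrack

Data-driven Gaussian dispersion modelling for hazardous-gas releases:
plume and multi-puff forward models whose dispersion coefficients are
continually re-estimated from sensor observations by a particle filter,
plus a relative-error-exponent calculus that flags where computed
concentrations are numerically untrustworthy.

## Who this is for

Air-quality and emergency-response modellers who have (i) a known point
source — stack location, height, release rate — (ii) a wind record, and
(iii) a network of ground-level concentration sensors, and who need both
*better* concentration predictions than a static Gaussian model gives and
an honest statement of *how trustworthy* each predicted number is.

## The model

The ground-reflected Gaussian plume for a steady release of q kg/s at
effective height H under wind speed v,

```
c(x,y,z) = D(t) q / (2π v σy σz) · exp(−y²/2σy²)
           · [exp(−(z−H)²/2σz²) + exp(−(z+H)²/2σz²)],
```

and the advected Gaussian puff (an instantaneous release, summed in a
train every `dt_release` seconds to represent a continuous one), share
the power-law dispersion coefficients

```
σy = a1·x^b1,   σz = a2·x^b2            (x = downwind / travelled distance).
```

The coefficient vector X = (a1, b1, a2, b2) is the hard-to-measure part:
it encodes atmospheric stability, terrain and insolation, and drifts over
a day.  `plumetrack` treats it as the state of the state-space model
X_{k+1} = X_k + n_k, Z_k = H(X_k) + v_k, and estimates it from each
hourly sensor batch with an annealed sequential-importance-resampling
particle filter, constrained to the box a1∈(0.1,0.5), b1∈(0.8,1.0),
a2∈(0.9,1.1), b2∈(0.4,0.6).

In parallel, every input can be wrapped as a tracked scalar carrying the
integer exponent r = ⌊log₂ Δ⌋ of its relative error (sensor resolution,
wind-vane error, float/double representation), and the dispersion
equations can be evaluated entirely in tracked arithmetic.  Six
propagation rules (addition, multiplication, inversion, exponential,
square root, sine — plus power/cosine extensions) yield an integer
error-exponent map: small r downwind and crosswind, saturated r where
the concentration is effectively zero and relative accuracy is
meaningless.  See `docs/methods.md` for the full rule table and the
degenerate-case conventions.

## Worked example

A twin experiment: generate a synthetic study day (an 83.8 m stack
releasing 4.65 g/s of SF₆, 160 arc sensors 0.25–12 km away, stable
1.85 m/s wind from 210°, 8 hourly batches) with known constant
coefficients (0.3, 0.9, 1.0, 0.5) and 1 % observation noise, then
recover the coefficients from the noisy table:

```python
from plumetrack import (GaussianDispersionPF, make_default_scenario,
                        simulate_observations)

sscen = make_default_scenario(seed=1, drift=(0.5, 0.5))   # constant truth
obs = simulate_observations(sscen, model="plume", noise="relative", rel_sd=0.01)
model = GaussianDispersionPF(obs, sscen.scenario, model="plume",
                             n_particles=1000, obs_noise_rel=0.01,
                             obs_noise_sd=1.0)
results = model.fit(seed=1)
print(results.summary())
```

prints

```
Gaussian dispersion particle-filter results
===============================================
observation operator: plume
particles: 1000   batches: 8   records: 1280
obs noise sd: 1   resample threshold: 0.5
-----------------------------------------------
  coef     estimate  ensemble sd            range
    a1       0.3013       0.0071       (0.1, 0.5)
    b1       0.8996       0.0029         (0.8, 1)
    a2       0.9997       0.0089       (0.9, 1.1)
    b2       0.5000       0.0018       (0.4, 0.6)
-----------------------------------------------
MSE: 1.6774e+01   Pearson r: 0.9999
mean obs: 1.4666e+02   mean model: 1.4677e+02
std obs:  3.6519e+02   std model:  3.6564e+02
final ESS: 1.2 / 1000
```

Every coefficient is recovered to well under 1 % of its range width
(estimate vs the true 0.3, 0.9, 1.0, 0.5), with the ensemble sd as the
uncertainty; the MSE of ≈17 ppt² against observations whose sd is
≈365 ppt says the fitted model reproduces the data to about the injected
noise level.  The tiny final ESS is the expected degeneracy diagnostic
for 160 sharp sensors per batch — it is why the filter uses annealed
updates internally.

The same objects drive the command line:

```
plumetrack simulate --seed 1 --out obs.csv --scenario-out scenario.yaml
plumetrack assimilate --config scenario.yaml --obs obs.csv --particles 1000 --out run/
plumetrack compare --config scenario.yaml --obs obs.csv --out report.json
plumetrack error-map --config scenario.yaml --time 3600 --out map.csv
```

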