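# ctds — camera-trap distance sampling

`ctds` estimates the abundance of unmarked animals from camera-trap imagery
using point-transect distance sampling. It was built around the survey design
used to validate the method on a fenced desert bighorn sheep (*Ovis
canadensis*) population: motion-triggered cameras on a regular grid, each
image yielding a measured radial distance between camera and animal, with
effort counted as trigger opportunities inside the animals' diel activity
window. The package is aimed at wildlife biologists who need credible
abundance estimates (with defensible uncertainty) for species in rugged or
vegetated terrain where aerial surveys and mark–recapture are impractical.

## The estimator

Each camera trigger opportunity is a partial-circle point sample. An animal
at radial distance *r* inside the camera's wedge (angle θ, truncated at
*w*) is recorded with probability *g(r)*, modelled as a key function
(uniform, half-normal `exp(−r²/2σ²)`, or hazard-rate `1 − exp(−(r/σ)^−b)`)
optionally multiplied by a cosine / simple-polynomial / Hermite series in
*r/w*, with *g(0) = 1*. Detection parameters are fitted by maximum
likelihood on the radial-distance density *f(r) = r g(r) / ∫₀ʷ u g(u) du*.

With *n* detections, *S* total trigger opportunities (operating seconds in
the availability window divided by the trigger interval *t*), wedge area
*a₀ = (θ/360)πw²* and mean detectability *p̂ = (2/w²)∫₀ʷ r g(r) dr*:

```
D̂ = n / (S a₀ p̂),        N̂ = D̂ · A
```

Uncertainty combines the effort-weighted between-camera encounter-rate
variance with the delta-method detection variance on the CV scale
(cv² = cv_enc² + cv_det²); intervals are log-normal with a *t* quantile on
Satterthwaite degrees of freedom. Models within 2 ΔAIC that pass a χ²
goodness-of-fit gate (α = 0.1) are model-averaged with AIC weights,
including the between-model variance. A survey-design planner converts the
achieved CV at K₀ sites into the site count needed for a target CV via
`cv(K)² = cv_enc²·(K₀/K) + cv_det²`.

A synthetic-survey generator with known truth (clustered groups redrawn
each snapshot moment, distance-dependent thinning, diel windows, 0.5-m
distance rounding) backs the test suite with parameter-recovery and
CI-coverage experiments.

## Worked example

Simulate a two-month survey of 60 animals watched by 11 cameras on an
800-m grid in a 6.2 km² fenced area, then run the full analysis:

```python
from ctds.synthetic import SimulationConfig, simulate_survey
from ctds.pipeline import AnalysisConfig, run_analysis

sim = SimulationConfig(true_N=60, n_days=30, seed=3)
records, deployments, truth = simulate_survey(sim)

cfg = AnalysisConfig(periods=[sim.period], truncation_w=40.0)
bundle = run_analysis(cfg, records=records, deployments=deployments)
print(bundle.estimates[["stratum", "n_obs", "N_hat", "ci_low", "ci_high",
                        "cv", "cv_encounter", "cv_detection"]]
      .round(2).to_string(index=False))
```

```
stratum  n_obs  N_hat  ci_low  ci_high   cv  cv_encounter  cv_detection
   rams     99  16.53   12.77    21.41 0.15          0.12          0.10
   ewes    145  24.01   19.21    30.03 0.13          0.06          0.12
  young    110  22.02   16.90    28.69 0.16          0.12          0.10
 adults    244  40.82   34.77    47.93 0.09          0.05          0.07
```

The simulated population held 60 animals drawn ~30/40/30% into
ram/ewe/young classes, so roughly 42 adults: the "adults" row (N̂ = 40.8,
90% CI 34.8–47.9) brackets the truth. The CV columns show each stratum's
uncertainty split between between-camera encounter-rate variation and
detection-function uncertainty.

The same pipeline runs from files via the CLI:

```
ctds simulate --out survey/ --true-n 60 --days 30 --seed 3
ctds analyze  --config analysis.yaml
ctds plan     --k0 11 --cv-encounter 0.47 --targets 0.2,0.3
ctds recover  --reps 200 --seed 0
```

`ctds plan` above prints the design table for a survey that achieved CV
0.47 at 11 sites: 61 sites for a CV of 0.2, and 27 for a CV of 0.3.

## Layout

- `ctds.observations` — data model, CSV/XLSX I/O, solar availability
  windows (NOAA equations), censoring, effort.
- `ctds.detection` — detection-function fitting, p̂, χ² GOF.
- `ctds.abundance` — density/abundance, variance components, intervals.
- `ctds.selection` — AIC ranking, GOF gating, model averaging.
- `ctds.planner` — CV-versus-sites design curves.
- `ctds.synthetic` — clustered-population survey simulator and
  recovery experiments.
- `ctds.pipeline`, `ctds.cli` — orchestration, reporting, CLI.

See `docs/methods.md` for the statistical details and design choices.
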