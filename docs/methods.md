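# Methods

This note documents the statistical model behind `ctds`, the choices made
where the design was genuinely open, and what the synthetic-survey
experiments do and do not demonstrate.

## Sampling model

A motion-triggered camera is treated as a point transect sampled at
discrete trigger opportunities: one every `t` seconds (default 15 s, the
realised minimum trigger interval of the field cameras) while the camera is
operating *and* the animals are available for detection. Availability is a
diel window from 1 h before sunrise to 2 h after sunset, computed daily
from the NOAA solar-position equations at the site coordinates (fixed UTC
offset, no DST — field camera clocks run on a fixed offset). Observations
and effort are censored to the same windows, so the "available for
detection" assumption of distance sampling holds by construction.

Effort per camera is `available_seconds / t` trigger opportunities, scaled
by the viewshed fraction `θ/360` (default θ = 50°). Snapshot counts are
kept real-valued: effort is a rate denominator, not an event count.
Windows are computed per day rather than per month; with month-midpoint
windows a handful of crepuscular images could censor differently, which is
the only expected divergence from analyses that use monthly windows.

## Detection function

Radial distances of recorded animals follow
`f(r) = r g(r) / ∫₀ʷ u g(u) du` on `[0, w]`. `g` is a key function —
uniform, half-normal `exp(−r²/2σ²)`, or hazard-rate `1 − exp(−(r/σ)^−b)`
(shape constrained to b > 1 so the function keeps a shoulder) — optionally
multiplied by `1 + Σ aⱼ sⱼ(r/w)` with cosine (`cos jπx`), simple-polynomial
(`x^{2j}`) or Hermite (`He₄, He₆`) terms, rescaled so `g(0) = 1`.

Fitting is maximum likelihood with L-BFGS-B from three scale starts
(σ₀ ∈ {sd/2, sd, 2·sd}; adjustment coefficients start at 0), making fits
deterministic. The normalising integral uses 128-node Gauss–Legendre
quadrature; the half-normal closed form
`p̂ = (2σ²/w²)(1 − exp(−w²/2σ²))` agrees with the quadrature to < 1e-6 and
serves as an internal oracle. Monotonicity is enforced by a 100-point grid
check *after* fitting — fits whose `g` rises or leaves [0, 1] are flagged
and excluded from model selection rather than repaired by constrained
optimisation; this is simpler and exactly reproducible. Variance of `p̂`
comes from the delta method with a central-difference Hessian.

Choices on open details:

- **Truncation `w`** defaults to the maximum observed distance per stratum
  (40 m in the motivating study, which reported distances 0–40 m with no
  stated truncation); configurable.
- **Zero distances** are real (animals directly at the camera, recorded at
  0 m by a 0.5-m-resolution rangefinder) but `f(0) = 0` would contribute
  −∞ to the likelihood. They are offset to 0.25 m — half the measurement
  resolution — and the adjustment is counted on the fit object.
- **Candidate grid**: uniform+{cosine, simple polynomial},
  half-normal+{none, cosine, Hermite}, hazard-rate+{none, simple
  polynomial}, with 1–2 adjustment terms where an expansion is present.
  This spans the conventional key × expansion menu without combinatorial
  blow-up; AIC chooses the adjustment order.

## Goodness of fit

A χ² test on (by default) 5 equal-width bins over `[0, w]`, expected
counts from the fitted density, deficient bins (expected < 5) merged
rightward, `df = bins − 1 − parameters` floored at 1. Because field
distances are recorded on a grid (0.5 m here), point masses can sit exactly
on equal-width cutpoints; interior cutpoints are therefore shifted by half
the detected measurement resolution so each atom and its underlying
interval fall inside one bin. Without this alignment the test over-rejects
badly (≈46% instead of ≈10% at α = 0.1 in simulation); with it the test is
calibrated on both exact and rounded data. Fits with GOF p < α (study-wide
α = 0.1) are excluded from the competing set.

## Abundance, variance, intervals

`D̂ = n / (S a₀ p̂)` with `a₀ = (θ/360)πw²`; `N̂ = D̂ A` (A = 6.2 km² by
default). Encounter-rate variance uses the standard effort-weighted
between-camera estimator
`var = K/(K−1) · Σ e_k²(n_k/e_k − r̄)² / (Σe_k)²` with `df = K − 1`;
cameras are the sampling units, so clustering and behavioural
heterogeneity are absorbed empirically. Total CV combines encounter and
detection components in quadrature. Intervals are log-normal,
`(N̂/C, N̂·C)` with `C = exp(t_{1−α/2,df} √ln(1+cv²))` and Satterthwaite
df combining `K − 1` (encounter) with `n − k` (detection); a plain-z form
is available by passing `df = inf`. The log-normal/t construction matches
the magnitude of published intervals for this design better than a normal
interval; the original analysis's exact df convention is unstated, so
second-decimal agreement with published intervals is not expected.

Animals are treated as independent individual observations (each
classified animal in an image is one record); no cluster-size regression
is attempted. Strata (rams, ewes, young, adults = rams + ewes +
adult-unknown) are fitted independently per period; "adults" is its own
fit over the pooled distances, not a sum of the ram and ewe estimates.

## Model selection and averaging

ΔAIC is computed over converged, monotone, GOF-passing fits; models within
2 ΔAIC compete and are averaged with AIC weights:
`N̄ = Σ wᵢN̂ᵢ`, `var = Σ wᵢ(varᵢ + (N̂ᵢ − N̄)²)`. Averaging applies
whenever ≥ 2 models compete — single-competitor strata pass through
unchanged. Two conventions are ours: the averaged estimate's df is the
smallest df among the averaged models (conservative), and the
between-model variance is allocated to the encounter/detection components
proportionally to their within-model shares so the quadrature identity
survives averaging (when no within-model variance exists it is booked as
encounter variance). Ties in AIC break deterministically by parameter
count, then key name.

## Survey-design planner

`cv(K)² = cv_enc²·(K₀/K) + cv_det²`: encounter variance scales as 1/K
because cameras are iid sampling units; detection variance is held fixed
because it depends on the pooled detections, and in surveys of this type
it is a small share of the total (> 90% of variance sat in encounter rates
in the motivating study). `required_sites` rounds half-up; published
site-count pairs for this design are internally inconsistent with any
single rounding of the *printed* (2-decimal) CVs — they were evidently
computed from unrounded CVs — so a ±1-site tolerance applies when
comparing against them.

## Synthetic surveys

The generator emulates the fenced-facility design: `true_N` animals in a
6.2 km² rectangle, 11 cameras at the nodes of an 800-m grid with a seeded
random origin, t = 15 s, θ = 50°, half-normal detection with σ = 6 m
truncated at 40 m, a 60-day survey, and distances rounded to 0.5 m.
Animals form groups with zero-truncated Poisson sizes (mean 4 — group
structure at the real site is unreported; this value is illustrative) and
a 20-m within-group spread around a parent point (Neyman–Scott). Group
positions are redrawn independently at every snapshot moment ("ideal
mixing"); the survey region is a 1.65:1 rectangle because an 800-m grid
with 11 full 40-m viewsheds cannot fit a square of this area and the real
facility is elongated; cameras keep ≥ w from the fence so wedges never
cross it.

Event generation is exact up to two documented approximations: a group can
only be detected when its parent lies within `R = w + 4σ_c` of a camera
(the offset tail beyond 4σ_c contributes O(e⁻⁸)), and per-(camera, group)
presence snapshots are drawn binomially with replacement (Poissonization).
Camera capture discs are disjoint at 800-m spacing, so per-camera draws
are independent.

What this shows — and does not. Because positions are redrawn each
snapshot, all cameras share one expected encounter rate: the simulator
produces clustering-induced overdispersion but *not* the persistent
habitat-driven heterogeneity that dominated the real study's variance
(simulated CVs ≈ 0.06 versus ≈ 0.45 in the field). Passing
coverage/recovery tests therefore validates the estimator chain under its
own assumptions (including clustered, overdispersed counts); it does not
demonstrate robustness to habitat preference, temporal autocorrelation, or
attraction/avoidance of cameras. The recovery experiment (200 replicates
at the defaults, full pipeline with a 4-model grid) yields 90% CI coverage
≈ 0.92 and median relative bias ≈ −2%; replicates where every candidate
model fails the GOF gate (≈ 7%, a consequence of overdispersion meeting a
nominal-α gate) are counted and reported, not silently dropped.

## Problem sizes

Default experiment sizes were chosen to keep estimator noise well below
the quantities being checked: n = 1,000 distances for σ recovery (±5%
band), 100 seeded replicates for GOF calibration, 200 replicates for CI
coverage (binomial SE ≈ 2%), 30–60-day synthetic surveys giving
350–700 detections, comparable to the motivating study's pooled sample.

## Known limitations

- No covariates in the detection function, no left truncation, no
  binned-likelihood fitting, no cluster-size modelling.
- The planner treats detection variance as design-independent; redesigns
  that change per-camera sample sizes violate this mildly.
- The simulator has no terrain, no viewshed occlusion, and (by default) no
  temporal autocorrelation; its group-size distribution is illustrative.
- Polar latitudes (|lat| ≥ 66°) are unsupported in the solar window code.
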