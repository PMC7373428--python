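# Methods

This note documents the models, estimators, numerical choices and known
limitations of the `ironage` package. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Lifespan model and synthetic cohorts

Lifespans are generated from a Weibull baseline hazard with per-animal Gamma
frailty. Conditional on frailty `z` (Gamma, mean 1, variance σ²), the hazard
is `z·(k/b')·(t/b')^(k−1)` with `b' = b·λ·exp(replicate offset)`, so
`T = b'·(E/z)^(1/k)` with `E ~ Exp(1)`. Marginally

    S(t) = (1 + σ²·(t/b')^k)^(−1/σ²),

which passes continuously into the Weibull `exp(−(t/b')^k)` as σ² → 0 (the
implementation uses `log1p`, with σ² floored at 1e−8). Frailty is
per-animal; replicate effects enter only as Gaussian offsets on the log
scale of `b` (SD 0.05 by default, which reproduces the 1–2-day spread of
control medians seen between replicate lifespan experiments). Death times
are continuous by default; `discretize=True` rounds them up to whole scoring
days to mimic daily survival scoring.

Default arms (the study conditions every default-driven analysis uses):

| arm     | k | b (d) | σ²  | λ     | Δlog k | Δlog σ² | model median |
|---------|---|-------|-----|-------|--------|---------|--------------|
| control | 4 | 7.40  | 0.4 | 1     | 0      | 0       | 7.0 d        |
| lip1    | 4 | 7.40  | 0.4 | 13/7  | +0.3   | −1      | ≈13.0 d      |
| sih     | 4 | 7.40  | 0.4 | 2     | +0.4   | −1      | ≈14.0 d      |

`b` was set so the control marginal median is 7 days at 25 °C; λ doubles
(or nearly doubles) median lifespan; the positive shape deltas square the
treated survival curves and the negative Δlog σ² makes treated arms less
heterogeneous — the combination that makes the interventions *not* act by
pure temporal scaling. Eight replicates of 90 animals per arm give pooled
arm sizes of ~720. These values were chosen once, from the experimental
design they emulate, and are not tuned.

## Buckley–James AFT and the modified K-S rescaling test

The AFT model `log T = μ + βx + scale·ε` is fitted by the Buckley–James
iteration: ordinary least squares on completed log-times, with each censored
log-time replaced by its conditional expectation under the Kaplan–Meier
estimate of the current residual distribution (largest residual treated as
an event so the distribution is proper). Iteration stops when coefficients
move < 1e−6; a two-cycle oscillation is detected, averaged and flagged.
With no censoring the first pass is exact OLS — an identity the acceptance
script verifies to machine precision.

Departure from temporal rescaling is tested with a two-sample
Kolmogorov–Smirnov statistic on the AFT residuals, censoring-aware on both
sides: arm-wise residual CDFs are Kaplan–Meier estimates, and the supremum
is restricted to the common support (values up to each arm's last observed
event), because beyond an arm's last event its KM estimate is a
censoring-induced plateau, not evidence of difference.

The null distribution is a **residual permutation with refit**: residuals
(carrying their censoring flags) are permuted across animals, pseudo
log-times are rebuilt from the fitted arm effects, and the AFT model is
refitted on each permuted dataset before recomputing D. Refitting accounts
for the estimated coefficients — the "modified" aspect of the test. A plain
label permutation was evaluated and rejected during development: permuted
groups are then scale *mixtures*, and the demeaned-sample K-S statistic is
not distribution-free, which inflated the type-I error to ≈0.08 at a nominal
0.05. The residual scheme is exact-level under exchangeability; the
acceptance script measures its rejection rate on 500 pure-scaling
simulations (n = 300/arm) and its power against a doubled Weibull shape.
Replicate-level p-values are combined by Fisher's method (the pooling rule
across replicates is this package's choice).

Limitation: under heavy *differential* censoring the residual censoring
patterns differ by arm, residuals are no longer exchangeable, and the test
becomes conservative (rejection rate below α; verified in development at a
shared day-12 cutoff). Lifespan cohorts followed to death — the intended
use — are unaffected.

## Weibull–Gamma frailty fits, selection, GOF, meta-analysis

The marginal likelihood uses `log f = log k − log b + (k−1)(log t − log b)
− (1/σ²+1)·log1p(σ²(t/b)^k)` for deaths and `log S` for censored records.
All parameters are optimized on the log scale (positivity without
constraints, and Δlog σ² is read directly); three Nelder–Mead starts
(k ∈ {1, 2, 4}, σ² ∈ {0.05, 0.2, 0.5}) are polished by BFGS and the best
log-likelihood wins. Standard errors come from the inverse of a
finite-difference Hessian. Per-fit σ̂² has ~15–20% sampling noise even at
n = 2000/arm, so recovery is assessed as a mean over seeds.

Model selection is forward over the nesting lattice {scaling-only → +shape,
+frailty → full}: all reachable extensions are tested by LRT at α = 0.05,
the most significant accepted extension is adopted (ties favour fewer
parameters), and selection stops when nothing passes. The chi-square GOF
transforms each death time by its arm's fitted CDF, bins [0,1] into
equal-probability bins (merged until expected ≥ 5) and uses df = bins − 1 —
the reference parameters are treated as externally estimated (e.g.
meta-analysis estimates applied back to a replicate), so no parameter count
is subtracted. Censored records are excluded from the GOF.

Meta-analysis is inverse-variance weighting: fixed effect
`Σwθ/Σw, w = 1/v`; random effect via DerSimonian–Laird
`τ² = max(0, (Q − (m−1))/(Σw − Σw²/Σw))` with weights `1/(v + τ²)`.

Hazard curves are life-table estimates (deaths per person-day at risk in
1-day bins) smoothed by a Gaussian kernel (default bandwidth 1.5 d), with
pointwise bootstrap-over-animals CIs. Near the end of follow-up the raw
life-table hazard is driven by a handful of animals and is noisy; the
interior of the curve is where deceleration statements live.

## φXANES speciation

**Energy grid.** The acquisition grid is built from the declared step table
(5×20, 5×1, 75×0.4, 15×2, 1×240, 5×5 eV). Counting points as
`1 + Σ steps` yields 107 for a declared total of 106, and the final
segment's span (50 eV) disagrees with its steps (25 eV); the builder trusts
the step counts, truncates to the declared total, and records both
discrepancies on the grid object rather than resolving them silently.

**Endmembers.** Synthetic Fe²⁺/Fe³⁺ endmember spectra are an arctangent
edge step plus one pre-edge Gaussian: centers 7112.1 / 7113.5 eV (standard
pre-edge positions for ferrous/ferric coordination), amplitude 0.12 of the
edge jump, σ = 0.9 eV, main edges at 7120 / 7124 eV. All are configurable.

**Energy calibration.** The foil spectrum's first prominent derivative peak
(first contiguous region above half the maximum derivative of a PCHIP
interpolant, evaluated densely) is mapped to 7112.0 eV. A flatness guard
(peak < 2× median |derivative|) rejects spectra without an edge.

**Alignment** is integer-pixel cross-correlation of each frame's calcium
map against the first frame's; subpixel interpolation is avoided because it
smears sparse counts. Frames requiring shifts beyond `max_shift` are
excluded and their energies marked missing.

**Normalization**: a line fitted below 7105 eV is subtracted; the edge jump
is a first-order polynomial fitted above 7135 eV evaluated at 7112 eV, and
the spectrum is divided by that scalar. This keeps normalization linear, so
a two-component mixture's normalized spectrum is the mixture of normalized
endmembers up to the (small) difference in their measured edge jumps.

**Pre-edge fit and centroid.** An arctangent tail plus a single Gaussian is
fitted jointly over 7108–7118 eV. The *reported centroid is the
intensity-weighted first moment* of the baseline-subtracted data over
7109–7116.5 eV, not the Gaussian center: for a two-component feature with
equal amplitudes the moment is exactly linear in the mixing fraction,
whereas a single Gaussian forced onto a two-Gaussian envelope is biased
toward the major component (measured at up to 0.065 in fraction units on
noiseless sweeps — larger than the accuracy budget). The Gaussian parameters
are retained for diagnostics and the centroid CI uses the fitted center's
standard error.

**Fraction estimation.** Centroid mode inverts linearly between reference
centroids; derivative mode integrates |dμ/dE| over the 1s→4s (7117–7123 eV)
and 1s→4p (7125–7131 eV) windows and inverts the ratio
`r(f) = (f·a₂+(1−f)·a₃)/(f·(a₂+b₂)+(1−f)·(a₃+b₃))` exactly — a ratio of
linear functions, so a linear rescale between endmember ratios would be
biased mid-range. Both modes are calibrated against pure endmember spectra
*processed by the same pipeline* (`SpeciationCalibration.from_endmembers`),
so systematic processing offsets cancel; with literature default centroids
instead, the centroid mode carries a ~0.08 systematic at the ferrous end.
Estimates outside [0,1] are clipped and flagged. CIs are parametric
bootstraps over Poisson resampling of the ROI-summed counts (200 resamples);
group contrasts are proportional changes vs a reference group with
bootstrap-over-animals CIs, flagged unavailable for single-animal groups.
Residual accuracy: ≤ ~0.035 (centroid) and ≤ ~0.01 (derivative) across the
f = 0.1–0.9 sweep at generator default counts, measured by the acceptance
script. The bootstrap CI reflects counting noise only, not the small
mode-specific inversion bias, so at very high counts the centroid-mode CI
can sit beside the true value; the derivative mode is the better-calibrated
estimator.

## XFM quantification

Segmentation thresholds the Compton channel with Otsu's two-class
variance-maximizing criterion (deterministic and parameter-free on a
bimodal scatter histogram), labels foreground with 8-connectivity (worm
bodies are thin and curved; 4-connectivity fragments them), and discards
components under 10,000 pixels. Uniform or inseparable Compton rasters
yield an empty ROI set with a warning status, not an exception. Partial
worms at scene edges are kept if they pass the size filter.

The Currie critical level uses the paired-blank convention
`L_C = z₁₋α·√(2B̄)` (α = 0.05 default, the classical 2.33·√B̄); map values at
or below L_C are zeroed before calibration. Its α-level false-detection
property is defined for net (sample − blank) signals, which is how the
calibration test and the acceptance script measure it. Foil calibration is
the zero-intercept least-squares slope of known areal density on measured
flux, per element; unit conversion is centralized
(1 µg cm⁻² = 0.01 pg µm⁻²). `total_mass = mean density × area` is an exact
identity per ROI and quantification is additive over ROI splits.

The scene generator plants non-overlapping elliptical worms of uniform
areal density (overlap is rejected because per-worm truth would be
ambiguous), converts density to expected counts via a configurable
counts-per-density (default 500 counts per pg µm⁻², roughly matching
low-count XFM of hydrated tissue at 0.64 µm² pixels), and draws Poisson
counts; the Compton foreground rate is `contrast × max(background, 1)` so a
zero-background scene stays strictly bimodal.

## Dose-response

Lethality follows a Hill curve `P(d) = d^h/(d^h + LD50^h)` with default
LD50 = 10 mM and slope 3, and the log-LD50 shifts by −0.1 per day of adult
age past the Day-4 reference (older animals more sensitive). The default
fit fixes asymptotes at 0/1, which makes the Hill fit an exact binomial GLM
on log-dose (zero-dose groups drop out); a four-parameter weighted
least-squares variant with free asymptotes is provided. Dose is linear in
the default parameterization (dose-response figures are plotted on linear
dose); log-dose is available via the GLM internally.

## What the synthetic data do and do not emulate

The generators reproduce the *statistical structure* each estimator
assumes: frailty-heterogeneous Weibull lifespans with replicate effects and
optional pure scaling; linear-mixture XANES spectra with Poisson counting
noise, frame jitter and a stable calcium channel; Compton-separable
worm foregrounds with Poisson backgrounds; Bernoulli dose-response. They do
not emulate detector response, spectral overlap/deconvolution, self-
absorption, non-uniform within-worm iron distributions, bacterial-diet or
temperature kinetics, or scoring-day heaping beyond optional 1-day
discretization. Passing tests therefore demonstrate estimator correctness
and calibration under the declared models, not robustness to every
real-data artifact.

## Problem sizes used by the acceptance script

Type-I calibration: 500 simulations × 200 permutations at n = 300/arm
(uncensored, where Buckley–James is a single OLS pass). Power: 200
simulations at Δlog k = log 2. Frailty recovery: 20 seeds × two arms ×
2000 animals, compared as across-seed means. Fe²⁺ sweep: 12×12-pixel
stacks at counts_scale 10⁴ across f ∈ {0.1, 0.3, 0.5, 0.7, 0.9}, both
modes. XFM: one 256×360 scene with a 12k-pixel worm and a 5k-pixel
fragment. Currie: two 300×300 background-only scenes at 20 counts/pixel.
Representative medians: one replicate of 90 animals/arm, day-discretized.
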