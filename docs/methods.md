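# Methods

## The quantity being modeled

Each subject contributes one number: the **overall MEP change**, the mean of
the six post-interventional block amplitudes expressed as percent of the
pooled baseline. Preprocessing is deliberately plain: contaminated trials
(pre-stimulus muscle activity) and the first trial of every block are
excluded, surviving trials are averaged per block with an unweighted
arithmetic mean, and the baseline is the mean of the two baseline *block
means* (not of the pooled trials — the two differ only when the blocks lose
different numbers of trials to exclusion). Subjects missing a block are
rejected rather than imputed. Values above 100 % indicate facilitation,
below 100 % depression.

## Synthetic cohorts

Because stratification methods need data with known structure, the
generator draws, per subject:

* a latent component from the tri-modal plasticity mixture — defaults
  m = (69.7, 115.1, 158.4) % of baseline, s = (4.2, 13, 26.4),
  w = (0.19, 0.55, 0.26) — then the subject's true effect from that
  component;
* a baseline amplitude from N(0.99, 0.17²) mV, truncated at 0.1 mV
  (amplitudes are physical, positive quantities; the target MEP amplitude
  in such protocols is ~1 mV);
* trial amplitudes around the block's expected value (baseline blocks: the
  baseline; post blocks: baseline × effect/100) with SD equal to a constant
  coefficient of variation (default 0.2) times that expectation, truncated
  at 0. A CV of 0.2 puts simulated baseline-block SDs in the 0.14–0.26 mV
  range typical of ~1 mV MEPs. One CV serves both baseline and post blocks;
  no inter-block drift is modeled.
* independent contamination flags at rate 0.05 — the flag *stands in for*
  the human audio-visual artifact judgment; no EMG waveforms are simulated.

All draws come from one seeded generator in document order, so a config +
seed pair reproduces the cohort byte for byte. The generator does **not**
emulate slow excitability drift, inter-trial correlation, or
amplitude-dependent artifact probability; passing tests therefore certify
the analysis chain, not robustness to those real-data features.

## Pareto density estimation

The density at grid point x is the count of observations within a fixed
radius r of x, rescaled to integrate to 1 (trapezoid) on a 256-point grid
spanning [min − r, max + r]. The radius is the 18th percentile of the
pairwise distances between data points — small enough to resolve modes,
large enough to smooth within-mode noise. The exact radius rule used by the
original PDE implementations is not restated in the sources this package
follows; the 18th-percentile rule is isolated in one function
(`pde.pareto_radius`) so it can be substituted. Above 5,000 points the
percentile is computed on a seeded random subsample (quadratic-cost cap).
With heavy ties the percentile can be 0; the fallback is the smallest
positive pairwise distance.

## Mixture fitting and model selection

The mixture p(x) = Σ wᵢN(x|mᵢ,sᵢ) is fit by maximum-likelihood EM:
one deterministic start (quantile partition of the sorted data into M
equal-count segments) plus seeded random restarts (means drawn from the
data, pooled-SD scales), 20 starts by default. Numerical choices:

* E-step in log space; M-step from sufficient statistics.
* Convergence when the per-iteration log-likelihood gain falls below
  `tol` (default 1e-8) **relative to |loglik|**; the per-iteration gain is
  never negative beyond 1e-9 (monotonicity is tested).
* Variance floor: component SDs are clamped at 1e-3 × data range during
  iteration; a solution whose SD ends on the floor is a collapse onto a
  point and that restart is discarded. If all restarts collapse, the fit
  errors.
* Components are reported sorted by ascending mean (the likelihood is
  label-symmetric; sorting fixes the labeling).

Model order is chosen by a forward likelihood-ratio ladder over
M = 1…4: the step M−1 → M is accepted when Δ₋₂LL = 2(LL_M − LL_{M−1})
strictly exceeds a χ² critical value, and the chosen M is where the ladder
first stalls. Each M > 1 fit receives a warm start that splits the widest
component of the M−1 solution, so the nested optimum is always reachable;
a Δ₋₂LL within convergence slack below zero (> −0.5) is treated as a failed
step, while a decisive decrease raises an error.

**The threshold.** The default critical value is 3.84 (α = 0.05, df = 1).
A step adds three parameters, so df = 3 (critical value 7.81) is the
textbook count and is available via `df=3`; the df = 1 value is the
operative criterion this analysis tradition uses. Neither is well
calibrated: the mixture likelihood-ratio statistic is *non-regular* (the
null hypothesis sits on the parameter-space boundary), its null
distribution is stochastically larger than χ²(1), and a fully ML-optimized
EM finds genuine broad two-component splits of single-Gaussian data with
Δ₋₂LL above 3.84 far more than 5 % of the time. Consequences observed with
this implementation: on single-Gaussian data (n = 1000) the ladder keeps
M = 1 only ~55 % of the time at the 3.84 threshold (~90 % at 7.81), and on
large tri-modal samples it occasionally accepts a spurious fourth
component. At n = 31 — a realistic cohort — the instability is worse, and a
spurious narrow component can be selected; the historical workflows that
fit such models interactively (by eye, against the PDE with an RMSE
criterion) implicitly regularized this away. The RMSE-to-PDE diagnostic is
computed and reported, but likelihood governs selection — a reproducible
build needs a non-interactive criterion.

CDF and quantile functions are exact mixture formulas with a bracketed
root-finder for the inverse (|cdf(q) − p| < 1e-10); QQ pairs match the i-th
order statistic with the model quantile at (i − 0.5)/n.

## Subgroup assignment

Posterior membership is pᵢ(x) = wᵢN(x|mᵢ,sᵢ) / Σⱼ wⱼN(x|mⱼ,sⱼ), computed in
log space. The decision limit between adjacent components is the root of
the weighted-density difference, bracketed strictly between the two means
(|log-density gap| < 1e-10 at the root); restricting to that bracket yields
exactly M − 1 limits and ignores second crossings far in the tails. If the
densities do not cross between the means (a sliver component nested inside
a broad one — which a liberal model-order choice can produce) the boundary
computation errors, naming the pair; the CLI suggests `--m-max`/`--lr-df`.

**Labels follow the decision limits, not the global posterior arg-max.**
For unequal variances the two disagree in the far tails: with the default
tri-modal parameters the widest (paradox) component owns the posterior
arg-max below ≈ 51 %, yet a subject at 40 % plainly shows the strongest
possible depression. Interval membership between the limits is the
clinically meaningful rule (a responder is anyone at or below the lower
limit) and coincides with the arg-max posterior everywhere between the
outer component means. Values exactly on a limit go to the lower-mean
component (a measure-zero tie, fixed for determinism). For M = 3 the
ascending components map to responder / non-responder / paradox-responder;
for other M the labels are `component-k`.

## ABC analysis

LTD responses (100 − MEP%, floor 0) are sorted descending (ties broken by
subject id) into the cumulative-contribution curve through (i/n, share of
total from the top i). The A/B limit is the curve point closest to the
ideal point (0, 1); the B/C limit is the last point whose segment slope
exceeds 1 (break-even: the item still contributes more than the uniform
share). If the break-even falls at or before the A limit, B is empty.
Zero-valued subjects can never be "profitable" and are forced into C. These
limit rules reconstruct the computed-ABC methodology from its published
description; edge handling (data-point indices rather than interpolated
limits) is a package choice isolated behind `abc_partition`. The ABC
responder set is A ∪ B — an independent route that agrees with the
mixture classification when the responder mode is well separated, and tends
to admit one or two borderline extra subjects otherwise.

## Confirmatory statistics

`paired_t` is the classical paired Student t (df = n − 1, two-sided p),
erroring on zero-variance differences. Post-hoc tests compare each post
block's normalized value against 100 % per subgroup — equivalent to raw
block means against each subject's own baseline. P-values are uncorrected
by default (with a log note), Bonferroni behind a flag. Repeated-measures
ANOVA machinery (sphericity corrections, between-subject factors) is out of
scope; standard statistical packages cover it.

## Pipeline and problem sizes

One `--seed` fans out to per-stage child seeds by fixed offsets (generation
+0, fitting +1009), so stages are independently reproducible and a run is
byte-identical given config + seed. The test suite exercises the chain at
the sizes a laptop handles in minutes: cohorts of 31 subjects for
study-scale behavior, 3,100–10,000 mixture draws for model-order and
parameter recovery, 31,000 subjects (1,000 × 31) for the expected responder
count, 2,000 simulations for t-test calibration.

## Known limitations

* Model-order selection inherits the anti-conservatism of the χ²-calibrated
  mixture LRT (above); at n = 31 the chosen M should be reviewed against
  the PDE plot and the QQ diagnostic, not trusted blindly.
* PDE's uniform kernel makes densities piecewise-constant before
  normalization; it is a discovery tool, not a smooth density estimator.
* The generator's constant-CV noise and independent contamination flags are
  idealizations; no claim is made about EMG-level artifacts.
* Decision limits carry no uncertainty intervals (no bootstrap of the
  mixture fit).
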