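# Methods

## The detection model

All analyses rest on one assumption: phage particles in a well-mixed
aqueous suspension are spatially random, so the number of PFU in a vessel
inoculated with volume *v* µL of a suspension at concentration *c* PFU/mL
is Poisson with mean λ = c·v/1000. A presence/absence method scores a
vessel positive exactly when it contains at least one viable phage, so

    P(positive) = 1 − e^−λ,      P(negative) = e^−λ.

Rates are always stored with the volume at which they are expressed
(`PoissonRate(lam, volume)`), and cross-volume comparisons go through
`scale_rate` (linear in volume). This prevents the silent unit errors that
arise when per-10 µL and per-100 µL readings are mixed.

The model ignores phage aggregation, adsorption losses and any non-Poisson
spatial structure; those are method-development questions, not statistics,
and are out of scope.

## MPN estimation and its interval

For a single dilution with *x* positives out of *n* vessels the binomial
likelihood with p = 1 − e^−λ is maximized at λ̂ = −ln((n−x)/n) — the
most probable number per vessel. Tests verify this against a brute-force
grid search of the likelihood (step 1e-4), and via the algebraic identity
e^λ̂ − 1 = x/(n−x).

The confidence interval is a delta-method interval on the log scale
("Jarvis approach"):

    SE(ln λ̂) = sqrt((x/(n−x))/n) / λ̂,
    CI = λ̂ · exp(∓ z · SE),   z = Φ⁻¹((1+conf)/2) = 1.959964 at 95%.

This exact formula reproduces all published interval bounds of the study
fixture at 2 d.p. ((0.29–0.79), (0.32–0.84), (0.72–2.29)), which is the
evidence that it is the right reading of "Jarvis approach". Simulated
coverage at λ ∈ {0.5, 1.3}, n ∈ {18, 42} is 93–97%, checked in the suite
with a ≥90% floor.

Edge cases:

* x = 0 — point 0 with the one-sided bound λ_up = −ln(1−conf)/n (the
  generalization of the rule of three; exact, from P(all negative) =
  e^−nλ);
* x = n — `computable=False`. The MLE is unbounded and the study tables
  mark these cells "non computable"; returning infinity would poison
  downstream arithmetic silently.

Display rounding is half-away-from-zero at 2 d.p. (MPN), 4 d.p. (rates),
2 d.p. (percentages); raw values are never rounded internally and JSON
reports carry `{"raw", "display"}` pairs. One fixture cell (the reference
method's 10 µL point, printed 0.51 where −ln(25/42) rounds to 0.52) cannot
be reproduced by the estimator even though its CI can; reports flag it as
a discrepancy rather than matching either value silently.

## Count-distribution fitting

`fit_poisson` (λ̂ = mean), `fit_negative_binomial` (mean µ profiled at the
sample mean, dispersion k by coarse log-grid search plus bounded Brent
refinement; variance µ + µ²/k), and `fit_normal` (MLE σ̂, divisor n) all
report exact log-likelihoods and AIC = 2·n_params − 2·loglik.
`select_by_aic` breaks ties toward fewer parameters, then a fixed family
order. When the sample variance does not exceed the mean the negative
binomial has no interior optimum; the fit is returned at the dispersion
cap (10⁶) with `boundary=True` and the log-likelihood set to its k → ∞
limit, the Poisson log-likelihood, so the nesting property
loglik_NB ≥ loglik_Poisson holds exactly.

Goodness of fit:

* **Pearson chi-squared** on integer bins with an open upper tail, pooled
  from the top until every expected count is ≥ 1 and at most 20% of bins
  are below 5 (the study does not state its binning; this common textbook
  rule is fixed here and calibrates well: simulated type-I error at the 5%
  level is ≈ 4.3% over 2000 null replicates of n = 1000). df =
  bins − 1 − n_params; df ≤ 0 yields a NaN p-value rather than a fake one.
  For the normal family, bin probabilities integrate the density over
  (k−½, k+½], with the lower tail folded into bin 0.
* **Kolmogorov–Smirnov** — sup |ECDF − fitted CDF| over the integer
  support for discrete fits (asymptotic Kolmogorov p-value, conservative
  under discreteness), the usual two-sided statistic for the normal fit.

The published per-volume AIC/λ/p table is carried in the fixture for
display only; its raw counts were never published, so nothing is fitted
against it.

## Control charts

`build_chart` takes the baseline mean as center and the n−1 sample
standard deviation as sigma, with limits at exactly center ± 2s (warning)
and ± 3s (control); baselines under 20 points warn. Limits are stored
explicitly rather than derived on the fly: published charts have rounded,
slightly asymmetric limits (the fixture's 100 µL chart prints 5.20–8.92
about a center of 7.00), and `ControlChart.from_limits` keeps such limits
verbatim (sigma = span/6, warning limits two-thirds of the way to each
control limit). `scale_chart` multiplies center, sigma and all four
limits, so printed limits scale exactly as printed (×0.75 → 3.90–6.69,
×0.10 → 0.52–0.89).

Out-of-control rules: R1, a single point strictly beyond a control limit;
R2, two of any three consecutive points strictly beyond the same warning
limit on the same side, indexed at the window's last point. "Beyond" is
strict inequality; points on a limit are in control. Under in-control
Poisson(7) monitoring with the chart's own parameters the per-point R1
rate is ≈ 0.6%, below the 2% bound asserted in the suite (counts are
skewed, so the normal ±3s calibration is only approximate).

## Accuracy/specificity bootstrap

The study states that simulated positive/negative counts were compared to
the reference method's real values "to calculate the accuracy and the
specificity" without defining either. The operationalization here (the one
that reproduces the published point accuracy exactly):

With per-volume rates λ_v estimated from the candidate method's own
positive fractions (at 10 µL the detection-limit fraction 15/42 is used,
not the reference's 17/42 — only that choice yields the published number),
expected positives E_v = n_v(1 − e^−λ_v), reference positives ref_v, and
N = Σn_v:

    accuracy    = 100 · (N − Σ_v |E_v − ref_v|) / N
    specificity = 100 · Σ_v min(n_v − E_v, n_v − ref_v) / Σ_v (n_v − ref_v)

With E = (15, 13), ref = (17, 13), N = 60: accuracy = 100·58/60 = 96.67%.
Each of the 10,000 bootstrap runs redraws k_v ~ Binomial(n_v, 1 − e^−λ_v)
and scores the same formulas with k_v in place of E_v; CIs are percentile
intervals over runs. Specificity is undefined (None) when the reference
saw no negative vessels. The published specificity (97.78%, CI 94.3–100%)
is **not** reproduced by this or any standard definition we could
construct from the published counts; it is kept as fixture data and the
implementation's specificity is validated by property tests (bounds,
determinism, degenerate cases) only.

RNG discipline: one `SeedSequence` per top-level call, spawned into one
child stream per volume, so results are bit-reproducible for a seed and
enlarging `runs` extends rather than reshuffles the draw sequence.

## Equivalence interval for the detection limit

The study reports a range of λ values "which did not statistically differ"
from the reference rate under a KS test, without sample sizes or replicate
counts. The procedure implemented: on the grid λ_ref ± 1 (step
`grid_step`, anchored at λ_ref, truncated at 0), each candidate is tested
by drawing `runs` pairs of size-n Poisson samples at (λ_cand, λ_ref) and
applying the asymptotic two-sample KS test at level α; the candidate is
accepted when its rejection fraction is at most α + 2·sqrt(α(1−α)/runs)
(nominal level plus two Monte-Carlo standard errors — the reference itself
is always accepted under this band, and the KS test's conservatism on
tied counts pushes null rejection below α). The interval is the maximal
contiguous accepted region containing λ_ref, found by walking outward to
the first rejection on each side. Each candidate draws from a seed keyed
by (seed, grid offset), so the result is independent of scan order and
comparable across n at a fixed seed.

Defaults: runs = 300, grid_step = 0.02, α = 0.05. At n = 42 and
λ_ref = 0.4418 the interval is ≈ (0.22, 0.68) — wider than the published
0.4032–0.4826, whose generating procedure (sample sizes, replicates,
whether counts or binary outcomes were compared) is not recoverable; the
published endpoints are fixture data and the implementation is validated
by its properties (contains λ_ref; width shrinks monotonically in n;
gross separation rejected outright).

## Two-proportion test

Pearson chi-squared on the pooled 2×2 table with optional Yates continuity
correction (the default, matching the classical equal-proportions test).
Degenerate tables (pooled proportion 0 or 1) return (0, 1) rather than
dividing by zero. Without the correction the statistic equals the square
of the pooled two-sample z statistic; a test asserts the identity to
1e-10. This replaces the study's Wilcoxon comparison, whose pairing of
observations is not stated and which is deliberately not implemented.

## Synthetic data

The generator defaults *are* the study conditions: concentration
70 PFU/mL (the middle of the stated 50–100 range, chosen so the 100 µL
per-vessel rate is 7.0, matching the fixture's chart center), volumes
(0, 10, 25, 75, 100) µL, vessel counts (80, 42, 18, 10, 10), 20-vial
control baselines. Positivity in generated data is exactly
(true count ≥ 1), cross-checked per vessel in the suite. The generator
emulates Poisson sampling only — no plating losses, operator effects,
assay-chemistry kinetics or aggregation — so passing tests demonstrate
the statistical machinery under the model's own assumptions, not method
performance on real water samples.

The negative-binomial generator (mean, dispersion k) supplies
overdispersed misspecification inputs for the fitting tests, matching the
fitter's parameterization.

## Problem sizes and numerical choices

Simulation-based checks run at: 2000 replicates for CI coverage and GOF
type-I error; 50 seeds for AIC selection and end-to-end rate recovery
(n = 500 vessels); 300 KS replicates per grid candidate for the
equivalence interval. These sizes put Monte-Carlo standard errors well
inside the asserted margins (e.g. rejection-rate SE ≈ 0.5% against a
[3%, 7%] band) while keeping the full suite under a minute of simulation
time. Probabilities use `expm1`/`log1p` where cancellation matters; the
normal quantile is taken at full precision (1.959964…), never 1.96.

## Known limitations

* The Jarvis delta-method interval is asymptotic; at x = 1 or x = n−1 its
  coverage dips toward the 90% floor the suite asserts.
* The chi-squared GOF uses parameters estimated from the ungrouped data,
  so its null distribution lies between χ²(k−1−p) and χ²(k−1); the
  simulated calibration shows the effect is small at the study's sizes.
* The equivalence procedure is one defensible reading of an
  under-specified published analysis; its endpoints are not comparable to
  the published ones, only its qualitative properties are.
* Control-limit calibration assumes approximate normality of counts;
  for centers below ~5 the ±3s false-alarm rate departs visibly from the
  nominal 0.27%.
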