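# Methods

## Problem and model

A ratio-scaled diagnostic variable x is measured in two categories,
"healthy" (label 0) and "diseased" (label 1), with the diseased distribution
lying to the right of the healthy one. A cut-off c dichotomizes the test
(positive if x ≥ c) and induces a 2×2 contingency table with sensitivity
Se = tp/(tp+fn) and specificity Sp = tn/(fp+tn). Three cut-off selectors are
compared:

1. **Youden index**: maximize J = Se + Sp − 1 over a cut-off grid.
2. **Mutual information**: maximize
   MI = Σᵢⱼ pᵢⱼ log₂[pᵢⱼ/(pᵢ·p·ⱼ)] of the 2×2 table (relative frequencies;
   0·log 0 := 0), over the same grid.
3. **Likelihood ratio (LR)**: fit the logistic model
   P(label = 1 | x) = expit(α₀ + α₁x) by maximum likelihood. Because the
   fitted intercept absorbs the sample's pre-test odds, the log
   likelihood-ratio function is log LR(x) = α₀ + α₁x − log[P(D)/(1−P(D))],
   and the cut-off is its root x\* = (log[P(D)/(1−P(D))] − α₀)/α₁, the point
   where post-test equals pre-test probability. Post-test probability curves
   for any target prevalence p follow from
   post-odds = p/(1−p) · LR(x).

The reference value for bias is the crossing point of the two category
densities, where (1−w)·f_h(x) = w·f_d(x); with equal weights w = 0.5 this is
the point where the dominant category flips for an equal-prevalence
population. Weighted crossings (w = target prevalence) quantify how much the
reference itself moves with prevalence.

## Distribution scenarios

Four built-in scenario pairs (all positive-support):

| scenario  | healthy            | diseased             | separation        |
|-----------|--------------------|----------------------|-------------------|
| scenario1 | lognormal(2.0, 0.4)| lognormal(2.5, 0.3)  | moderate          |
| scenario2 | χ², df = 7         | χ², df = 10          | weak              |
| scenario3 | inv-gamma(6, 20)   | inv-gamma(3, 20)     | moderate, skewed  |
| scenario4 | χ², df = 6         | Weibull(10, 20)      | strong            |

Lognormal parameters are on the log scale (μ, σ); the inverse gamma uses
shape/scale with density ∝ x^(−α−1)·e^(−β/x); the Weibull uses shape/scale
with density (k/λ)(x/λ)^(k−1)e^(−(x/λ)^k). These conventions are pinned down
by the known crossing points of the four pairs (9.20041, 7.47228, 5.10873,
13.4333), which this parameterization reproduces to all printed digits;
a unit test asserts this.

## Numerical choices

- **Crossing solver**: the root of g(x) = (1−w)f_h − w·f_d is bracketed by a
  4096-point scan between the two medians and refined by Brent's method to
  1e−6 absolute tolerance. Restricting to the inter-median interval is
  deliberate: densities from different families can cross again in the far
  tails, but the decision-relevant crossing is where the dominant category
  flips. No sign change raises a "no crossing" error; multiple sign changes
  raise an "ambiguous crossing" error rather than silently picking one.
- **Cut-off grid**: candidates run from the sample minimum in steps of
  exactly 1.0 up to the first candidate above the sample maximum (so the
  all-negative table is always evaluated). Ties in the criterion are broken
  toward the smallest cut-off — deterministic, and it favors sensitivity.
  For the Youden criterion the comparison uses the integer score
  tp·n_h + tn·n_d, which is order-equivalent to Se + Sp and makes ties exact;
  for MI, scores within 1e−12 of the maximum are treated as tied, since
  mathematically equal tables can differ in the last floating-point ulp.
  MI is reported in bits; the argmax is invariant to the logarithm base
  (tested).
- **Logistic fitting**: Newton iterations with step halving, starting from
  (logit of prevalence, 0); convergence when the log-likelihood change is
  below 1e−10 or the gradient norm below 1e−8; iteration cap 50. The
  log-likelihood uses `logaddexp` and probabilities use `expit`, so deeply
  separated fits do not overflow. Under quasi-complete separation (frequent
  in scenario 4, where the class supports barely overlap) the estimates at
  the cap are returned flagged `converged=False` — never an exception — and
  still contribute to summaries, with non-convergence counted per cell so
  the effect is auditable. A fit whose slope is not positive has no usable
  LR root; that replication is recorded as failed for the LR method only.
- **Pre-test-odds correction** uses the empirical disease fraction of the
  fitted dataset, not a nominal design value; the two coincide by
  construction for simulated datasets but can differ for user data.
- **LR sensitivity/specificity** are evaluated on the fitting dataset at the
  continuous root x\* (no snapping to the search grid), with the same
  x ≥ cut-off rule as the grid methods.

## Monte Carlo design

A design cell is (scenario, N, P(D)); defaults follow the study conditions:
N ∈ {50, 100, 200}, P(D) = 0.10 … 0.90 in steps of 0.10, 1000 replications
per cell. Each replication draws a dataset of fixed composition — exactly
round(N·P(D)) diseased values, the rest healthy, healthy block drawn first —
so the label split is deterministic, not binomial. Every replication gets
its own RNG substream seeded by (master seed, N, P(D), replication index),
making any single cell bit-reproducible in isolation and independent of
execution order. Summaries report means and sample SDs (n−1 denominator)
over valid replications, plus failed/non-converged counts; LR rows carry the
coefficient means and SDs as well, since the prevalence dependence of α₀,
α₁ and the corrected intercept is itself a quantity of interest.

## What the generator emulates — and what it does not

The simulator produces clean parametric samples at exact composition: no
measurement error beyond the distributions themselves, no label noise, no
censoring or detection limits, no covariates, and a disease composition
fixed by design rather than sampled. Passing tests therefore demonstrate the
comparative behavior of the three selectors under known distributional
shapes — stability of Youden/LR cut-offs across prevalence, the
prevalence-tracking drift of the mutual-information cut-off, the positive
bias and superior precision of the LR method — not their performance under
real-data complications such as mixed or contaminated distributions,
verification bias, or non-representative sampling.

## Design choices on genuinely open points

- The grid is anchored at the sample minimum (not at zero or an integer):
  "the range of all test values" reads most directly as [min, max], and the
  anchor choice only shifts candidates by a fraction of the step.
- Separated logistic fits are included in summaries (flagged) rather than
  discarded: the strongly separated scenario still yields LR summaries, so a
  return-estimates policy is the only one consistent with complete result
  tables; exclusion would also bias the cut-off summaries toward the easier
  replications.
- Sample SD uses the n−1 denominator, the standard choice for empirical SD
  estimates over replications.
- For low-value-indicates-disease tests, the file reader's `invert` flag
  swaps the class labels so the x ≥ c rule stays oriented toward the
  relabelled disease class; reported Se/Sp then refer to the relabelled
  classes.

## Problem sizes used by the shipped checks

The packaged test suite runs the complete study — 4 scenarios × 3 sample
sizes × 9 prevalence cells × 1000 replications — once per session (about a
minute on one CPU) and checks the summary ranges against their published
counterparts; the reproduction script runs the crossing-point solves plus
the scenario-1 N = 200 coefficient experiment (2 × 1000 replications).

## Known limitations

- The 1.0-unit grid step is coarse relative to scenario 3's scale (optimal
  cut-offs near 5.1), exactly as in the original design; cut-off resolution
  for the two non-parametric methods is limited accordingly.
- Mean LR sensitivity computed on the fitting data carries a small optimism
  at extreme prevalence (about +0.009 at P(D) = 0.10 with 20 diseased cases
  per replication of N = 200, relative to evaluating the same cut-offs on
  the true diseased distribution); specificity, supported by 180 healthy
  cases, shows no measurable optimism.
- Only two-category problems and a single test variable are supported;
  multi-category generalizations, ROC/AUC machinery, utility weighting and
  confidence intervals for x\* are out of scope.
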