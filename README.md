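# cutpointsim

Choosing a binary cut-off for a ratio-scaled diagnostic test — "call the
result positive if the measured value x is at least c" — is a recurring
problem in laboratory medicine and epidemiology. `cutpointsim` implements
and compares three standard answers on a common footing:

- **Youden index method** — grid-search the cut-off maximizing
  J = Se + Sp − 1, where Se = tp/(tp+fn) and Sp = tn/(fp+tn) come from the
  2×2 table induced by the cut-off;
- **Mutual information method** — grid-search the cut-off maximizing the
  mutual information (in bits) between disease status and the dichotomized
  test result;
- **Likelihood-ratio (LR) method** — fit a logistic regression of the
  disease label on x, correct the intercept for the sample's pre-test odds,

  log LR(x) = α₀ + α₁·x − log[P(D)/(1−P(D))],

  and take the cut-off x\* where LR(x\*) = 1, i.e. where a test result
  leaves the disease probability unchanged. The corrected LR function also
  yields transferable post-test probability curves via
  post-odds = pre-odds × LR(x).

The package ships a Monte Carlo engine that evaluates the bias and precision
of the three methods across four built-in distributional scenarios
(lognormal vs lognormal; χ²₇ vs χ²₁₀; inverse-gamma(6, 20) vs
inverse-gamma(3, 20); χ²₆ vs Weibull(10, 20)), sample sizes N ∈ {50, 100, 200}
and pre-test probabilities P(D) from 0.10 to 0.90. The bias reference is the
analytic crossing point of the two category densities, solved by bracketed
root finding (optionally prevalence-weighted).

## Worked example

```python
import numpy as np
from cutpointsim import (crossing_point, generate_dataset, get_scenario,
                         run_replication, Method)

scenario = get_scenario("scenario1")          # lognormal(2.0, 0.4) vs (2.5, 0.3)
rng = np.random.default_rng(7)
data = generate_dataset(scenario, n_total=200, p_d=0.3, rng=rng)

print(crossing_point(scenario.healthy, scenario.diseased, 0.5).x_star)
result = run_replication(data)
for method in Method:
    est = result.estimates[method]
    print(method.value, est.cutoff, est.sensitivity, est.specificity)
```

prints (abridged):

```
9.200406331664125
mutual_information  cutoff = 8.700  Se = 0.900  Sp = 0.757
youden              cutoff = 8.700  Se = 0.900  Sp = 0.757
likelihood_ratio    cutoff = 9.563  Se = 0.867  Sp = 0.793
```

The analytic crossing point of the two densities is 9.20; on this draw the
two non-parametric grid searches pick 8.7 (within one grid step of it),
while the LR method's root sits slightly higher with higher specificity and
lower sensitivity — its characteristic positive bias.

The `examples/` directory contains one short script per capability
(crossing points, applying the methods, the Monte Carlo range report,
post-test probability curves), each printing the numbers it computes and a
line on what they mean.

## Command line

```sh
cutpointsim crossings --scenario scenario4 --pd 0.10      # weighted crossings
cutpointsim simulate --scenario scenario1 --n 200 --reps 1000 --seed 42 \
    --out-dir results/                                    # summary + ranges
cutpointsim apply mydata.csv                              # 3 methods on a file
```

`apply` reads a two-column delimited file of (value, 0/1 label). `simulate`
writes a full-precision long-format `summary.csv`, a `ranges.csv` of
min–max-over-P(D) cells, and a human-readable `ranges.txt`.

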