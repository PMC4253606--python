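"""Apply all three cut-off methods to one synthetic dataset.

Draws a single scenario-1 dataset (lognormal healthy vs diseased arms,
N = 200 at 30% prevalence) and compares the cut-offs chosen by maximizing
mutual information, maximizing the Youden index, and the logistic
likelihood-ratio method, against the analytic crossing point 9.20.
"""

import numpy as np

from cutpointsim import Method, crossing_point, generate_dataset, get_scenario, run_replication

scenario = get_scenario("scenario1")
rng = np.random.default_rng(7)
data = generate_dataset(scenario, n_total=200, p_d=0.3, rng=rng)

result = run_replication(data)
reference = crossing_point(scenario.healthy, scenario.diseased, 0.5).x_star
print(f"analytic crossing point (reference): {reference:.3f}\n")

for method in Method:
    est = result.estimates[method]
    print(
        f"{method.value:>20s}: cutoff = {est.cutoff:6.3f}  "
        f"Se = {est.sensitivity:.3f}  Sp = {est.specificity:.3f}"
    )

fit = result.fit
print(
    f"\nlogistic fit: alpha0 = {fit.alpha0:.3f}, alpha1 = {fit.alpha1:.3f}, "
    f"corrected intercept = {fit.alpha0_corrected:.3f} (converged: {fit.converged})"
)
print(
    "\nThe two grid methods land within about one grid step of the reference;"
    "\nthe LR cut-off is the root of the corrected linear predictor and sits"
    "\nslightly above it (the method's characteristic positive bias)."
)
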