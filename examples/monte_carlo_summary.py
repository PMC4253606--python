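"""A reduced Monte Carlo experiment with the summary range report.

Runs scenario 1 at N = 200 with 200 replications per prevalence cell
(the full study uses 1000) and prints the range report: for each method,
the min-max over P(D) = 0.1 .. 0.9 of the mean (and SD) cut-off,
sensitivity and specificity.
"""

from cutpointsim import (
    ExperimentDesign,
    format_range_report,
    get_scenario,
    run_experiment,
    summary_ranges,
)

design = ExperimentDesign(
    scenario=get_scenario("scenario1"), n_total=200, n_reps=200, seed=42
)
summary = run_experiment(design)
print(format_range_report(summary_ranges(summary)))
print(
    "Reading the report: Youden and LR mean cut-offs barely move across the"
    "\nwhole P(D) range (stability), the mutual-information column spans a much"
    "\nwider band (its cut-off tracks prevalence), and the SD ranges order the"
    "\nmethods' precision as LR < Youden < mutual information."
)
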