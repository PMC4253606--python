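"""Analytic density crossing points for the four built-in scenarios.

The crossing point of the two category densities is the theoretical optimum
cut-off: below it the healthy density dominates, above it the diseased one.
Weighting the densities by pre-test probability moves the crossing, which is
why the unweighted (equal-weight) crossing is used as the stable reference.
"""

from cutpointsim import SCENARIOS, crossing_point

for name, scenario in SCENARIOS.items():
    cp = crossing_point(scenario.healthy, scenario.diseased, 0.5)
    print(f"{name}: equal-weight crossing at x* = {cp.x_star:.5f}")

print()
scenario4 = SCENARIOS["scenario4"]
for p_d in (0.10, 0.50, 0.90):
    cp = crossing_point(scenario4.healthy, scenario4.diseased, p_d)
    print(f"scenario4 weighted by P(D) = {p_d:.2f}: x* = {cp.x_star:.3f}")

print(
    "\nThe weighted scenario-4 crossing drops as P(D) rises: with more of the"
    "\nprobability mass on the diseased side, the dominant category flips at a"
    "\nlower test value."
)
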