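"""Render the accuracy-vs-information quadrant scatter.

Each point is one feature: x = Youden's J, y = fraction of entropy
removed.  Dashed cutlines at J = 0.60 and ER = 0.40 divide the plane
into four quadrants of diagnostic practicality.
"""

from entrodx import SynthConfig, evaluate_table, generate_cohort, quadrant_plot

results = evaluate_table(generate_cohort(SynthConfig(seed=42))).results
path = quadrant_plot(results, "quadrants.svg")
print(f"wrote {path}: {len(results)} features; points right of the vertical line are")
print("high-accuracy, points above the horizontal line are high-information.")
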