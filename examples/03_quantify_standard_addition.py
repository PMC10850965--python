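"""Quantify an unknown by the modified standard-addition method.

Aliquots of a cream with unknown urea content (truth: 10 % w/w) are spiked
with 0/5/10/15 % w/w additions and photographed next to a 10 % w/w
reference standard plus calibration standards.  Because the response is
nonlinear below ~2.5 % w/w, the addition line is extrapolated to the
reference standard's signal instead of to zero:

    c0 = c_ref + (a - y_ref) / b
"""

import pandas as pd

import dicplate as dp
from dicplate.pipeline import analyze_plate

TRUE_C0 = 10.0
entries = [
    ("S01", "spiked_sample", "cream_b", TRUE_C0, 0.0),
    ("S02", "spiked_sample", "cream_b", TRUE_C0, 5.0),
    ("S03", "spiked_sample", "cream_b", TRUE_C0, 10.0),
    ("S04", "spiked_sample", "cream_b", TRUE_C0, 15.0),
    ("R01", "reference_standard", "cream_b", 10.0, None),
] + [
    (f"C{i:02d}", "standard", "cream_b", conc, None)
    for i, conc in enumerate(dp.DEFAULT_STANDARD_LEVELS)
]
plate_map = pd.DataFrame(
    entries, columns=["well_id", "role", "matrix", "nominal_conc", "added_conc"]
)

model = dp.ResponseModel()
grid = dp.strip_grid(len(plate_map))
image, _ = dp.render_plate(model, plate_map, grid, seed=21)

analysis = analyze_plate(image, plate_map, grid)
row = analysis.results[analysis.results["method"] == "standard_addition"].iloc[0]

print(f"standard-addition estimate: {row['estimate']:.2f} % w/w "
      f"(truth {TRUE_C0:.2f}, addition-line r^2 {row['r2']:.4f})")
print(f"bias: {dp.bias_percent(row['estimate'], TRUE_C0):+.2f} %")
print("\nthe estimate comes from extrapolating the fitted addition line to "
      "the in-photo reference standard; a bias within ~+/-11 % matches the "
      "method's documented standard-addition accuracy.")
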