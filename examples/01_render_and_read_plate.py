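"""Render a synthetic microstrip photo and extract per-well color statistics.

A strip of eight wells holds an o/w cream spiked with increasing urea.
Residual methyl-red color grows with urea (urea consumes the hypochlorite
bleach), so the blue channel falls linearly with concentration.
"""

import dicplate as dp

model = dp.ResponseModel().noiseless()  # switch off noise to see the pure response
levels = (2.52, 6.03, 10.07, 14.0, 18.13, 23.32, 27.21, 30.03)

plate_map = dp.standards_plate_map(levels)
grid = dp.strip_grid(len(levels))
image, manifest = dp.render_plate(model, plate_map, grid, seed=0)

layout = dp.locate_wells(image, grid)
observations = dp.read_plate(image, layout, plate_map)

print(f"{'well':>5} {'urea %w/w':>10} {'blue mean':>10} {'model value':>12} {'masked':>7}")
for obs, truth in zip(observations, manifest.wells):
    print(
        f"{obs.well_id:>5} {obs.nominal_conc:10.2f} {obs.signal('blue'):10.2f} "
        f"{truth['response_rgb'][2]:12.2f} {obs.masked_fraction:7.1%}"
    )
print(
    "\nEach ROI mean tracks the configured blue response within 8-bit "
    "quantization; masked fraction 0% means no glare/bubble pixels."
)
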