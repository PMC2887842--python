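"""Solve the intraurethral stimulation field for a ring electrode.

Builds the parametric cat-urethra voxel model, places a 1 mm ring contact
2 cm from the meatus, drives 1 mA cathodic regulated current, and reports
the potential at a few landmarks.
"""

import numpy as np

import iesim

params = iesim.AnatomyParams.desk_scale()
model = iesim.build_anatomy(params)
placed = iesim.place_catheter(model, "ring-1mm", depth_cm=2.0)
field = iesim.solve_potential(placed)

print(f"grid: {model.grid.shape} = {model.grid.n_cells:,} voxels")
print(f"compartments: {sorted(model.present_labels())}")
print(f"solver relative residual: {field.residual:.2e}")

landmarks = {
    "urethral wall at the contact (x=20, r=1.3)": [20.0, 0.0, 1.3],
    "DNP trunk above the contact (x=20, z=6.5)": [20.0, 1.5, 6.5],
    "CSN, membranous urethra (x=60, z=5.9)": [60.0, 2.0, 5.9],
}
for name, pt in landmarks.items():
    v = field.at([pt])[0]
    print(f"  V at {name}: {1e3 * v:8.2f} mV")

print(
    "\nThe potential is negative everywhere (cathodic stimulus, grounded far\n"
    "boundary) and largest in magnitude at the urethral wall beside the\n"
    "contact; it decays only about tenfold over the 4 cm to the membranous\n"
    "urethra because the low-conductivity surroundings channel current\n"
    "axially along the urethra."
)
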