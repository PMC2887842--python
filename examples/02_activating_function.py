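"""Activating function along the dorsal penile nerve.

Samples the extracellular potential at 0.1 mm steps along the bilateral DNP
trunks, evaluates the second-difference activating function on the nodal
grid (l = 0.5 mm, 5 um fibers) for the five terminal-node offsets, and
summarizes the ensemble.
"""

import numpy as np

import iesim

session = iesim.Session()
field = session.field("ring-1mm", depth_cm=2.0)

path = session.dnp[1]  # right DNP
profile = iesim.sample_potential(field, path)
print(f"{path.name}: {profile.v.size} samples over {path.arclength_mm:.1f} mm")

for offset in range(5):
    af = iesim.activating_function(profile, offset)
    k = int(np.argmax(af.interior_af))
    print(
        f"  offset {offset}: max AF {af.max_af:9.1f} V/m^2 "
        f"(interior peak {af.interior_af[k]:9.1f} at s = {af.node_s_mm[k + 1]:.1f} mm)"
    )

stats = iesim.max_af_stats(field, session.dnp, "DNP")
print(
    f"\nDNP ensemble (5 offsets x 2 sides): {stats.mean:.1f} +- {stats.sd:.1f} V/m^2"
)
print(
    "\nThe peak sits on the trunk directly dorsal to the contact; shifting\n"
    "the node grid by fractions of the internodal length changes the maximum\n"
    "by well under a percent, which is why the ensemble SD is small."
)
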