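"""Sensitivity of the predictions to electrode orientation and catheter fit.

(a) rotates the short sector contact to face ventrally (away from the
nerves); (b) halves the catheter diameter and fills the freed lumen with
urine (sigma = 1.55 S/m), for the ring electrode at 2 and 7 cm.
"""

import iesim

session = iesim.Session()
report = iesim.perturbation_studies(session)

rot = report["short_rotation"]
print(
    f"short contact at {rot['depth_cm']:.0f} cm: dorsal max AF "
    f"{rot['dorsal_max_af']:.0f}, ventral {rot['ventral_max_af']:.0f} "
    f"-> reduction {rot['reduction_pct']:.0f}%"
)
for depth, r in report["half_catheter"].items():
    print(
        f"ring at {depth:.0f} cm ({r['nerve']}): full-diameter {r['full_max_af']:.0f}, "
        f"half + urine {r['half_urine_max_af']:.0f} "
        f"-> reduction {r['reduction_pct']:.0f}%"
    )

print(
    "\nOrientation matters a lot for a sector contact: facing away from the\n"
    "nerves costs about half the drive in this geometry, which is why ring\n"
    "contacts (orientation-independent) are the practical choice.  A loose,\n"
    "thin catheter in a urine-filled lumen loses a fifth to a quarter of\n"
    "the peak activating function: the conductive fluid annulus shunts\n"
    "current axially before it reaches the tissue."
)
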