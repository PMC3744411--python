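"""Receptor-level pharmacology: dose-response curves and nicotine pretreatment.

Builds nothing external: loads the two shipped receptor parameter sets,
scans 200 ms ACh pulse responses, locates the half-maximal concentration,
and measures how much a physiological 0.5 µM nicotine background suppresses
that response for each subtype.
"""

import numpy as np

from vtanic import (
    half_max_concentration,
    load_preset,
    peak_pulse_response,
    pretreatment_reduction,
    s_inf,
)

for name in ("a4b2", "a7"):
    p = load_preset(name)
    ec50 = half_max_concentration(lambda c: peak_pulse_response(c, p))
    reduction = pretreatment_reduction(p, nic_pre=0.5)
    print(f"{name}: pulse EC50 = {ec50:.1f} uM, "
          f"half-max response reduced {reduction:.1f}% by 0.5 uM nicotine")

p = load_preset("a4b2")
print(f"a4b2 desensitized fraction at 0.5 uM nicotine: "
      f"{100 * (1 - s_inf(0.5, p)):.1f}%")

grid = np.geomspace(1, 1000, 7)
peaks = [peak_pulse_response(c, p) for c in grid]
print("a4b2 dose-response (ACh uM -> peak open fraction):")
for c, pk in zip(grid, peaks):
    print(f"  {c:8.1f} -> {pk:.4f}")

# The EC50s sit at the activation half-max constants (30 and 80 uM); the
# strong asymmetry of the pretreatment reduction (~73% vs ~13%) is what makes
# the high-affinity a4b2 subtype the lever for nicotine's circuit effects.
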