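"""How much signal survives under a surface blood vessel?

A 250 um-radius vessel is modelled as a totally absorbing cylinder on
the tissue surface. Paired runs with and without the vessel give the
illumination and collection ratios in the column under its centre line;
their product is the relative widefield fluorescence. Scattered photons
bypass the absorber, so tissue under the vessel still contributes.
"""

import numpy as np

import widefield_mc as wm
from widefield_mc.hemodynamics import BloodOpticalModel, beer_lambert_transmission

t200 = beer_lambert_transmission(BloodOpticalModel(path_length=0.02))
t500 = beer_lambert_transmission(BloodOpticalModel(path_length=0.05))
print(f"Beer-Lambert: 200 um of blood transmits {100 * t200:.1f}%, "
      f"500 um only {100 * t500:.2f}% — treating large vessels as total "
      "absorbers is a mild overestimate")

scene = wm.build_scene("vessel-250um")
shadow = wm.fluorescence_under_vessel(
    scene, wm.TL2X_SAP, np.array([0.5, 1.0]), 200_000, seed=4
)  # bump photons to 1e6 for publication-grade ratios
for d, il, co, fl in zip(shadow.depths, shadow.illumination_ratio,
                         shadow.collection_ratio, shadow.fluorescence_ratio):
    print(f"depth {d:.1f} mm under the vessel centre: illumination x{il:.2f}, "
          f"collection x{co:.2f} -> fluorescence {100 * fl:.1f}% of no-vessel")
print("the shadow weakens with depth as scattered photons wrap around "
      "the vessel")
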