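"""Measure bone volume from a synthetic labeled raster.

Generates a micro-CT-like labeled volume of a cylindrical element with
a known analytic volume and quantifies it by voxel counting at two
resolutions.
"""

import math

from bulkybone import labeled_volume_quantify
from bulkybone.synth import ProfileGenParams, gen_profile_volume

for voxel in (0.04, 0.02):
    vol, exact = gen_profile_volume(ProfileGenParams(voxel=voxel))
    measured = labeled_volume_quantify(vol, label=1)
    print(f"voxel {voxel:.2f} mm: measured {measured:.4f} mm^3, "
          f"analytic {exact:.4f} mm^3, "
          f"error {100 * abs(measured - exact) / exact:.3f}%")

print()
print(f"The analytic solid volume is pi R^2 L = {math.pi * 10:.4f} mm^3; "
      "voxel-centre counting recovers it to well under 1% at 0.02 mm "
      "voxels, the scale used for skeletal-element quantification.")
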