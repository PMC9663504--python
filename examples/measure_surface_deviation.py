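"""Nominal/actual comparison of two known surfaces.

Generates a gaussian-bulged rod (the "actual" shape) and a straight
cylinder (the "nominal" reference), maps the exact closest-point
deviation of every actual vertex, and checks the map against the
generator's analytic ground truth.
"""

import numpy as np

from bulkybone import surface_deviation
from bulkybone.synth import gen_surface_pair

test, ref, expected, lateral = gen_surface_pair(
    "bulge_vs_straight", delta=0.3, n_z=80, n_theta=48)

dm = surface_deviation(test.vertices, ref.vertices, ref.tris,
                       summary_mask=lateral)

z = test.vertices[lateral, 2]
print(f"mean deviation      : {dm.mean:.4f} mm")
print(f"max deviation       : {dm.max:.4f} mm  (analytic bump height 0.3 mm)")
print(f"95th percentile     : {dm.p95:.4f} mm")
print(f"max located at z    : {z[np.argmax(dm.distance[lateral])]:.2f} mm "
      f"(bump centre at 5.00 mm)")
print(f"worst error vs truth: "
      f"{np.abs(dm.distance[lateral] - expected).max():.2e} mm")
print()
print("Each actual-surface vertex carries its exact distance to the "
      "nominal triangle set, signed by side; the map localises the bulge "
      "at mid-shaft and matches the generator's analytic profile "
      "difference to discretization accuracy.")
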