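"""Simulate long-bone growth under the two loading configurations.

Builds a cylinder mesh of a rod-shaped skeletal element, applies the
uniform (regeneration) and the centre-graded (development) internal
growth pressures at matched total radial drive, and compares the
resulting shapes.
"""

import json

from bulkybone import CylinderSpec, RunConfig, run_pipeline

# A coarser mesh than the library default keeps this demo to a few seconds.
cfg = RunConfig(geometry=CylinderSpec(10.0, 1.0, 40, 8, 16))
res = run_pipeline(cfg, outdir="scratch/growth_demo")

s = res.summary
print(json.dumps(s, indent=2, sort_keys=True))
print()
print(f"bulge index regeneration : {s['bulge_index']['regeneration']:.3f}")
print(f"bulge index development  : {s['bulge_index']['development']:.3f}")
print(f"outward deviation band at axial fraction "
      f"{s['deviation_band_axial_fraction']:.2f}")
print()
print("The bulge index is the mid-shaft over end-band effective-radius "
      "ratio: > 1 means a bulky mid-shaft.  Uniform regenerative growth "
      "pressure bulges the shaft more than development's centre-suppressed "
      "pressure at the same total radial drive, and the band where the "
      "regenerated surface stands proud of the developed one sits at "
      "mid-shaft — the regenerated-bone phenotype.")
print("Deformed meshes and the deviation heat-map were written to "
      "scratch/growth_demo/*.vtu (viewable in ParaView).")
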