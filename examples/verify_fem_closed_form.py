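"""Verify the elasticity solver against a closed-form solution.

A cylinder on a roller base is loaded with a fixed axial force
F = sigma * pi R^2 spread over its free end.  The continuum solution is
homogeneous uniaxial stress: tip extension sigma L / E and lateral
Poisson contraction -nu sigma R / E.  The measured error equals the
cap-area discretization error of the inscribed-polygon cross-section
and shrinks as the angular resolution grows.
"""

from bulkybone import CylinderSpec, Material
from bulkybone.fem import uniaxial_verification

for n_angular in (8, 16, 32):
    spec = CylinderSpec(10.0, 1.0, 20, 5, n_angular)
    out = uniaxial_verification(spec, Material(1.0, 0.40), sigma_fraction=0.01)
    print(f"n_angular={n_angular:3d}  tip u_z={out['tip_uz_mm']:.6f} mm "
          f"(exact {out['tip_uz_exact_mm']:.6f})  "
          f"rel err={100 * out['tip_rel_err']:.3f}%")

print()
print("The tip displacement converges to sigma*L/E = 0.1 mm from above "
      "as the polygonal cross-section approaches the circle; at the "
      "library's default resolution (n_angular=20) the error is ~1.7%.")
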