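"""Loading scenarios for development vs regeneration.

Two configurations of internal growth pressures shape the elastic rod:

* **regeneration** — every axial region carries the same axial and
  radial force-density moduli (growth by cartilage expansion with
  delayed ossification, unhindered along the whole shaft);
* **development** — radial moduli are graded, smallest at the mid-shaft
  and rising linearly (in region index) toward both ends, emulating how
  early cortical ossification at the centre mechanically suppresses
  transversal expansion there.

The grading is a symmetric piecewise-linear ramp controlled by a centre
fraction ``c`` in (0, 1]: the central region's radial modulus is
``c * f_r0``, the two end regions get the full ``f_r0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fem import Material, RegionLoading
from .mesh import RegionPartition, TetMesh, DEFAULT_PARTITION, region_volumes

__all__ = [
    "Scenario",
    "make_scenario",
    "development_ramp",
    "total_radial_impulse",
    "match_radial_impulse",
]


@dataclass(frozen=True)
class Scenario:
    """A named, fully declarative loading configuration."""

    name: str
    partition: RegionPartition
    loads: RegionLoading
    material: Material = field(default_factory=Material)
    normalization: float = 0.2  # target max |u| as a fraction of R; None disables

    def __post_init__(self):
        if self.name not in ("development", "regeneration", "custom"):
            raise ValueError(f"unknown scenario name {self.name!r}")
        regions = set(range(1, self.partition.n_regions + 1))
        covered = set(self.loads.axial) & set(self.loads.radial)
        if not regions <= covered:
            raise ValueError(
                f"loads must cover all regions {sorted(regions)}; "
                f"covered {sorted(covered)}"
            )
        fr = [self.loads.radial[k] for k in sorted(regions)]
        if self.name == "regeneration" and len(set(np.round(fr, 12))) != 1:
            raise ValueError("regeneration scenario requires uniform radial moduli")
        if self.name == "development":
            n = len(fr)
            mid = (n - 1) // 2
            left, right = fr[: mid + 1], fr[n // 2:]
            if not (
                all(np.diff(left) <= 1e-12)
                and all(np.diff(right) >= -1e-12)
                and fr[mid] < fr[0]
                and fr[mid] < fr[-1]
            ):
                raise ValueError(
                    "development scenario requires radial moduli decreasing toward "
                    "the centre and strictly smaller there than at the ends"
                )

    def with_loads(self, loads: RegionLoading) -> "Scenario":
        return replace(self, loads=loads)


def development_ramp(n_regions: int, center_fraction: float) -> np.ndarray:
    """Symmetric linear ramp over region indices.

    Equals ``center_fraction`` at the central region and 1.0 at both end
    regions; linear in region index on each side.  For an even region
    count the two middle regions share the minimum-adjacent values.
    """
    if not (0 < center_fraction <= 1):
        raise ValueError(f"center_fraction must lie in (0, 1], got {center_fraction}")
    if n_regions < 3:
        raise ValueError("development grading needs at least 3 regions")
    m = (n_regions - 1) / 2.0
    k = np.arange(n_regions)
    return center_fraction + (1.0 - center_fraction) * np.abs(k - m) / m


def make_scenario(
    name: str,
    f_a0: float = 1.0,
    f_r0: float = 1.0,
    partition: RegionPartition = DEFAULT_PARTITION,
    center_fraction: float = 0.2,
    material: Material = None,
    normalization: float = 0.2,
) -> Scenario:
    """Build a development or regeneration scenario.

    ``f_a0`` / ``f_r0`` are the base axial/radial force-density moduli
    (kPa/mm).  Regeneration assigns (f_a0, f_r0) to every region;
    development keeps axial moduli at f_a0 but multiplies the radial
    modulus of region k by the symmetric ramp (see
    :func:`development_ramp`).
    """
    if material is None:
        material = Material()
    n = partition.n_regions
    regions = list(range(1, n + 1))
    axial = {k: float(f_a0) for k in regions}
    if name == "regeneration":
        radial = {k: float(f_r0) for k in regions}
    elif name == "development":
        ramp = development_ramp(n, center_fraction)
        radial = {k: float(f_r0 * ramp[k - 1]) for k in regions}
    else:
        raise ValueError(f"make_scenario builds 'development' or 'regeneration', got {name!r}")
    return Scenario(
        name=name,
        partition=partition,
        loads=RegionLoading(axial=axial, radial=radial),
        material=material,
        normalization=normalization,
    )


def total_radial_impulse(scenario: Scenario, mesh: TetMesh) -> float:
    """Sum over regions of |f_r| x region volume (kPa mm^2 equivalent).

    A scalar measure of the total radial growth drive, used to compare
    scenarios at matched load.
    """
    n = scenario.partition.n_regions
    present = np.unique(mesh.region_of_tet)
    if present.min() < 1 or present.max() > n:
        raise ValueError(
            f"mesh region labels {present.tolist()} do not match the "
            f"scenario partition with {n} regions"
        )
    vols = region_volumes(mesh, n)
    return float(
        sum(abs(scenario.loads.radial[k]) * vols[k - 1] for k in range(1, n + 1))
    )


def match_radial_impulse(scenario: Scenario, reference: Scenario, mesh: TetMesh) -> Scenario:
    """Rescale ``scenario``'s radial moduli so its total radial impulse
    equals the reference's on the given mesh.  Axial moduli unchanged."""
    own = total_radial_impulse(scenario, mesh)
    target = total_radial_impulse(reference, mesh)
    if own == 0:
        raise ValueError("cannot match impulse: scenario has zero radial impulse")
    s = target / own
    loads = RegionLoading(
        axial=dict(scenario.loads.axial),
        radial={k: v * s for k, v in scenario.loads.radial.items()},
    )
    return scenario.with_loads(loads)
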