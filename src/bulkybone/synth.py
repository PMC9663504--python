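"""Synthetic data generators with analytic ground truth.

Everything downstream stages consume can be generated here: doublet
point-pairs with a controlled axial-angle distribution (emulating EdU
doublet measurements), labeled cylinder volumes with analytic radial
profiles (emulating segmented micro-CT rasters), and paired surfaces
with a closed-form deviation field.  Every generator is deterministic
under its seed and returns the analytic ground truth beside the data so
downstream oracles never re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.integrate import quad

from .mesh import CylinderSpec
from .orientation import DoubletSet
from .shape import LabeledVolume

__all__ = [
    "DoubletGenParams",
    "ProfileGenParams",
    "TriSurface",
    "truncated_normal_mean",
    "gen_doublets",
    "radial_profile",
    "gen_profile_volume",
    "revolve_profile",
    "gen_surface_pair",
]


@dataclass(frozen=True)
class TriSurface:
    """Plain triangulated surface (vertices mm, triangle vertex indices)."""

    vertices: np.ndarray
    tris: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "vertices", np.asarray(self.vertices, dtype=float))
        object.__setattr__(self, "tris", np.asarray(self.tris, dtype=np.int64))


# ----------------------------------------------------------- doublets


@dataclass(frozen=True)
class DoubletGenParams:
    """Parameters of the synthetic doublet generator.

    The division axis polar angle (to the bone axis) is drawn from a
    normal(mean_angle, sd_angle) truncated to [0°, 90°]; the azimuth is
    uniform; doublet midpoints are uniform inside the cylinder.
    """

    n: int = 100
    mean_angle: float = 70.0
    sd_angle: float = 10.0
    doublet_length: float = 0.02  # mm, daughter-nucleus separation
    domain: CylinderSpec = field(default_factory=CylinderSpec)
    seed: int = 0
    group: str = "synthetic"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0 <= self.mean_angle <= 90):
            raise ValueError("mean_angle must lie in [0, 90] degrees")
        if not self.sd_angle > 0:
            raise ValueError("sd_angle must be positive")
        if not self.doublet_length > 0:
            raise ValueError("doublet_length must be positive")


def truncated_normal_mean(mean: float, sd: float, lo: float = 0.0, hi: float = 90.0) -> float:
    """Analytic mean of a normal(mean, sd) truncated to [lo, hi]."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.mean(a, b, loc=mean, scale=sd))


def gen_doublets(params: DoubletGenParams) -> DoubletSet:
    """Sample a synthetic :class:`DoubletSet`; byte-identical under seed."""
    rng = np.random.default_rng(params.seed)
    a, b = (0.0 - params.mean_angle) / params.sd_angle, (
        90.0 - params.mean_angle
    ) / params.sd_angle
    theta = np.radians(
        stats.truncnorm.rvs(
            a, b, loc=params.mean_angle, scale=params.sd_angle,
            size=params.n, random_state=rng,
        )
    )
    phi = rng.uniform(0.0, 2 * np.pi, params.n)
    direction = np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    R, L = params.domain.radius_mm, params.domain.length_mm
    r = R * np.sqrt(rng.uniform(0.0, 1.0, params.n))
    ang = rng.uniform(0.0, 2 * np.pi, params.n)
    mid = np.column_stack(
        [r * np.cos(ang), r * np.sin(ang), rng.uniform(0.0, L, params.n)]
    )
    half = 0.5 * params.doublet_length * direction
    return DoubletSet(
        points_a=mid - half,
        points_b=mid + half,
        groups=np.full(params.n, params.group, dtype=object),
        axis=np.array([0.0, 0.0, 1.0]),
    )


# ----------------------------------------------- labeled volumes / surfaces


PROFILE_KINDS = ("constant", "gaussian_bulge", "gaussian_waist", "linear_taper")


@dataclass(frozen=True)
class ProfileGenParams:
    """Axisymmetric radius profile r(z) of a synthetic skeletal element."""

    base_radius: float = 1.0
    kind: str = "constant"
    amplitude: float = 0.0  # mm; bump/waist height or total taper drop
    width: float = 2.0  # mm; gaussian width
    length: float = 10.0
    voxel: float = 0.02
    label: int = 1

    def __post_init__(self):
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"kind must be one of {PROFILE_KINDS}, got {self.kind!r}")
        if self.base_radius <= 0 or self.length <= 0 or self.voxel <= 0:
            raise ValueError("base_radius, length and voxel must be positive")
        z = np.linspace(0, self.length, 1001)
        if np.any(radial_profile(self, z) <= 0):
            raise ValueError("profile radius must stay positive over the length")


def radial_profile(params: ProfileGenParams, z) -> np.ndarray:
    """Evaluate r(z) for the given profile parameters."""
    z = np.asarray(z, dtype=float)
    R, A, w, L = params.base_radius, params.amplitude, params.width, params.length
    if params.kind == "constant":
        return np.full_like(z, R)
    if params.kind == "gaussian_bulge":
        return R + A * np.exp(-(((z - L / 2) / w) ** 2))
    if params.kind == "gaussian_waist":
        return R - A * np.exp(-(((z - L / 2) / w) ** 2))
    # linear_taper: radius drops linearly by `amplitude` from z=0 to z=L
    return R - A * z / L


def analytic_profile_volume(params: ProfileGenParams) -> float:
    """Exact solid volume of the revolution body, integral of pi r(z)^2 dz."""
    val, _ = quad(lambda z: np.pi * radial_profile(params, z) ** 2, 0, params.length,
                  limit=200)
    return float(val)


def gen_profile_volume(params: ProfileGenParams) -> tuple:
    """Rasterise the revolution solid into a :class:`LabeledVolume`.

    A voxel is labeled iff its *center* lies within r(z) of the axis.
    Returns (volume, analytic solid volume in mm^3) so tests can compare
    the voxel count against the exact integral.
    """
    h = params.voxel
    rmax = float(
        np.max(radial_profile(params, np.linspace(0, params.length, 2001)))
    )
    nxy = int(np.ceil(2 * rmax / h)) + 2
    nz = int(np.ceil(params.length / h))
    # voxel centers
    xy = (np.arange(nxy) - (nxy - 1) / 2) * h
    zc = (np.arange(nz) + 0.5) * h
    r_of_z = radial_profile(params, zc)
    rr = np.sqrt(xy[:, None] ** 2 + xy[None, :] ** 2)  # (nxy, nxy)
    data = (rr[None, :, :] <= r_of_z[:, None, None]).astype(np.int8) * np.int8(
        params.label
    )
    vol = LabeledVolume(data=data, voxel_mm=h)
    return vol, analytic_profile_volume(params)


def revolve_profile(
    params: ProfileGenParams, n_z: int = 100, n_theta: int = 64, cap: bool = True
) -> TriSurface:
    """Triangulate the surface of revolution of r(z), outward oriented.

    With ``cap=True`` the two ends are closed by triangle fans so the
    surface is watertight.
    """
    if n_z < 2 or n_theta < 6:
        raise ValueError("need n_z >= 2 and n_theta >= 6")
    zs = np.linspace(0.0, params.length, n_z + 1)
    rs = radial_profile(params, zs)
    theta = 2 * np.pi * np.arange(n_theta) / n_theta
    ct, st = np.cos(theta), np.sin(theta)
    verts = np.concatenate(
        [np.column_stack([r * ct, r * st, np.full(n_theta, z)]) for z, r in zip(zs, rs)]
    )
    tris = []
    for i in range(n_z):
        lo, hi = i * n_theta, (i + 1) * n_theta
        for k in range(n_theta):
            k1 = (k + 1) % n_theta
            a, b = lo + k, lo + k1
            c, d = hi + k, hi + k1
            tris.append((a, b, d))  # outward for CCW theta, +z up
            tris.append((a, d, c))
    if cap:
        base_c = len(verts)
        verts = np.vstack([verts, [0.0, 0.0, 0.0], [0.0, 0.0, params.length]])
        top_c = base_c + 1
        top0 = n_z * n_theta
        for k in range(n_theta):
            k1 = (k + 1) % n_theta
            tris.append((base_c, k1, k))  # bottom cap, normal -z
            tris.append((top_c, top0 + k, top0 + k1))  # top cap, normal +z
    return TriSurface(vertices=verts, tris=np.asarray(tris, dtype=np.int64))


def gen_surface_pair(
    kind: str,
    delta: float = 0.2,
    base_radius: float = 1.0,
    length: float = 10.0,
    width: float = 2.0,
    n_z: int = 100,
    n_theta: int = 64,
) -> tuple:
    """Paired test/reference surfaces with a closed-form deviation field.

    ``kind='concentric'``: test is a cylinder of radius R+delta around
    the reference cylinder of radius R — the expected lateral deviation
    is ``delta`` everywhere.  ``kind='bulge_vs_straight'``: test is a
    gaussian-bulged rod against the straight reference — the expected
    deviation at a lateral test vertex at height z is r(z) - R, maximal
    (= delta) at mid-shaft.

    Returns (test surface, reference surface, expected deviation per
    *lateral* test vertex, lateral-vertex mask).  Expected values are
    the analytic normal-offset distances; for gently sloped bulges they
    match the true closest-point distance to first order in the slope.
    """
    if kind == "concentric":
        ref = revolve_profile(
            ProfileGenParams(base_radius=base_radius, kind="constant", length=length),
            n_z=n_z, n_theta=n_theta,
        )
        test = revolve_profile(
            ProfileGenParams(base_radius=base_radius + delta, kind="constant",
                             length=length),
            n_z=n_z, n_theta=n_theta,
        )
        expected_of_z = lambda z: np.full_like(z, abs(delta))
    elif kind == "bulge_vs_straight":
        ref = revolve_profile(
            ProfileGenParams(base_radius=base_radius, kind="constant", length=length),
            n_z=n_z, n_theta=n_theta,
        )
        bulge = ProfileGenParams(
            base_radius=base_radius, kind="gaussian_bulge", amplitude=delta,
            width=width, length=length,
        )
        test = revolve_profile(bulge, n_z=n_z, n_theta=n_theta)
        expected_of_z = lambda z: radial_profile(bulge, z) - base_radius
    else:
        raise ValueError(f"kind must be 'concentric' or 'bulge_vs_straight', got {kind!r}")
    z = test.vertices[:, 2]
    lateral = (z > 1e-9) & (z < length - 1e-9)
    # cap-center vertices sit on the axis; ring vertices at z=0, L are caps' rims
    r = np.linalg.norm(test.vertices[:, :2], axis=1)
    lateral &= r > 1e-9
    expected = expected_of_z(z[lateral])
    return test, ref, expected, lateral
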