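"""Structured tetrahedral meshing of a cylindrical bone rod.

The computational domain is a right circular cylinder — the idealised
rod-shaped cartilage element of a salamander zeugopod — with its axis on
+z and the proximal face at z=0.  The mesh is structured: each axial
layer carries a triangulated disk (a central fan plus concentric
annuli), disks are extruded into triangular prisms, and each prism is
split into three tetrahedra with an index-based diagonal rule that keeps
the mesh conforming.  All lengths are millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CylinderSpec",
    "TetMesh",
    "RegionPartition",
    "MeshQualityReport",
    "InvertedElementError",
    "build_cylinder_mesh",
    "assign_axial_regions",
    "mesh_quality",
    "enclosed_volume",
    "tet_volumes",
    "DEFAULT_PARTITION",
]


class InvertedElementError(ValueError):
    """Raised when one or more tetrahedra have non-positive signed volume."""

    def __init__(self, tet_indices):
        self.tet_indices = list(tet_indices)
        super().__init__(
            f"{len(self.tet_indices)} inverted/degenerate tetrahedra: "
            f"{self.tet_indices[:20]}"
        )


@dataclass(frozen=True)
class CylinderSpec:
    """Geometry and resolution of the cylindrical domain.

    Parameters
    ----------
    length_mm, radius_mm:
        Cylinder length L and radius R in mm.
    n_axial:
        Number of element layers along the axis (>= 2).
    n_radial:
        Number of concentric rings in each disk (>= 1).
    n_angular:
        Number of angular sectors (>= 6, even so the node set is mirror
        symmetric about the x=0 and y=0 planes).
    """

    length_mm: float = 10.0
    radius_mm: float = 1.0
    n_axial: int = 60
    n_radial: int = 10
    n_angular: int = 20

    def __post_init__(self):
        if not self.length_mm > 0:
            raise ValueError(f"length_mm must be positive, got {self.length_mm}")
        if not self.radius_mm > 0:
            raise ValueError(f"radius_mm must be positive, got {self.radius_mm}")
        if int(self.n_axial) < 2:
            raise ValueError(f"n_axial must be >= 2, got {self.n_axial}")
        if int(self.n_radial) < 1:
            raise ValueError(f"n_radial must be >= 1, got {self.n_radial}")
        if int(self.n_angular) < 6:
            raise ValueError(f"n_angular must be >= 6, got {self.n_angular}")
        if int(self.n_angular) % 2 != 0:
            raise ValueError(f"n_angular must be even, got {self.n_angular}")


@dataclass(frozen=True)
class RegionPartition:
    """Axial slab partition given as increasing fractions of the length.

    ``boundaries`` runs from 0 to 1 and delimits ``n_regions`` contiguous
    slabs; region labels are 1..n_regions from proximal to distal.
    """

    boundaries: tuple = (0.0, 0.15, 0.35, 0.65, 0.85, 1.0)

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("boundaries must contain at least 2 values")
        if abs(b[0]) > 1e-12 or abs(b[-1] - 1.0) > 1e-12:
            raise ValueError("boundaries must start at 0 and end at 1")
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", tuple(float(x) for x in b))

    @property
    def n_regions(self) -> int:
        return len(self.boundaries) - 1

    def slab_thicknesses(self) -> np.ndarray:
        return np.diff(np.asarray(self.boundaries))


DEFAULT_PARTITION = RegionPartition()


@dataclass
class TetMesh:
    """Tetrahedral mesh with an explicit bone axis and per-element regions.

    Attributes
    ----------
    vertices : (n_v, 3) float array, mm
    tets : (n_t, 4) int array, positively oriented
    surface_tris : (n_s, 3) int array, outward oriented
    region_of_tet : (n_t,) int array, labels 1..n_regions (0 = unassigned)
    axis : unit 3-vector of the bone axis
    axis_origin : a point on the axis
    """

    vertices: np.ndarray
    tets: np.ndarray
    surface_tris: np.ndarray
    region_of_tet: np.ndarray = None
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    axis_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.surface_tris = np.ascontiguousarray(self.surface_tris, dtype=np.int64)
        if self.region_of_tet is None:
            self.region_of_tet = np.zeros(len(self.tets), dtype=np.int64)
        else:
            self.region_of_tet = np.ascontiguousarray(self.region_of_tet, dtype=np.int64)
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise ValueError("axis must be nonzero")
        self.axis = self.axis / n
        self.axis_origin = np.asarray(self.axis_origin, dtype=float)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        return tet_volumes(self.vertices, self.tets)

    def total_volume(self) -> float:
        return float(self.tet_volumes().sum())

    def axial_coordinate(self, points: np.ndarray) -> np.ndarray:
        """Coordinate along the bone axis, 0 at ``axis_origin``."""
        return (np.asarray(points) - self.axis_origin) @ self.axis

    def radial_vectors(self, points: np.ndarray) -> np.ndarray:
        """Component of (p - origin) perpendicular to the axis."""
        d = np.atleast_2d(points) - self.axis_origin
        return d - np.outer(d @ self.axis, self.axis)

    def copy(self) -> "TetMesh":
        return TetMesh(
            vertices=self.vertices.copy(),
            tets=self.tets.copy(),
            surface_tris=self.surface_tris.copy(),
            region_of_tet=self.region_of_tet.copy(),
            axis=self.axis.copy(),
            axis_origin=self.axis_origin.copy(),
        )

    def validate(self) -> None:
        vols = self.tet_volumes()
        bad = np.flatnonzero(vols <= 0)
        if bad.size:
            raise InvertedElementError(bad)
        vs = enclosed_volume(self.vertices, self.surface_tris)
        vt = float(vols.sum())
        if abs(vs - vt) > 1e-9 * max(vt, 1e-30):
            raise ValueError(
                f"surface-enclosed volume {vs} disagrees with tet-volume sum {vt}"
            )


def tet_volumes(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes det(v1-v0, v2-v0, v3-v0)/6 for each tetrahedron."""
    v = vertices[tets]
    a = v[:, 1] - v[:, 0]
    b = v[:, 2] - v[:, 0]
    c = v[:, 3] - v[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def enclosed_volume(vertices: np.ndarray, tris: np.ndarray) -> float:
    """Volume enclosed by a closed, consistently oriented triangulation.

    Divergence theorem: V = sum over triangles of det(v0, v1, v2)/6.
    Positive for outward orientation.  Raises if the surface is not
    watertight (some edge is not shared by exactly two triangles).
    """
    tris = np.asarray(tris, dtype=np.int64)
    if len(tris) == 0:
        raise ValueError("empty surface")
    edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    und = np.sort(edges, axis=1)
    _, counts = np.unique(und, axis=0, return_counts=True)
    if not np.all(counts == 2):
        raise ValueError("surface is not watertight: edges not shared by 2 triangles")
    # directed edges must appear exactly once each -> consistent orientation
    _, dcounts = np.unique(edges, axis=0, return_counts=True)
    if not np.all(dcounts == 1):
        raise ValueError("surface orientation is inconsistent")
    v = np.asarray(vertices, dtype=float)[tris]
    return float(np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6.0)


def _disk_nodes(spec: CylinderSpec):
    """Nodes of one disk layer: center + rings; returns (n,2) xy coords."""
    R, nr, na = spec.radius_mm, spec.n_radial, spec.n_angular
    theta = 2.0 * np.pi * np.arange(na) / na
    xy = [np.zeros((1, 2))]
    for j in range(1, nr + 1):
        r = R * j / nr
        xy.append(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
    return np.concatenate(xy)


def _disk_triangles(spec: CylinderSpec) -> np.ndarray:
    """CCW triangles of one disk layer, indices local to the layer."""
    nr, na = spec.n_radial, spec.n_angular

    def ring(j, k):  # node index of ring j (1-based), sector k
        return 1 + (j - 1) * na + (k % na)

    tris = []
    for k in range(na):  # central fan
        tris.append((0, ring(1, k), ring(1, k + 1)))
    for j in range(1, nr):  # annuli, quads split along a fixed diagonal
        for k in range(na):
            a, b = ring(j, k), ring(j, k + 1)
            c, d = ring(j + 1, k), ring(j + 1, k + 1)
            tris.append((a, d, c))
            tris.append((a, b, d))
    return np.asarray(tris, dtype=np.int64)


def _split_prisms(bottom_tris: np.ndarray, npl: int, n_layers: int) -> np.ndarray:
    """Split extruded triangular prisms into tets, conforming across faces.

    Uses the smallest-global-index rule for the diagonal of each
    rectangular face (Dompierre et al. style), which is consistent
    between prisms sharing a face.  Orientation is fixed afterwards.
    """
    tets = []
    for layer in range(n_layers):
        lo = bottom_tris + layer * npl
        hi = lo + npl
        for (i0, i1, i2), (i3, i4, i5) in zip(lo, hi):
            v = [i0, i1, i2, i3, i4, i5]
            # rotate so the smallest index is a bottom corner v0
            # (bottom indices are always smaller than their top partners,
            # so the global min is on the bottom face)
            m = int(np.argmin(v[:3]))
            if m == 1:
                v = [v[1], v[2], v[0], v[4], v[5], v[3]]
            elif m == 2:
                v = [v[2], v[0], v[1], v[5], v[3], v[4]]
            v0, v1, v2, v3, v4, v5 = v
            if min(v1, v5) < min(v2, v4):
                new = [(v0, v1, v2, v5), (v0, v1, v5, v4), (v0, v4, v5, v3)]
            else:
                new = [(v0, v1, v2, v4), (v0, v4, v2, v5), (v0, v4, v5, v3)]
            tets.extend(new)
    return np.asarray(tets, dtype=np.int64)


def extract_surface(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Boundary triangles of a tet mesh, oriented outward.

    A face is on the boundary iff it belongs to exactly one tet; it is
    oriented so its normal points away from the tet's fourth vertex.
    """
    # local faces ordered so that, for a positively oriented tet,
    # each face's normal points outward of the tet
    faces = np.concatenate(
        [
            tets[:, [0, 2, 1]],
            tets[:, [0, 1, 3]],
            tets[:, [1, 2, 3]],
            tets[:, [0, 3, 2]],
        ]
    )
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = counts[inv] == 1
    return np.ascontiguousarray(faces[boundary])


def build_cylinder_mesh(spec: CylinderSpec) -> TetMesh:
    """Generate the structured tetrahedral cylinder mesh.

    The lateral surface is the inscribed regular polygon swept along z,
    so the mesh volume is slightly below pi R^2 L and converges to it as
    ``n_angular`` grows.  All tets are positively oriented and the
    extracted surface is watertight by construction.
    """
    xy = _disk_nodes(spec)
    npl = len(xy)
    L, nz = spec.length_mm, spec.n_axial
    zs = np.linspace(0.0, L, nz + 1)
    vertices = np.concatenate(
        [np.column_stack([xy, np.full(npl, z)]) for z in zs]
    )
    tets = _split_prisms(_disk_triangles(spec), npl, nz)
    # enforce positive orientation (swapping two vertices does not
    # change the geometric faces, so conformity is preserved)
    vols = tet_volumes(vertices, tets)
    neg = vols < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]
    if np.any(tet_volumes(vertices, tets) <= 0):
        raise InvertedElementError(np.flatnonzero(tet_volumes(vertices, tets) <= 0))
    surface = extract_surface(vertices, tets)
    mesh = TetMesh(vertices=vertices, tets=tets, surface_tris=surface)
    mesh.validate()
    return mesh


def assign_axial_regions(mesh: TetMesh, partition: RegionPartition) -> TetMesh:
    """Label every tet by the axial slab containing its centroid.

    Returns a new mesh; emits a warning for any region left empty (slab
    thinner than the element layer).
    """
    centroids = mesh.vertices[mesh.tets].mean(axis=1)
    z = mesh.axial_coordinate(centroids)
    zmin, zmax = mesh.axial_coordinate(mesh.vertices).min(), mesh.axial_coordinate(
        mesh.vertices
    ).max()
    frac = (z - zmin) / (zmax - zmin)
    b = np.asarray(partition.boundaries)
    labels = np.searchsorted(b, frac, side="right")
    labels = np.clip(labels, 1, partition.n_regions)
    out = mesh.copy()
    out.region_of_tet = labels.astype(np.int64)
    for k in range(1, partition.n_regions + 1):
        if not np.any(labels == k):
            warnings.warn(
                f"region {k} contains no elements (slab thinner than one layer)",
                stacklevel=2,
            )
    return out


@dataclass(frozen=True)
class MeshQualityReport:
    n_tets: int
    min_volume: float
    max_volume: float
    min_quality: float  # radius-ratio proxy in (0, 1], 1 for regular tet

    def __str__(self):
        return (
            f"tets={self.n_tets} vol=[{self.min_volume:.3e}, {self.max_volume:.3e}] "
            f"min_quality={self.min_quality:.3f}"
        )


def mesh_quality(mesh: TetMesh) -> MeshQualityReport:
    """Quality report; raises :class:`InvertedElementError` listing any
    non-positive-volume elements."""
    vols = mesh.tet_volumes()
    bad = np.flatnonzero(vols <= 0)
    if bad.size:
        raise InvertedElementError(bad)
    v = mesh.vertices[mesh.tets]
    e = np.stack(
        [v[:, i] - v[:, j] for i, j in ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))],
        axis=1,
    )
    lrms = np.sqrt((e ** 2).sum(-1).mean(axis=1))
    # 6*sqrt(2)*V / l_rms^3 == 1 for the regular tetrahedron
    q = 6.0 * np.sqrt(2.0) * vols / lrms ** 3
    return MeshQualityReport(
        n_tets=mesh.n_tets,
        min_volume=float(vols.min()),
        max_volume=float(vols.max()),
        min_quality=float(q.min()),
    )


def region_volumes(mesh: TetMesh, n_regions: int = None) -> np.ndarray:
    """Total element volume per region label 1..n_regions."""
    if n_regions is None:
        n_regions = int(mesh.region_of_tet.max())
    vols = mesh.tet_volumes()
    out = np.zeros(n_regions)
    for k in range(1, n_regions + 1):
        out[k - 1] = vols[mesh.region_of_tet == k].sum()
    return out
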