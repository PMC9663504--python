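"""Small-strain linear-elasticity finite elements on P1 tetrahedra.

This is the mechanical core: tissue growth driven by cell division is
modelled as region-wise body-force densities (axial + radial components)
acting on an elastic, homogeneous cylinder, and the resulting
displacement field is the growth increment of the bone shape.  The
element is the standard 4-node linear tetrahedron with isotropic
Hooke's law; units are mm, kPa and kPa/mm (force per unit volume).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import TetMesh, tet_volumes

__all__ = [
    "Material",
    "RegionLoading",
    "Constraint",
    "ConstraintSet",
    "DisplacementField",
    "element_stiffness",
    "assemble_system",
    "assemble_body_load",
    "assemble_surface_traction",
    "solve_static",
    "incremental_growth",
    "default_constraints",
]


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material.

    ``young_modulus`` in kPa (soft-tissue scale), ``poisson_ratio``
    dimensionless in (-1, 0.5).  P1 tetrahedra lock volumetrically as
    nu -> 0.5; a warning is issued for nu >= 0.49.
    """

    young_modulus: float = 1.0
    poisson_ratio: float = 0.40

    def __post_init__(self):
        if not self.young_modulus > 0:
            raise ValueError(f"young_modulus must be positive, got {self.young_modulus}")
        if not (-1.0 < self.poisson_ratio < 0.5):
            raise ValueError(
                f"poisson_ratio must lie in (-1, 0.5), got {self.poisson_ratio}"
            )
        if self.poisson_ratio >= 0.49:
            warnings.warn(
                "poisson_ratio >= 0.49: P1 tetrahedra exhibit volumetric locking",
                stacklevel=2,
            )

    @property
    def lame(self):
        E, nu = self.young_modulus, self.poisson_ratio
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        return lam, mu

    @property
    def hooke_matrix(self) -> np.ndarray:
        """6x6 stiffness in Voigt order (xx, yy, zz, xy, yz, zx),
        engineering shear strains."""
        lam, mu = self.lame
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] += 2 * mu
        D[np.arange(3, 6), np.arange(3, 6)] = mu
        return D


@dataclass(frozen=True)
class RegionLoading:
    """Per-region growth force densities, kPa/mm (force per unit volume).

    ``axial`` and ``radial`` map region label -> modulus.  The axial
    component acts along the bone axis; the radial component acts along
    the outward unit vector from the axis (zero on the axis itself).
    """

    axial: dict
    radial: dict

    def regions(self):
        return sorted(set(self.axial) | set(self.radial))

    def moduli(self, region: int):
        return float(self.axial.get(region, 0.0)), float(self.radial.get(region, 0.0))

    def scaled(self, factor: float, radial_factor: float = None) -> "RegionLoading":
        rf = factor if radial_factor is None else radial_factor
        return RegionLoading(
            axial={k: v * factor for k, v in self.axial.items()},
            radial={k: v * rf for k, v in self.radial.items()},
        )


@dataclass(frozen=True)
class Constraint:
    vertex: int
    component: int  # 0=x, 1=y, 2=z
    value: float = 0.0


@dataclass
class ConstraintSet:
    """Dirichlet constraints on vertex displacement components."""

    constraints: list

    def __post_init__(self):
        seen = {}
        for c in self.constraints:
            key = (c.vertex, c.component)
            if key in seen and seen[key] != c.value:
                raise ValueError(f"conflicting constraints on vertex {c.vertex}")
            seen[key] = c.value

    def dofs_values(self, n_vertices: int):
        dofs = np.array([3 * c.vertex + c.component for c in self.constraints], dtype=int)
        vals = np.array([c.value for c in self.constraints], dtype=float)
        if dofs.size and (dofs.min() < 0 or dofs.max() >= 3 * n_vertices):
            raise ValueError("constraint vertex index out of range")
        order = np.argsort(dofs)
        return dofs[order], vals[order]

    def __len__(self):
        return len(self.constraints)


@dataclass
class DisplacementField:
    """Per-vertex displacement solution u (mm) plus solver metadata."""

    u: np.ndarray  # (n_vertices, 3)
    residual: float
    method: str

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def flat(self) -> np.ndarray:
        return self.u.reshape(-1)

    def max_magnitude(self) -> float:
        return float(np.linalg.norm(self.u, axis=1).max())


def _shape_gradients(coords: np.ndarray):
    """Gradients of the 4 barycentric shape functions of one tet.

    Returns (grads (4,3), volume)."""
    M = np.column_stack([np.ones(4), coords])
    vol = np.linalg.det(M) / 6.0
    if vol <= 0:
        raise ValueError(f"degenerate or inverted tetrahedron (volume {vol:.3e})")
    grads = np.linalg.inv(M)[1:, :].T  # rows: nodes, cols: d/dx d/dy d/dz
    return grads, vol


def _b_matrix(grads: np.ndarray) -> np.ndarray:
    """6x12 strain-displacement matrix in Voigt order with engineering
    shears, node-major DOF ordering (ux1 uy1 uz1 ux2 ...)."""
    B = np.zeros((6, 12))
    for a in range(4):
        gx, gy, gz = grads[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    return B


def element_stiffness(tet_coords: np.ndarray, material: Material) -> np.ndarray:
    """12x12 stiffness of one P1 tetrahedron: K = V * B^T D B."""
    grads, vol = _shape_gradients(np.asarray(tet_coords, dtype=float))
    B = _b_matrix(grads)
    return vol * B.T @ material.hooke_matrix @ B


def _all_shape_gradients(mesh: TetMesh):
    """Vectorised shape gradients: (n_t, 4, 3) array and (n_t,) volumes."""
    v = mesh.vertices[mesh.tets]  # (n,4,3)
    M = np.concatenate([np.ones((len(v), 4, 1)), v], axis=2)  # (n,4,4)
    vols = np.linalg.det(M) / 6.0
    bad = np.flatnonzero(vols <= 0)
    if bad.size:
        raise ValueError(f"degenerate/inverted elements at indices {bad[:20].tolist()}")
    Minv = np.linalg.inv(M)
    grads = np.transpose(Minv[:, 1:, :], (0, 2, 1))  # (n,4,3)
    return grads, vols


def assemble_system(mesh: TetMesh, material: Material) -> sp.csr_matrix:
    """Global sparse stiffness, dimension 3*n_vertices, CSR.

    Symmetric PSD; before constraints its nullspace is the 6 rigid-body
    modes.
    """
    grads, vols = _all_shape_gradients(mesh)
    n_t = len(vols)
    B = np.zeros((n_t, 6, 12))
    for a in range(4):
        c = 3 * a
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    D = material.hooke_matrix
    DB = np.matmul(D[None, :, :], B)  # (n,6,12)
    Ke = np.matmul(np.transpose(B, (0, 2, 1)), DB) * vols[:, None, None]
    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(n_t, 12)
    rows = np.repeat(dofs, 12, axis=1).reshape(-1)
    cols = np.tile(dofs, (1, 12)).reshape(-1)
    n_dof = 3 * mesh.n_vertices
    K = sp.coo_matrix((Ke.reshape(-1), (rows, cols)), shape=(n_dof, n_dof)).tocsr()
    return K


def _body_force_per_tet(mesh: TetMesh, loading: RegionLoading) -> np.ndarray:
    """Piecewise-constant body force (n_t, 3) evaluated at tet centroids."""
    present = set(np.unique(mesh.region_of_tet).tolist())
    missing = present - set(loading.regions())
    if missing:
        raise ValueError(f"loading does not cover mesh regions {sorted(missing)}")
    centroids = mesh.vertices[mesh.tets].mean(axis=1)
    rad = mesh.radial_vectors(centroids)
    rnorm = np.linalg.norm(rad, axis=1)
    rdir = np.zeros_like(rad)
    ok = rnorm > 1e-12
    rdir[ok] = rad[ok] / rnorm[ok, None]  # zero on the axis
    f = np.zeros((mesh.n_tets, 3))
    for region in sorted(present):
        fa, fr = loading.moduli(region)
        m = mesh.region_of_tet == region
        f[m] = fa * mesh.axis[None, :] + fr * rdir[m]
    return f


def assemble_body_load(mesh: TetMesh, loading: RegionLoading) -> np.ndarray:
    """Consistent P1 load vector for piecewise-constant body force.

    Each tet distributes f * V_tet equally to its four vertices (the
    exact P1 integral for an element-wise constant force).
    """
    f = _body_force_per_tet(mesh, loading)
    vols = mesh.tet_volumes()
    contrib = f * vols[:, None] / 4.0  # (n_t, 3) per vertex of each tet
    F = np.zeros((mesh.n_vertices, 3))
    for a in range(4):
        np.add.at(F, mesh.tets[:, a], contrib)
    return F.reshape(-1)


def assemble_surface_traction(
    mesh: TetMesh, face_selector, traction: np.ndarray
) -> np.ndarray:
    """Consistent load vector for a constant traction on selected
    boundary faces.

    ``face_selector`` is a boolean mask over ``mesh.surface_tris`` or a
    callable mapping face centroids (n,3) to a mask.  The resultant
    equals traction x selected area exactly.
    """
    tris = mesh.surface_tris
    if callable(face_selector):
        centroids = mesh.vertices[tris].mean(axis=1)
        mask = np.asarray(face_selector(centroids), dtype=bool)
    else:
        mask = np.asarray(face_selector, dtype=bool)
    sel = tris[mask]
    if len(sel) == 0:
        raise ValueError("face selector matched no surface triangles")
    v = mesh.vertices[sel]
    areas = 0.5 * np.linalg.norm(
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
    )
    t = np.asarray(traction, dtype=float)
    contrib = areas[:, None] * t[None, :] / 3.0
    F = np.zeros((mesh.n_vertices, 3))
    for a in range(3):
        np.add.at(F, sel[:, a], contrib)
    return F.reshape(-1)


def cap_face_mask(mesh: TetMesh, which: str = "distal", tol: float = 1e-9) -> np.ndarray:
    """Mask over surface triangles lying on an end cap."""
    z = mesh.axial_coordinate(mesh.vertices)
    zmin, zmax = z.min(), z.max()
    target = zmax if which == "distal" else zmin
    fz = z[mesh.surface_tris]
    return np.all(np.abs(fz - target) < tol * max(1.0, zmax - zmin), axis=1)


def default_constraints(mesh: TetMesh, tol: float = 1e-9) -> ConstraintSet:
    """Roller proximal face plus a straight-axis condition.

    u_z = 0 on the whole proximal face (z = min); u_x = u_y = 0 on all
    vertices lying on the bone axis; and the proximal node farthest
    along +x pinned in y (blocks rotation about the axis).  This
    removes all six rigid modes while leaving radial expansion and
    axial growth free everywhere.

    Pinning the whole axis rather than a single node matters for a
    slender rod: with only point pins the lateral bending modes are
    nearly singular (stiffness eigenvalues ~1e-5 of typical), and the
    unavoidable asymmetry of a tetrahedral connectivity then converts
    an axisymmetric load into a large spurious lateral deflection.
    Holding the axis straight is the appropriate statement of symmetry
    for axisymmetric growth loads.  For meshes without on-axis nodes
    the proximal node nearest the axis is fully fixed instead (with a
    warning), recovering the minimal-pin scheme.
    """
    z = mesh.axial_coordinate(mesh.vertices)
    zmin, zmax = z.min(), z.max()
    scale = max(1.0, zmax - zmin)
    prox = np.flatnonzero(np.abs(z - zmin) < tol * scale)
    if prox.size < 3:
        raise ValueError("proximal face has fewer than 3 vertices")
    cons = [Constraint(int(i), 2, 0.0) for i in prox]
    r = np.linalg.norm(mesh.radial_vectors(mesh.vertices), axis=1)
    rmax = r.max()
    on_axis = np.flatnonzero(r < 1e-6 * max(rmax, 1.0))
    if on_axis.size >= 2:
        for i in on_axis:
            cons += [Constraint(int(i), 0, 0.0), Constraint(int(i), 1, 0.0)]
    else:
        warnings.warn(
            "mesh has no on-axis vertex line; falling back to point pins "
            "(lateral bending is then only weakly constrained)",
            stacklevel=2,
        )
        center = int(prox[np.argmin(r[prox])])
        cons += [Constraint(center, 0, 0.0), Constraint(center, 1, 0.0)]
    x = mesh.vertices[prox, 0]
    pin = int(prox[np.argmax(x)])
    if r[pin] < 1e-6 * max(rmax, 1.0):
        raise ValueError("cannot find an off-axis rotation pin node")
    cons.append(Constraint(pin, 1, 0.0))
    return ConstraintSet(cons)


def solve_static(
    stiffness: sp.spmatrix,
    load: np.ndarray,
    constraints: ConstraintSet,
    method: str = "direct",
    cg_tol: float = 1e-10,
) -> DisplacementField:
    """Solve K u = f with Dirichlet constraints by elimination.

    ``method`` is "direct" (sparse LU, deterministic) or "cg"
    (Jacobi-preconditioned conjugate gradients).  The returned field
    satisfies the constraints exactly and carries the relative residual
    of the full system.
    """
    K = stiffness.tocsr()
    n_dof = K.shape[0]
    f = np.asarray(load, dtype=float).reshape(-1)
    if f.shape[0] != n_dof:
        raise ValueError("load vector size does not match stiffness")
    cdofs, cvals = constraints.dofs_values(n_dof // 3)
    if cdofs.size == 0:
        raise ValueError("no constraints: rigid-body modes are unconstrained")
    free = np.setdiff1d(np.arange(n_dof), cdofs, assume_unique=False)
    u = np.zeros(n_dof)
    u[cdofs] = cvals
    rhs = f[free] - K[free][:, cdofs] @ cvals
    Kff = K[free][:, free].tocsc()
    if method == "direct":
        try:
            lu = spla.splu(Kff)
        except RuntimeError as e:  # pragma: no cover - defensive
            raise RuntimeError(
                "constrained stiffness is singular; constraints likely do not "
                "remove all rigid-body modes"
            ) from e
        uf = lu.solve(rhs)
    elif method == "cg":
        d = Kff.diagonal()
        M = sp.diags(np.where(d > 0, 1.0 / d, 1.0))
        uf, info = spla.cg(Kff, rhs, rtol=cg_tol, maxiter=20000, M=M)
        if info != 0:
            res = np.linalg.norm(Kff @ uf - rhs) / max(np.linalg.norm(rhs), 1e-300)
            raise RuntimeError(f"CG did not converge (info={info}, rel residual {res:.2e})")
    else:
        raise ValueError(f"unknown solver method {method!r}")
    u[free] = uf
    fnorm = np.linalg.norm(f)
    if fnorm > 0:
        # residual measured on free equations (reactions act on the rest)
        res = np.linalg.norm(K[free] @ u - f[free]) / fnorm
    else:
        res = float(np.linalg.norm(K[free] @ u))
    if not np.all(np.isfinite(u)):
        raise RuntimeError("solver produced non-finite displacements")
    if fnorm > 0 and res > 1e-8:
        raise RuntimeError(f"relative residual {res:.2e} exceeds 1e-8")
    return DisplacementField(u=u.reshape(-1, 3), residual=float(res), method=method)


def uniaxial_verification(
    spec=None, material: Material = None, sigma_fraction: float = 0.01,
    method: str = "direct",
) -> dict:
    """Closed-form verification problem: end-loaded cylinder on rollers.

    A fixed physical force F = sigma * pi R^2 (with sigma =
    ``sigma_fraction`` x E) is spread uniformly over the discretized
    distal cap of a cylinder held by the default roller constraints.
    The exact solution of the continuum problem is homogeneous uniaxial
    stress: mean tip axial displacement sigma L / E and mean lateral
    radial displacement -nu sigma R / E.  Because the P1 solution of
    the *discrete* cylinder is exact for its own (inscribed-polygon)
    cross-section, the measured relative error equals the cap-area
    discretization error and shrinks monotonically under angular
    refinement.

    Returns a dict with the measured and exact values and relative
    errors.
    """
    from .mesh import CylinderSpec, build_cylinder_mesh

    if spec is None:
        spec = CylinderSpec()
    if material is None:
        material = Material()
    mesh = build_cylinder_mesh(spec)
    E, nu = material.young_modulus, material.poisson_ratio
    sigma = sigma_fraction * E
    L, R = spec.length_mm, spec.radius_mm
    mask = cap_face_mask(mesh, "distal")
    v = mesh.vertices[mesh.surface_tris[mask]]
    area = float(
        (0.5 * np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
                              axis=1)).sum()
    )
    force = sigma * np.pi * R ** 2
    F = assemble_surface_traction(mesh, mask, np.array([0.0, 0.0, force / area]))
    K = assemble_system(mesh, material)
    sol = solve_static(K, F, default_constraints(mesh), method=method)
    z = mesh.axial_coordinate(mesh.vertices)
    tip = np.abs(z - L) < 1e-9 * L
    tip_uz = float(sol.u[tip, 2].mean())
    rad = mesh.radial_vectors(mesh.vertices)
    rnorm = np.linalg.norm(rad, axis=1)
    lateral = np.abs(rnorm - R) < 1e-9 * R
    ur = float(
        (np.einsum("ij,ij->i", sol.u[lateral], rad[lateral]) / rnorm[lateral]).mean()
    )
    tip_exact = sigma * L / E
    ur_exact = -nu * sigma * R / E
    return {
        "tip_uz_mm": tip_uz,
        "tip_uz_exact_mm": tip_exact,
        "tip_rel_err": tip_uz / tip_exact - 1.0,
        "lateral_ur_mm": ur,
        "lateral_ur_exact_mm": ur_exact,
        "lateral_rel_err": ur / ur_exact - 1.0,
        "n_tets": mesh.n_tets,
        "residual": sol.residual,
    }


def incremental_growth(
    mesh: TetMesh,
    material: Material,
    loading: RegionLoading,
    constraints: ConstraintSet = None,
    n_steps: int = 1,
    step_scale: float = 1.0,
    method: str = "direct",
):
    """Quasi-static growth: repeatedly solve on the current geometry and
    advect the vertices by the displacement increment.

    Returns (list of deformed meshes, one per step, and the list of
    per-step displacement fields).  With ``n_steps=1`` this is exactly a
    single solve followed by a deformation.  A warning is issued when a
    step's maximum displacement exceeds 0.3 x the current radius (the
    small-strain assumption degrades); element inversion aborts with the
    step index.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    from .mesh import tet_volumes as _tv  # local import to avoid cycle noise

    current = mesh.copy()
    snapshots, fields = [], []
    for step in range(n_steps):
        cons = constraints if constraints is not None else default_constraints(current)
        K = assemble_system(current, material)
        F = assemble_body_load(current, loading) * step_scale
        sol = solve_static(K, F, cons, method=method)
        radius = np.linalg.norm(
            current.radial_vectors(current.vertices), axis=1
        ).max()
        if sol.max_magnitude() > 0.3 * radius:
            warnings.warn(
                f"step {step}: max displacement {sol.max_magnitude():.3g} mm exceeds "
                f"0.3 R = {0.3 * radius:.3g} mm; small-strain assumption is strained",
                stacklevel=2,
            )
        new = current.copy()
        new.vertices = current.vertices + sol.u
        if np.any(_tv(new.vertices, new.tets) <= 0):
            raise RuntimeError(
                f"element inversion after advection at step {step}; "
                "reduce step_scale or n_steps"
            )
        snapshots.append(new)
        fields.append(sol)
        current = new
    return snapshots, fields
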