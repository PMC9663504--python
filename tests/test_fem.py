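import math

import numpy as np
import pytest
import scipy.sparse as sp

from bulkybone.fem import (Constraint, ConstraintSet, Material, RegionLoading,
                           assemble_body_load, assemble_surface_traction,
                           assemble_system, cap_face_mask, default_constraints,
                           element_stiffness, incremental_growth, solve_static,
                           uniaxial_verification)
from bulkybone.mesh import (CylinderSpec, RegionPartition, assign_axial_regions,
                            build_cylinder_mesh)
from bulkybone.shape import deform, diameter_profile


REF_TET = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


def stiffness_energy_oracle(coords, material):
    """Independent element-stiffness computation.

    Never forms a strain-displacement matrix: interpolates each unit
    nodal displacement with explicit linear shape functions, takes the
    displacement gradient by central finite differences at the
    centroid (exact for linear fields up to rounding), and integrates
    the bilinear elastic energy with Hooke's law in tensor form.
    """
    coords = np.asarray(coords, dtype=float)
    M = np.column_stack([np.ones(4), coords])
    vol = np.linalg.det(M) / 6.0
    lam, mu = material.lame
    coeffs = np.linalg.solve(M, np.eye(4))  # shape-function coefficients

    def shape(x):
        return np.array([1.0, *x]) @ coeffs

    centroid = coords.mean(axis=0)
    h = 1e-6

    def strain(node, comp):
        grad = np.zeros((3, 3))  # du_i/dx_j for u = N_node(x) e_comp
        for j in range(3):
            xp, xm = centroid.copy(), centroid.copy()
            xp[j] += h
            xm[j] -= h
            grad[comp, j] = (shape(xp)[node] - shape(xm)[node]) / (2 * h)
        return 0.5 * (grad + grad.T)

    K = np.zeros((12, 12))
    strains = [strain(a, i) for a in range(4) for i in range(3)]
    for p, ep in enumerate(strains):
        sig = lam * np.trace(ep) * np.eye(3) + 2 * mu * ep
        for q, eq in enumerate(strains):
            K[p, q] = vol * np.tensordot(sig, eq)
    return K


class TestElementStiffness:
    def test_matches_independent_energy_oracle(self):
        mat = Material(1.0, 0.3)
        K = element_stiffness(REF_TET, mat)
        K_oracle = stiffness_energy_oracle(REF_TET, mat)
        assert np.abs(K - K_oracle).max() < 1e-9  # FD rounding floor

    def test_symmetry_and_rigid_translation_nullspace(self, rng):
        coords = REF_TET + 0.1 * rng.normal(size=(4, 3))
        K = element_stiffness(coords, Material(2.0, 0.25))
        assert np.abs(K - K.T).max() < 1e-12
        for comp in range(3):
            t = np.tile(np.eye(3)[comp], 4)
            assert np.abs(K @ t).max() < 1e-10 * np.abs(K).max()

    def test_six_rigid_modes(self):
        K = element_stiffness(REF_TET, Material(1.0, 0.3))
        w = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(w) < 1e-10) == 6
        assert np.all(w > -1e-10)

    def test_degenerate_tet_rejected(self):
        flat = REF_TET.copy()
        flat[3] = [0.5, 0.5, 0.0]
        with pytest.raises(ValueError, match="degenerate|inverted"):
            element_stiffness(flat, Material())


class TestAssembleSystem:
    def test_two_tet_mesh_equals_manual_scatter(self, material):
        verts = np.array(
            [[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]]
        )
        tets = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
        from bulkybone.mesh import TetMesh, extract_surface

        mesh = TetMesh(verts, tets, extract_surface(verts, tets))
        K = assemble_system(mesh, material).toarray()
        K_manual = np.zeros((15, 15))
        for tet in tets:
            Ke = element_stiffness(verts[tet], material)
            dofs = np.concatenate([3 * v + np.arange(3) for v in tet])
            K_manual[np.ix_(dofs, dofs)] += Ke
        assert np.abs(K - K_manual).max() < 1e-12

    def test_global_symmetry_and_rigid_nullspace(self, small_mesh, material):
        K = assemble_system(small_mesh, material)
        assert abs(K - K.T).max() < 1e-12
        t = np.tile([1.0, -2.0, 0.5], small_mesh.n_vertices)
        assert np.abs(K @ t).max() < 1e-10 * abs(K).max()

    def test_constrained_stiffness_positive_definite(self, small_mesh, material):
        K = assemble_system(small_mesh, material)
        cdofs, _ = default_constraints(small_mesh).dofs_values(small_mesh.n_vertices)
        free = np.setdiff1d(np.arange(K.shape[0]), cdofs)[:500]
        Kff = K[free][:, free].toarray()
        w = np.linalg.eigvalsh(Kff)
        assert w.min() > 0


class TestLoads:
    def test_zero_loading_gives_zero_vector(self, small_mesh_regions):
        loads = RegionLoading(axial={k: 0.0 for k in range(1, 6)},
                              radial={k: 0.0 for k in range(1, 6)})
        F = assemble_body_load(small_mesh_regions, loads)
        assert np.all(F == 0)

    def test_uniform_axial_resultant_equals_density_times_volume(
        self, small_mesh_regions
    ):
        loads = RegionLoading(axial={k: 0.1 for k in range(1, 6)},
                              radial={k: 0.0 for k in range(1, 6)})
        F = assemble_body_load(small_mesh_regions, loads).reshape(-1, 3)
        assert F[:, 2].sum() == pytest.approx(
            0.1 * small_mesh_regions.total_volume(), rel=1e-9
        )
        assert np.abs(F[:, :2].sum(axis=0)).max() < 1e-12

    def test_pure_radial_loading_has_no_net_lateral_resultant(
        self, small_mesh_regions
    ):
        loads = RegionLoading(axial={k: 0.0 for k in range(1, 6)},
                              radial={k: 1.0 for k in range(1, 6)})
        F = assemble_body_load(small_mesh_regions, loads)
        assert np.abs(F.reshape(-1, 3).sum(axis=0)).max() < 1e-9 * np.abs(F).sum()

    def test_missing_region_raises_naming_region(self, small_mesh_regions):
        loads = RegionLoading(axial={1: 1.0}, radial={1: 1.0})
        with pytest.raises(ValueError, match=r"\[2, 3, 4, 5\]"):
            assemble_body_load(small_mesh_regions, loads)

    def test_cap_traction_resultant_equals_traction_times_area(self, small_mesh):
        mask = cap_face_mask(small_mesh, "distal")
        v = small_mesh.vertices[small_mesh.surface_tris[mask]]
        area = 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
        ).sum()
        F = assemble_surface_traction(small_mesh, mask, np.array([0, 0, 0.01]))
        assert F.reshape(-1, 3)[:, 2].sum() == pytest.approx(0.01 * area, rel=1e-9)

    def test_zero_traction_and_opposite_caps_cancel(self, small_mesh):
        distal = cap_face_mask(small_mesh, "distal")
        proximal = cap_face_mask(small_mesh, "proximal")
        assert np.all(
            assemble_surface_traction(small_mesh, distal, np.zeros(3)) == 0
        )
        Fd = assemble_surface_traction(small_mesh, distal, np.array([0, 0, 1.0]))
        Fp = assemble_surface_traction(small_mesh, proximal, np.array([0, 0, -1.0]))
        assert abs((Fd + Fp).reshape(-1, 3).sum(axis=0)).max() < 1e-12

    def test_empty_face_selection_rejected(self, small_mesh):
        empty = np.zeros(len(small_mesh.surface_tris), dtype=bool)
        with pytest.raises(ValueError, match="no surface triangles"):
            assemble_surface_traction(small_mesh, empty, np.array([0, 0, 1.0]))


@pytest.fixture(scope="module")
def solved_uniform(small_mesh_regions, material):
    mesh = small_mesh_regions
    K = assemble_system(mesh, material)
    cons = default_constraints(mesh)
    loads = RegionLoading(axial={k: 0.02 for k in range(1, 6)},
                          radial={k: 0.2 for k in range(1, 6)})
    F = assemble_body_load(mesh, loads)
    return mesh, K, cons, F, solve_static(K, F, cons)


class TestSolveStatic:
    def test_zero_load_zero_displacement(self, small_mesh_regions, material):
        K = assemble_system(small_mesh_regions, material)
        cons = default_constraints(small_mesh_regions)
        sol = solve_static(K, np.zeros(K.shape[0]), cons)
        assert np.abs(sol.u).max() == 0

    def test_linearity_under_load_scaling(self, solved_uniform):
        mesh, K, cons, F, sol = solved_uniform
        sol2 = solve_static(K, 2 * F, cons)
        assert np.allclose(sol2.u, 2 * sol.u, rtol=1e-9, atol=1e-15)

    def test_superposition(self, solved_uniform, material):
        mesh, K, cons, F, sol = solved_uniform
        mask = cap_face_mask(mesh, "distal")
        F2 = assemble_surface_traction(mesh, mask, np.array([0, 0, 0.01]))
        u12 = solve_static(K, F + F2, cons).u
        u2 = solve_static(K, F2, cons).u
        assert np.allclose(u12, sol.u + u2, rtol=1e-9, atol=1e-14)

    def test_reciprocity(self, solved_uniform):
        mesh, K, cons, F1, sol1 = solved_uniform
        F2 = assemble_surface_traction(
            mesh, cap_face_mask(mesh, "distal"), np.array([0, 0, 0.01])
        )
        sol2 = solve_static(K, F2, cons)
        a = sol2.flat @ F1
        b = sol1.flat @ F2
        assert a == pytest.approx(b, rel=1e-9)

    def test_frame_invariance_under_rigid_translation(
        self, small_mesh_regions, material
    ):
        mesh = small_mesh_regions
        loads = RegionLoading(axial={k: 0.02 for k in range(1, 6)},
                              radial={k: 0.2 for k in range(1, 6)})
        u_ref = solve_static(
            assemble_system(mesh, material), assemble_body_load(mesh, loads),
            default_constraints(mesh),
        ).u
        shifted = mesh.copy()
        shifted.vertices = mesh.vertices + np.array([3.0, -2.0, 7.0])
        shifted.axis_origin = mesh.axis_origin + np.array([3.0, -2.0, 7.0])
        u_shift = solve_static(
            assemble_system(shifted, material),
            assemble_body_load(shifted, loads),
            default_constraints(shifted),
        ).u
        assert np.allclose(u_shift, u_ref, rtol=1e-9, atol=1e-12)

    def test_direct_and_cg_agree(self, solved_uniform):
        mesh, K, cons, F, sol = solved_uniform
        sol_cg = solve_static(K, F, cons, method="cg", cg_tol=1e-12)
        assert np.allclose(sol_cg.u, sol.u, rtol=1e-6, atol=1e-12)

    def test_missing_constraints_rejected(self, small_mesh_regions, material):
        K = assemble_system(small_mesh_regions, material)
        with pytest.raises(ValueError, match="constraint|rigid"):
            solve_static(K, np.zeros(K.shape[0]), ConstraintSet([]))

    def test_energy_nonnegative(self, solved_uniform):
        _, K, _, _, sol = solved_uniform
        assert sol.flat @ (K @ sol.flat) >= 0


class TestUniaxialVerification:
    def test_small_mesh_tracks_cap_area_error(self):
        spec = CylinderSpec(10.0, 1.0, 12, 3, 16)
        out = uniaxial_verification(spec)
        expected_err = 2 * math.pi / 16 / math.sin(2 * math.pi / 16) * (
            16 * math.sin(2 * math.pi / 16) / (2 * math.pi)
        )
        # error equals the inverse inscribed-polygon area fraction - 1
        frac = 16 / (2 * math.pi) * math.sin(2 * math.pi / 16)
        assert out["tip_rel_err"] == pytest.approx(1 / frac - 1, rel=1e-6)
        assert out["lateral_rel_err"] == pytest.approx(1 / frac - 1, rel=1e-6)


class TestIncrementalGrowth:
    def test_single_step_equals_solve_plus_deform(self, small_mesh_regions, material):
        mesh = small_mesh_regions
        loads = RegionLoading(axial={k: 0.0 for k in range(1, 6)},
                              radial={k: 0.1 for k in range(1, 6)})
        snaps, fields = incremental_growth(mesh, material, loads, n_steps=1)
        sol = solve_static(
            assemble_system(mesh, material), assemble_body_load(mesh, loads),
            default_constraints(mesh),
        )
        direct = deform(mesh, sol)
        assert np.array_equal(snaps[0].vertices, direct.vertices)

    def test_uniform_radial_growth_monotone_midshaft_radius(
        self, small_mesh_regions, material
    ):
        mesh = small_mesh_regions
        loads = RegionLoading(axial={k: 0.0 for k in range(1, 6)},
                              radial={k: 0.05 for k in range(1, 6)})
        snaps, _ = incremental_growth(mesh, material, loads, n_steps=3)
        radii = []
        for snap in [mesh] + snaps:
            sv = np.unique(snap.surface_tris)
            prof = diameter_profile(snap.vertices[sv], n_bins=10)
            radii.append(np.nanmean(prof.effective_radius[4:6]))
        assert all(b > a for a, b in zip(radii, radii[1:]))

    def test_large_step_warns(self, small_mesh_regions, material):
        loads = RegionLoading(axial={k: 0.0 for k in range(1, 6)},
                              radial={k: 2.0 for k in range(1, 6)})
        with pytest.warns(UserWarning, match="small-strain"):
            incremental_growth(small_mesh_regions, material, loads, n_steps=1)


class TestMaterial:
    def test_lame_parameters(self):
        lam, mu = Material(1.0, 0.25).lame
        assert lam == pytest.approx(0.4)
        assert mu == pytest.approx(0.4)

    @pytest.mark.parametrize("nu", [0.5, -1.0, 0.7])
    def test_invalid_poisson_rejected(self, nu):
        with pytest.raises(ValueError):
            Material(1.0, nu)

    def test_near_incompressible_warns(self):
        with pytest.warns(UserWarning, match="locking"):
            Material(1.0, 0.495)
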