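import numpy as np
import pytest

from gnawfe.hexfem import (
    ConvergenceError,
    FEError,
    MaterialError,
    SingularModelError,
    build_mesh,
    element_stiffness,
    element_stiffness_incompatible,
    principal_strains,
    reactions_and_bite_force,
    recover_strain_stress,
    solve,
    von_mises,
)
from gnawfe.loading import ConstraintSet, LoadCase
from gnawfe.voxel_model import Label, MaterialTable, VoxelGrid


def block_grid(shape=(3, 3, 3), spacing=1.0, label=Label.BONE):
    return VoxelGrid(np.full(shape, int(label), np.uint8), spacing)


def zero_loads(mesh):
    return LoadCase(forces=np.zeros((mesh.n_nodes, 3)))


def oracle_element_stiffness(E, nu, h):
    """Independent hex8 stiffness: shape functions written directly in
    physical coordinates on [0,h]^3 and integrated with numpy's
    Gauss-Legendre rule (different parametrisation and assembly loop from
    the implementation)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] += lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[3:, 3:] = np.eye(3) * mu
    corners = [(a, b, c) for c in (0, 1) for b in (0, 1) for a in (0, 1)]
    # reorder to VTK hex order
    order = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]

    def grad(i, x, y, z):
        cx, cy, cz = order[i]
        fx = x / h if cx else 1 - x / h
        fy = y / h if cy else 1 - y / h
        fz = z / h if cz else 1 - z / h
        dfx = (1 / h) if cx else (-1 / h)
        dfy = (1 / h) if cy else (-1 / h)
        dfz = (1 / h) if cz else (-1 / h)
        return np.array([dfx * fy * fz, fx * dfy * fz, fx * fy * dfz])

    pts, wts = np.polynomial.legendre.leggauss(2)
    pts = (pts + 1) * h / 2
    wts = wts * h / 2
    K = np.zeros((24, 24))
    for x, wx in zip(pts, wts):
        for y, wy in zip(pts, wts):
            for z, wz in zip(pts, wts):
                B = np.zeros((6, 24))
                for i in range(8):
                    gx, gy, gz = grad(i, x, y, z)
                    c = 3 * i
                    B[0, c] = gx
                    B[1, c + 1] = gy
                    B[2, c + 2] = gz
                    B[3, c], B[3, c + 1] = gy, gx
                    B[4, c + 1], B[4, c + 2] = gz, gy
                    B[5, c], B[5, c + 2] = gz, gx
                K += wx * wy * wz * (B.T @ C @ B)
    return K


class TestElementStiffness:
    def test_matches_independent_quadrature_oracle(self):
        K = element_stiffness(17000.0, 0.3, 0.25)
        K_oracle = oracle_element_stiffness(17000.0, 0.3, 0.25)
        np.testing.assert_allclose(K, K_oracle, rtol=1e-10, atol=1e-10 * np.abs(K).max())

    @pytest.mark.parametrize("maker", [element_stiffness, element_stiffness_incompatible])
    def test_rigid_body_modes_are_zero_energy(self, maker):
        K = element_stiffness(55000.0, 0.32, 0.05) if maker is element_stiffness else maker(55000.0, 0.32, 0.05)
        scale = np.abs(K).max()
        for d in np.eye(3):
            u = np.tile(d, 8)
            assert np.abs(K @ u).max() < 1e-12 * scale
        vals = np.linalg.eigvalsh(K)
        assert (vals[:6] < 1e-9 * scale).all() and (vals[6:] > 1e-9 * scale).all()

    def test_linear_in_youngs_modulus(self):
        K17 = element_stiffness(17000.0, 0.3, 0.1)
        K55 = element_stiffness(55000.0, 0.3, 0.1)
        np.testing.assert_allclose(K17, (17000.0 / 55000.0) * K55, rtol=1e-12)

    def test_linear_in_edge_length(self):
        np.testing.assert_allclose(
            element_stiffness(1000.0, 0.25, 0.8),
            2.0 * element_stiffness(1000.0, 0.25, 0.4),
            rtol=1e-12,
        )

    def test_invalid_material_rejected(self):
        with pytest.raises(MaterialError):
            element_stiffness(1000.0, 0.5, 1.0)
        with pytest.raises(MaterialError):
            element_stiffness(1000.0, 0.3, 0.0)

    def test_incompatible_element_is_softer(self):
        Kp = element_stiffness(17000.0, 0.3, 0.25)
        Ki = element_stiffness_incompatible(17000.0, 0.3, 0.25)
        vals = np.linalg.eigvalsh(Kp - Ki)
        assert vals.min() > -1e-9 * np.abs(Kp).max()


def random_connected_blob(seed=0):
    r = np.random.default_rng(seed)
    labels = np.zeros((6, 5, 4), np.uint8)
    labels[1:5, 1:4, 1:3] = Label.BONE
    extra = r.random(labels.shape) < 0.3
    from scipy import ndimage

    grown = ndimage.binary_dilation(labels > 0) & extra
    labels[grown] = Label.BONE  # homogeneous: uniform strain must be an equilibrium state
    from gnawfe.voxel_model import largest_component

    grid, _ = largest_component(VoxelGrid(labels, 0.5))
    return grid


class TestPatchTest:
    @pytest.mark.parametrize("formulation", ["plain", "incompatible"])
    def test_uniform_strain_reproduced_exactly(self, materials, formulation):
        grid = random_connected_blob(3)
        mesh = build_mesh(grid)
        A = np.array([[1.2e-3, 3.0e-4, -2.0e-4], [3.0e-4, -7.0e-4, 1.0e-4], [-2.0e-4, 1.0e-4, 5.0e-4]])
        surf = np.where(mesh.surface_node_mask())[0]
        cons = ConstraintSet(fixed_nodes=surf, fixed_values=mesh.node_coords[surf] @ A.T)
        sol = solve(mesh, materials, zero_loads(mesh), cons, method="direct", formulation=formulation)
        expected = np.array([A[0, 0], A[1, 1], A[2, 2], A[0, 1], A[1, 2], A[2, 0]])
        assert np.abs(sol.element_strain - expected).max() < 1e-10


class TestSolve:
    def test_zero_load_gives_zero_displacement(self, materials):
        grid = block_grid()
        mesh = build_mesh(grid)
        fixed = np.where(mesh.node_ijk[:, 0] == 0)[0]
        sol = solve(mesh, materials, zero_loads(mesh), ConstraintSet(fixed_nodes=fixed))
        assert np.abs(sol.displacements).max() == 0.0
        assert np.abs(sol.von_mises).max() == 0.0

    def test_single_element_uniaxial_closed_form(self, materials):
        grid = block_grid((1, 1, 1), spacing=1.0)
        mesh = build_mesh(grid)
        sigma = 5.0
        f = np.zeros((mesh.n_nodes, 3))
        plus_x = np.where(mesh.node_ijk[:, 0] == 1)[0]
        f[plus_x, 0] = sigma / len(plus_x)
        rollers = []
        for axis in range(3):
            for n in np.where(mesh.node_ijk[:, axis] == 0)[0]:
                rollers.append(3 * n + axis)
        cons = ConstraintSet(fixed_nodes=np.empty(0, int), extra_dofs=np.array(rollers))
        sol = solve(mesh, materials, LoadCase(forces=f), cons, method="direct")
        E, nu = 17000.0, 0.3
        assert sol.element_strain[0, 0] == pytest.approx(sigma / E, rel=1e-8)
        assert sol.element_strain[0, 1] == pytest.approx(-nu * sigma / E, rel=1e-8)
        assert sol.element_strain[0, 2] == pytest.approx(-nu * sigma / E, rel=1e-8)
        assert sol.von_mises[0] == pytest.approx(sigma, rel=1e-8)

    def test_missing_constraints_name_free_rigid_modes(self, materials):
        grid = block_grid()
        mesh = build_mesh(grid)
        with pytest.raises(SingularModelError, match="rigid-body"):
            solve(mesh, materials, zero_loads(mesh), ConstraintSet(fixed_nodes=np.empty(0, int)))
        # bite-only constraints along one direction leave in-plane modes free
        tips = np.arange(4)
        cons = ConstraintSet(
            fixed_nodes=np.empty(0, int), bite_nodes=tips, bite_direction=np.array([0.0, 0.0, 1.0])
        )
        with pytest.raises(SingularModelError):
            solve(mesh, materials, zero_loads(mesh), cons)

    def test_non_convergence_raises(self, materials):
        grid = block_grid((6, 2, 2))
        mesh = build_mesh(grid)
        fixed = np.where(mesh.node_ijk[:, 0] == 0)[0]
        f = np.zeros((mesh.n_nodes, 3))
        f[-1, 2] = 1.0
        with pytest.raises(ConvergenceError):
            solve(mesh, materials, LoadCase(forces=f), ConstraintSet(fixed_nodes=fixed), max_iter=2)

    def test_linearity_in_load(self, materials):
        grid = block_grid((4, 3, 3), spacing=0.5)
        mesh = build_mesh(grid)
        fixed = np.where(mesh.node_ijk[:, 0] == 0)[0]
        f = np.zeros((mesh.n_nodes, 3))
        f[np.where(mesh.node_ijk[:, 0] == 4)[0], 2] = -0.5
        lc = LoadCase(forces=f)
        cons = ConstraintSet(fixed_nodes=fixed)
        s1 = solve(mesh, materials, lc, cons, tol=1e-12, method="direct")
        s3 = solve(mesh, materials, lc.scaled(3.0), cons, tol=1e-12, method="direct")
        np.testing.assert_allclose(s3.displacements, 3.0 * s1.displacements, rtol=1e-9, atol=1e-16)
        np.testing.assert_allclose(s3.von_mises, 3.0 * s1.von_mises, rtol=1e-9)

    def test_stiffer_material_does_not_increase_compliance(self):
        labels = np.full((6, 2, 2), int(Label.BONE), np.uint8)
        soft = VoxelGrid(labels.copy(), 0.5)
        labels[2:4] = Label.INCISOR  # upgrade mid-span to the stiffer material
        stiff = VoxelGrid(labels, 0.5)
        mats = MaterialTable.default()
        work = {}
        for name, grid in (("soft", soft), ("stiff", stiff)):
            mesh = build_mesh(grid)
            fixed = np.where(mesh.node_ijk[:, 0] == 0)[0]
            f = np.zeros((mesh.n_nodes, 3))
            f[np.where(mesh.node_ijk[:, 0] == 6)[0], 2] = -1.0
            sol = solve(mesh, mats, LoadCase(forces=f), ConstraintSet(fixed_nodes=fixed), method="direct")
            work[name] = float(np.sum(f * sol.displacements))
        assert work["stiff"] <= work["soft"]

    def test_oblique_bite_direction_honoured(self, materials):
        grid = block_grid((4, 3, 3), spacing=0.5)
        mesh = build_mesh(grid)
        fixed = np.where(mesh.node_ijk[:, 0] == 0)[0]
        bite = np.where(mesh.node_ijk[:, 0] == 4)[0]
        d = np.array([1.0, 1.0, 2.0]) / 3.0
        f = np.zeros((mesh.n_nodes, 3))
        f[bite] = [0.1, -0.2, 0.3]
        cons = ConstraintSet(fixed_nodes=fixed, bite_nodes=bite, bite_direction=d)
        sol = solve(mesh, materials, LoadCase(forces=f), cons, method="direct")
        proj = sol.displacements[bite] @ cons.bite_direction
        assert np.abs(proj).max() < 1e-12


class TestRecovery:
    def test_rigid_rotation_produces_no_strain(self, materials):
        grid = block_grid((3, 3, 3), spacing=0.5)
        mesh = build_mesh(grid)
        theta = 1e-6
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        u = mesh.node_coords @ (R - np.eye(3)).T
        strain, _ = recover_strain_stress(mesh, materials, u)
        assert np.abs(strain).max() < 1e-10

    def test_linear_field_recovered_exactly(self, materials):
        grid = block_grid((4, 2, 3), spacing=0.25)
        mesh = build_mesh(grid)
        A = np.array([[2e-3, 5e-4, 0.0], [5e-4, -1e-3, 2e-4], [0.0, 2e-4, 7e-4]])
        strain, stress = recover_strain_stress(mesh, materials, mesh.node_coords @ A.T)
        expected = np.array([A[0, 0], A[1, 1], A[2, 2], A[0, 1], A[1, 2], A[2, 0]])
        np.testing.assert_allclose(strain, np.tile(expected, (mesh.n_elements, 1)), atol=1e-15)
        E, nu = 17000.0, 0.3
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        tr = expected[:3].sum()
        np.testing.assert_allclose(stress[0, 0], 2 * mu * A[0, 0] + lam * tr, rtol=1e-12)

    def test_centroid_strain_matches_finite_differences(self, materials):
        grid = block_grid((2, 2, 2), spacing=0.5)
        mesh = build_mesh(grid)
        r = np.random.default_rng(7)
        u = r.normal(scale=1e-3, size=(mesh.n_nodes, 3))
        strain, _ = recover_strain_stress(mesh, materials, u)

        def interp(e, p):
            # trilinear interpolation of u inside element e at local p in [0,1]^3
            corners = mesh.conn[e]
            vals = np.zeros(3)
            from gnawfe.hexfem import _CORNERS

            for i, c in enumerate(_CORNERS):
                w = np.prod(np.where(c == 1, p, 1 - p))
                vals += w * u[corners[i]]
            return vals

        h = mesh.spacing
        eps_fd = 1e-5
        for e in range(mesh.n_elements):
            grad = np.zeros((3, 3))
            for axis in range(3):
                dp = np.zeros(3)
                dp[axis] = eps_fd
                grad[:, axis] = (interp(e, 0.5 + dp) - interp(e, 0.5 - dp)) / (2 * eps_fd * h)
            sym = 0.5 * (grad + grad.T)
            expected = [sym[0, 0], sym[1, 1], sym[2, 2], sym[0, 1], sym[1, 2], sym[2, 0]]
            np.testing.assert_allclose(strain[e], expected, rtol=1e-6, atol=1e-12)


class TestTensorInvariants:
    def test_von_mises_uniaxial_and_hydrostatic(self):
        assert von_mises(np.array([3.0, 0, 0, 0, 0, 0])) == pytest.approx(3.0)
        assert von_mises(np.array([-2.0, 0, 0, 0, 0, 0])) == pytest.approx(2.0)
        assert von_mises(np.diag([5.0, 5.0, 5.0])) == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_rotation_invariant(self):
        r = np.random.default_rng(11)
        for _ in range(50):
            S = r.normal(size=(3, 3))
            S = 0.5 * (S + S.T)
            A = np.linalg.qr(r.normal(size=(3, 3)))[0]
            v1, v2 = von_mises(S), von_mises(A @ S @ A.T)
            assert abs(v1 - v2) <= 1e-10 * max(1.0, v1)

    def test_principal_strains_sorted_and_shear(self):
        np.testing.assert_allclose(principal_strains(np.diag([1.0, 3.0, 2.0])), [3, 2, 1])
        gamma = 4e-3
        voigt = np.array([0, 0, 0, gamma / 2, 0, 0])  # tensor shear e_xy
        np.testing.assert_allclose(
            principal_strains(voigt), [gamma / 2, 0, -gamma / 2], atol=1e-15
        )

    def test_principal_strain_invariants(self):
        r = np.random.default_rng(5)
        S = r.normal(size=(40, 3, 3))
        S = 0.5 * (S + S.transpose(0, 2, 1))
        p = principal_strains(S)
        assert (np.diff(p, axis=1) <= 1e-12).all()  # descending
        np.testing.assert_allclose(p.sum(axis=1), np.trace(S, axis1=1, axis2=2), atol=1e-12)
        np.testing.assert_allclose(p.prod(axis=1), np.linalg.det(S), rtol=1e-8, atol=1e-12)


class TestReactions:
    def test_point_load_equilibrium(self, materials):
        grid = block_grid((3, 3, 3), spacing=0.5)
        mesh = build_mesh(grid)
        fixed = np.where(mesh.node_ijk[:, 2] == 0)[0]
        f = np.zeros((mesh.n_nodes, 3))
        top = np.where(mesh.node_ijk[:, 2] == 3)[0]
        P = 2.5
        f[top[0], 2] = -P
        sol = solve(mesh, materials, LoadCase(forces=f), ConstraintSet(fixed_nodes=fixed), method="direct")
        assert sol.reactions[fixed, 2].sum() == pytest.approx(P, rel=1e-9)
        assert sol.solver_report["equilibrium_residual"] < 1e-9

    def test_bite_force_sign_and_balance(self, coarse_mandible, materials):
        from gnawfe.loading import build_constraints, build_load_case, read_muscle_table
        from gnawfe.synthetic_mandible import default_muscle_table

        grid, ann = coarse_mandible
        mesh = build_mesh(grid)
        lc = build_load_case(grid, ann, mesh, read_muscle_table(default_muscle_table()))
        cons = build_constraints(grid, ann, mesh)
        sol = solve(mesh, materials, lc, cons)
        _, bite = reactions_and_bite_force(sol, cons)
        assert bite > 0  # jaw pushes up into the bite constraint
        assert sol.solver_report["equilibrium_residual"] < 1e-6
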