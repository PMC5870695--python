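"""Stiffness assembly, St. Venant loads, reference handling, solver,
transfer matrix and leadfields."""
import numpy as np
import pytest
from scipy.sparse.linalg import spsolve

import hexfem as hx
from hexfem._element import CORNER_OFFSETS
from oracles import element_energy_quadrature, element_stiffness_quadrature

UNIT_CUBE = CORNER_OFFSETS.astype(float)


class TestElementStiffness:
    def test_zero_conductivity(self):
        assert np.all(hx.element_stiffness(UNIT_CUBE, 0.0) == 0.0)

    @pytest.mark.parametrize(
        "coords",
        [
            UNIT_CUBE,
            2.0 * UNIT_CUBE,
            UNIT_CUBE * np.array([1.0, 2.0, 0.5]),  # anisotropic box
            UNIT_CUBE + 0.3 * UNIT_CUBE[:, [1]] * np.array([1.0, 0, 0]),  # shear
        ],
    )
    def test_matches_quadrature_oracle(self, coords):
        K = hx.element_stiffness(coords, 1.7)
        K_ref = element_stiffness_quadrature(coords, 1.7, order=4)
        assert np.abs(K - K_ref).max() < 1e-10

    def test_scaling_law(self):
        K1 = hx.element_stiffness(UNIT_CUBE, 1.0)
        K2 = hx.element_stiffness(2.0 * UNIT_CUBE, 1.0)
        assert np.allclose(K2, 2.0 * K1, atol=1e-12)

    def test_symmetry_and_rowsums(self):
        rng = np.random.default_rng(0)
        coords = UNIT_CUBE + 0.15 * rng.standard_normal((8, 3))
        K = hx.element_stiffness(coords, 0.8)
        assert np.abs(K - K.T).max() < 1e-12
        assert np.abs(K.sum(axis=1)).max() < 1e-12

    def test_inverted_element_rejected(self):
        coords = UNIT_CUBE.copy()
        coords[:, 0] *= -1.0  # left-handed
        with pytest.raises(ValueError, match="Jacobian"):
            hx.element_stiffness(coords, 1.0)


class TestAssembly:
    def test_single_element_equals_element_matrix(self):
        vol = hx.LabeledVolume(np.ones((1, 1, 1), dtype=np.int32), voxel_size=2.0)
        mesh = hx.build_hex_mesh(vol, 0.0, hx.ConductivityTable({1: 0.5}))
        A = hx.assemble_stiffness(mesh).matrix.toarray()
        Ke = hx.element_stiffness(mesh.element_coords(0), 0.5)
        # map element-local to global ordering
        perm = mesh.elements[0]
        full = np.zeros((8, 8))
        full[np.ix_(perm, perm)] = Ke
        assert np.allclose(A, full, atol=1e-14)

    def test_energy_matches_quadrature_oracle(self):
        rng = np.random.default_rng(7)
        data = rng.integers(1, 3, (3, 3, 3)).astype(np.int32)
        vol = hx.LabeledVolume(data, voxel_size=1.3)
        table = hx.ConductivityTable({1: 0.33, 2: 1.79})
        mesh = hx.build_hex_mesh(vol, 0.0, table)
        A = hx.assemble_stiffness(mesh)
        u = rng.standard_normal(mesh.n_nodes)
        energy = float(u @ (A.matrix @ u))
        ref = sum(
            element_energy_quadrature(
                mesh.element_coords(e),
                mesh.element_conductivity[e],
                u[mesh.elements[e]],
            )
            for e in range(mesh.n_elements)
        )
        assert abs(energy - ref) <= 1e-9 * abs(ref)

    def test_rowsums_vanish_and_psd(self, brain_sphere):
        A = brain_sphere["A"].matrix
        assert np.abs(np.asarray(A.sum(axis=1))).max() < 1e-10
        rng = np.random.default_rng(1)
        for _ in range(5):
            u = rng.standard_normal(A.shape[0])
            assert u @ (A @ u) >= -1e-10

    def test_conductivity_linearity(self):
        data = np.ones((2, 2, 2), dtype=np.int32)
        vol = hx.LabeledVolume(data)
        A1 = hx.assemble_stiffness(
            hx.build_hex_mesh(vol, 0.0, hx.ConductivityTable({1: 0.4}))
        ).matrix
        A2 = hx.assemble_stiffness(
            hx.build_hex_mesh(vol, 0.0, hx.ConductivityTable({1: 0.8}))
        ).matrix
        assert np.allclose(A2.toarray(), 2.0 * A1.toarray(), atol=1e-14)

    def test_disconnected_mesh_warns(self):
        data = np.zeros((3, 1, 1), dtype=np.int32)
        data[0] = data[2] = 1
        with pytest.warns(UserWarning, match="disconnected"):
            hx.assemble_stiffness(hx.build_hex_mesh(hx.LabeledVolume(data), 0.0))


class TestVenant:
    def test_zero_moment_and_homogeneity(self, brain_sphere):
        mesh = brain_sphere["mesh"]
        b0 = hx.venant_rhs(mesh, hx.Dipole([3.0, 1.0, -2.0], [0.0, 0.0, 0.0]))
        assert np.all(b0.values == 0.0)
        m = np.array([0.3, -1.2, 0.7])
        b1 = hx.venant_rhs(mesh, hx.Dipole([3.0, 1.0, -2.0], m))
        b2 = hx.venant_rhs(mesh, hx.Dipole([3.0, 1.0, -2.0], 2.0 * m))
        assert np.allclose(b2.values, 2.0 * b1.values, rtol=1e-12)

    def test_moment_identities(self, brain_sphere):
        """Monopole and first-moment sums by direct summation over the patch."""
        mesh = brain_sphere["mesh"]
        rng = np.random.default_rng(5)
        for _ in range(25):
            x = rng.uniform(-1, 1, 3)
            x = x / np.linalg.norm(x) * rng.uniform(0, 15)
            m = rng.standard_normal(3)
            b = hx.venant_rhs(mesh, hx.Dipole(x, m))
            assert abs(b.values.sum()) <= 1e-12 * np.abs(b.values).max()
            mom = b.values @ (mesh.nodes[b.node_indices] - x)
            assert np.linalg.norm(mom - m) <= 1e-8 * np.linalg.norm(m)

    def test_outside_mesh_rejected(self, brain_sphere):
        with pytest.raises(ValueError, match="outside"):
            hx.venant_rhs(brain_sphere["mesh"], hx.Dipole([50.0, 0, 0], [1.0, 0, 0]))

    def test_admissible_label_enforced(self, four_shell_scan):
        mesh = four_shell_scan["mesh"]
        with pytest.raises(ValueError, match="non-admissible"):
            # radius 23 mm lies in the skull shell (label 3)
            hx.venant_rhs(mesh, hx.Dipole([0.0, 0.0, 23.0], [1.0, 0, 0]),
                          admissible_labels={1})


class TestReferenceAndSolver:
    def test_reference_node_grounded(self, brain_sphere):
        mesh, A = brain_sphere["mesh"], brain_sphere["A"]
        b = hx.venant_rhs(mesh, hx.Dipole([2.0, -3.0, 4.0], [1.0, 1.0, 0.0]))
        u = hx.solve_forward(A, b, ref_node=0)
        assert u[0] == 0.0

    def test_gauge_invariance(self, brain_sphere):
        mesh, A = brain_sphere["mesh"], brain_sphere["A"]
        b = hx.venant_rhs(mesh, hx.Dipole([2.0, -3.0, 4.0], [0.5, -1.0, 2.0]))
        u1 = hx.solve_forward(A, b, ref_node=0, rel_tol=1e-10)
        u2 = hx.solve_forward(A, b, ref_node=A.n // 2, rel_tol=1e-10)
        d1 = u1 - u1[17]
        d2 = u2 - u2[17]
        assert np.abs(d1 - d2).max() <= 1e-8 * np.abs(d1).max()

    def test_constrained_matrix_spd_probe(self, brain_sphere):
        sys_ = hx.apply_reference(brain_sphere["A"], ref_node=3)
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.standard_normal(sys_.matrix.shape[0])
            assert x @ (sys_.matrix @ x) > 0.0

    def test_invalid_ref_node(self, brain_sphere):
        with pytest.raises(IndexError):
            hx.apply_reference(brain_sphere["A"], ref_node=brain_sphere["A"].n)

    def test_zero_rhs(self, brain_sphere):
        sys_ = hx.apply_reference(brain_sphere["A"], ref_node=0)
        u = hx.solve_pcg(sys_, np.zeros(sys_.matrix.shape[0]))
        assert np.all(u == 0.0)

    def test_matches_dense_direct_solve(self):
        data = np.ones((4, 4, 4), dtype=np.int32)  # 125 nodes
        mesh = hx.build_hex_mesh(hx.LabeledVolume(data), 0.0,
                                 hx.ConductivityTable({1: 1.0}))
        A = hx.assemble_stiffness(mesh)
        sys_ = hx.apply_reference(A, ref_node=0)
        rng = np.random.default_rng(3)
        b = rng.standard_normal(A.n - 1)
        u = hx.solve_pcg(sys_, b, rel_tol=1e-12)
        u_ref = np.linalg.solve(sys_.matrix.toarray(), b)
        assert np.abs(u - u_ref).max() <= 1e-8 * np.abs(u_ref).max()

    def test_tighter_tolerance_never_worse(self, brain_sphere):
        sys_ = hx.apply_reference(brain_sphere["A"], ref_node=0)
        rng = np.random.default_rng(9)
        b = rng.standard_normal(sys_.matrix.shape[0])
        res = []
        for tol in (1e-4, 1e-8):
            u = hx.solve_pcg(sys_, b, rel_tol=tol)
            res.append(np.linalg.norm(sys_.matrix @ u - b) / np.linalg.norm(b))
        assert res[1] <= res[0]


class TestTransfer:
    def test_reference_row_zero(self, brain_sphere_transfer):
        T = brain_sphere_transfer
        assert np.all(T.matrix[T.ref_index] == 0.0)

    def test_two_electrode_equivalence(self, brain_sphere):
        mesh, A = brain_sphere["mesh"], brain_sphere["A"]
        proj = brain_sphere["proj"]
        two = hx.ElectrodeSet(
            ["a", "b"],
            positions=proj.positions[:2],
            node_index=proj.node_index[:2],
        )
        T = hx.transfer_matrix(A, two, rel_tol=1e-10)
        b = hx.venant_rhs(mesh, hx.Dipole([1.0, 4.0, -2.0], [1.0, 0.5, 0.2]))
        u = hx.solve_forward(A, b, ref_node=int(two.node_index[1]), rel_tol=1e-10)
        expected = u[two.node_index[0]] - u[two.node_index[1]]
        assert np.isclose(T.apply(b)[0], expected, atol=1e-10)

    def test_batch_equivalence_with_direct_solves(self, brain_sphere,
                                                  brain_sphere_transfer):
        """T.b vs exact direct solves for random dipoles on the phantom."""
        mesh, A, proj = (brain_sphere[k] for k in ("mesh", "A", "proj"))
        T = brain_sphere_transfer
        ref_node = int(proj.node_index[T.ref_index])
        sys_ = hx.apply_reference(A, ref_node)
        lu_factor = sys_.matrix.tocsc()
        rng = np.random.default_rng(12)
        maxdev = 0.0
        for _ in range(20):
            x = rng.uniform(-1, 1, 3)
            x = x / np.linalg.norm(x) * rng.uniform(0, 15)
            b = hx.venant_rhs(mesh, hx.Dipole(x, rng.standard_normal(3)))
            u = sys_.expand(spsolve(lu_factor, sys_.reduce(b.toarray())))
            direct = u[proj.node_index] - u[ref_node]
            maxdev = max(maxdev, np.abs(T.apply(b) - direct).max())
        assert maxdev <= 1e-6


class TestLeadfield:
    def test_linearity_and_average_reference(self, four_shell_scan):
        L, T, mesh = (four_shell_scan[k] for k in ("L", "T", "mesh"))
        # columns sum to zero in average reference
        assert np.abs(L.matrix.sum(axis=0)).max() < 1e-10
        m = np.array([0.2, -0.4, 1.0])
        k = 5
        via_lf = L.potentials(k, m)
        b = hx.venant_rhs(mesh, hx.Dipole(L.positions[k], m))
        via_transfer = hx.average_reference(T.apply(b))
        assert np.allclose(via_lf, via_transfer, atol=1e-12)

    def test_transfer_vs_direct_rdm(self, brain_sphere, brain_sphere_transfer):
        """Leadfield columns agree with per-dipole direct solves to RDM < 1e-6."""
        mesh, A, proj = (brain_sphere[k] for k in ("mesh", "A", "proj"))
        T = brain_sphere_transfer
        positions = np.array([[0.0, 0, 0], [5.0, -3.0, 2.0], [-8.0, 1.0, 6.0]])
        L = hx.compute_leadfield(T, mesh, positions)
        ref_node = int(proj.node_index[T.ref_index])
        sys_ = hx.apply_reference(A, ref_node)
        for k, x in enumerate(positions):
            for ax in range(3):
                m = np.zeros(3)
                m[ax] = 1.0
                b = hx.venant_rhs(mesh, hx.Dipole(x, m))
                u = sys_.expand(
                    spsolve(sys_.matrix.tocsc(), sys_.reduce(b.toarray()))
                )
                direct = hx.average_reference(u[proj.node_index] - u[ref_node])
                assert hx.rdm(L.matrix[:, 3 * k + ax], direct) < 1e-6

    def test_inadmissible_sources_skipped(self, four_shell_scan):
        T, mesh = four_shell_scan["T"], four_shell_scan["mesh"]
        pos = np.array([[0.0, 0, 0], [0.0, 0, 23.0], [100.0, 0, 0]])
        L = hx.compute_leadfield(T, mesh, pos, admissible_labels={1})
        assert L.skipped == [1, 2]
        assert L.n_sources == 1
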