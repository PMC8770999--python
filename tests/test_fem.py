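import numpy as np
import pytest

import mandifem as mf
from mandifem.fem import FEMError
from conftest import merge_meshes, solve_cantilever, contact_blocks


def cst_stiffness_oracle(coords, E, nu):
    """Independent textbook constant-strain-tetrahedron stiffness.

    Shape-function coefficients come from inverting the [1 x y z] matrix,
    and K = V B^T D B is accumulated entry by entry.
    """
    A = np.hstack([np.ones((4, 1)), coords])
    C = np.linalg.inv(A)
    V = abs(np.linalg.det(A)) / 6.0
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    for i in range(3):
        for j in range(3):
            D[i, j] = lam
        D[i, i] += 2 * mu
        D[i + 3, i + 3] = mu
    B = np.zeros((6, 12))
    for a in range(4):
        bx, by, bz = C[1, a], C[2, a], C[3, a]
        B[0, 3 * a] = bx
        B[1, 3 * a + 1] = by
        B[2, 3 * a + 2] = bz
        B[3, 3 * a], B[3, 3 * a + 1] = by, bx
        B[4, 3 * a + 1], B[4, 3 * a + 2] = bz, by
        B[5, 3 * a], B[5, 3 * a + 2] = bz, bx
    K = np.zeros((12, 12))
    for i in range(12):
        for j in range(12):
            K[i, j] = V * B[:, i] @ D @ B[:, j]
    return K


def single_tet_mesh():
    coords = np.array([[0.0, 0.0, 0.0], [1.2, 0.1, 0.0],
                       [0.2, 1.1, 0.05], [0.1, 0.2, 0.9]])
    return mf.Mesh(nodes=coords, tets=np.array([[0, 1, 2, 3]]),
                   element_sets={"solid": np.array([0])})


class TestAssembly:
    def test_single_tet_matches_textbook_oracle(self):
        mesh = single_tet_mesh()
        E, nu = 10000.0, 0.3
        system = mf.assemble_stiffness(mesh, {"solid": mf.Material("solid",
                                                                   E, nu)})
        K = system.K.toarray()
        Kref = cst_stiffness_oracle(mesh.nodes, E, nu)
        scale = np.abs(Kref).max()
        assert np.abs(K - Kref).max() < 1e-10 * scale

    def test_stiffness_scales_linearly_with_modulus(self):
        mesh = single_tet_mesh()
        K1 = mf.assemble_stiffness(
            mesh, {"solid": mf.Material("solid", 1000.0, 0.3)}).K.toarray()
        K2 = mf.assemble_stiffness(
            mesh, {"solid": mf.Material("solid", 2000.0, 0.3)}).K.toarray()
        assert np.allclose(K2, 2 * K1, rtol=1e-12)

    def test_symmetry(self, small_mandible, materials):
        K = mf.assemble_stiffness(small_mandible, materials).K
        asym = abs(K - K.T).max()
        assert asym < 1e-9 * abs(K).max()

    def test_six_rigid_body_modes_before_constraints(self):
        mesh = mf.box_mesh(2, 2, 2, 2, 2, 2)
        K = mf.assemble_stiffness(
            mesh, {"solid": mf.Material("solid", 1000.0, 0.3)}).K
        assert mf.count_rigid_body_modes(K) == 6

    def test_disconnected_mesh_has_extra_zero_modes(self):
        a = mf.box_mesh(1, 1, 1, 1, 1, 1)
        b = mf.box_mesh(1, 1, 1, 1, 1, 1, origin=(5.0, 0, 0))
        mesh = merge_meshes(a, b)
        mats = {"a_solid": mf.Material("a_solid", 1000.0, 0.3),
                "b_solid": mf.Material("b_solid", 1000.0, 0.3)}
        K = mf.assemble_stiffness(mesh, mats).K
        assert mf.count_rigid_body_modes(K) == 12

    def test_missing_material_names_region(self, small_mandible):
        with pytest.raises(FEMError, match="trabecular"):
            mf.assemble_stiffness(small_mandible,
                                  {"cortical": mf.Material("cortical",
                                                           17000.0, 0.3)})


class TestPatchAndBeam:
    def test_uniform_strain_patch_reproduced_exactly(self):
        # linear tets are exact for any uniform strain state
        mesh = mf.box_mesh(2.0, 2.0, 2.0, 2, 2, 2)
        system = mf.apply_ties(mf.assemble_stiffness(
            mesh, {"solid": mf.Material("solid", 1000.0, 0.3)}))
        A = np.array([[1e-3, 4e-4, 0.0], [4e-4, -2e-4, 1e-4],
                      [0.0, 1e-4, 5e-4]])
        x = mesh.nodes
        on_bnd = np.any((np.abs(x) < 1e-12) | (np.abs(x - 2.0) < 1e-12),
                        axis=1)
        u_exact = x @ A.T
        cons = [(int(n), d, float(u_exact[n, d]))
                for n in np.flatnonzero(on_bnd) for d in range(3)]
        lc = mf.LoadCase(forces=np.zeros((mesh.n_nodes, 3)), constraints=cons)
        sol = mf.solve_contact(system, lc)
        assert np.abs(sol.displacements - u_exact).max() < 1e-10
        field = mf.element_strain(sol, mesh)
        assert np.abs(field.element_tensors - A).max() < 1e-10

    def test_cantilever_converges_to_euler_deflection(self):
        euler = 10.0 * 100.0 ** 3 / (3 * 10000.0 * (10.0 * 10.0 ** 3 / 12))
        tips = []
        for n in [(10, 2, 2), (20, 4, 4), (30, 5, 5)]:
            _m, _s, sol, tip = solve_cantilever(n)
            tips.append(-sol.displacements[tip, 2].mean())
        assert tips[0] < tips[1] < tips[2] < 1.1 * euler  # monotone from below

    def test_energy_consistency(self):
        mesh, system, sol, _tip = solve_cantilever((10, 2, 2))
        u = sol.displacements.ravel()
        strain_energy = 0.5 * u @ (system.K @ u)
        external_work = 0.5 * sol.loadcase.forces.ravel() @ u
        assert strain_energy == pytest.approx(external_work, rel=1e-9)

    def test_reactions_balance_tip_load_exactly(self):
        _mesh, system, sol, _tip = solve_cantilever((10, 2, 2))
        _r, residual = mf.compute_reactions(sol, system)
        assert residual < 1e-10
        rz = sum(r for (n, d, _v), r in zip(sol.loadcase.constraints,
                                            sol.reactions) if d == 2)
        assert rz == pytest.approx(10.0, rel=1e-9)

    def test_zero_load_zero_reactions(self):
        mesh = mf.box_mesh(1, 1, 1, 1, 1, 1)
        system = mf.apply_ties(mf.assemble_stiffness(
            mesh, {"solid": mf.Material("solid", 1000.0, 0.3)}))
        cons = [(int(n), d, 0.0)
                for n in np.flatnonzero(np.abs(mesh.nodes[:, 0]) < 1e-12)
                for d in range(3)]
        sol = mf.solve_contact(system, mf.LoadCase(
            forces=np.zeros((mesh.n_nodes, 3)), constraints=cons))
        assert np.abs(sol.reactions).max() == 0.0


class TestTies:
    @staticmethod
    def stacked_blocks(tied):
        a = mf.box_mesh(1.0, 1.0, 1.0, 2, 2, 2)
        b = mf.box_mesh(1.0, 1.0, 1.0, 2, 2, 2, origin=(0, 0, 1.0))
        mesh = merge_meshes(a, b)
        bot = np.flatnonzero(np.abs(mesh.nodes[:, 2]) < 1e-12)
        ifc_a = np.flatnonzero((np.abs(mesh.nodes[:, 2] - 1.0) < 1e-12)
                               & (np.arange(mesh.n_nodes) < a.n_nodes))
        ifc_b = np.flatnonzero((np.abs(mesh.nodes[:, 2] - 1.0) < 1e-12)
                               & (np.arange(mesh.n_nodes) >= a.n_nodes))
        oa = np.lexsort((mesh.nodes[ifc_a, 1], mesh.nodes[ifc_a, 0]))
        ob = np.lexsort((mesh.nodes[ifc_b, 1], mesh.nodes[ifc_b, 0]))
        if tied:
            mesh.tie_pairs = np.column_stack([ifc_b[ob], ifc_a[oa]])
        top = np.flatnonzero(np.abs(mesh.nodes[:, 2] - 2.0) < 1e-12)
        f = np.zeros((mesh.n_nodes, 3))
        f[top, 2] = 1.0 / len(top)
        cons = [(int(n), d, 0.0) for n in bot for d in range(3)]
        mats = {"a_solid": mf.Material("a_solid", 1000.0, 0.3),
                "b_solid": mf.Material("b_solid", 1000.0, 0.3)}
        system = mf.apply_ties(mf.assemble_stiffness(mesh, mats))
        sol = mf.solve_contact(system, mf.LoadCase(forces=f, constraints=cons))
        return mesh, sol, (ifc_a[oa], ifc_b[ob])

    def test_tied_stack_equals_monolithic_block(self):
        mesh, sol, _ = self.stacked_blocks(tied=True)
        mono = mf.box_mesh(1.0, 1.0, 1.0 * 2, 2, 2, 4)
        system = mf.apply_ties(mf.assemble_stiffness(
            mono, {"solid": mf.Material("solid", 1000.0, 0.3)}))
        bot = np.flatnonzero(np.abs(mono.nodes[:, 2]) < 1e-12)
        top = np.flatnonzero(np.abs(mono.nodes[:, 2] - 2.0) < 1e-12)
        f = np.zeros((mono.n_nodes, 3))
        f[top, 2] = 1.0 / len(top)
        cons = [(int(n), d, 0.0) for n in bot for d in range(3)]
        ref = mf.solve_contact(system, mf.LoadCase(forces=f, constraints=cons))
        from scipy.spatial import cKDTree
        _d, idx = cKDTree(mono.nodes).query(mesh.nodes)
        assert np.abs(sol.displacements
                      - ref.displacements[idx]).max() < 1e-10

    def test_untied_interface_opens(self):
        _mesh, sol, (ia, ib) = self.stacked_blocks(tied=False)
        jump = np.abs(sol.displacements[ib] - sol.displacements[ia]).max()
        assert jump > 1e-6

    def test_screw_ties_transmit_load_across_gap(self):
        # two blocks bridged only by tie pairs: loading one moves the other
        a = mf.box_mesh(1, 1, 1, 1, 1, 1)
        b = mf.box_mesh(1, 1, 1, 1, 1, 1, origin=(1.5, 0, 0))
        mesh = merge_meshes(a, b)
        fa = np.flatnonzero(np.abs(mesh.nodes[:, 0] - 1.0) < 1e-12)
        fb = np.flatnonzero(np.abs(mesh.nodes[:, 0] - 1.5) < 1e-12)
        oa = np.lexsort((mesh.nodes[fa, 2], mesh.nodes[fa, 1]))
        ob = np.lexsort((mesh.nodes[fb, 2], mesh.nodes[fb, 1]))
        mesh.tie_pairs = np.column_stack([fb[ob], fa[oa]])
        mats = {"a_solid": mf.Material("a_solid", 1000.0, 0.3),
                "b_solid": mf.Material("b_solid", 1000.0, 0.3)}
        system = mf.apply_ties(mf.assemble_stiffness(mesh, mats))
        left = np.flatnonzero(np.abs(mesh.nodes[:, 0]) < 1e-12)
        cons = [(int(n), d, 0.0) for n in left for d in range(3)]
        f = np.zeros((mesh.n_nodes, 3))
        pulled = np.flatnonzero(np.abs(mesh.nodes[:, 0] - 2.5) < 1e-12)
        f[pulled, 0] = 1.0
        sol = mf.solve_contact(system, mf.LoadCase(forces=f, constraints=cons))
        assert sol.displacements[pulled, 0].mean() > 1e-6
        # tied partners move identically
        assert np.abs(sol.displacements[fb[ob]]
                      - sol.displacements[fa[oa]]).max() < 1e-12


class TestContact:
    @staticmethod
    def _solve(mesh, cons, forces=None, contact=None):
        mats = {k: mf.Material(k, 1000.0, 0.3) for k in mesh.element_sets}
        system = mf.apply_ties(mf.assemble_stiffness(mesh, mats))
        f = np.zeros((mesh.n_nodes, 3)) if forces is None else forces
        lc = mf.LoadCase(forces=f, constraints=cons)
        return mf.solve_contact(system, lc, contact,
                                pairs=mesh.fracture_pairs), system, lc

    def test_open_gap_equals_contact_free_solution(self):
        mesh = contact_blocks()
        left = np.flatnonzero(np.abs(mesh.nodes[:, 0]) < 1e-9)
        right = np.flatnonzero(np.abs(mesh.nodes[:, 0] - 20.2) < 1e-9)
        # pull the blocks apart: the gap widens, contact must do nothing
        cons = ([(int(n), d, 0.0) for n in left for d in range(3)]
                + [(int(n), 0, 0.1) for n in right]
                + [(int(n), d, 0.0) for n in right for d in (1, 2)])
        sol, system, lc = self._solve(mesh, cons)
        assert sol.converged
        assert np.all(sol.contact_normal == 0.0)
        free = mf.solve_contact(system, lc, pairs=None)
        assert np.abs(sol.displacements - free.displacements).max() < 1e-12

    def test_overclosure_gives_compression_within_penetration_tol(self):
        mesh = contact_blocks(gap=0.2)
        left = np.flatnonzero(np.abs(mesh.nodes[:, 0]) < 1e-9)
        right = np.flatnonzero(np.abs(mesh.nodes[:, 0] - 20.2) < 1e-9)
        cons = ([(int(n), d, 0.0) for n in left for d in range(3)]
                + [(int(n), 0, -0.3) for n in right]
                + [(int(n), d, 0.0) for n in right for d in (1, 2)])
        contact = mf.ContactParams(penetration_tol=1e-3)
        sol, _sys, _lc = self._solve(mesh, cons, contact=contact)
        assert sol.converged
        assert np.all(sol.contact_normal > 0)
        fp = mesh.fracture_pairs
        du = sol.displacements[fp.anterior] - sol.displacements[fp.posterior]
        gap = fp.distance + np.einsum("ij,ij->i", du, fp.normal)
        assert gap.min() >= -1e-3

    def test_coulomb_bound_respected_under_shear(self):
        mesh = contact_blocks(gap=0.2)
        left = np.flatnonzero(np.abs(mesh.nodes[:, 0]) < 1e-9)
        right = np.flatnonzero(np.abs(mesh.nodes[:, 0] - 20.2) < 1e-9)
        cons = ([(int(n), d, 0.0) for n in left for d in range(3)]
                + [(int(n), 0, -0.3) for n in right]
                + [(int(n), 1, 0.5) for n in right]
                + [(int(n), 2, 0.0) for n in right])
        contact = mf.ContactParams(mu=0.3)
        sol, _sys, _lc = self._solve(mesh, cons, contact=contact)
        assert sol.converged
        active = sol.contact_normal > 0
        assert active.any()
        ft = np.linalg.norm(sol.contact_tangential[active], axis=1)
        assert np.all(ft <= 0.3 * sol.contact_normal[active] + 1e-9)
        assert np.any(ft > 0)

    def test_contact_complementarity(self):
        mesh = contact_blocks(gap=0.2)
        left = np.flatnonzero(np.abs(mesh.nodes[:, 0]) < 1e-9)
        right = np.flatnonzero(np.abs(mesh.nodes[:, 0] - 20.2) < 1e-9)
        cons = ([(int(n), d, 0.0) for n in left for d in range(3)]
                + [(int(n), 0, -0.25) for n in right]
                + [(int(n), d, 0.0) for n in right for d in (1, 2)])
        sol, _sys, _lc = self._solve(mesh, cons)
        fp = mesh.fracture_pairs
        du = sol.displacements[fp.anterior] - sol.displacements[fp.posterior]
        gap = fp.distance + np.einsum("ij,ij->i", du, fp.normal)
        open_pairs = gap > 1e-8
        assert np.all(sol.contact_normal[open_pairs] == 0.0)
        closed = ~open_pairs
        assert np.all(sol.contact_normal[closed] >= 0.0)
        assert np.all(gap[closed] > -1e-3)

    def test_infinite_friction_approaches_tied_interface(self):
        mesh = contact_blocks(gap=0.2, n=(2, 2, 2))
        left = np.flatnonzero(np.abs(mesh.nodes[:, 0]) < 1e-9)
        right = np.flatnonzero(np.abs(mesh.nodes[:, 0] - 20.2) < 1e-9)
        cons = ([(int(n), d, 0.0) for n in left for d in range(3)]
                + [(int(n), 0, -0.3) for n in right]
                + [(int(n), 1, 0.2) for n in right]
                + [(int(n), 2, 0.0) for n in right])
        kn = 1e7
        stiff = mf.ContactParams(mu=1e9, normal_penalty=kn,
                                 penetration_tol=1e-2)
        sol, _sys, _lc = self._solve(mesh, cons, contact=stiff)
        # reference: same pairs as equal-displacement ties, with the gap
        # closed by moving block B flush (ties demand coincident motion)
        slick = mf.ContactParams(mu=0.0, normal_penalty=kn,
                                 penetration_tol=1e-2)
        sol0, _s, _l = self._solve(mesh, cons, contact=slick)
        fp = mesh.fracture_pairs
        slip_inf = sol.displacements[fp.anterior] - sol.displacements[fp.posterior]
        slip_inf -= (slip_inf @ [1.0, 0, 0])[:, None] * np.array([[1.0, 0, 0]])
        slip_0 = sol0.displacements[fp.anterior] - sol0.displacements[fp.posterior]
        slip_0 -= (slip_0 @ [1.0, 0, 0])[:, None] * np.array([[1.0, 0, 0]])
        # frictionless slides freely; infinite friction locks the interface
        assert np.abs(slip_inf).max() < 0.02 * np.abs(slip_0).max()

    def test_friction_sweep_varies_continuously(self):
        mesh = contact_blocks(gap=0.2)
        left = np.flatnonzero(np.abs(mesh.nodes[:, 0]) < 1e-9)
        right = np.flatnonzero(np.abs(mesh.nodes[:, 0] - 20.2) < 1e-9)
        cons = ([(int(n), d, 0.0) for n in left for d in range(3)]
                + [(int(n), 0, -0.3) for n in right]
                + [(int(n), 1, 0.5) for n in right]
                + [(int(n), 2, 0.0) for n in right])
        slips = []
        for mu in (0.1, 0.2, 0.3, 0.4, 0.5):
            sol, _s, _l = self._solve(mesh, cons,
                                      contact=mf.ContactParams(mu=mu))
            fp = mesh.fracture_pairs
            du = sol.displacements[fp.anterior] - sol.displacements[fp.posterior]
            tang = du - (du @ [1.0, 0, 0])[:, None] * np.array([[1.0, 0, 0]])
            slips.append(np.linalg.norm(tang, axis=1).mean())
        diffs = np.diff(slips)
        assert np.all(np.abs(diffs) < 0.5 * max(slips))  # no jumps
        assert slips[0] > slips[-1]  # more friction, less interface slip

    def test_nonconvergence_reported_not_raised(self):
        mesh = contact_blocks(gap=0.2)
        left = np.flatnonzero(np.abs(mesh.nodes[:, 0]) < 1e-9)
        right = np.flatnonzero(np.abs(mesh.nodes[:, 0] - 20.2) < 1e-9)
        cons = ([(int(n), d, 0.0) for n in left for d in range(3)]
                + [(int(n), 0, -0.3) for n in right]
                + [(int(n), d, 0.0) for n in right for d in (1, 2)])
        contact = mf.ContactParams(max_outer_iters=1)
        sol, _s, _l = self._solve(mesh, cons, contact=contact)
        assert not sol.converged
        assert sol.trace  # iteration history available for diagnosis
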