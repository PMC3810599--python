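"""Finite-volume assembly and backward-Euler stepping."""

import math

import numpy as np
import pytest
import scipy.sparse as sp

from tetvolt.mesh import CompartmentProps, TetMesh
from tetvolt.ordering import (breadth_first_order, principal_axis_order,
                              random_ordering, VertexGraph)
from tetvolt.solver import (CouplingAssembly, EFieldSystem, SolverError,
                            build_assembly, step, vertex_capacitances,
                            vertex_coupling_constants)

UNIT_TET = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


def fem_stiffness(mesh, sigma):
    """Independent P1 Galerkin stiffness oracle (4x4 solve per tet)."""
    n = mesh.n_vertices
    K = np.zeros((n, n))
    for tet in mesh.tets:
        v = mesh.vertices[tet]
        A = np.hstack([np.ones((4, 1)), v])
        vol = abs(np.linalg.det(A)) / 6.0
        grads = np.linalg.inv(A)[1:, :]
        K[np.ix_(tet, tet)] += sigma * vol * grads.T @ grads
    return K


class TestCouplingConstants:
    @pytest.mark.parametrize("seed", [0, 7, 21])
    def test_equals_p1_stiffness(self, random_mesh_factory, seed):
        mesh = random_mesh_factory(seed=seed, npts=35)
        sigma = 1.0 if seed else 2.5
        asm = vertex_coupling_constants(mesh, CompartmentProps(sigma=sigma))
        K = fem_stiffness(mesh, sigma)
        G_fem = -K.copy()
        np.fill_diagonal(G_fem, 0.0)
        scale = np.abs(G_fem).max()
        assert np.abs(asm.G.toarray() - G_fem).max() <= 1e-9 * scale

    def test_unit_tet_dual_patch_flux(self):
        """For the unit right tet with a unit x-gradient, the dual-surface
        flux gathered at the origin vertex is 1/6 (the sum of cross
        products is (1,1,1))."""
        mesh = TetMesh.from_arrays(UNIT_TET, [[0, 1, 2, 3]])
        asm = vertex_coupling_constants(mesh, CompartmentProps(sigma=1.0))
        phi = mesh.vertices[:, 0]          # Phi = x, grad = (1,0,0)
        flux_in = -(asm.laplacian() @ phi)
        assert abs(flux_in[0]) == pytest.approx(1.0 / 6.0, rel=1e-12)

    def test_uniform_potential_zero_flux(self, random_mesh_factory):
        mesh = random_mesh_factory(seed=2, npts=50)
        asm = vertex_coupling_constants(mesh, CompartmentProps(sigma=3.0))
        flux = asm.laplacian() @ np.full(mesh.n_vertices, 0.42)
        assert np.abs(flux).max() <= 1e-9 * np.abs(asm.G.data).max()

    def test_symmetry(self, random_mesh_factory):
        mesh = random_mesh_factory(seed=4, npts=30)
        asm = vertex_coupling_constants(mesh, CompartmentProps(sigma=1.0))
        assert (asm.G - asm.G.T).nnz == 0

    def test_degenerate_tet_names_culprit(self):
        pts = np.vstack([UNIT_TET, [[0.5, 0.5, 0.0]]])
        mesh = TetMesh(vertices=pts,
                       tets=np.array([[0, 1, 2, 4]]))  # coplanar, unchecked
        with pytest.raises(SolverError, match="tet ids"):
            vertex_coupling_constants(mesh, CompartmentProps(sigma=1.0))


class TestVertexCapacitances:
    def test_single_triangle_thirds(self, tiny_cylinder):
        memb = tiny_cylinder.membrane
        one = memb.restricted(memb.tri_indices[:1])
        C = vertex_capacitances(one, c_spec=0.01)
        nz = C[C > 0]
        assert len(nz) == 3
        np.testing.assert_allclose(nz, 0.01 * one.area / 3)

    def test_closed_membrane_conservation(self, tiny_cylinder):
        C = vertex_capacitances(tiny_cylinder.membrane, c_spec=0.01)
        assert C.sum() == pytest.approx(0.01 * tiny_cylinder.membrane.area,
                                        rel=1e-10)

    def test_interior_vertices_zero(self, tiny_cylinder):
        mesh = tiny_cylinder.mesh
        C = vertex_capacitances(tiny_cylinder.membrane, c_spec=0.01,
                                n=mesh.n_vertices)
        surface = np.unique(mesh.boundary_tris)
        interior = np.setdiff1d(np.arange(mesh.n_vertices), surface)
        assert interior.size > 0
        assert np.all(C[interior] == 0.0)


def two_vertex_assembly(g=2e-9, c1=1e-12, c2=3e-12):
    G = sp.csr_matrix(np.array([[0.0, g], [g, 0.0]]))
    return CouplingAssembly(n=2, G=G, C=np.array([c1, c2]))


class TestSystemAssembly:
    def test_two_vertex_matrix_form(self):
        g, dt = 2e-9, 1e-5
        asm = two_vertex_assembly(g=g)
        M = asm.matrix(dt).toarray()
        expected = np.array([[1e-12 + dt * g, -dt * g],
                             [-dt * g, 3e-12 + dt * g]])
        np.testing.assert_allclose(M, expected, rtol=1e-14)

    def test_dt_to_zero_limit(self):
        asm = two_vertex_assembly()
        M = asm.matrix(1e-20).toarray()
        np.testing.assert_allclose(M, np.diag(asm.C), atol=1e-25)

    def test_banded_equals_dense(self, tiny_cylinder):
        """One backward-Euler step via the banded factorisation equals the
        dense solve of the same matrix to 1e-10."""
        mesh = tiny_cylinder.mesh
        asm = build_assembly(mesh, CompartmentProps(sigma=1.0),
                             tiny_cylinder.membrane, c_spec=0.01)
        dt = 1e-5
        rng = np.random.default_rng(0)
        v0 = rng.normal(0, 1e-3, mesh.n_vertices)
        sysb = EFieldSystem(asm, dt, v_init=v0, solver="banded")
        step(sysb)
        M = asm.matrix(dt).toarray()
        dense = np.linalg.solve(M, asm.C * v0)
        assert np.abs(sysb.phi - dense).max() <= 1e-10 * np.abs(dense).max()

    def test_splu_equals_banded(self, tiny_cylinder):
        mesh = tiny_cylinder.mesh
        asm = build_assembly(mesh, CompartmentProps(sigma=1.0),
                             tiny_cylinder.membrane, c_spec=0.01)
        v0 = np.random.default_rng(1).normal(0, 1e-3, mesh.n_vertices)
        sa = EFieldSystem(asm, 1e-5, v_init=v0, solver="banded")
        sb = EFieldSystem(asm, 1e-5, v_init=v0, solver="splu")
        step(sa)
        step(sb)
        assert np.abs(sa.phi - sb.phi).max() <= 1e-12

    def test_band_memory_cap_advises_reordering(self, tiny_cylinder):
        mesh = tiny_cylinder.mesh
        asm = build_assembly(mesh, CompartmentProps(sigma=1.0),
                             tiny_cylinder.membrane, c_spec=0.01)
        with pytest.raises(SolverError, match="ordering"):
            EFieldSystem(asm, 1e-5, solver="banded", max_band_bytes=100.0)


class TestOrderingInvariance:
    def test_solution_independent_of_ordering(self, tiny_cylinder):
        """Reordering changes cost, never the potentials (1e-10)."""
        mesh = tiny_cylinder.mesh
        asm = build_assembly(mesh, CompartmentProps(sigma=1.0),
                             tiny_cylinder.membrane, c_spec=0.01)
        g = VertexGraph.from_mesh(mesh)
        perms = [None, principal_axis_order(mesh),
                 breadth_first_order(g, start_fraction=0.02, seed=0),
                 random_ordering(mesh.n_vertices, seed=3)]
        phis = []
        for perm in perms:
            sysm = EFieldSystem(asm, 1e-5, perm=perm, v_init=-65e-3)
            sysm.inject(tiny_cylinder.end0_vertices, 1e-10)
            for _ in range(20):
                step(sysm)
            phis.append(sysm.phi.copy())
        scale = np.abs(phis[0]).max()
        for other in phis[1:]:
            assert np.abs(other - phis[0]).max() <= 1e-10 * scale

    def test_solution_invariant_under_vertex_relabeling(self,
                                                        tiny_cylinder):
        mesh = tiny_cylinder.mesh
        memb = tiny_cylinder.membrane
        rng = np.random.default_rng(8)
        relab = rng.permutation(mesh.n_vertices)
        mesh2 = mesh.relabel(relab)
        tris2 = relab[memb.tris]
        # identify the same boundary triangles in the relabeled mesh
        key2 = {tuple(sorted(t)): i
                for i, t in enumerate(mesh2.boundary_tris.tolist())}
        idx2 = np.array([key2[tuple(sorted(t))] for t in tris2.tolist()])
        from tetvolt.mesh import MembraneSurface
        memb2 = MembraneSurface(mesh2, idx2, c_spec=memb.c_spec)

        out = []
        for msh, mb, inj in ((mesh, memb, tiny_cylinder.end0_vertices),
                             (mesh2, memb2,
                              relab[tiny_cylinder.end0_vertices])):
            asm = build_assembly(msh, CompartmentProps(sigma=1.0), mb,
                                 c_spec=0.01)
            sysm = EFieldSystem(asm, 1e-5, v_init=-65e-3)
            sysm.inject(inj, 1e-10)
            for _ in range(10):
                step(sysm)
            out.append(sysm.phi)
        assert np.abs(out[1][relab] - out[0]).max() <= \
            1e-10 * np.abs(out[0]).max()


class TestStepping:
    def test_uniform_equilibrium(self, tiny_cylinder):
        mesh = tiny_cylinder.mesh
        asm = build_assembly(mesh, CompartmentProps(sigma=1.0),
                             tiny_cylinder.membrane, c_spec=0.01)
        sysm = EFieldSystem(asm, 1e-5, v_init=-65e-3)
        step(sysm)
        assert np.abs(sysm.phi + 65e-3).max() <= 1e-12

    def test_isolated_capacitor(self):
        asm = CouplingAssembly(n=2, G=sp.csr_matrix((2, 2)),
                               C=np.array([2e-12, 1e-12]))
        sysm = EFieldSystem(asm, 1e-5)
        sysm.inject([0], 4e-12)
        step(sysm)
        assert sysm.phi[0] == pytest.approx(4e-12 * 1e-5 / 2e-12, rel=1e-12)

    def test_rc_pair_matches_closed_form(self):
        g, c, dt = 2e-9, 1e-12, 1e-6
        asm = two_vertex_assembly(g=g, c1=c, c2=c)
        v0 = np.array([0.01, 0.0])
        sysm = EFieldSystem(asm, dt, v_init=v0)
        M = np.diag([c, c]) + dt * (np.diag([g, g]) - np.array(
            [[0, g], [g, 0]]))
        v = v0.copy()
        for _ in range(200):
            step(sysm)
            v = np.linalg.solve(M, c * v)
        np.testing.assert_allclose(sysm.phi, v, rtol=0, atol=1e-18)
        # over many steps the difference decays like the analytic
        # exponential, within O(dt) accuracy
        t = 200 * dt
        analytic = 0.01 * math.exp(-t * 2 * g / c)
        got = sysm.phi[0] - sysm.phi[1]
        assert got == pytest.approx(analytic, rel=2 * dt * 2 * g / c * 200)

    def test_charge_conservation_free_run(self, tiny_cylinder):
        """With no injection and no clamps, sum(C_p Phi_p) is constant."""
        mesh = tiny_cylinder.mesh
        asm = build_assembly(mesh, CompartmentProps(sigma=1.0),
                             tiny_cylinder.membrane, c_spec=0.01)
        rng = np.random.default_rng(5)
        sysm = EFieldSystem(asm, 1e-5,
                            v_init=rng.normal(0, 1e-2, mesh.n_vertices))
        q0 = None
        for _ in range(30):
            step(sysm)
            q = float(asm.C @ sysm.phi)
            if q0 is None:
                q0 = q
        assert q == pytest.approx(q0, rel=1e-9)

    def test_injection_charges_at_total_rate(self, random_mesh_factory):
        """sum(C_p dPhi_p) = I_total dt: internal fluxes cancel pairwise
        by the symmetry of G."""
        mesh = random_mesh_factory(seed=12, npts=40)
        nb = len(mesh.boundary_tris)
        from tetvolt.mesh import MembraneSurface
        memb = MembraneSurface(mesh, np.arange(nb), c_spec=0.01)
        asm = build_assembly(mesh, CompartmentProps(sigma=1.0), memb)
        sysm = EFieldSystem(asm, 1e-6)
        sysm.inject([0, 1, 2], 5e-12, split="equal")
        q_prev = float(asm.C @ sysm.phi)
        for _ in range(5):
            step(sysm)
            q = float(asm.C @ sysm.phi)
            assert q - q_prev == pytest.approx(5e-12 * 1e-6, rel=1e-9)
            q_prev = q

    def test_equal_split_divides_current(self):
        asm = two_vertex_assembly()
        sysm = EFieldSystem(asm, 1e-5)
        sysm.inject([0, 1], 0.1e-9, split="equal")
        np.testing.assert_allclose(sysm.injected_base, [0.05e-9, 0.05e-9])

    def test_clamp_pins_everything(self, tiny_cylinder):
        mesh = tiny_cylinder.mesh
        asm = build_assembly(mesh, CompartmentProps(sigma=1.0),
                             tiny_cylinder.membrane, c_spec=0.01)
        sysm = EFieldSystem(asm, 1e-5, v_init=-65e-3)
        sysm.set_clamp(np.arange(mesh.n_vertices), 0.0)
        step(sysm)
        assert np.abs(sysm.phi).max() == 0.0

    def test_clamp_overrides_injection_with_warning(self):
        asm = two_vertex_assembly()
        sysm = EFieldSystem(asm, 1e-5)
        sysm.set_clamp([0], -70e-3)
        with pytest.warns(UserWarning, match="clamp wins"):
            sysm.inject([0, 1], 1e-10)
        step(sysm)
        assert sysm.phi[0] == -70e-3

    def test_nonfinite_current_rejected(self, tiny_cylinder):
        mesh = tiny_cylinder.mesh
        asm = build_assembly(mesh, CompartmentProps(sigma=1.0),
                             tiny_cylinder.membrane, c_spec=0.01)
        sysm = EFieldSystem(asm, 1e-5)
        bad = np.zeros(len(tiny_cylinder.membrane.tris))
        bad[0] = np.nan
        with pytest.raises(SolverError, match="non-finite"):
            step(sysm, tri_currents=bad)

    def test_adaptive_elapsed_reassembles(self):
        asm = two_vertex_assembly()
        sysm = EFieldSystem(asm, 1e-5)
        sysm.inject([0], 1e-12)
        step(sysm, elapsed=2.5e-6)
        assert sysm.dt == pytest.approx(2.5e-6)

    def test_permute_then_solve_equals_solve_then_permute(self,
                                                          tiny_cylinder):
        mesh = tiny_cylinder.mesh
        asm = build_assembly(mesh, CompartmentProps(sigma=1.0),
                             tiny_cylinder.membrane, c_spec=0.01)
        perm = principal_axis_order(mesh)
        v0 = np.random.default_rng(2).normal(0, 1e-3, mesh.n_vertices)
        s1 = EFieldSystem(asm, 1e-5, perm=perm, v_init=v0)
        step(s1)
        M = asm.matrix(1e-5)
        p2o = perm.inverse
        Mp = M[p2o][:, p2o].toarray()
        xp = np.linalg.solve(Mp, (asm.C * v0)[p2o])
        assert np.abs(s1.phi - xp[perm.perm]).max() <= \
            1e-10 * np.abs(xp).max()
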