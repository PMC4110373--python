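import numpy as np
import pytest

from kneesquat import fem

PE = dict(youngs=312.5, poisson=0.46)


def uniaxial_patch_problem(order, size=5.0, lengths=(10.0, 10.0, 20.0)):
    """PE bar under 1 MPa end tension with minimal (statically determinate) fixities."""
    lx, ly, lz = lengths
    mesh = fem.box_mesh(lengths, size, order=order, **PE)
    bottom = fem.boundary_nodes(mesh, lambda x, y, z: z < 1e-9)
    top = fem.boundary_faces(mesh, lambda x, y, z: z > lz - 1e-9)
    tractions = [(f, np.array([0.0, 0.0, 1.0])) for f in top]
    fix = [(int(n), 2) for n in bottom]
    c00 = fem.boundary_nodes(mesh, lambda x, y, z: (x < 1e-9) & (y < 1e-9) & (z < 1e-9))[0]
    c10 = fem.boundary_nodes(mesh, lambda x, y, z: (x > lx - 1e-9) & (y < 1e-9) & (z < 1e-9))[0]
    fix += [(int(c00), 0), (int(c00), 1), (int(c10), 1)]
    return mesh, tractions, fix


def bending_problem(order, size):
    """Pure bending of a bar: linear axial stress, smooth everywhere.

    Equal-and-opposite linear end tractions and statically determinate pins
    only — no clamped face, hence no support singularity; nu = 0.3 keeps the
    linear tetrahedra away from near-incompressible locking.
    """
    lx, ly, lz = 6.0, 6.0, 24.0
    mesh = fem.box_mesh((lx, ly, lz), size, order=order, youngs=200.0, poisson=0.3)
    tractions = []
    for zsel, sign in ((lambda x, y, z: z > lz - 1e-9, 1.0), (lambda x, y, z: z < 1e-9, -1.0)):
        for face in fem.boundary_faces(mesh, zsel):
            yc = mesh.nodes[list(face)][:, 1].mean()
            tractions.append((face, np.array([0.0, 0.0, sign * 0.4 * (yc - ly / 2.0)])))
    # statically determinate pins on the bottom face
    pins = []
    c000 = fem.boundary_nodes(mesh, lambda x, y, z: (x < 1e-9) & (y < 1e-9) & (z < 1e-9))[0]
    c100 = fem.boundary_nodes(mesh, lambda x, y, z: (x > lx - 1e-9) & (y < 1e-9) & (z < 1e-9))[0]
    c010 = fem.boundary_nodes(mesh, lambda x, y, z: (x < 1e-9) & (y > ly - 1e-9) & (z < 1e-9))[0]
    pins += [(int(c000), 0), (int(c000), 1), (int(c000), 2)]
    pins += [(int(c100), 1), (int(c100), 2)]
    pins += [(int(c010), 2)]
    return mesh, tractions, pins


class TestPatchTest:
    @pytest.mark.parametrize("order", [1, 2])
    def test_uniform_uniaxial_state_reproduced_exactly(self, order):
        mesh, tractions, fix = uniaxial_patch_problem(order)
        sol = fem.assemble_and_solve(mesh, tractions=tractions, fixities=fix)
        szz = sol.element_nodal_stress[..., 2]
        others = np.delete(sol.element_nodal_stress, 2, axis=-1)
        assert np.abs(szz - 1.0).max() < 1e-8
        assert np.abs(others).max() < 1e-8
        vm = fem.von_mises(sol.element_nodal_stress)
        assert np.abs(vm - 1.0).max() < 1e-8

    @pytest.mark.parametrize("order", [1, 2])
    def test_error_energy_vanishes_on_uniform_stress(self, order):
        mesh, tractions, fix = uniaxial_patch_problem(order)
        sol = fem.assemble_and_solve(mesh, tractions=tractions, fixities=fix)
        e_i, total = fem.error_energy(sol)
        assert np.abs(e_i).max() < 1e-10
        assert total < 1e-10

    def test_zero_traction_gives_zero_solution(self):
        mesh, _, fix = uniaxial_patch_problem(1)
        sol = fem.assemble_and_solve(mesh, tractions=[], fixities=fix)
        assert np.abs(sol.displacements).max() == 0.0
        assert np.abs(sol.element_stress).max() == 0.0

    @pytest.mark.parametrize("order", [1, 2])
    def test_reactions_balance_applied_load(self, order):
        mesh, tractions, fix = uniaxial_patch_problem(order)
        sol = fem.assemble_and_solve(mesh, tractions=tractions, fixities=fix)
        applied = 1.0 * 10.0 * 10.0
        assert sol.reactions[:, 2].sum() == pytest.approx(-applied, rel=1e-6)

    @pytest.mark.parametrize("order", [1, 2])
    def test_strain_energy_equals_half_external_work(self, order):
        mesh, tractions, fixed = bending_problem(order, 3.0)
        sol = fem.assemble_and_solve(mesh, tractions=tractions, fixities=fixed)
        assert sol.strain_energy == pytest.approx(0.5 * sol.external_work, rel=1e-6)


class TestVonMises:
    @pytest.mark.parametrize(
        "voigt, expected",
        [
            ([3.0, 3.0, 3.0, 0, 0, 0], 0.0),  # hydrostatic
            ([2.5, 0, 0, 0, 0, 0], 2.5),  # uniaxial
            ([0, 0, 0, 1.7, 0, 0], 1.7 * np.sqrt(3.0)),  # pure shear
            ([0, 0, 0, 0, 0.9, 0], 0.9 * np.sqrt(3.0)),
        ],
    )
    def test_closed_forms(self, voigt, expected):
        assert fem.von_mises(np.array(voigt)) == pytest.approx(expected, abs=1e-12)

    def test_non_negative_on_random_states(self, rng):
        s = rng.standard_normal((100, 6))
        assert np.all(fem.von_mises(s) >= 0.0)


class TestErrorEnergyOracle:
    @staticmethod
    def _ref_mass_matrix(order):
        """Exact integral of N_a N_b over the reference tetrahedron via the
        barycentric monomial formula (independent of the solver quadrature)."""
        import sympy as sp

        r, s, t = sp.symbols("r s t", nonnegative=True)
        l0 = 1 - r - s - t
        if order == 1:
            shapes = [l0, r, s, t]
        else:
            lam = [l0, r, s, t]
            shapes = [li * (2 * li - 1) for li in lam]
            for a, b in fem.EDGES:
                shapes.append(4 * lam[a] * lam[b])
        n = len(shapes)
        m = np.zeros((n, n))
        for a in range(n):
            for b in range(a, n):
                val = sp.integrate(
                    sp.integrate(sp.integrate(shapes[a] * shapes[b], (t, 0, 1 - r - s)), (s, 0, 1 - r)),
                    (r, 0, 1),
                )
                m[a, b] = m[b, a] = float(val)
        return m

    @pytest.mark.parametrize("order", [1, 2])
    def test_per_element_energy_matches_exact_integral(self, order):
        """e_i from the implementation equals the exact closed-form integral of
        the interpolated nodal stress error, element by element."""
        mesh, tractions, fixed = bending_problem(order, 6.0)
        sol = fem.assemble_and_solve(mesh, tractions=tractions, fixities=fixed)
        e_impl, _ = fem.error_energy(sol)
        m_ref = self._ref_mass_matrix(order)
        d_inv = np.linalg.inv(fem.elastic_matrix(mesh.youngs, mesh.poisson))
        avg = fem.averaged_nodal_stress(sol)
        vols = np.abs(mesh.corner_volumes())
        for e, el in enumerate(mesh.tets):
            ds = avg[el] - sol.element_nodal_stress[e]  # (nn, 6)
            quad = ds @ d_inv @ ds.T  # (nn, nn)
            # straight-sided elements: |J| = 6 V, reference volume = 1/6
            expected = 0.5 * 6.0 * vols[e] * float((m_ref * quad).sum())
            if expected > 1e-12:
                assert e_impl[e] == pytest.approx(expected, rel=1e-8)
            else:
                assert abs(e_impl[e] - expected) < 1e-12

    def test_total_error_energy_non_increasing_under_refinement(self):
        """Quadratic elements over the 3 -> 1.5 mm study range: refining a
        smooth bending problem drives the total error energy down."""
        totals = []
        for size in (3.0, 2.0, 1.5):
            mesh, tractions, fixed = bending_problem(2, size)
            sol = fem.assemble_and_solve(mesh, tractions=tractions, fixities=fixed)
            _, total = fem.error_energy(sol)
            totals.append(total)
        assert all(b <= a for a, b in zip(totals, totals[1:]))


class TestCantileverBeamOracle:
    def test_tip_deflection_matches_timoshenko_within_5_percent(self):
        """Quadratic-element cantilever vs the Euler-Bernoulli + shear oracle."""
        b = h = 10.0
        length = 40.0
        e_mod, nu = 200.0, 0.3
        p = 50.0  # N end load
        mesh = fem.box_mesh((b, h, length), 2.5, order=2, youngs=e_mod, poisson=nu)
        fixed = fem.boundary_nodes(mesh, lambda x, y, z: z < 1e-9)
        tip_faces = fem.boundary_faces(mesh, lambda x, y, z: z > length - 1e-9)
        traction = p / (b * h)
        tractions = [(f, np.array([0.0, traction, 0.0])) for f in tip_faces]
        sol = fem.assemble_and_solve(mesh, tractions=tractions, fixities=fixed)
        tip_nodes = fem.boundary_nodes(mesh, lambda x, y, z: z > length - 1e-9)
        tip_deflection = sol.displacements[tip_nodes, 1].mean()
        inertia = b * h**3 / 12.0
        g_mod = e_mod / (2 * (1 + nu))
        kappa = 10.0 * (1 + nu) / (12.0 + 11.0 * nu)  # rectangular section
        oracle = p * length**3 / (3 * e_mod * inertia) + p * length / (kappa * g_mod * b * h)
        assert tip_deflection == pytest.approx(oracle, rel=0.05)


class TestConvergenceStudy:
    @staticmethod
    def _patch_problem(size):
        return uniaxial_patch_problem(1, size=size)

    def test_patch_test_rows_identical_and_converged(self):
        table = fem.convergence_study(self._patch_problem, [5.0, 3.3, 2.5])
        assert len(table) == 3
        assert np.allclose(table.peak_von_mises, 1.0, atol=1e-8)
        assert np.all(table.total_error_energy < 1e-10)
        assert not table.converged.iloc[0]
        assert table.converged.iloc[1:].all()
        assert not table.failed.any()

    def test_single_size_degenerate_study(self):
        table = fem.convergence_study(self._patch_problem, [4.0])
        assert len(table) == 1
        assert not table.converged.iloc[0]

    def test_failed_size_marked_and_study_continues(self):
        def problem(size):
            if size > 4.0:
                raise RuntimeError("mesher exploded")
            return self._patch_problem(size)

        table = fem.convergence_study(problem, [5.0, 4.0])
        assert table.failed.iloc[0]
        assert not table.failed.iloc[1]

    def test_bending_error_energy_decreases_with_size(self):
        table = fem.convergence_study(lambda s: bending_problem(2, s), [3.0, 2.0, 1.5])
        e = table.total_error_energy.values
        assert np.all(np.diff(e) <= 0)


class TestMeshInfrastructure:
    def test_insufficient_fixities_raise_rank_error(self):
        mesh = fem.box_mesh((10, 10, 10), 5.0, **PE)
        with pytest.raises(ValueError, match="rigid-body"):
            fem.assemble_and_solve(mesh, point_loads=[(mesh.n_nodes - 1, [0, 0, -1.0])], fixities=[0])

    def test_box_mesh_volume_and_positive_jacobians(self):
        mesh = fem.box_mesh((10, 12, 8), 3.0, **PE)
        mesh.validate()
        assert mesh.corner_volumes().sum() == pytest.approx(10 * 12 * 8, rel=1e-12)

    def test_quadratic_conversion_preserves_corners(self):
        lin = fem.box_mesh((6, 6, 6), 3.0, **PE)
        quad = fem.to_quadratic(lin)
        assert quad.order == 2
        assert np.array_equal(quad.tets[:, :4], lin.tets)
        # midside nodes sit at edge midpoints
        for el in quad.tets[:3]:
            for k, (a, b) in enumerate(fem.EDGES):
                mid = quad.nodes[el[4 + k]]
                assert np.allclose(mid, 0.5 * (quad.nodes[el[a]] + quad.nodes[el[b]]))

    @pytest.mark.parametrize("order", [1, 2])
    def test_vtk_round_trip(self, tmp_path, order):
        mesh = fem.box_mesh((6, 6, 6), 3.0, order=order, **PE)
        path = tmp_path / "mesh.vtk"
        fem.write_vtk(path, mesh)
        back = fem.read_vtk(path)
        assert np.allclose(back.nodes, mesh.nodes)
        assert np.array_equal(back.tets, mesh.tets)

    def test_malformed_vtk_raises(self, tmp_path):
        bad = tmp_path / "bad.vtk"
        bad.write_text("# vtk DataFile\njunk\nASCII\nPOINTS three double\n")
        with pytest.raises(ValueError):
            fem.read_vtk(bad)

    def test_elastic_matrix_validation(self):
        with pytest.raises(ValueError):
            fem.elastic_matrix(-1.0, 0.3)
        with pytest.raises(ValueError):
            fem.elastic_matrix(100.0, 0.5)
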