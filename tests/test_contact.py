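import numpy as np
import pytest

from kneesquat import contact as C
from kneesquat.geometry import RigidPose, SurfaceMesh


def flat_patch_field(n=10, extent=10.0, k_f=5.0, mu=0.1):
    """Square grid of patches in the z=0 plane, normals +z."""
    xs = (np.arange(n) + 0.5) * (2 * extent / n) - extent
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    centers = np.stack([gx.ravel(), gy.ravel(), np.zeros(n * n)], axis=1)
    area = (2 * extent / n) ** 2
    normals = np.tile([0.0, 0.0, 1.0], (n * n, 1))
    return C.ContactPatchField(centers, np.full(n * n, area), normals, k_f, mu)


IDENT = RigidPose.identity()


class TestGapField:
    def test_separated_surfaces_have_positive_gaps_and_no_force(self):
        patches = flat_patch_field()
        plane = C.PlaneSDF([0, 0, 2.0], [0, 0, -1.0])
        gaps = C.compute_gap_field(plane, IDENT, patches, IDENT)
        assert np.all(gaps > 0)
        _, resultant, _ = C.foundation_pressure(patches, IDENT)
        assert np.allclose(resultant, 0.0)

    def test_touching_plane_gives_zero_gap(self):
        patches = flat_patch_field()
        plane = C.PlaneSDF([0, 0, 0.0], [0, 0, -1.0])
        gaps = C.compute_gap_field(plane, IDENT, patches, IDENT)
        assert np.allclose(gaps, 0.0, atol=1e-12)

    def test_plane_lowered_gives_uniform_negative_gap(self):
        patches = flat_patch_field()
        plane = C.PlaneSDF([0, 0, -0.1], [0, 0, -1.0])
        gaps = C.compute_gap_field(plane, IDENT, patches, IDENT)
        assert np.allclose(gaps, -0.1, atol=1e-12)

    def test_disjoint_beyond_cutoff_reports_cutoff_not_error(self):
        patches = flat_patch_field()
        plane = C.PlaneSDF([0, 0, 1e4], [0, 0, -1.0])
        gaps = C.compute_gap_field(plane, IDENT, patches, IDENT, cutoff=5.0)
        assert np.all(gaps == 5.0)

    def test_mesh_rigid_surface_matches_analytic_plane(self):
        patches = flat_patch_field(n=5)
        verts = np.array([[-50, -50, 0.3], [50, -50, 0.3], [50, 50, 0.3], [-50, 50, 0.3]], dtype=float)
        tris = np.array([[0, 1, 2], [0, 2, 3]])
        mesh_sdf = C.MeshSDF(SurfaceMesh(verts, tris))
        gaps = C.compute_gap_field(mesh_sdf, IDENT, patches, IDENT)
        assert np.allclose(gaps, 0.3, atol=1e-9)


class TestFoundationPressure:
    def test_uniform_penetration_closed_form_resultant(self):
        patches = flat_patch_field(n=8, extent=5.0, k_f=3.0)
        delta = 0.25
        plane = C.PlaneSDF([0, 0, -delta], [0, 0, -1.0])
        C.compute_gap_field(plane, IDENT, patches, IDENT)
        p, resultant, _ = C.foundation_pressure(patches, IDENT)
        area_total = patches.areas.sum()
        assert np.allclose(p, 3.0 * delta)
        assert np.linalg.norm(resultant) == pytest.approx(3.0 * delta * area_total, rel=1e-12)
        # pressure acts against the patch normals (pushes the surface in)
        assert resultant[2] < 0

    def test_sphere_on_foundation_matches_quadrature_oracle(self):
        """Sphere pressed delta into a flat foundation: resultant equals the
        independent polar-quadrature integral of k*max(0, delta - r^2/(2R))."""
        k_f, radius, delta = 7.7, 40.0, 0.2
        patches = flat_patch_field(n=160, extent=8.0, k_f=k_f)
        sphere = C.SphereSDF([0, 0, radius - delta], radius)
        C.compute_gap_field(sphere, IDENT, patches, IDENT)
        _, resultant, _ = C.foundation_pressure(patches, IDENT)
        # oracle: dense 1-D radial quadrature of the paraboloid-gap pressure,
        # using the exact sphere gap g(r) = sqrt((R-d)^2 + r^2) - R
        r = np.linspace(0.0, 8.0, 20001)
        gap = np.sqrt((radius - delta) ** 2 + r**2) - radius
        integrand = k_f * np.maximum(0.0, -gap) * 2 * np.pi * r
        oracle = np.trapezoid(integrand, r)
        assert np.linalg.norm(resultant) == pytest.approx(oracle, rel=2e-2)

    def test_zero_penetration_zero_resultant(self):
        patches = flat_patch_field()
        plane = C.PlaneSDF([0, 0, 0.5], [0, 0, -1.0])
        C.compute_gap_field(plane, IDENT, patches, IDENT)
        _, resultant, moment = C.foundation_pressure(patches, IDENT)
        assert np.allclose(resultant, 0.0) and np.allclose(moment, 0.0)

    def test_complementarity_pressure_times_positive_gap(self):
        patches = flat_patch_field(n=20)
        sphere = C.SphereSDF([0, 0, 39.9], 40.0)  # partial contact
        C.compute_gap_field(sphere, IDENT, patches, IDENT)
        p, _, _ = C.foundation_pressure(patches, IDENT)
        assert np.all(p * np.maximum(0.0, patches.gap) == 0.0)
        assert np.any(p > 0)


class TestFrictionTraction:
    def _pressurized(self):
        patches = flat_patch_field(n=6, k_f=2.0, mu=0.05)
        plane = C.PlaneSDF([0, 0, -0.2], [0, 0, -1.0])
        C.compute_gap_field(plane, IDENT, patches, IDENT)
        C.foundation_pressure(patches, IDENT)
        return patches

    def test_zero_mu_gives_zero_traction(self):
        patches = self._pressurized()
        v = np.tile([1.0, 0, 0], (len(patches), 1))
        t = C.tangential_traction(patches, v, mu=0.0)
        assert np.allclose(t, 0.0)

    def test_fast_sliding_saturates_at_coulomb_limit(self):
        patches = self._pressurized()
        v = np.tile([1000.0, 0, 0], (len(patches), 1))
        t = C.tangential_traction(patches, v, mu=0.05)
        mag = np.linalg.norm(t, axis=1)
        assert np.all(mag <= 0.05 * patches.pressure + 1e-15)
        assert np.allclose(mag, 0.05 * patches.pressure, rtol=1e-2)

    def test_traction_opposes_sliding_and_is_antisymmetric(self):
        patches = self._pressurized()
        v = np.tile([2.0, 1.0, 0], (len(patches), 1))
        t_fwd = C.tangential_traction(patches, v, mu=0.05).copy()
        t_bwd = C.tangential_traction(patches, -v, mu=0.05)
        assert np.allclose(t_fwd, -t_bwd)
        assert np.all(np.einsum("ij,ij->i", t_fwd, v) <= 0)

    def test_cone_bound_holds_for_all_speeds(self):
        patches = self._pressurized()
        for speed in (0.0, 0.01, 0.1, 1.0, 100.0):
            v = np.tile([speed, 0, 0], (len(patches), 1))
            t = C.tangential_traction(patches, v, mu=0.05)
            assert np.all(np.linalg.norm(t, axis=1) <= 0.05 * patches.pressure + 1e-15)


class TestStressProxy:
    def test_zero_pressure_zero_stress(self):
        patches = flat_patch_field()
        patches.pressure = np.zeros(len(patches))
        stress, _ = C.surface_stress_proxy(patches)
        assert np.allclose(stress, 0.0)

    def test_homogeneity_and_peak_location(self, rng):
        patches = flat_patch_field()
        patches.pressure = rng.uniform(0.0, 5.0, len(patches))
        s1, peak1 = C.surface_stress_proxy(patches)
        patches.pressure = 2.0 * patches.pressure
        s2, peak2 = C.surface_stress_proxy(patches)
        assert np.allclose(s2, 2.0 * s1)
        assert peak1 == peak2 == int(np.argmax(patches.pressure))


def test_foundation_modulus_constrained_column():
    # PE inlay layer: E=312.5 MPa, nu=0.46, h=8 mm
    expected = 312.5 * (1 - 0.46) / ((1 + 0.46) * (1 - 0.92) * 8.0)
    assert C.foundation_modulus(312.5, 0.46, 8.0) == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError):
        C.foundation_modulus(312.5, 0.5, 8.0)
    with pytest.raises(ValueError):
        C.foundation_modulus(312.5, 0.3, 0.0)


def test_patch_export_csv(tmp_path):
    patches = flat_patch_field(n=4)
    plane = C.PlaneSDF([0, 0, -0.1], [0, 0, -1.0])
    C.compute_gap_field(plane, IDENT, patches, IDENT)
    C.foundation_pressure(patches, IDENT)
    path = tmp_path / "patches.csv"
    C.export_patch_csv(patches, path)
    import pandas as pd

    df = pd.read_csv(path)
    assert len(df) == len(patches)
    assert {"x", "y", "z", "area", "gap", "pressure", "stress_proxy"} <= set(df.columns)
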