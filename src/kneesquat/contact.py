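"""Elastic-foundation frictional contact between a rigid surface and a
deformable patch field.

The deformable surfaces (PE inlay, patellar cartilage) are discretized into
patches (one per mesh triangle).  Contact pressure follows the elastic
foundation model p = k_f * max(0, -gap), with the foundation modulus derived
from the layer material as k_f = E(1-nu) / ((1+nu)(1-2nu) h) — the constrained
(oedometric) column stiffness of a layer of thickness h.  Friction is a
regularized Coulomb law, so |t| <= mu * p holds patch-wise by construction.

The rigid counter-surface (the CoCr femoral component) is represented either
by an analytic signed-distance function (fast path used inside the solver) or
by a triangle mesh probed by ray casting along the patch normals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import RigidPose, SurfaceMesh

DEFAULT_GAP_CUTOFF = 10.0  # mm; beyond this the pair is reported as "no contact"
DEFAULT_FRICTION_REGULARIZATION = 0.1  # mm/step, regularized Coulomb velocity scale


def foundation_modulus(youngs_modulus: float, poisson_ratio: float, thickness: float) -> float:
    """Constrained-column foundation modulus k_f (MPa/mm) of an elastic layer."""
    if not 0.0 <= poisson_ratio < 0.5:
        raise ValueError("poisson_ratio must be in [0, 0.5)")
    if thickness <= 0:
        raise ValueError("thickness must be > 0")
    e, nu = youngs_modulus, poisson_ratio
    return e * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu) * thickness)


# ---------------------------------------------------------------------------
# rigid surfaces (signed distance functions, local frame of the rigid body)
# ---------------------------------------------------------------------------


class PlaneSDF:
    """Half-space rigid body; sdf > 0 on the outward-normal side."""

    def __init__(self, point, normal):
        self.point = np.asarray(point, dtype=float)
        n = np.asarray(normal, dtype=float)
        self.normal = n / np.linalg.norm(n)

    def signed_distance(self, points: np.ndarray):
        d = (points - self.point) @ self.normal
        grad = np.broadcast_to(self.normal, points.shape)
        return d, grad


class SphereSDF:
    def __init__(self, center, radius: float):
        self.center = np.asarray(center, dtype=float)
        self.radius = float(radius)

    def signed_distance(self, points: np.ndarray):
        u = points - self.center
        r = np.linalg.norm(u, axis=1)
        r_safe = np.maximum(r, 1e-12)
        return r - self.radius, u / r_safe[:, None]


class CondylePairSDF:
    """Two torus condyles about the mediolateral (x) axis, femur frame.

    Each condyle is a torus with tube radius r_f (frontal) whose major circle
    (radius r_s - r_f) lies in the sagittal plane at x = +/- spacing/2.  The
    pair sdf is the pointwise minimum; its valley at the midline centres the
    patella mediolaterally.
    """

    def __init__(self, radius_sagittal: float, radius_frontal: float, spacing: float, center_z: float = 0.0):
        self.r_major = radius_sagittal - radius_frontal
        self.r_tube = radius_frontal
        if self.r_major <= 0:
            raise ValueError("sagittal radius must exceed frontal radius")
        self.centers_x = (-0.5 * spacing, 0.5 * spacing)
        self.center_z = float(center_z)

    def _single(self, points: np.ndarray, xc: float):
        ux = points[:, 0] - xc
        uy = points[:, 1]
        uz = points[:, 2] - self.center_z
        rho = np.sqrt(uy**2 + uz**2)
        rho_safe = np.maximum(rho, 1e-12)
        k = rho - self.r_major
        s = np.sqrt(k**2 + ux**2)
        s_safe = np.maximum(s, 1e-12)
        d = s - self.r_tube
        grad = np.empty_like(points)
        grad[:, 0] = ux / s_safe
        scale = k / (s_safe * rho_safe)
        grad[:, 1] = uy * scale
        grad[:, 2] = uz * scale
        return d, grad

    def signed_distance(self, points: np.ndarray):
        d0, g0 = self._single(points, self.centers_x[0])
        d1, g1 = self._single(points, self.centers_x[1])
        take1 = d1 < d0
        d = np.where(take1, d1, d0)
        g = np.where(take1[:, None], g1, g0)
        return d, g


class TrochleaSDF:
    """Anterior flange / trochlear groove of the femoral component.

    A cylinder of sagittal radius R about the mediolateral (x) axis through
    the knee centre, with a shallow parabolic groove in x that centres the
    patella on the midline:  sdf = sqrt(y^2 + z^2) - R + x^2 / (2 * groove_radius).
    """

    def __init__(self, radius_sagittal: float, groove_radius: float = 100.0):
        self.radius = float(radius_sagittal)
        self.groove_radius = float(groove_radius)
        if self.radius <= 0 or self.groove_radius <= 0:
            raise ValueError("radii must be > 0")

    def signed_distance(self, points: np.ndarray):
        rho = np.sqrt(points[:, 1] ** 2 + points[:, 2] ** 2)
        rho_safe = np.maximum(rho, 1e-12)
        d = rho - self.radius + points[:, 0] ** 2 / (2.0 * self.groove_radius)
        grad = np.empty_like(points)
        grad[:, 0] = points[:, 0] / self.groove_radius
        grad[:, 1] = points[:, 1] / rho_safe
        grad[:, 2] = points[:, 2] / rho_safe
        return d, grad


class MeshSDF:
    """Rigid surface given as a triangle mesh; gaps probed by ray casting.

    Uses a vectorized Moller-Trumbore intersection (no spatial index), which
    is plenty for desk-scale meshes.
    """

    def __init__(self, mesh: SurfaceMesh):
        v = np.asarray(mesh.vertices, dtype=float)
        f = np.asarray(mesh.triangles, dtype=np.int64)
        self._v0 = v[f[:, 0]]
        self._e1 = v[f[:, 1]] - self._v0
        self._e2 = v[f[:, 2]] - self._v0

    def _ray_distances(self, origins: np.ndarray, directions: np.ndarray) -> np.ndarray:
        """Smallest positive ray parameter t per ray, +inf when no hit."""
        eps = 1e-12
        n_rays = len(origins)
        best = np.full(n_rays, np.inf)
        # broadcast rays x triangles
        d = directions[:, None, :]
        pvec = np.cross(d, self._e2[None, :, :])
        det = np.einsum("rtk,tk->rt", pvec, self._e1)
        ok = np.abs(det) > eps
        inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = origins[:, None, :] - self._v0[None, :, :]
        u = np.einsum("rtk,rtk->rt", tvec, pvec) * inv_det
        qvec = np.cross(tvec, self._e1[None, :, :])
        v = np.einsum("rtk,rk->rt", qvec, directions) * inv_det
        t = np.einsum("rtk,tk->rt", qvec, self._e2) * inv_det
        hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > eps)
        t = np.where(hit, t, np.inf)
        best = t.min(axis=1)
        return best

    def gap_along_normals(self, points: np.ndarray, normals: np.ndarray, cutoff: float):
        """Signed distance along each normal to the first surface hit.

        Positive when the surface lies ahead of the patch along its normal,
        negative when behind (penetration); +cutoff when no hit either way.
        """
        fwd = self._ray_distances(points, normals)
        bwd = self._ray_distances(points, -normals)
        gaps = np.where(np.abs(fwd) <= np.abs(bwd), fwd, -bwd)
        gaps = np.where(np.isinf(gaps), cutoff, gaps)
        return np.clip(gaps, -cutoff, cutoff)


# ---------------------------------------------------------------------------
# patch fields
# ---------------------------------------------------------------------------


@dataclass
class ContactPatchField:
    """Patch discretization of a deformable surface with per-patch state.

    Geometry (centers, areas, normals) lives in the deformable body's local
    frame; gap/pressure/traction are state filled in by the contact queries.
    """

    centers: np.ndarray  # (n, 3) mm, body frame
    areas: np.ndarray  # (n,) mm^2
    normals: np.ndarray  # (n, 3) unit, body frame, pointing toward the rigid body
    foundation_modulus: float  # MPa/mm
    friction_mu: float = 0.0
    gap: np.ndarray | None = None  # mm, negative = penetration
    pressure: np.ndarray | None = None  # MPa
    traction: np.ndarray | None = None  # (n, 3) MPa, world frame

    @classmethod
    def from_mesh(cls, mesh: SurfaceMesh, k_f: float, mu: float = 0.0, orient: np.ndarray | None = None):
        """Build one patch per triangle; optionally flip normals toward ``orient``."""
        normals = mesh.face_normals()
        if orient is not None:
            flip = normals @ np.asarray(orient, dtype=float) < 0
            normals[flip] *= -1.0
        return cls(mesh.face_centers(), mesh.face_areas(), normals, k_f, mu)

    def __len__(self) -> int:
        return len(self.areas)


def compute_gap_field(
    rigid_surface,
    rigid_pose: RigidPose,
    patches: ContactPatchField,
    patch_pose: RigidPose,
    cutoff: float = DEFAULT_GAP_CUTOFF,
) -> np.ndarray:
    """Per-patch gap (mm) between a posed rigid surface and a posed patch field.

    For analytic rigid surfaces the gap is the signed distance function
    evaluated at the patch centre (equal to the along-normal distance in the
    near-contact limit); for mesh surfaces it is the ray-cast distance along
    the patch normal.  Fully disjoint pairs report +cutoff, not an error.
    """
    world = patch_pose.transform(patches.centers)
    local = (world - rigid_pose.translation) @ rigid_pose.rotation
    if isinstance(rigid_surface, MeshSDF):
        n_world = patches.normals @ patch_pose.rotation.T
        n_local = n_world @ rigid_pose.rotation
        gaps = rigid_surface.gap_along_normals(local, n_local, cutoff)
    else:
        gaps, _ = rigid_surface.signed_distance(local)
        gaps = np.minimum(gaps, cutoff)
    patches.gap = gaps
    return gaps


def foundation_pressure(patches: ContactPatchField, patch_pose: RigidPose, moment_about=None):
    """Elastic-foundation pressure p = k_f * max(0, -gap) and its resultant.

    Returns (pressure MPa, resultant force N on the deformable body, moment
    N*mm about ``moment_about``).  The force on each patch acts along the
    inward (-outward) patch normal, i.e. the rigid body presses the surface in.
    """
    if patches.gap is None:
        raise RuntimeError("gap field not computed")
    p = patches.foundation_modulus * np.maximum(0.0, -patches.gap)
    patches.pressure = p
    n_world = patches.normals @ patch_pose.rotation.T
    c_world = patch_pose.transform(patches.centers)
    f_per = -(p * patches.areas)[:, None] * n_world
    resultant = f_per.sum(axis=0)
    ref = np.zeros(3) if moment_about is None else np.asarray(moment_about, dtype=float)
    moment = np.cross(c_world - ref, f_per).sum(axis=0)
    return p, resultant, moment


def tangential_traction(
    patches: ContactPatchField,
    sliding_velocity: np.ndarray,
    mu: float | None = None,
    regularization: float = DEFAULT_FRICTION_REGULARIZATION,
) -> np.ndarray:
    """Regularized Coulomb traction t = -mu p v / (|v| + eps_v), (n, 3) MPa.

    ``sliding_velocity`` is the per-patch tangential relative velocity of the
    deformable surface with respect to the rigid one (mm per load step).  The
    friction cone |t| <= mu p holds exactly for every patch.
    """
    if patches.pressure is None:
        raise RuntimeError("pressure field not computed")
    mu = patches.friction_mu if mu is None else mu
    if mu < 0:
        raise ValueError("mu must be >= 0")
    v = np.asarray(sliding_velocity, dtype=float)
    speed = np.linalg.norm(v, axis=1)
    scale = -mu * patches.pressure / (speed + regularization)
    t = scale[:, None] * v
    patches.traction = t
    return t


def surface_stress_proxy(patches: ContactPatchField, poisson_ratio: float = 0.46):
    """Monotone von-Mises-like surface stress from the contact pressure field.

    Uses the confined-layer approximation: under a surface pressure p a
    laterally constrained layer sees sigma = diag(p, eta*p, eta*p) with
    eta = nu/(1-nu), whose von Mises stress is p*(1-2nu)/(1-nu).  The factor
    is a documented proportionality constant — trends, not magnitudes, are the
    quantity of interest.  Returns (stress array MPa, index of peak patch).
    """
    if patches.pressure is None:
        raise RuntimeError("pressure field not computed")
    factor = (1.0 - 2.0 * poisson_ratio) / (1.0 - poisson_ratio)
    stress = factor * patches.pressure
    peak = int(np.argmax(stress)) if len(stress) else -1
    return stress, peak


def export_patch_csv(patches: ContactPatchField, path) -> None:
    """Write the patch field (center, area, gap, pressure, stress proxy) as CSV."""
    import pandas as pd

    stress, _ = surface_stress_proxy(patches) if patches.pressure is not None else (None, -1)
    df = pd.DataFrame(
        {
            "x": patches.centers[:, 0],
            "y": patches.centers[:, 1],
            "z": patches.centers[:, 2],
            "area": patches.areas,
            "gap": patches.gap if patches.gap is not None else np.nan,
            "pressure": patches.pressure if patches.pressure is not None else np.nan,
            "stress_proxy": stress if stress is not None else np.nan,
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")
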