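"""Parametric knee geometry: prosthesis surfaces, body frames, attachment points.

The simulator does not use subject-specific (MRI/CAD) geometry.  Instead the
femoral component is modelled as two convex sphere/torus condyle patches, the
tibial inlay as a pair of matching dished (spherical-cup) surfaces carrying the
built-in posterior slope, and the retropatellar cartilage as a shallow convex
facet.  Defaults are chosen to be physiological: epicondylar width ~80 mm,
condylar radii in the 20-35 mm range, 3 degrees of posterior inlay slope.

Units are mm throughout; the global frame is right-handed with the origin at
the ankle joint, z superior, x mediolateral (the flexion axis) and y anterior.

Body-local frames:

* ``tibia``  — origin at the ankle joint, plateau near z = tibia length;
* ``femur``  — origin at the knee centre (midpoint of the condyle centres),
  hip at z = femur length;
* ``patella`` — origin at the patella centre, posterior facet towards -y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _so3

#: bundle / actuator names that every attachment table must provide
REQUIRED_ATTACHMENTS = frozenset(
    {
        "LCL",
        "MCLa",
        "MCLo",
        "MCLd",
        "PCLa",
        "PCLp",
        "vastus_lateralis",
        "vastus_medialis",
        "vastus_intermedius",
        "hamstring_lateral",
        "hamstring_medial",
        "patellar_tendon",
    }
)


@dataclass(frozen=True)
class Attachment:
    """Origin/insertion pair of a line element, each in its owning body frame."""

    origin_body: str
    origin: tuple[float, float, float]
    insertion_body: str
    insertion: tuple[float, float, float]


def default_attachment_table() -> dict[str, Attachment]:
    """Non-subject-specific attachment coordinates (mm, body-local).

    Values follow anatomical-landmark descriptions of the collateral and
    cruciate attachment sites; they are repo constants, not measurements of
    any individual knee.  +x is lateral, +y anterior, +z superior.
    """
    return {
        # ligaments: origin on femur, insertion on tibia (plateau near z = 370)
        "LCL": Attachment("femur", (40.0, 0.0, 6.0), "tibia", (42.0, 0.0, 332.0)),
        "MCLa": Attachment("femur", (-40.0, 0.5, 0.0), "tibia", (-36.0, 10.0, 300.0)),
        "MCLo": Attachment("femur", (-40.0, 2.0, 0.0), "tibia", (-38.0, -15.0, 328.0)),
        "MCLd": Attachment("femur", (-40.0, 0.0, -1.0), "tibia", (-39.0, -2.0, 360.0)),
        "PCLa": Attachment("femur", (0.0, 6.0, -10.0), "tibia", (0.0, -28.0, 356.0)),
        "PCLp": Attachment("femur", (0.0, 0.0, -11.0), "tibia", (0.0, -32.0, 352.0)),
        # quadriceps: femur shaft (anterior of the bone) -> patella
        "vastus_lateralis": Attachment("femur", (22.0, 30.0, 160.0), "patella", (14.0, 2.0, 16.0)),
        "vastus_medialis": Attachment("femur", (-22.0, 30.0, 140.0), "patella", (-14.0, 2.0, 14.0)),
        "vastus_intermedius": Attachment("femur", (0.0, 35.0, 200.0), "patella", (0.0, 2.0, 20.0)),
        # hamstrings: proximal anchor -> posterior tibia
        "hamstring_lateral": Attachment("femur", (30.0, -20.0, 180.0), "tibia", (34.0, -22.0, 338.0)),
        "hamstring_medial": Attachment("femur", (-30.0, -20.0, 180.0), "tibia", (-30.0, -24.0, 335.0)),
        # patellar tendon: patella apex -> tibial tubercle
        "patellar_tendon": Attachment("patella", (0.0, -2.0, -20.0), "tibia", (0.0, 48.0, 330.0)),
    }


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the synthetic knee geometry (mm / degrees)."""

    femoral_condyle_radius_sagittal: float = 30.0
    femoral_condyle_radius_frontal: float = 20.0
    condyle_spacing: float = 44.0
    #: superior offset of the condylar arc centre from the knee centre (an
    #: offset makes the tibiofemoral contact migrate with flexion)
    condyle_center_superior_offset: float = 0.0
    epicondylar_width: float = 80.0
    inlay_dish_radius: float = 250.0  # sagittal (AP) dish radius: low conformity
    inlay_frontal_radius: float = 22.0  # mediolateral trough radius: high conformity
    inlay_posterior_slope: float = 3.0  # degrees, posterior-down positive
    femur_length: float = 400.0
    tibia_length: float = 400.0
    patella_thickness: float = 20.0
    patella_facet_radius: float = 70.0  # proximodistal facet radius
    patella_facet_radius_ml: float = 30.0  # mediolateral facet radius
    #: half-extents of each inlay dish patch (mediolateral, anteroposterior)
    inlay_patch_half_extent: tuple[float, float] = (15.0, 22.0)
    patella_facet_half_extent: tuple[float, float] = (12.0, 14.0)
    attachment_table: dict[str, Attachment] = field(default_factory=default_attachment_table)

    def validate(self) -> None:
        lengths = {
            "femoral_condyle_radius_sagittal": self.femoral_condyle_radius_sagittal,
            "femoral_condyle_radius_frontal": self.femoral_condyle_radius_frontal,
            "condyle_spacing": self.condyle_spacing,
            "epicondylar_width": self.epicondylar_width,
            "inlay_dish_radius": self.inlay_dish_radius,
            "femur_length": self.femur_length,
            "tibia_length": self.tibia_length,
            "patella_thickness": self.patella_thickness,
            "patella_facet_radius": self.patella_facet_radius,
            "patella_facet_radius_ml": self.patella_facet_radius_ml,
        }
        for name, value in lengths.items():
            if not value > 0:
                raise ValueError(f"geometry parameter {name!r} must be > 0, got {value}")
        missing = REQUIRED_ATTACHMENTS - set(self.attachment_table)
        if missing:
            raise ValueError(f"attachment_table missing entries: {sorted(missing)}")
        if self.inlay_frontal_radius <= self.femoral_condyle_radius_frontal:
            raise ValueError("inlay_frontal_radius must exceed femoral_condyle_radius_frontal")
        if self.inlay_dish_radius <= self.femoral_condyle_radius_sagittal:
            raise ValueError("inlay_dish_radius must exceed femoral_condyle_radius_sagittal")


@dataclass
class SurfaceMesh:
    """Triangle surface mesh with a body tag; winding is outward-consistent."""

    vertices: np.ndarray  # (n, 3) float, mm
    triangles: np.ndarray  # (m, 3) int
    body_tag: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)

    def face_areas(self) -> np.ndarray:
        a, b, c = (self.vertices[self.triangles[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def face_centers(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def face_normals(self) -> np.ndarray:
        a, b, c = (self.vertices[self.triangles[:, i]] for i in range(3))
        n = np.cross(b - a, c - a)
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def validate(self) -> None:
        if len(self.triangles) == 0:
            raise ValueError("mesh has no triangles")
        if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle indices out of range")
        areas = self.face_areas()
        if np.any(areas <= 1e-9):
            raise ValueError("mesh contains degenerate triangles (area <= 1e-9 mm^2)")


@dataclass
class RigidPose:
    """Pose of a body segment: world = rotation @ local + translation (mm)."""

    translation: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-9:
            raise ValueError(f"rotation must be proper orthonormal (det={det})")

    def transform(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "RigidPose":
        return RigidPose(np.zeros(3), np.eye(3))


def _grid_surface(u: np.ndarray, v: np.ndarray, fn) -> tuple[np.ndarray, np.ndarray]:
    """Triangulated graph surface over a (u, v) grid; fn maps (U, V) -> (n,3).

    The split diagonal of each quad follows the sign of the cell-centre x so
    that mirror-image surfaces triangulate as exact mirror images (a fixed
    diagonal would bias contact-patch centroids towards one side).
    """
    U, V = np.meshgrid(u, v, indexing="ij")
    verts = fn(U.ravel(), V.ravel())
    nu, nv = len(u), len(v)
    idx = np.arange(nu * nv).reshape(nu, nv)
    tri = []
    for i in range(nu - 1):
        for j in range(nv - 1):
            a, b, c, d = idx[i, j], idx[i + 1, j], idx[i + 1, j + 1], idx[i, j + 1]
            x_center = 0.25 * (verts[a, 0] + verts[b, 0] + verts[c, 0] + verts[d, 0])
            if x_center >= 0.0:
                tri.append((a, b, c))
                tri.append((a, c, d))
            else:
                tri.append((a, b, d))
                tri.append((b, c, d))
    return verts, np.array(tri, dtype=np.int64)


def plateau_height(params: GeometryParams) -> float:
    """z of the inlay dish bottom in the tibia frame."""
    reach = params.femoral_condyle_radius_sagittal - params.condyle_center_superior_offset
    return params.tibia_length - reach


def build_condyle_surface(params: GeometryParams, n_theta: int = 24, n_phi: int = 10) -> SurfaceMesh:
    """Femoral component: two torus patches about the mediolateral axis (femur frame)."""
    rs = params.femoral_condyle_radius_sagittal
    rf = params.femoral_condyle_radius_frontal
    z0 = params.condyle_center_superior_offset
    r_major = rs - rf
    if r_major <= 0:
        raise ValueError("femoral_condyle_radius_sagittal must exceed the frontal radius")
    theta = np.linspace(math.radians(-60.0), math.radians(120.0), n_theta)
    phi = np.linspace(math.radians(-70.0), math.radians(70.0), n_phi)
    verts_all, tris_all = [], []
    offset = 0
    for xc in (-0.5 * params.condyle_spacing, 0.5 * params.condyle_spacing):

        def torus(TH, PH, xc=xc):
            d = np.stack([np.zeros_like(TH), -np.sin(TH), -np.cos(TH)], axis=-1)
            radial = r_major + rf * np.cos(PH)
            pts = d * radial[:, None]
            pts[:, 0] = xc + rf * np.sin(PH)
            pts[:, 2] += z0
            return pts

        v, t = _grid_surface(theta, phi, torus)
        verts_all.append(v)
        tris_all.append(t + offset)
        offset += len(v)
    mesh = SurfaceMesh(np.vstack(verts_all), np.vstack(tris_all), body_tag="femur_component")
    mesh.validate()
    return mesh


def build_inlay_surface(params: GeometryParams, spacing: float = 1.5) -> SurfaceMesh:
    """Tibial inlay top: two biradial dished troughs, tilted by the posterior slope.

    Each condylar dish is an elliptic paraboloid: tightly conforming in the
    mediolateral direction (frontal trough radius, close to the condyle tube
    radius — this is what restrains internal/external rotation) and shallow in
    the anteroposterior direction (low sagittal conformity, letting the femur
    translate AP as real fixed-bearing inlays do).  The slope is applied as a
    rotation about the mediolateral axis through the plateau centre;
    posterior-down for positive slope.  Tibia frame.
    """
    rd = params.inlay_dish_radius
    rm = params.inlay_frontal_radius
    hw, hl = params.inlay_patch_half_extent
    # the dish bottom sits one distal-condyle reach below the knee centre, so
    # the component rests on the inlay at full extension
    lt = plateau_height(params)
    nu = max(4, int(round(2 * hw / spacing)) + 1)
    nv = max(4, int(round(2 * hl / spacing)) + 1)
    u = np.linspace(-hw, hw, nu)
    v = np.linspace(-hl, hl, nv)
    verts_all, tris_all = [], []
    offset = 0
    for xc in (-0.5 * params.condyle_spacing, 0.5 * params.condyle_spacing):

        def dish(U, V, xc=xc):
            z = lt + U**2 / (2.0 * rm) + V**2 / (2.0 * rd)
            return np.stack([xc + U, V, z], axis=-1)

        pts, t = _grid_surface(u, v, dish)
        verts_all.append(pts)
        tris_all.append(t + offset)
        offset += len(pts)
    verts = np.vstack(verts_all)
    # posterior slope: rotate about x through the plateau centre (0, 0, lt)
    alpha = math.radians(params.inlay_posterior_slope)
    rot = _so3.rotx(alpha)
    pivot = np.array([0.0, 0.0, lt])
    verts = (verts - pivot) @ rot.T + pivot
    mesh = SurfaceMesh(verts, np.vstack(tris_all), body_tag="inlay")
    mesh.validate()
    return mesh


def build_patella_surface(params: GeometryParams, spacing: float = 1.5) -> SurfaceMesh:
    """Retropatellar cartilage facet: shallow biradial convex patch facing -y.

    The facet carries different mediolateral and proximodistal radii (median
    ridge vs facet curvature): the curvature mismatch against the trochlea
    gives the patella a restoring stiffness against spin about the contact
    normal, which a perfectly spherical facet would lack.  Patella frame.
    """
    r_ml = params.patella_facet_radius_ml
    r_pd = params.patella_facet_radius
    hx, hz = params.patella_facet_half_extent
    y0 = -0.5 * params.patella_thickness
    nu = max(4, int(round(2 * hx / spacing)) + 1)
    nv = max(4, int(round(2 * hz / spacing)) + 1)
    u = np.linspace(-hx, hx, nu)
    v = np.linspace(-hz, hz, nv)

    def facet(U, V):
        y = y0 + U**2 / (2.0 * r_ml) + V**2 / (2.0 * r_pd)
        return np.stack([U, y, V], axis=-1)

    verts, tris = _grid_surface(u, v, facet)
    mesh = SurfaceMesh(verts, tris, body_tag="patella_cartilage")
    mesh.validate()
    return mesh


@dataclass
class Geometry:
    """Bundle of generated surfaces, landmarks and the attachment table."""

    params: GeometryParams
    meshes: dict[str, SurfaceMesh]
    attachments: dict[str, Attachment]
    landmarks: dict[str, np.ndarray]


def build_default_geometry(params: GeometryParams | None = None) -> Geometry:
    """Deterministically generate the synthetic prosthesis geometry.

    Returns the femoral-component, inlay and patellar-cartilage surfaces in
    their owning body frames, together with the attachment table and the
    epicondyle landmarks (femur frame).
    """
    params = params or GeometryParams()
    params.validate()
    meshes = {
        "femur_component": build_condyle_surface(params),
        "inlay": build_inlay_surface(params),
        "patella_cartilage": build_patella_surface(params),
    }
    w = params.epicondylar_width
    landmarks = {
        "lateral_epicondyle": np.array([0.5 * w, 0.0, 0.0]),
        "medial_epicondyle": np.array([-0.5 * w, 0.0, 0.0]),
        "tibial_plateau_center": np.array([0.0, 0.0, plateau_height(params)]),
        # tibia-frame point coinciding with the knee centre in extension; the
        # reference point for AP-translation measurements
        "tibial_knee_center": np.array([0.0, 0.0, params.tibia_length]),
        "knee_center": np.zeros(3),
    }
    return Geometry(params=params, meshes=meshes, attachments=dict(params.attachment_table), landmarks=landmarks)


def mirror_params(params: GeometryParams) -> GeometryParams:
    """Mirror the attachment table about the sagittal (x=0) plane."""
    mirrored = {
        name: Attachment(
            a.origin_body,
            (-a.origin[0], a.origin[1], a.origin[2]),
            a.insertion_body,
            (-a.insertion[0], a.insertion[1], a.insertion[2]),
        )
        for name, a in params.attachment_table.items()
    }
    return replace(params, attachment_table=mirrored)


def pose_at_reference_flexion(flexion_deg: float, params: GeometryParams | None = None) -> dict[str, RigidPose]:
    """Kinematically consistent pose chain at a given knee flexion angle.

    The ankle stays at the origin and the hip on the z-axis; the flexion is
    split symmetrically between an anterior tibia tilt and a posterior femur
    tilt (closed-chain squat configuration).  The 15 degree pose is the
    reference used for ligament slack-length calibration.
    """
    if not 0.0 <= flexion_deg <= 90.0:
        raise ValueError(f"flexion_deg must be in [0, 90], got {flexion_deg}")
    params = params or GeometryParams()
    half = math.radians(flexion_deg) / 2.0
    lt, lf = params.tibia_length, params.femur_length
    r_t = _so3.rotx(-half)
    knee = r_t @ np.array([0.0, 0.0, lt])
    r_f = _so3.rotx(half)
    poses = {
        "tibia": RigidPose(np.zeros(3), r_t),
        "femur": RigidPose(knee, r_f),
    }
    rs = params.femoral_condyle_radius_sagittal
    pat_offset = np.array([0.0, rs + 0.5 * params.patella_thickness + 4.0, 6.0])
    poses["patella"] = RigidPose(knee + r_f @ pat_offset, r_f.copy())
    return poses


def hip_height(poses: dict[str, RigidPose], params: GeometryParams) -> float:
    """z-coordinate of the femoral head for a pose chain."""
    fem = poses["femur"]
    return float((fem.translation + fem.rotation @ np.array([0.0, 0.0, params.femur_length]))[2])


# ---------------------------------------------------------------------------
# STL I/O (via trimesh)
# ---------------------------------------------------------------------------


def export_mesh(mesh: SurfaceMesh, path) -> None:
    """Write a surface mesh as STL (binary)."""
    import trimesh

    mesh.validate()
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    tm.export(str(path))


def import_mesh(path, body_tag: str = "") -> SurfaceMesh:
    """Read an STL file (binary or ASCII) into a SurfaceMesh."""
    import trimesh

    try:
        tm = trimesh.load_mesh(str(path), process=False)
    except Exception as exc:  # pragma: no cover - exact trimesh error classes vary
        raise ValueError(f"malformed STL file {path}: {exc}") from exc
    if not hasattr(tm, "faces") or len(tm.faces) == 0:
        raise ValueError(f"malformed or empty STL file {path}")
    out = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), body_tag=body_tag)
    out.validate()
    return out
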