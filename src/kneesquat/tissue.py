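"""Tension-only ligament bundles and constant-preload muscle actuators.

Ligaments are linear tension-only springs (one per anatomical bundle): the
lateral collateral (LCL) as a single bundle, the medial collateral as three
bundles (anterior MCLa, oblique MCLo, deep MCLd) and the posterior cruciate as
two bundles (anterior PCLa, posterior PCLp).  Each bundle carries a stiffness
k (N/mm) and a reference engineering strain prescribed at the 15-degree
flexion pose; the slack length follows from L0 = L_ref / (1 + eps_ref), so a
negative reference strain means the bundle is slack at the reference pose.

Muscles are preload actuators: a constant preload F0 plus a very soft spring
(default 0.001 N/mm) whose only purpose is to keep the line of action defined
while the origin-insertion distance changes over the squat, so the delivered
force stays within F0 +/- 0.001*|dL|.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: default ligament table: name -> (stiffness N/mm, reference strain at 15 deg)
DEFAULT_LIGAMENT_TABLE: dict[str, tuple[float, float]] = {
    "LCL": (91.3, 0.02),
    "MCLa": (27.9, 0.02),
    "MCLo": (21.1, 0.02),
    "MCLd": (72.2, 0.02),
    "PCLa": (125.0, -0.10),
    "PCLp": (60.0, -0.02),
}

#: stiffness of the patellar tendon spring (N/mm); zero reference strain at 15 deg
PATELLAR_TENDON_STIFFNESS = 2000.0

#: soft spring keeping constant-preload actuators aligned (N/mm)
PRELOAD_SPRING_STIFFNESS = 0.001

#: default muscle preloads (N)
DEFAULT_MUSCLE_PRELOADS: dict[str, float] = {
    "vastus_lateralis": 20.0,
    "vastus_medialis": 20.0,
    "hamstring_lateral": 10.0,
    "hamstring_medial": 10.0,
}

#: initial preload of the controllable vastus intermedius (N)
DEFAULT_INITIAL_QUAD_FORCE = 21.0

PCL_BUNDLES = ("PCLa", "PCLp")


@dataclass
class LigamentBundle:
    """Linear tension-only spring between two body-fixed points."""

    name: str
    origin_body: str
    origin: np.ndarray
    insertion_body: str
    insertion: np.ndarray
    stiffness: float  # N/mm
    reference_strain: float  # engineering strain at the 15 deg reference pose
    release_scale: float = 1.0
    slack_length: float | None = None  # mm, set by calibrate_slack_lengths

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.insertion = np.asarray(self.insertion, dtype=float).reshape(3)
        if not self.stiffness > 0:
            raise ValueError(f"{self.name}: stiffness must be > 0")
        if not 0.0 < self.release_scale <= 1.0:
            raise ValueError(f"{self.name}: release_scale must be in (0, 1]")

    @property
    def effective_stiffness(self) -> float:
        return self.release_scale * self.stiffness

    def force(self, current_length: float) -> float:
        """Tension (N) at a given origin-insertion distance; 0 when slack."""
        if self.slack_length is None:
            raise RuntimeError(f"{self.name}: bundle not calibrated (slack length unset)")
        if current_length <= 0:
            raise ValueError("current_length must be > 0")
        elong = current_length - self.slack_length
        return self.effective_stiffness * elong if elong > 0.0 else 0.0

    def strain(self, current_length: float) -> float:
        if self.slack_length is None:
            raise RuntimeError(f"{self.name}: bundle not calibrated (slack length unset)")
        return (current_length - self.slack_length) / self.slack_length


def ligament_force(bundle: LigamentBundle, origin_world: np.ndarray, insertion_world: np.ndarray):
    """Force magnitude (N) and line of action (unit vector origin->insertion)."""
    d = np.asarray(insertion_world, dtype=float) - np.asarray(origin_world, dtype=float)
    length = float(np.linalg.norm(d))
    f = bundle.force(length)
    return f, d / length


@dataclass
class MuscleActuator:
    """Constant-preload spring actuator (tension only)."""

    name: str
    origin_body: str
    origin: np.ndarray
    insertion_body: str
    insertion: np.ndarray
    preload: float  # N
    spring_stiffness: float = PRELOAD_SPRING_STIFFNESS  # N/mm
    controllable: bool = False
    natural_length: float | None = None  # mm, set at calibration

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.insertion = np.asarray(self.insertion, dtype=float).reshape(3)
        if self.preload < 0:
            raise ValueError(f"{self.name}: preload must be >= 0")
        if not self.spring_stiffness > 0:
            raise ValueError(f"{self.name}: spring_stiffness must be > 0")

    def force(self, current_length: float) -> float:
        """Delivered tension (N): preload plus the soft-spring correction, clamped at 0."""
        if self.natural_length is None:
            raise RuntimeError(f"{self.name}: actuator not calibrated (natural length unset)")
        dl = current_length - self.natural_length
        return max(0.0, self.preload + self.spring_stiffness * dl)


def muscle_force(actuator: MuscleActuator, current_length: float) -> float:
    return actuator.force(current_length)


def _attachment_world(poses, body: str, point: np.ndarray) -> np.ndarray:
    return poses[body].transform(point)


def calibrate_slack_lengths(bundles: dict[str, LigamentBundle], reference_poses) -> dict[str, LigamentBundle]:
    """Set slack lengths so the strain at the reference pose equals eps_ref.

    ``reference_poses`` maps body name -> RigidPose at the 15-degree flexion
    reference.  L0 = L_ref / (1 + eps_ref); calibration is idempotent because
    L_ref depends only on the pose, not on the previous slack length.
    """
    out = {}
    for name, b in bundles.items():
        if b.reference_strain <= -1.0:
            raise ValueError(f"{name}: reference strain {b.reference_strain} implies nonpositive slack length")
        o = _attachment_world(reference_poses, b.origin_body, b.origin)
        i = _attachment_world(reference_poses, b.insertion_body, b.insertion)
        l_ref = float(np.linalg.norm(i - o))
        out[name] = replace(b, slack_length=l_ref / (1.0 + b.reference_strain))
    return out


def calibrate_muscles(muscles: dict[str, MuscleActuator], reference_poses) -> dict[str, MuscleActuator]:
    """Set actuator natural lengths to the reference-pose origin-insertion distance."""
    out = {}
    for name, m in muscles.items():
        o = _attachment_world(reference_poses, m.origin_body, m.origin)
        i = _attachment_world(reference_poses, m.insertion_body, m.insertion)
        out[name] = replace(m, natural_length=float(np.linalg.norm(i - o)))
    return out


def apply_pcl_release(bundles: dict[str, LigamentBundle], release_percent: float) -> dict[str, LigamentBundle]:
    """Scale the stiffness of both PCL bundles by (1 - release/100).

    The release acts on stiffness only; slack lengths are untouched.  100 %
    is rejected (remove the bundles explicitly instead).
    """
    if not 0.0 <= release_percent < 100.0:
        raise ValueError(f"release_percent must be in [0, 100), got {release_percent}")
    scale = 1.0 - release_percent / 100.0
    out = {}
    for name, b in bundles.items():
        out[name] = replace(b, release_scale=scale) if name in PCL_BUNDLES else replace(b)
    return out


def build_default_bundles(attachments) -> dict[str, LigamentBundle]:
    """Ligament bundles from the attachment table and the default stiffness table.

    Includes the patellar tendon as a stiff tension-only spring with zero
    reference strain (its properties are a repo constant).
    """
    bundles = {}
    for name, (k, eps) in DEFAULT_LIGAMENT_TABLE.items():
        a = attachments[name]
        bundles[name] = LigamentBundle(name, a.origin_body, np.array(a.origin), a.insertion_body, np.array(a.insertion), k, eps)
    a = attachments["patellar_tendon"]
    bundles["patellar_tendon"] = LigamentBundle(
        "patellar_tendon", a.origin_body, np.array(a.origin), a.insertion_body, np.array(a.insertion), PATELLAR_TENDON_STIFFNESS, 0.0
    )
    return bundles


def build_default_muscles(attachments, initial_quad_force: float = DEFAULT_INITIAL_QUAD_FORCE) -> dict[str, MuscleActuator]:
    """Muscle actuators: VL/VM 20 N, hamstrings 2 x 10 N, controllable VI."""
    muscles = {}
    for name, f0 in DEFAULT_MUSCLE_PRELOADS.items():
        a = attachments[name]
        muscles[name] = MuscleActuator(name, a.origin_body, np.array(a.origin), a.insertion_body, np.array(a.insertion), f0)
    a = attachments["vastus_intermedius"]
    muscles["vastus_intermedius"] = MuscleActuator(
        "vastus_intermedius", a.origin_body, np.array(a.origin), a.insertion_body, np.array(a.insertion),
        initial_quad_force, controllable=True,
    )
    return muscles
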