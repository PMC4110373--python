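"""Quasi-static equilibrium of the femur-tibia-patella system over a squat.

The rig boundary conditions: the ankle is pinned at the origin with all three
tibial rotations free; the femoral head slides on the z-axis with a prescribed
per-step vertical drop, with flexion (about x) and varus/valgus (about y)
free; the patella is fully free (6 DOF).  Total 11 free degrees of freedom.

Equilibrium at each of the (default 30) load steps is found by minimizing the
total potential energy

    E = sum ligament spring energy (tension-only, quadratic)
      + sum muscle actuator energy (constant preload + 0.001 N/mm spring)
      + elastic-foundation contact energy (femorotibial + patellofemoral)

with analytic gradients (SO(3) right-Jacobian chain rule).  Friction enters
through a fixed-point outer iteration: regularized Coulomb tractions computed
from the slip since the previous converged step are applied as constant
generalized forces and the energy is re-minimized.  "Dynamic" squatting is a
sequence of such implicit load steps — no inertia.

Ground reaction force is the vertical ankle reaction, obtained by direct force
bookkeeping on the tibia (spring + contact + friction forces); the controller
in :mod:`kneesquat.control` adapts the vastus intermedius force until the GRF
lies in the prescribed band.

Units: mm, N, MPa, degrees in reported metrics (radians internally).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from . import _so3, contact as _contact, geometry as _geometry, tissue as _tissue
from .contact import CondylePairSDF, ContactPatchField, TrochleaSDF, foundation_modulus
from .geometry import Geometry, GeometryParams, RigidPose, build_default_geometry, pose_at_reference_flexion

REFERENCE_FLEXION_DEG = 15.0
DEFAULT_N_STEPS = 30
DEFAULT_HIP_DROP = 150.0  # mm
DEFAULT_FLEXION_CAP = 73.0  # degrees
DEFAULT_TOL_RES = 1e-3  # N-equivalent mixed residual norm
DEFAULT_MAX_ITER = 200  # inner L-BFGS iterations per (re)start

#: lever used to scale rotational DOFs so gradients are N-equivalent
ROTATION_LEVER = 400.0  # mm
_ZHAT = np.array([0.0, 0.0, 1.0])


class StepFailureError(RuntimeError):
    """A load step failed to reach the residual tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class SingularConfigurationError(RuntimeError):
    """Fully straight leg at zero drop tolerance; start from flexion > 0."""


@dataclass
class SquatSchedule:
    """Linear hip-drop ramp: step 1 has zero drop, step n the full drop."""

    n_steps: int = DEFAULT_N_STEPS
    hip_drop_total: float = DEFAULT_HIP_DROP

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.hip_drop_total < 0:
            raise ValueError("hip_drop_total must be >= 0")

    def drops(self) -> np.ndarray:
        if self.n_steps == 1:
            return np.array([0.0])
        return np.linspace(0.0, self.hip_drop_total, self.n_steps)


@dataclass
class SolverState:
    """Converged configuration of a load step (poses + controller memory)."""

    r_tibia: np.ndarray
    phi_femur: float  # flexion about x, rad
    psi_femur: float  # varus/valgus about y, rad
    r_patella: np.ndarray
    t_patella: np.ndarray
    quad_force: float
    drop: float = 0.0

    def poses(self, model: "KneeModel", drop: float | None = None) -> dict[str, RigidPose]:
        drop = self.drop if drop is None else drop
        z_hip = model.z_hip0 - drop
        r_f = _so3.rotx(self.phi_femur) @ _so3.roty(self.psi_femur)
        hip = np.array([0.0, 0.0, z_hip])
        t_f = hip + r_f @ np.array([0.0, 0.0, -model.geometry.params.femur_length])
        return {
            "tibia": RigidPose(np.zeros(3), self.r_tibia),
            "femur": RigidPose(t_f, r_f),
            "patella": RigidPose(self.t_patella, self.r_patella),
        }


@dataclass
class StepResult:
    state: SolverState
    grf: float
    residual: float
    n_iterations: int
    diagnostics: dict


@dataclass
class SquatTrace:
    """Per-load-step record of the squat simulation."""

    records: list[dict] = field(default_factory=list)
    stopped_early: bool = False
    failure: str | None = None

    def append(self, rec: dict) -> None:
        self.records.append(rec)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def summary(self) -> dict:
        df = self.to_frame()
        if df.empty:
            return {"n_steps": 0}
        return {
            "n_steps": int(len(df)),
            "flexion_range_deg": [float(df.flexion_deg.min()), float(df.flexion_deg.max())],
            "grf_range_N": [float(df.grf_N.min()), float(df.grf_N.max())],
            "quad_force_final_N": float(df.quad_force_N.iloc[-1]),
            "ap_translation_range_mm": [float(df.ap_translation_mm.min()), float(df.ap_translation_mm.max())],
            "peak_inlay_stress_MPa": float(df.inlay_peak_stress_MPa.max()),
            "peak_patella_stress_MPa": float(df.patella_peak_stress_MPa.max()),
            "total_controller_restarts": int(df.controller_restarts.sum()),
        }


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class _ContactPair:
    """A deformable patch field against the rigid femoral component."""

    name: str
    body: str  # body owning the patches: "tibia" or "patella"
    patches: ContactPatchField
    mu: float
    poisson: float  # for the surface stress proxy
    sdf: object = None  # rigid counter-surface in the femur frame (defaults to the condyles)


class KneeModel:
    """Calibrated femur-tibia-patella model ready for load-step solves."""

    def __init__(
        self,
        geometry: Geometry,
        bundles: dict[str, _tissue.LigamentBundle],
        muscles: dict[str, _tissue.MuscleActuator],
        contact_pairs: list[_ContactPair],
        femur_sdf: CondylePairSDF,
        tol_res: float = DEFAULT_TOL_RES,
        max_iter: int = DEFAULT_MAX_ITER,
        friction_iterations: int = 2,
        friction_regularization: float = _contact.DEFAULT_FRICTION_REGULARIZATION,
        perturbation_seed: int = 0,
    ):
        self.geometry = geometry
        self.bundles = bundles
        self.muscles = muscles
        self.contact_pairs = contact_pairs
        self.femur_sdf = femur_sdf
        self.tol_res = tol_res
        self.max_iter = max_iter
        self.friction_iterations = friction_iterations
        self.friction_regularization = friction_regularization
        self.perturbation_seed = perturbation_seed
        ref = pose_at_reference_flexion(REFERENCE_FLEXION_DEG, geometry.params)
        self.z_hip0 = _geometry.hip_height(ref, geometry.params)
        self._lever = ROTATION_LEVER

    # -- construction -------------------------------------------------------

    @classmethod
    def build_default(
        cls,
        params: GeometryParams | None = None,
        release_percent: float = 0.0,
        contact_spacing: float = 1.5,
        mu_femorotibial: float = 0.05,
        mu_patellofemoral: float = 0.02,
        inlay_thickness: float = 8.0,
        cartilage_thickness: float = 3.0,
        **solver_kwargs,
    ) -> "KneeModel":
        """Default synthetic model: PE inlay on CoCr component, optional PCL release."""
        params = params or GeometryParams()
        geom = build_default_geometry(params)
        # rebuild deformable surfaces at the requested contact resolution
        inlay = _geometry.build_inlay_surface(params, spacing=contact_spacing)
        pat = _geometry.build_patella_surface(params, spacing=contact_spacing)
        ref = pose_at_reference_flexion(REFERENCE_FLEXION_DEG, params)
        bundles = _tissue.build_default_bundles(geom.attachments)
        bundles = _tissue.calibrate_slack_lengths(bundles, ref)
        bundles = _tissue.apply_pcl_release(bundles, release_percent)
        muscles = _tissue.calibrate_muscles(_tissue.build_default_muscles(geom.attachments), ref)
        kf_pe = foundation_modulus(312.5, 0.46, inlay_thickness)
        kf_cart = foundation_modulus(5.0, 0.46, cartilage_thickness)
        pairs = [
            _ContactPair(
                "femorotibial",
                "tibia",
                ContactPatchField.from_mesh(inlay, kf_pe, mu_femorotibial, orient=np.array([0.0, 0.0, 1.0])),
                mu_femorotibial,
                0.46,
            ),
            _ContactPair(
                "patellofemoral",
                "patella",
                ContactPatchField.from_mesh(pat, kf_cart, mu_patellofemoral, orient=np.array([0.0, -1.0, 0.0])),
                mu_patellofemoral,
                0.46,
                sdf=TrochleaSDF(params.femoral_condyle_radius_sagittal),
            ),
        ]
        sdf = CondylePairSDF(
            params.femoral_condyle_radius_sagittal,
            params.femoral_condyle_radius_frontal,
            params.condyle_spacing,
            center_z=params.condyle_center_superior_offset,
        )
        return cls(geom, bundles, muscles, pairs, sdf, **solver_kwargs)

    def initial_state(self, quad_force: float = _tissue.DEFAULT_INITIAL_QUAD_FORCE) -> SolverState:
        ref = pose_at_reference_flexion(REFERENCE_FLEXION_DEG, self.geometry.params)
        half = math.radians(REFERENCE_FLEXION_DEG) / 2.0
        return SolverState(
            r_tibia=ref["tibia"].rotation.copy(),
            phi_femur=half,
            psi_femur=0.0,
            r_patella=ref["patella"].rotation.copy(),
            t_patella=ref["patella"].translation.copy(),
            quad_force=quad_force,
            drop=0.0,
        )

    # -- kinematics of the DOF vector --------------------------------------

    def _fold(self, state: SolverState, x: np.ndarray, drop: float) -> SolverState:
        s = 1.0 / self._lever
        return replace(
            state,
            r_tibia=state.r_tibia @ _so3.exp(s * x[0:3]),
            phi_femur=state.phi_femur + s * x[3],
            psi_femur=state.psi_femur + s * x[4],
            t_patella=state.t_patella + x[5:8],
            r_patella=state.r_patella @ _so3.exp(s * x[8:11]),
            drop=drop,
        )

    # -- energy and gradient -------------------------------------------------

    def _energy_grad(
        self,
        x: np.ndarray,
        state: SolverState,
        drop: float,
        quad_force: float,
        q_friction: np.ndarray | None = None,
        diagnostics: bool = False,
    ):
        """Total potential energy, gradient w.r.t. the 11 scaled DOFs, diagnostics.

        The DOF scaling (rotations by 1/ROTATION_LEVER) makes every gradient
        component an equivalent force in N at a 400 mm lever, so the residual
        tolerance has a single unit.
        """
        s = 1.0 / self._lever
        lf = self.geometry.params.femur_length
        z_hip = self.z_hip0 - drop
        hip = np.array([0.0, 0.0, z_hip])
        l_vec = np.array([0.0, 0.0, -lf])

        th_t = s * x[0:3]
        r_t = state.r_tibia @ _so3.exp(th_t)
        jr_t = _so3.right_jacobian(th_t)
        phi = state.phi_femur + s * x[3]
        psi = state.psi_femur + s * x[4]
        rx, ry = _so3.rotx(phi), _so3.roty(psi)
        r_f = rx @ ry
        drf_dphi = _so3.drotx(phi) @ ry
        drf_dpsi = rx @ _so3.droty(psi)
        t_f = hip + r_f @ l_vec
        th_p = s * x[8:11]
        r_p = state.r_patella @ _so3.exp(th_p)
        jr_p = _so3.right_jacobian(th_p)
        t_p = state.t_patella + x[5:8]

        energy = 0.0
        grad = np.zeros(11)
        # force accumulators for reaction bookkeeping (world frame)
        f_tibia = np.zeros(3)
        f_femur = np.zeros(3)
        f_patella = np.zeros(3)
        diag: dict = {"bundle_forces": {}, "muscle_forces": {}} if diagnostics else {}

        def point_world_and_jac(body: str, p_local: np.ndarray):
            """World position and (3, 11) Jacobian of a body-fixed point."""
            jac = np.zeros((3, 11))
            if body == "tibia":
                w = r_t @ p_local
                # d(R0 Exp(th) p)/dth = -R [p]x Jr ; columns scaled by s
                jac[:, 0:3] = -s * (r_t @ _so3.hat(p_local) @ jr_t)
            elif body == "femur":
                rel = p_local + l_vec
                w = hip + r_f @ rel
                jac[:, 3] = s * (drf_dphi @ rel)
                jac[:, 4] = s * (drf_dpsi @ rel)
            elif body == "patella":
                w = r_p @ p_local + t_p
                jac[:, 5:8] = np.eye(3)
                jac[:, 8:11] = -s * (r_p @ _so3.hat(p_local) @ jr_p)
            else:  # pragma: no cover
                raise KeyError(body)
            return w, jac

        def add_body_force(body: str, f: np.ndarray) -> None:
            nonlocal f_tibia, f_femur, f_patella
            if body == "tibia":
                f_tibia = f_tibia + f
            elif body == "femur":
                f_femur = f_femur + f
            else:
                f_patella = f_patella + f

        # --- line elements (ligaments + patellar tendon + muscles) ---
        for name, b in self.bundles.items():
            a_w, a_j = point_world_and_jac(b.origin_body, b.origin)
            b_w, b_j = point_world_and_jac(b.insertion_body, b.insertion)
            d = b_w - a_w
            length = float(np.linalg.norm(d))
            u = d / length
            elong = length - b.slack_length
            if elong > 0.0:
                k = b.effective_stiffness
                energy += 0.5 * k * elong * elong
                f = k * elong
                grad += f * (u @ (b_j - a_j))
            else:
                f = 0.0
            add_body_force(b.origin_body, f * u)
            add_body_force(b.insertion_body, -f * u)
            if diagnostics:
                diag["bundle_forces"][name] = f

        for name, m in self.muscles.items():
            f0 = quad_force if m.controllable else m.preload
            a_w, a_j = point_world_and_jac(m.origin_body, m.origin)
            b_w, b_j = point_world_and_jac(m.insertion_body, m.insertion)
            d = b_w - a_w
            length = float(np.linalg.norm(d))
            u = d / length
            dl = length - m.natural_length
            f = f0 + m.spring_stiffness * dl
            if f > 0.0:
                energy += f0 * dl + 0.5 * m.spring_stiffness * dl * dl
                grad += f * (u @ (b_j - a_j))
            else:  # fully slack actuator: constant energy plateau
                f = 0.0
                energy += -0.5 * f0 * f0 / m.spring_stiffness
            add_body_force(m.origin_body, f * u)
            add_body_force(m.insertion_body, -f * u)
            if diagnostics:
                diag["muscle_forces"][name] = f

        # --- elastic-foundation contact (deformable patches vs femoral sdf) ---
        for pair in self.contact_pairs:
            patches = pair.patches
            c_local = patches.centers
            if pair.body == "tibia":
                x_w = c_local @ r_t.T
            else:
                x_w = c_local @ r_p.T + t_p
            rel = x_w - hip
            p_fem = rel @ r_f - l_vec  # femur-local coordinates
            sdf = pair.sdf if pair.sdf is not None else self.femur_sdf
            g, g_grad = sdf.signed_distance(p_fem)
            pen = np.maximum(0.0, -g)
            active = pen > 0.0
            kf = patches.foundation_modulus
            area = patches.areas
            energy += 0.5 * kf * float((area * pen * pen).sum())
            if diagnostics:
                n_w_all = patches.normals @ (r_t.T if pair.body == "tibia" else r_p.T)
                pressures = kf * pen
                stress, _ = _proxy(pressures, pair.poisson)
                diag[pair.name] = {
                    "gap": g,
                    "pressure": pressures,
                    "stress_proxy": stress,
                    "peak_pressure": float(pressures.max(initial=0.0)),
                    "peak_stress": float(stress.max(initial=0.0)),
                    "normal_force": float((pressures * area).sum()),
                    "world_centers": x_w,
                    "femur_local": p_fem,
                }
            if not np.any(active):
                continue
            # dE/dP_i = -kf * A_i * pen_i * grad_sdf_i  (femur-local frame)
            coef = (-kf * area * pen)[active]
            de_dp = coef[:, None] * g_grad[active]
            w_i = de_dp @ r_f.T  # world-frame dE/dX_i
            # contact force on the deformable body at patch i is -w_i
            f_on_def = -w_i.sum(axis=0)
            add_body_force(pair.body, f_on_def)
            add_body_force("femur", -f_on_def)
            # deformable-body DOFs
            if pair.body == "tibia":
                v = w_i @ r_t  # tibia-local
                m_vec = np.cross(v, c_local[active]).sum(axis=0)
                grad[0:3] += -s * (jr_t.T @ m_vec)
            else:
                grad[5:8] += w_i.sum(axis=0)
                v = w_i @ r_p
                m_vec = np.cross(v, c_local[active]).sum(axis=0)
                grad[8:11] += -s * (jr_p.T @ m_vec)
            # femur DOFs: dP/dphi = (dRf/dphi)^T rel, dP/dz_hip = -Rf^T zhat
            rel_a = rel[active]
            grad[3] += s * float(np.einsum("ij,ij->", de_dp, rel_a @ drf_dphi))
            grad[4] += s * float(np.einsum("ij,ij->", de_dp, rel_a @ drf_dpsi))

        if q_friction is not None:
            energy -= float(q_friction @ x)
            grad -= q_friction

        if diagnostics:
            diag["force_on_tibia"] = f_tibia
            diag["force_on_femur"] = f_femur
            diag["force_on_patella"] = f_patella
            diag["grf"] = -float(f_tibia[2])
            diag["poses"] = {
                "tibia": RigidPose(np.zeros(3), r_t),
                "femur": RigidPose(t_f, r_f),
                "patella": RigidPose(t_p, r_p),
            }
        return energy, grad, diag

    # -- friction -----------------------------------------------------------

    def _friction_generalized_force(self, state_prev: SolverState, state_now: SolverState, quad_force: float):
        """Fixed-point Coulomb friction: generalized force and per-pair tractions.

        Slip per patch is the relative displacement of the deformable surface
        w.r.t. the femoral component since the previous converged step,
        tangentialized against the contact normal.
        """
        poses_prev = state_prev.poses(self)
        poses_now = state_now.poses(self)
        r_f, t_f = poses_now["femur"].rotation, poses_now["femur"].translation
        r_fp, t_fp = poses_prev["femur"].rotation, poses_prev["femur"].translation
        s = 1.0 / self._lever
        q = np.zeros(11)
        tractions = {}
        for pair in self.contact_pairs:
            patches = pair.patches
            c_local = patches.centers
            pose_def = poses_now[pair.body]
            pose_def_prev = poses_prev[pair.body]
            x_w = pose_def.transform(c_local)
            p_fem = (x_w - t_f) @ r_f
            sdf = pair.sdf if pair.sdf is not None else self.femur_sdf
            g, g_grad = sdf.signed_distance(p_fem)
            pen = np.maximum(0.0, -g)
            pressures = patches.foundation_modulus * pen
            active = pen > 0.0
            t_arr = np.zeros_like(x_w)
            if np.any(active):
                x_fem_prev = p_fem[active] @ r_fp.T + t_fp
                x_def_prev = pose_def_prev.transform(c_local[active])
                slip = x_fem_prev - x_def_prev
                n_w = g_grad[active] @ r_f.T
                n_w /= np.linalg.norm(n_w, axis=1, keepdims=True)
                slip -= (np.einsum("ij,ij->i", slip, n_w))[:, None] * n_w
                speed = np.linalg.norm(slip, axis=1)
                scale = -pair.mu * pressures[active] / (speed + self.friction_regularization)
                t_act = scale[:, None] * slip  # traction on the deformable body, MPa
                t_arr[active] = t_act
                fa = patches.areas[active][:, None] * t_act  # force on deformable body, N
                # virtual work on the deformable body DOFs
                if pair.body == "tibia":
                    r_t = poses_now["tibia"].rotation
                    v = fa @ r_t
                    m_vec = np.cross(v, c_local[active]).sum(axis=0)
                    th_t = np.zeros(3)
                    q[0:3] += -s * (_so3.right_jacobian(th_t).T @ m_vec)
                else:
                    q[5:8] += fa.sum(axis=0)
                    r_p = poses_now["patella"].rotation
                    v = fa @ r_p
                    m_vec = np.cross(v, c_local[active]).sum(axis=0)
                    q[8:11] += -s * (_so3.right_jacobian(np.zeros(3)).T @ m_vec)
                # reaction on the femur DOFs
                rel = (x_w[active] - np.array([0.0, 0.0, self.z_hip0 - state_now.drop]))
                phi, psi = state_now.phi_femur, state_now.psi_femur
                dphi = _so3.drotx(phi) @ _so3.roty(psi)
                dpsi = _so3.rotx(phi) @ _so3.droty(psi)
                lf = self.geometry.params.femur_length
                l_vec = np.array([0.0, 0.0, -lf])
                p_rel = p_fem[active] + l_vec
                q[3] += -s * float(np.einsum("ij,ij->", fa, p_rel @ dphi.T))
                q[4] += -s * float(np.einsum("ij,ij->", fa, p_rel @ dpsi.T))
            tractions[pair.name] = t_arr
        return q, tractions

    # -- solving -------------------------------------------------------------

    def solve_load_step(
        self,
        state: SolverState,
        drop: float,
        quad_force: float,
        diagnostics: bool = True,
        perturb: float = 0.0,
    ) -> StepResult:
        """Equilibrate one load step at a prescribed hip drop and quadriceps force.

        Warm-starts from ``state``; raises :class:`StepFailureError` when the
        mixed force residual cannot be brought below ``tol_res``.
        """
        if quad_force < 0:
            raise ValueError("quad_force must be >= 0")
        work = replace(state)
        q_fric = None
        tractions = None
        n_outer = self.friction_iterations if any(p.mu > 0 for p in self.contact_pairs) else 1
        total_iters = 0
        res_inf = np.inf
        for outer in range(max(1, n_outer)):
            x0 = self._predict_increments(work, drop) if outer == 0 else np.zeros(11)
            if perturb > 0.0 and outer == 0:
                rng = np.random.default_rng(self.perturbation_seed)
                x0 = x0 + perturb * rng.standard_normal(11)
            scale = self._diag_scaling(x0, work, drop, quad_force, q_fric)

            def fun(y):
                e, g, _ = self._energy_grad(scale * y, work, drop, quad_force, q_fric)
                return e, scale * g

            y0 = x0 / scale
            best = None
            for _restart in range(4):
                res = minimize(
                    fun,
                    y0,
                    jac=True,
                    method="L-BFGS-B",
                    options={"maxiter": self.max_iter, "ftol": 1e-18, "gtol": 1e-14, "maxcor": 30},
                )
                total_iters += res.nit
                x_sol = scale * res.x
                _, g_raw, _ = self._energy_grad(x_sol, work, drop, quad_force, q_fric)
                res_inf = float(np.abs(g_raw).max())
                if best is None or res_inf < best[0]:
                    best = (res_inf, x_sol)
                if res_inf < self.tol_res:
                    break
                y0 = res.x
            res_inf, x_sol = best
            work = self._fold(work, x_sol, drop)
            work, res_inf = self._newton_polish(work, drop, quad_force, q_fric, res_inf)
            if outer < n_outer - 1:
                q_fric, tractions = self._friction_generalized_force(state, work, quad_force)
                q_fric_folded = q_fric  # increments re-centered at the folded pose
                q_fric = q_fric_folded
        if res_inf >= self.tol_res * 10:
            raise StepFailureError(
                f"load step did not converge: residual {res_inf:.3e} N-equivalent "
                f"(tol {self.tol_res:.1e}) at drop {drop:.2f} mm",
                res_inf,
            )
        _, _, diag = self._energy_grad(np.zeros(11), work, drop, quad_force, q_fric, diagnostics=True)
        grf = diag["grf"]
        if tractions is not None:
            # add friction transmission to the tibial force balance
            ft = tractions.get("femorotibial")
            if ft is not None:
                pair = self.contact_pairs[0]
                f_fric = (pair.patches.areas[:, None] * ft).sum(axis=0)
                diag["force_on_tibia"] = diag["force_on_tibia"] + f_fric
                diag["force_on_femur"] = diag["force_on_femur"] - f_fric
                grf = -float(diag["force_on_tibia"][2])
            diag["tractions"] = tractions
        diag["grf"] = grf
        work = replace(work, quad_force=quad_force)
        if not diagnostics:
            diag = {"grf": grf}
        return StepResult(state=work, grf=grf, residual=res_inf, n_iterations=total_iters, diagnostics=diag)

    def _predict_increments(self, state: SolverState, drop: float) -> np.ndarray:
        """Closed-chain kinematic warm-start prediction for a new hip drop.

        Splits the extra flexion implied by the drop symmetrically between the
        tibia and femur tilts and carries the patella along with the femur, so
        even coarse load schedules start near the flexed branch of the energy
        landscape rather than the jammed (over-penetrated) one.
        """
        from scipy.spatial.transform import Rotation

        p = self.geometry.params
        tot = p.femur_length + p.tibia_length
        half_now = math.acos(np.clip((self.z_hip0 - state.drop) / tot, -1.0, 1.0))
        half_new = math.acos(np.clip((self.z_hip0 - drop) / tot, -1.0, 1.0))
        d = half_new - half_now
        x0 = np.zeros(11)
        if abs(d) < 1e-12:
            return x0
        x0[0] = -d * self._lever
        x0[3] = d * self._lever
        poses = state.poses(self)
        r_f, t_f = poses["femur"].rotation, poses["femur"].translation
        r_f_new = _so3.rotx(state.phi_femur + d) @ _so3.roty(state.psi_femur)
        hip_new = np.array([0.0, 0.0, self.z_hip0 - drop])
        t_f_new = hip_new + r_f_new @ np.array([0.0, 0.0, -p.femur_length])
        spin = r_f_new @ r_f.T
        t_p_new = t_f_new + spin @ (state.t_patella - t_f)
        x0[5:8] = t_p_new - state.t_patella
        r_p_new = spin @ state.r_patella
        x0[8:11] = self._lever * Rotation.from_matrix(state.r_patella.T @ r_p_new).as_rotvec()
        return x0

    def _newton_polish(self, state: SolverState, drop: float, quad_force: float, q_fric, res_inf: float):
        """Damped Newton steps on the FD Hessian of the analytic gradient.

        L-BFGS reliably reaches ~1e-4 N-equivalent residuals; the soft patellar
        and rotational modes need a curvature-aware polish to push the residual
        to the tolerance.  Eigenvalues are clamped from below so near-singular
        soft modes take bounded steps.
        """
        for _ in range(4):
            if res_inf < 0.05 * self.tol_res:
                break
            _, g0, _ = self._energy_grad(np.zeros(11), state, drop, quad_force, q_fric)
            h = np.empty((11, 11))
            delta = 1e-5
            for j in range(11):
                xj = np.zeros(11)
                xj[j] = delta
                _, gj, _ = self._energy_grad(xj, state, drop, quad_force, q_fric)
                h[:, j] = (gj - g0) / delta
            h = 0.5 * (h + h.T)
            w, v = np.linalg.eigh(h)
            w = np.maximum(w, max(1e-6 * w.max(), 1e-9))
            dx = -(v @ ((v.T @ g0) / w))
            step = np.clip(dx, -1.0, 1.0)  # bound to 1 mm-equivalent
            candidate = self._fold(state, step, drop)
            _, g1, _ = self._energy_grad(np.zeros(11), candidate, drop, quad_force, q_fric)
            new_res = float(np.abs(g1).max())
            if new_res >= res_inf:
                break
            state, res_inf = candidate, new_res
        return state, res_inf

    def _diag_scaling(self, x0, state, drop, quad_force, q_fric):
        """Per-DOF inverse-sqrt-curvature scaling (finite-difference Hessian diagonal)."""
        _, g0, _ = self._energy_grad(x0, state, drop, quad_force, q_fric)
        h = np.empty(11)
        delta = 1e-4
        for j in range(11):
            xj = x0.copy()
            xj[j] += delta
            _, gj, _ = self._energy_grad(xj, state, drop, quad_force, q_fric)
            h[j] = abs(gj[j] - g0[j]) / delta
        h = np.maximum(h, 1e-3 * max(h.max(), 1e-12))
        return 1.0 / np.sqrt(h)

    # -- metrics -------------------------------------------------------------

    def flexion_deg(self, state: SolverState) -> float:
        poses = state.poses(self)
        zt = poses["tibia"].rotation @ _ZHAT
        zf = poses["femur"].rotation @ _ZHAT
        return math.degrees(math.acos(np.clip(zt @ zf, -1.0, 1.0)))


def _proxy(pressures: np.ndarray, poisson: float):
    factor = (1.0 - 2.0 * poisson) / (1.0 - poisson)
    stress = factor * pressures
    return stress, int(np.argmax(stress)) if len(stress) else -1


def kinematic_metrics(model: KneeModel, state: SolverState, reference: dict | None = None) -> dict:
    """Flexion, AP tibial translation and internal tibial rotation of a pose.

    AP translation is the anteroposterior (y) offset of the tibial knee-centre
    point (the tibial mechanical-axis point at the joint line) expressed in
    the femoral epicondylar frame, anterior positive, reported relative to
    ``reference`` (typically the first recorded step) when given.  Because the
    measured point lies on the flexion axis at the reference pose, pure
    flexion produces no spurious AP offset.  Internal rotation is the rotation
    of the tibia about its long axis relative to the femur; positive internal
    (tibial tuberosity towards medial, i.e. -x).
    """
    poses = state.poses(model)
    r_f, t_f = poses["femur"].rotation, poses["femur"].translation
    center_t = poses["tibia"].transform(model.geometry.landmarks["tibial_knee_center"])
    ap = float((r_f.T @ (center_t - t_f))[1])
    r_rel = r_f.T @ poses["tibia"].rotation
    # yaw of the tibia about its own z-axis relative to the femur
    x_rel = r_rel[:, 0]
    z_rel = r_rel[:, 2]
    x_proj = x_rel - (x_rel @ z_rel) * z_rel
    x_proj /= np.linalg.norm(x_proj)
    yaw = math.degrees(math.atan2(float(np.cross(np.array([1.0, 0.0, 0.0]), x_proj) @ z_rel), float(x_proj[0])))
    out = {
        "flexion_deg": model.flexion_deg(state),
        "ap_translation_mm": ap,
        "internal_rotation_deg": yaw,
    }
    if reference is not None:
        out["ap_translation_mm"] -= reference["ap_translation_mm"]
    return out


def run_squat(
    model: KneeModel,
    schedule: SquatSchedule | None = None,
    controller=None,
    band=None,
    flexion_cap: float = DEFAULT_FLEXION_CAP,
    initial_quad_force: float = _tissue.DEFAULT_INITIAL_QUAD_FORCE,
) -> SquatTrace:
    """Run the force-controlled squat and return the per-step trace.

    Each load step passes through the GRF controller before being recorded;
    the run halts once the flexion angle exceeds ``flexion_cap`` (the
    simulation does not model quadriceps-tendon-femur wrapping, which would
    engage above ~73 degrees).  On an unrecoverable step failure the partial
    trace is returned with the failure message attached.
    """
    from . import control as _control

    schedule = schedule or SquatSchedule()
    band = band or _control.GrfBand()
    controller = controller or _control.ControllerConfig(initial_quad_force=initial_quad_force)
    trace = SquatTrace()
    state = model.initial_state(quad_force=controller.initial_quad_force)
    reference_metrics = None
    memory: dict = {}
    for i_step, drop in enumerate(schedule.drops(), start=1):
        try:
            outcome = _control.control_step(model, state, drop, band, controller, memory)
        except (StepFailureError, _control.ControllerError) as exc:
            trace.failure = f"step {i_step}: {exc}"
            break
        result = outcome.result
        state = result.state
        metrics = kinematic_metrics(model, state, reference_metrics)
        if reference_metrics is None:
            reference_metrics = dict(metrics)
            metrics["ap_translation_mm"] = 0.0
        diag = result.diagnostics
        rec = {
            "step": i_step,
            "drop_mm": drop,
            "flexion_deg": metrics["flexion_deg"],
            "grf_N": result.grf,
            "quad_force_N": outcome.quad_force,
            "total_quad_force_N": outcome.quad_force
            + sum(diag["muscle_forces"][m] for m in ("vastus_lateralis", "vastus_medialis")),
            "ap_translation_mm": metrics["ap_translation_mm"],
            "internal_rotation_deg": metrics["internal_rotation_deg"],
            "inlay_peak_pressure_MPa": diag["femorotibial"]["peak_pressure"],
            "inlay_peak_stress_MPa": diag["femorotibial"]["peak_stress"],
            "patella_peak_pressure_MPa": diag["patellofemoral"]["peak_pressure"],
            "patella_peak_stress_MPa": diag["patellofemoral"]["peak_stress"],
            "controller_restarts": outcome.n_restarts,
            "residual": result.residual,
        }
        for name in ("LCL", "MCLa", "MCLo", "MCLd", "PCLa", "PCLp", "patellar_tendon"):
            rec[f"force_{name}_N"] = diag["bundle_forces"][name]
        trace.append(rec)
        if metrics["flexion_deg"] > flexion_cap:
            trace.stopped_early = True
            break
    return trace
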