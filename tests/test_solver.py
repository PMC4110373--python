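import math

import numpy as np
import pytest

from kneesquat import geometry as G
from kneesquat.solver import (
    KneeModel,
    SolverState,
    SquatSchedule,
    kinematic_metrics,
    run_squat,
)


def closed_chain_flexion(drop, z0, lf, lt):
    """Independent oracle: three-link ankle-knee-hip closure with the hip on
    the vertical axis and equal segment tilts gives flexion = 2*acos(z/(lf+lt))."""
    return 2.0 * math.degrees(math.acos(min(1.0, (z0 - drop) / (lf + lt))))


class TestEnergyGradient:
    def test_analytic_gradient_matches_finite_differences(self, coarse_model, rng):
        state = coarse_model.initial_state()
        x0 = 0.05 * rng.standard_normal(11)
        _, g, _ = coarse_model._energy_grad(x0, state, 4.0, 35.0)
        num = np.zeros(11)
        h = 1e-6
        for j in range(11):
            xp, xm = x0.copy(), x0.copy()
            xp[j] += h
            xm[j] -= h
            ep, _, _ = coarse_model._energy_grad(xp, state, 4.0, 35.0)
            em, _, _ = coarse_model._energy_grad(xm, state, 4.0, 35.0)
            num[j] = (ep - em) / (2 * h)
        assert np.abs(num - g).max() / max(1.0, np.abs(g).max()) < 1e-6


class TestLoadStep:
    def test_converged_step_meets_residual_contract(self, coarse_model, coarse_first_step):
        assert coarse_first_step.residual < coarse_model.tol_res

    def test_force_balance_over_all_bodies(self, coarse_first_step):
        d = coarse_first_step.diagnostics
        total = d["force_on_tibia"] + d["force_on_femur"] + d["force_on_patella"]
        assert np.abs(total).max() < 1e-6

    def test_negative_quad_force_rejected(self, coarse_model):
        with pytest.raises(ValueError):
            coarse_model.solve_load_step(coarse_model.initial_state(), 0.0, -1.0)

    def test_warm_start_independence(self, rng):
        """Two different feasible warm starts converge to the same equilibrium.

        Checked frictionless: with Coulomb friction the warm-start state also
        defines the slip reference, so the equilibrium legitimately carries a
        small history dependence.
        """
        model = KneeModel.build_default(contact_spacing=2.5, mu_femorotibial=0.0, mu_patellofemoral=0.0)
        base = model.solve_load_step(model.initial_state(), 0.0, 60.0).state
        r1 = model.solve_load_step(base, 6.0, 70.0)
        perturbed = model._fold(base, 0.3 * rng.standard_normal(11), base.drop)
        r2 = model.solve_load_step(perturbed, 6.0, 70.0)
        assert np.abs(r1.state.t_patella - r2.state.t_patella).max() < 1e-4
        assert abs(r1.state.phi_femur - r2.state.phi_femur) < 1e-4 / 400.0
        assert np.abs(r1.state.r_tibia - r2.state.r_tibia).max() < 1e-4 / 400.0
        spin = np.degrees(np.arccos(np.clip((np.trace(r1.state.r_patella.T @ r2.state.r_patella) - 1) / 2, -1, 1)))
        assert abs(spin) < 1e-4

    def test_flexion_strictly_increases_with_drop(self, coarse_model):
        state = coarse_model.initial_state()
        drops = np.linspace(0.0, 120.0, 9)
        flexions = []
        for drop in drops:
            res = coarse_model.solve_load_step(state, float(drop), 80.0)
            state = res.state
            flexions.append(coarse_model.flexion_deg(state))
        assert all(b > a for a, b in zip(flexions, flexions[1:]))
        # closed-chain oracle: the rigid three-link closure predicts the trend
        p = coarse_model.geometry.params
        oracle = [closed_chain_flexion(d, coarse_model.z_hip0, p.femur_length, p.tibia_length) for d in drops]
        # contact compliance and ligament balance shift the split slightly
        assert np.abs(np.array(flexions[1:]) - np.array(oracle[1:])).max() < 4.0

    def test_grf_monotone_in_quad_force(self, coarse_model, coarse_first_step):
        grfs = [coarse_model.solve_load_step(coarse_first_step.state, 6.0, f).grf for f in (40.0, 90.0, 140.0)]
        assert grfs[0] < grfs[1] < grfs[2]


class TestSymmetry:
    def test_symmetric_model_stays_in_sagittal_plane(self):
        """Mirror-symmetric bundles and muscles at zero drop give zero
        varus/valgus and zero mediolateral patellar offset."""
        table = {
            "LCL": G.Attachment("femur", (40.0, 0.0, 6.0), "tibia", (42.0, 0.0, 332.0)),
            "MCLa": G.Attachment("femur", (-40.0, 0.0, 6.0), "tibia", (-42.0, 0.0, 332.0)),
            "MCLo": G.Attachment("femur", (38.0, -6.0, 4.0), "tibia", (40.0, -6.0, 336.0)),
            "MCLd": G.Attachment("femur", (-38.0, -6.0, 4.0), "tibia", (-40.0, -6.0, 336.0)),
            "PCLa": G.Attachment("femur", (0.0, 6.0, -10.0), "tibia", (0.0, -28.0, 356.0)),
            "PCLp": G.Attachment("femur", (0.0, 0.0, -11.0), "tibia", (0.0, -32.0, 352.0)),
            "vastus_lateralis": G.Attachment("femur", (22.0, 30.0, 160.0), "patella", (14.0, 2.0, 16.0)),
            "vastus_medialis": G.Attachment("femur", (-22.0, 30.0, 160.0), "patella", (-14.0, 2.0, 16.0)),
            "vastus_intermedius": G.Attachment("femur", (0.0, 35.0, 200.0), "patella", (0.0, 2.0, 20.0)),
            "hamstring_lateral": G.Attachment("femur", (30.0, -20.0, 180.0), "tibia", (32.0, -23.0, 336.0)),
            "hamstring_medial": G.Attachment("femur", (-30.0, -20.0, 180.0), "tibia", (-32.0, -23.0, 336.0)),
            "patellar_tendon": G.Attachment("patella", (0.0, -2.0, -20.0), "tibia", (0.0, 48.0, 330.0)),
        }
        params = G.GeometryParams(attachment_table=table)
        model = KneeModel.build_default(params=params, contact_spacing=2.5)
        # mirror the stiffnesses too: medial bundles copy their lateral twins
        import dataclasses

        model.bundles["MCLa"] = dataclasses.replace(model.bundles["MCLa"], stiffness=model.bundles["LCL"].stiffness)
        model.bundles["MCLd"] = dataclasses.replace(model.bundles["MCLd"], stiffness=model.bundles["MCLo"].stiffness)
        from kneesquat.geometry import pose_at_reference_flexion
        from kneesquat.solver import REFERENCE_FLEXION_DEG
        from kneesquat.tissue import calibrate_slack_lengths

        model.bundles = calibrate_slack_lengths(model.bundles, pose_at_reference_flexion(REFERENCE_FLEXION_DEG, params))
        res = model.solve_load_step(model.initial_state(), 0.0, 40.0)
        assert abs(res.state.psi_femur) < 1e-6
        assert abs(res.state.t_patella[0]) < 1e-6


class TestKinematicMetrics:
    def _neutral_state(self, model):
        return SolverState(
            r_tibia=np.eye(3),
            phi_femur=0.0,
            psi_femur=0.0,
            r_patella=np.eye(3),
            t_patella=np.array([0.0, 44.0, 400.0]),
            quad_force=0.0,
            drop=model.z_hip0 - 800.0,
        )

    def test_identical_poses_give_zero_relative_translation(self, coarse_model, coarse_first_step):
        m1 = kinematic_metrics(coarse_model, coarse_first_step.state)
        m2 = kinematic_metrics(coarse_model, coarse_first_step.state, reference=m1)
        assert m2["ap_translation_mm"] == pytest.approx(0.0, abs=1e-12)

    def test_pure_anterior_offset_is_reported_exactly(self, coarse_model):
        """Tilting the extended tibia so its knee-centre point moves 5 mm
        anterior reads out as +5 mm AP translation."""
        state = self._neutral_state(coarse_model)
        ref = kinematic_metrics(coarse_model, state)
        lt = coarse_model.geometry.params.tibia_length
        from kneesquat import _so3

        alpha = math.asin(5.0 / lt)
        tilted = SolverState(
            r_tibia=_so3.rotx(-alpha),
            phi_femur=0.0,
            psi_femur=0.0,
            r_patella=np.eye(3),
            t_patella=state.t_patella,
            quad_force=0.0,
            drop=state.drop,
        )
        met = kinematic_metrics(coarse_model, tilted, reference=ref)
        assert met["ap_translation_mm"] == pytest.approx(5.0, abs=1e-9)

    def test_internal_rotation_sign_convention(self, coarse_model):
        """Rotating the tibia about its long axis so the tuberosity moves
        medially (-x) reads out as positive internal rotation."""
        from kneesquat import _so3

        state = self._neutral_state(coarse_model)
        spun = SolverState(
            r_tibia=_so3.exp(np.array([0.0, 0.0, math.radians(4.0)])),
            phi_femur=0.0,
            psi_femur=0.0,
            r_patella=np.eye(3),
            t_patella=state.t_patella,
            quad_force=0.0,
            drop=state.drop,
        )
        # +z rotation moves an anterior point towards -x (medial)
        tub = spun.r_tibia @ np.array([0.0, 1.0, 0.0])
        assert tub[0] < 0
        met = kinematic_metrics(coarse_model, spun)
        assert met["internal_rotation_deg"] == pytest.approx(4.0, abs=1e-9)

    def test_pure_flexion_leaves_ap_translation_unchanged(self, coarse_model):
        """Flexing the closed chain (both segments tilt, no transverse slide at
        the joint) leaves the AP reading at zero for every flexion angle."""
        from kneesquat import _so3
        from kneesquat.geometry import hip_height, pose_at_reference_flexion

        params = coarse_model.geometry.params
        readings = []
        for flexion in (0.0, 15.0, 40.0, 70.0):
            poses = pose_at_reference_flexion(flexion, params)
            half = math.radians(flexion) / 2.0
            state = SolverState(
                r_tibia=_so3.rotx(-half),
                phi_femur=half,
                psi_femur=0.0,
                r_patella=poses["patella"].rotation,
                t_patella=poses["patella"].translation,
                quad_force=0.0,
                drop=coarse_model.z_hip0 - hip_height(poses, params),
            )
            readings.append(kinematic_metrics(coarse_model, state)["ap_translation_mm"])
        assert np.abs(np.diff(readings)).max() < 1e-9


class TestRunSquat:
    def test_single_step_zero_drop_schedule(self, coarse_model):
        trace = run_squat(coarse_model, SquatSchedule(n_steps=1, hip_drop_total=0.0))
        assert len(trace.records) == 1
        assert trace.records[0]["flexion_deg"] == pytest.approx(15.0, abs=1.0)
        assert 50.0 <= trace.records[0]["grf_N"] <= 55.0

    def test_flexion_cap_stops_after_first_exceeding_step(self, coarse_model):
        trace = run_squat(coarse_model, SquatSchedule(n_steps=12, hip_drop_total=60.0), flexion_cap=20.0)
        df = trace.to_frame()
        assert trace.stopped_early
        assert df.flexion_deg.iloc[-1] > 20.0
        assert all(df.flexion_deg.iloc[:-1] <= 20.0)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            SquatSchedule(n_steps=0)
        with pytest.raises(ValueError):
            SquatSchedule(hip_drop_total=-1.0)
        assert SquatSchedule(n_steps=1).drops().tolist() == [0.0]
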