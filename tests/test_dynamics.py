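"""Forward dynamics of the planar muscle-driven chain."""

import numpy as np
import pytest

from stairgait.contact import ContactParams, FlatGround
from stairgait.dynamics import ENERGY_STEP_BOUND, PlanarEngine, forward_step
from stairgait.model import (
    GRAVITY,
    apply_isometric_scaling,
    full_3d_model,
    load_model,
    planar_model,
    save_model,
)

CP = ContactParams()
STAND = [0.0, 0.94, 0.0, 0, 0, 0, 0, 0, 0]


class TestModelSpec:
    def test_planar_presets(self):
        stairs = planar_model("stairs")
        ramp = planar_model("ramp")
        assert stairs.trunk_pelvis_angle == -15.0
        assert ramp.trunk_pelvis_angle == -5.0
        assert stairs.isometric_scale == pytest.approx(1.8)
        assert ramp.isometric_scale == pytest.approx(1.0)
        assert len(stairs.muscles) == 14
        assert len(stairs.bodies) == 7

    def test_stairs_preset_scales_all_fmax_by_1_8(self):
        stairs = planar_model("stairs")
        ramp = planar_model("ramp")
        # same muscle table; the stair task boosts isometric force by 80%
        for ms, mr in zip(stairs.muscles, ramp.muscles):
            assert ms.params.f_max == pytest.approx(1.8 * mr.params.f_max)

    def test_isometric_scaling_op(self):
        spec = planar_model("ramp")
        base = spec.muscles[0].params.f_max
        scaled = apply_isometric_scaling(spec, 1.8)
        assert scaled.muscles[0].params.f_max == pytest.approx(1.8 * base)
        assert scaled.muscles[0].params.l_opt == spec.muscles[0].params.l_opt
        identity = apply_isometric_scaling(spec, 1.0)
        assert identity.muscles[0].params.f_max == base
        composed = apply_isometric_scaling(apply_isometric_scaling(spec, 1.2), 1.5)
        assert composed.muscles[0].params.f_max == pytest.approx(1.8 * base)
        with pytest.raises(ValueError):
            apply_isometric_scaling(spec, -1.0)

    def test_full_3d_preset_topology(self):
        spec = full_3d_model("stairs")
        assert len(spec.muscles) == 18
        assert len(spec.bodies) == 7
        # 6 free + 2x(2 hip + 1 knee + 1 ankle) = 14 degrees of freedom
        dof = 6 + sum({"pin": 1, "planar": 2}[j.kind]
                      for j in spec.joints if j.kind != "free")
        assert dof == 14

    def test_yaml_round_trip(self, tmp_path):
        spec = planar_model("stairs")
        path = tmp_path / "model.yaml"
        save_model(spec, path)
        back = load_model(path)
        assert back.trunk_pelvis_angle == spec.trunk_pelvis_angle
        assert [b.name for b in back.bodies] == [b.name for b in spec.bodies]
        for a, b in zip(spec.muscles, back.muscles):
            assert a.params == b.params
            assert a.points == b.points


class TestKinematics:
    def test_set_pose_round_trip(self, stair_engine, rng):
        gq = rng.uniform(-0.5, 0.5, 9)
        gu = rng.uniform(-1, 1, 9)
        st = stair_engine.set_pose(gq, gu)
        assert np.allclose(stair_engine.gen_coords(st), gq, atol=1e-12)
        assert np.allclose(stair_engine.gen_speeds(st), gu, atol=1e-12)

    def test_joint_constraints_satisfied_after_set_pose(self, stair_engine, rng):
        st = stair_engine.set_pose(rng.uniform(-0.5, 0.5, 9), rng.uniform(-1, 1, 9))
        J, C = stair_engine._constraint_matrices(st.q)
        assert np.max(np.abs(C)) < 1e-12          # positions coincide
        assert np.max(np.abs(J @ st.u)) < 1e-12   # velocities consistent

    def test_moment_arm_signs_at_standing(self, stair_engine):
        st = stair_engine.set_pose(STAND)
        names = [m.params.name for m in stair_engine.muscles]
        # flexors have positive, extensors negative moment arms about their
        # joints under this sign convention (hip flex +, knee flex -)
        checks = {
            "iliopsoas_l": ("hip_l", +1),
            "glut_max_l": ("hip_l", -1),
            "vasti_l": ("knee_l", +1),      # extensor: positive dL with flexion
            "bifemsh_l": ("knee_l", -1),
            "soleus_l": ("ankle_l", -1),    # plantarflexor
            "tib_ant_l": ("ankle_l", +1),
        }
        for mus, (dof, sign) in checks.items():
            arm = stair_engine.moment_arm(st, names.index(mus), dof)
            assert np.sign(arm) == sign, (mus, arm)
            assert 0.01 < abs(arm) < 0.12  # centimetre-scale anatomy


class TestForwardStep:
    def test_equilibrium_without_forces(self):
        """No gravity, no excitation, no contact, at rest: the state is
        unchanged except for time."""
        eng = PlanarEngine(planar_model("ramp"), gravity=0.0)
        st = eng.set_pose(STAND)
        new, info = eng.step(st, np.zeros(14), [], CP, 0.001)
        assert not info.terminated
        assert np.allclose(new.q, st.q, atol=1e-12)
        assert np.allclose(new.u, 0.0, atol=1e-12)
        assert new.t == pytest.approx(st.t + 0.001)

    def test_ballistic_free_fall(self, stair_engine):
        st = stair_engine.set_pose(STAND)
        dt = 0.001
        n = 200
        for _ in range(n):
            st, info = stair_engine.step(st, np.zeros(14), [], CP, dt)
        t = n * dt
        # symplectic Euler drops 0.5*g*t*(t+dt) exactly for uniform gravity
        expect = 0.5 * GRAVITY * t * (t + dt)
        assert 0.94 - st.q[1] == pytest.approx(expect, abs=1e-6)

    def test_horizontal_momentum_conserved_without_contact(self, stair_engine, rng):
        st = stair_engine.set_pose(rng.uniform(-0.4, 0.4, 9), rng.uniform(-1.5, 1.5, 9))
        p_prev = stair_engine.linear_momentum(st)[0]
        for _ in range(100):
            st, _ = stair_engine.step(st, rng.uniform(0, 1, 14), [], CP, 0.001)
            p = stair_engine.linear_momentum(st)[0]
            assert abs(p - p_prev) < 1e-8
            p_prev = p

    def test_drop_energy_non_increasing(self, stair_engine):
        """Dissipative contact, zero excitation: mechanical energy (incl.
        elastic contact energy) never rises by more than the integrator
        bound while the model is in its operating envelope."""
        ground = [FlatGround(0.0)]
        st = stair_engine.set_pose([0.0, 0.99, 0.0, 0, 0, 0, 0, 0, 0])
        y0 = st.q[1]
        e_prev = stair_engine.mechanical_energy(st, ground, CP)
        while st.q[1] > 0.6 * y0 and st.t < 2.0:
            st, info = stair_engine.step(st, np.zeros(14), ground, CP, 0.001)
            e = stair_engine.mechanical_energy(st, ground, CP)
            assert e - e_prev <= ENERGY_STEP_BOUND
            e_prev = e
            if info.terminated:
                break

    def test_drop_peak_heights_decrease(self, stair_engine):
        ground = [FlatGround(0.0)]
        st = stair_engine.set_pose([0.0, 1.00, 0.0, 0, 0, 0, 0, 0, 0])
        ys = []
        for _ in range(800):
            st, _ = stair_engine.step(st, np.zeros(14), ground, CP, 0.001)
            ys.append(st.q[1])
        ys = np.array(ys)
        peaks = [ys[i] for i in range(1, len(ys) - 1)
                 if ys[i] > ys[i - 1] and ys[i] > ys[i + 1] and ys[i] > ys[-1] + 1e-4]
        assert all(b < a for a, b in zip(peaks, peaks[1:]))

    def test_divergence_flagged_not_propagated(self, stair_engine):
        st = stair_engine.set_pose(STAND, np.full(9, 150.0))
        new, info = stair_engine.step(st, np.zeros(14), [], CP, 0.5)
        assert info.terminated
        assert info.reason == "divergence"
        assert np.all(np.isfinite(new.q))

    def test_excitation_length_checked(self, stair_engine):
        st = stair_engine.set_pose(STAND)
        with pytest.raises(ValueError, match="muscle count"):
            stair_engine.step(st, np.zeros(5), [], CP, 0.001)

    def test_forward_step_wrapper_adds_ground(self, stair_engine):
        st = stair_engine.set_pose(STAND)
        new, info = forward_step(stair_engine, st, np.zeros(14), None, CP, 0.001)
        assert not info.terminated
        assert "l" in info.grf and "r" in info.grf

    def test_activations_advanced_in_step(self, stair_engine):
        st = stair_engine.set_pose(STAND)
        new, _ = stair_engine.step(st, np.ones(14), [], CP, 0.01)
        assert np.all(new.act > 0.6)  # tau_act = 10 ms: most of the way up
        assert np.all(new.act <= 1.0)
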