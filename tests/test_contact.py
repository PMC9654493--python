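"""Elastic-foundation contact: detection, pressure law, friction, resultants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stairgait.contact import (
    ContactParams,
    ContactPoint,
    FlatGround,
    RampField,
    StairField,
    TerrainField,
    contact_forces,
    detect_contacts,
    friction_force,
    normal_pressure,
    resultant_grf,
)
from stairgait.dynamics import PlanarEngine
from stairgait.model import BodySpec, ModelSpec
from stairgait.terrain import (
    ContactSphereSpec,
    RampSpec,
    StairSpec,
    TriMesh,
    build_contact_sphere,
    build_ramp,
    build_stairs,
)

CP = ContactParams()


def _slab():
    """Flat box slab with its top face at y = 0."""
    mesh = build_stairs(StairSpec(1, 0.5, 2.0, 2.0))
    return mesh.translated((-1.0, -0.5, 0.0))


class TestDetectContacts:
    def test_sphere_above_terrain_no_contacts(self):
        sphere = build_contact_sphere(ContactSphereSpec(0.05))
        pts = detect_contacts(sphere, _slab(), position=(0, 0.1, 0))
        assert pts == []

    def test_nadir_depth_equals_lowering(self):
        sphere = build_contact_sphere(ContactSphereSpec(0.05))
        delta = 0.004
        # centre at r - delta above the surface: lowest vertex is delta deep
        pts = detect_contacts(sphere, _slab(), position=(0, 0.025 - delta, 0))
        assert pts, "expected penetrating vertices"
        deepest = max(p.depth for p in pts)
        assert deepest == pytest.approx(delta, abs=1e-9)
        for p in pts:
            assert p.normal @ np.array([0, 1, 0]) == pytest.approx(1.0)
            assert p.area == pytest.approx(4 * np.pi * 0.025**2 / 107)

    def test_depth_rate_from_velocity(self):
        sphere = build_contact_sphere(ContactSphereSpec(0.05))
        pts = detect_contacts(sphere, _slab(), position=(0, 0.02, 0),
                              linear_velocity=(0, -1.0, 0))
        assert all(p.depth_rate == pytest.approx(1.0) for p in pts)
        assert all(np.allclose(p.slip_velocity, 0.0) for p in pts)

    def test_rejects_open_terrain(self):
        slab = _slab()
        broken = TriMesh(slab.vertices, slab.faces[:-1])
        sphere = build_contact_sphere(ContactSphereSpec(0.05))
        with pytest.raises(ValueError, match="watertight"):
            detect_contacts(sphere, broken, position=(0, 0.0, 0))


class TestAnalyticFieldsMatchMeshes:
    """The fast-path stair/ramp fields agree with generic mesh queries.

    The analytic fields measure depth against the walking surfaces (treads,
    risers, incline, front face); the mesh query may find the bottom, back
    or side walls closer for deep interior points, so exact agreement is
    asserted only where the walking surface is the nearest one, plus the
    one-sided inequality everywhere.
    """

    def _compare(self, mesh, field, pts, wall_clearance):
        from stairgait.contact import _segment_distances

        in_m, d_m, n_m = mesh.query(pts)
        in_f, d_f, n_f = field.query(pts)
        assert np.array_equal(in_m, in_f)
        assert np.all(d_m <= d_f + 1e-9)
        near = in_m & (d_f < wall_clearance)
        assert near.sum() > 20, "sample did not cover near-surface points"
        assert np.allclose(d_m[near], d_f[near], atol=1e-9)
        # normals are compared only away from corner ties, where the nearest
        # surface feature (and hence the face normal) is unambiguous
        segs = field._segs if hasattr(field, "_segs") else field._seg
        dists, _ = _segment_distances(pts[:, 0] - field.origin[0],
                                      pts[:, 1] - field.origin[1], segs)
        dists = np.sort(dists, axis=1)
        untied = near if dists.shape[1] == 1 else near & (dists[:, 1] - dists[:, 0] > 1e-9)
        assert np.allclose(n_m[untied], n_f[untied], atol=1e-9)

    def test_stairs(self, rng):
        spec = StairSpec()
        mesh = TerrainField(build_stairs(spec))
        field = StairField(spec)
        pts = rng.uniform([-0.1, -0.05, -1.2], [0.85, 0.7, 1.2], size=(500, 3))
        clearance = np.minimum.reduce([
            pts[:, 1],                                      # bottom face
            spec.width / 2 - np.abs(pts[:, 2]),             # side walls
            spec.n_steps * spec.step_depth - pts[:, 0],     # back face
        ])
        self._compare(mesh, field, pts, clearance)

    def test_ramp(self, rng):
        spec = RampSpec()
        mesh = TerrainField(build_ramp(spec))
        field = RampField(spec)
        pts = rng.uniform([-0.1, -0.05, -1.2], [3.4, 0.5, 1.2], size=(500, 3))
        clearance = np.minimum.reduce([
            pts[:, 1],
            spec.width / 2 - np.abs(pts[:, 2]),
            spec.run - pts[:, 0],
        ])
        self._compare(mesh, field, pts, clearance)


class TestNormalPressure:
    def test_zero_depth_zero_pressure(self):
        assert normal_pressure(0.0, 5.0, CP) == 0.0
        assert normal_pressure(0.0, -5.0, CP) == 0.0

    def test_linear_in_depth_at_rest(self):
        # 50 MPa/m * 1 mm = 50 kPa
        assert normal_pressure(0.001, 0.0, CP) == pytest.approx(50e3)
        assert normal_pressure(0.002, 0.0, CP) == pytest.approx(100e3)

    def test_clamped_at_dissipation_boundary(self):
        # xdot = -1/c makes the multiplicative factor zero
        assert normal_pressure(0.01, -1.0 / CP.dissipation, CP) == 0.0
        assert normal_pressure(0.01, -1.0, CP) == 0.0

    def test_rejects_negative_depth(self):
        with pytest.raises(ValueError):
            normal_pressure(-0.001, 0.0, CP)


class TestFrictionForce:
    def test_zero_normal_force(self):
        assert np.allclose(friction_force(0.0, [1.0, 0, 0], CP), 0.0)

    def test_zero_at_rest(self):
        assert np.allclose(friction_force(100.0, [0.0, 0.0, 0.0], CP), 0.0)

    def test_coulomb_limit_at_high_slip(self):
        v = np.array([50.0, 0.0, 0.0])  # >> transition velocity
        f = friction_force(100.0, v, CP)
        coulomb = -CP.mu_dynamic * 100.0
        viscous = -CP.mu_viscous * (50.0 / CP.transition_velocity) * 100.0
        assert f[0] == pytest.approx(coulomb + viscous, rel=1e-3)

    @given(st.floats(0.0, 500.0), st.floats(-3, 3), st.floats(-3, 3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_opposes_slip_and_bounded(self, n, vx, vz):
        v = np.array([vx, 0.0, vz])
        f = friction_force(n, v, CP)
        speed = np.linalg.norm(v)
        if speed > 0 and n > 0:
            assert f @ v <= 0.0
            bound = (CP.mu_static + CP.mu_viscous * speed / CP.transition_velocity) * n
            assert np.linalg.norm(f) <= bound * (1 + 1e-9)

    def test_zero_coefficients_zero_force(self):
        params = ContactParams(mu_static=0.0, mu_dynamic=0.0, mu_viscous=0.0)
        assert np.allclose(friction_force(500.0, [2.0, 0, 1.0], params), 0.0)


class TestResultantGRF:
    def _point(self, pos):
        return ContactPoint(np.asarray(pos, float), np.array([0.0, 1.0, 0.0]),
                            0.001, 0.0, 1e-4, np.zeros(3))

    def test_single_point(self):
        p = self._point([0.3, 0.0, 0.1])
        res = resultant_grf([p], [np.array([0.0, 10.0, 0.0])])
        assert res.defined
        assert np.allclose(res.cop, p.position)
        assert np.allclose(res.force, [0, 10, 0])

    def test_two_equal_forces_midpoint(self):
        pts = [self._point([0, 0, 0]), self._point([1, 0, 0])]
        fs = [np.array([0.0, 5.0, 0.0])] * 2
        res = resultant_grf(pts, fs)
        assert np.allclose(res.cop, [0.5, 0, 0])

    def test_empty_flagged_undefined(self):
        res = resultant_grf([], [])
        assert not res.defined
        assert np.allclose(res.force, 0.0)

    def test_moment_about_cop_vanishes(self, rng):
        pts = [self._point(rng.uniform(-1, 1, 3) * [1, 0, 1]) for _ in range(20)]
        fs = [np.array([0.0, float(rng.uniform(0.1, 30)), 0.0]) for _ in pts]
        res = resultant_grf(pts, fs)
        moment = np.zeros(3)
        for p, f in zip(pts, fs):
            moment += np.cross(p.position - res.cop, f)
        assert np.linalg.norm(moment) < 1e-9


class TestSettleAndRestitution:
    def _single_foot_engine(self):
        spec = ModelSpec(bodies=[BodySpec("foot_l", 1.25, 0.005, 0.2)],
                         joints=[], muscles=[])
        return PlanarEngine(spec)

    def test_static_force_balance_within_one_percent(self):
        eng = self._single_foot_engine()
        ground = [FlatGround(0.0)]
        st = eng.set_pose([0, 0.06, 0] + [0] * 6)
        for _ in range(3000):
            st, info = eng.step(st, np.zeros(0), ground, CP, 0.001)
        weight = 1.25 * 9.80665
        fy = info.grf["l"][0][1]
        assert abs(fy - weight) / weight < 0.01
        assert abs(st.u).max() < 1e-3  # at rest

    def test_rebound_peaks_strictly_decreasing(self):
        eng = self._single_foot_engine()
        ground = [FlatGround(0.0)]
        st = eng.set_pose([0, 0.12, 0] + [0] * 6)
        ys = []
        for _ in range(3000):
            st, _ = eng.step(st, np.zeros(0), ground, CP, 0.001)
            ys.append(st.q[1])
        ys = np.array(ys)
        peaks = [ys[i] for i in range(1, len(ys) - 1)
                 if ys[i] > ys[i - 1] and ys[i] > ys[i + 1]]
        # genuine rebound apexes (above the settled height) decay strictly
        rest = ys[-1]
        bounces = [p for p in peaks if p > rest + 1e-4]
        assert len(bounces) >= 2
        assert all(b2 < b1 for b1, b2 in zip(bounces, bounces[1:]))

    def test_elastic_bounce_energy_drift_bounded_and_first_order(self):
        """With zero dissipation and friction the bouncing energy drift is
        bounded (no blow-up) and shrinks roughly linearly with the step."""
        eng = self._single_foot_engine()
        ground = [FlatGround(0.0)]
        params = ContactParams(dissipation=0.0, mu_static=0.0,
                               mu_dynamic=0.0, mu_viscous=0.0)
        drifts = {}
        for dt in (5e-4, 2.5e-4):
            st = eng.set_pose([0, 0.12, 0] + [0] * 6)
            e0 = eng.mechanical_energy(st, ground, params)
            worst = 0.0
            for _ in range(int(2.0 / dt)):
                st, _ = eng.step(st, np.zeros(0), ground, params, dt)
                worst = max(worst, abs(eng.mechanical_energy(st, ground, params) - e0))
            drifts[dt] = worst / e0
        assert drifts[5e-4] < 0.15
        assert drifts[2.5e-4] < 0.75 * drifts[5e-4]

    def test_contact_force_continuity_at_initiation(self):
        """First-contact force stays within one stiffness*penetration step."""
        eng = self._single_foot_engine()
        ground = [FlatGround(0.0)]
        st = eng.set_pose([0, 0.032, 0] + [0] * 6)  # 2 mm above touch
        dt = 0.001
        prev_fy = 0.0
        while True:
            st, info = eng.step(st, np.zeros(0), ground, CP, dt)
            fy = info.grf["l"][0][1]
            if fy > 0:
                v_impact = abs(st.u[1])
                area = 4 * np.pi * 0.025**2 / 107
                # generous per-vertex count bound at first touch
                bound = CP.stiffness * (1 + CP.dissipation * v_impact) \
                    * (v_impact * dt) * area * 107
                assert fy - prev_fy < bound
                break
            prev_fy = fy
            assert st.t < 0.5, "never touched down"


class TestContactForcesHelper:
    def test_matches_pressure_times_area(self):
        p = ContactPoint(np.zeros(3), np.array([0.0, 1.0, 0.0]), 0.001, 0.0,
                         2e-4, np.zeros(3))
        f = contact_forces([p], CP)
        assert f.shape == (1, 3)
        assert f[0, 1] == pytest.approx(50e6 * 0.001 * 2e-4)
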