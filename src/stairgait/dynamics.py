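"""Planar forward dynamics of the muscle-driven biped.

The engine integrates the seven segments in maximal planar coordinates
(x, y, theta per body) and enforces the six pin joints with constraint
impulses solved exactly each step (a 12x12 linear system).  This redundant
formulation was chosen over minimal joint coordinates because every internal
force — joint constraint impulses, muscle path tension pairs, joint-limit
torque pairs — then cancels pairwise by construction, so the total linear
momentum of the chain is conserved to machine precision in the absence of
external forces, and no Coriolis bookkeeping can break that.

Integration is semi-implicit (symplectic) Euler: forces are evaluated at the
current state, velocities updated, joint impulses applied, then positions
advanced with the new velocities.  Joint drift is removed by Baumgarte
stabilization at the velocity level.  Contact damping terms (the
Hunt-Crossley dissipation factor and the viscous/low-speed friction) are
explicit but impulse-clamped so a damping force can at most cancel the
relative motion it opposes within one step; without the clamp the default
elastic-foundation coefficients would make the explicit update unstable at
practical step sizes.

The default physics step is 1 ms: the contact stiffness (50 MPa/m) acting on
the light foot segments makes 5 ms unstable and 2 ms marginal, while at 1 ms
drop tests show no measurable per-step energy injection.  Excitations are
held across a control interval of 10 ms by the environment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .contact import ContactParams, FlatGround
from .model import (
    GRAVITY,
    ModelSpec,
    ModelState,
    PLANAR_DOF_NAMES,
    CALCN_IN_FOOT,
    TOES_IN_FOOT,
)
from .muscles import (
    FL_GAMMA,
    FV_ECCENTRIC_MAX,
    FV_SHORTENING_A,
    PE_K,
    PE_STRAIN,
)
from .terrain import ContactSphereSpec, build_contact_sphere, foot_geometry

__all__ = ["PlanarEngine", "StepInfo", "forward_step"]

# joint-limit spring/damper and passive joint damping
LIMIT_STIFFNESS = 300.0   # N m / rad
LIMIT_DAMPING = 2.0       # N m s / rad
JOINT_DAMPING = 0.10      # N m s / rad, passive viscous term inside the range
BAUMGARTE = 0.2           # fraction of position error removed per step
DIVERGENCE_SPEED = 200.0  # m/s or rad/s; beyond this the step is flagged
DEFAULT_PHYSICS_DT = 0.001  # s; see module docstring on contact stiffness
#: documented integrator bound on the per-step mechanical energy increase in
#: the operating envelope (feet-first contact, pre-fall), at the default step
ENERGY_STEP_BOUND = 0.01  # J

_FOOT_Z = {"l": -0.09, "r": 0.09}


def _rot2(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass
class StepInfo:
    """Diagnostics of one physics step."""

    terminated: bool = False
    reason: str = ""
    grf: dict = field(default_factory=dict)        # side -> (force (3,), cop or None)
    muscle_forces: np.ndarray = None
    limit_torques: np.ndarray = None


@dataclass
class _Sphere:
    body: int
    center: np.ndarray       # (3,) local in the foot frame
    verts: np.ndarray        # (n, 3) local, relative to the centre
    radius: float
    area: float              # tributary area per vertex
    side: str


class PlanarEngine:
    """Compiled planar model ready for forward integration."""

    def __init__(self, spec: ModelSpec, gravity: float = GRAVITY):
        self.spec = spec
        self.gravity = gravity
        self.body_names = [b.name for b in spec.bodies]
        self.n_bodies = len(spec.bodies)
        self.mass = np.array([b.mass for b in spec.bodies])
        self.inertia = np.array([b.inertia for b in spec.bodies])
        # diagonal maximal mass matrix (x, y, theta per body)
        self.m_diag = np.repeat(self.mass, 3)
        self.m_diag[2::3] = self.inertia

        self.pins = []  # (parent_idx, child_idx, p_anchor, c_anchor, q_min, q_max, name)
        for j in spec.joints:
            if j.kind == "free":
                continue
            self.pins.append(
                (
                    spec.body_index(j.parent),
                    spec.body_index(j.child),
                    np.asarray(j.parent_point, dtype=float),
                    np.asarray(j.child_point, dtype=float),
                    j.q_min,
                    j.q_max,
                    j.name,
                )
            )
        self.n_pins = len(self.pins)

        self.muscles = spec.muscles
        self._mus_bodies = [
            [spec.body_index(b) for b, _ in m.points] for m in spec.muscles
        ]
        self._mus_points = [
            [np.asarray(p[:2], dtype=float) for _, p in m.points] for m in spec.muscles
        ]
        # flattened path-point and segment index arrays for vectorized assembly
        pt_body, pt_local, seg_a, seg_b, seg_mus = [], [], [], [], []
        for mi, (bodies, locals_) in enumerate(zip(self._mus_bodies, self._mus_points)):
            start = len(pt_body)
            pt_body.extend(bodies)
            pt_local.extend(locals_)
            for k in range(len(bodies) - 1):
                seg_a.append(start + k)
                seg_b.append(start + k + 1)
                seg_mus.append(mi)
        self._pt_body = np.array(pt_body, dtype=int)
        self._pt_local = np.array(pt_local, dtype=float).reshape(-1, 2)
        self._seg_a = np.array(seg_a, dtype=int)
        self._seg_b = np.array(seg_b, dtype=int)
        self._seg_mus = np.array(seg_mus, dtype=int)
        self._p_fmax = np.array([m.params.f_max for m in spec.muscles])
        self._p_lopt = np.array([m.params.l_opt for m in spec.muscles])
        self._p_lslack = np.array([m.params.l_slack for m in spec.muscles])
        self._p_vmax = np.array([m.params.v_max for m in spec.muscles])
        self._p_cospenn = np.cos([m.params.penn for m in spec.muscles])
        self._tau_act = np.array([m.params.tau_act for m in spec.muscles])
        self._tau_deact = np.array([m.params.tau_deact for m in spec.muscles])

        self.spheres: list[_Sphere] = []
        frame_offsets = {"calcn": CALCN_IN_FOOT, "toes": TOES_IN_FOOT}
        mesh_cache: dict[float, np.ndarray] = {}
        body_names = set(self.body_names)
        for side in ("l", "r"):
            if f"foot_{side}" not in body_names:
                continue
            foot_idx = spec.body_index(f"foot_{side}")
            for placed in foot_geometry("left" if side == "l" else "right"):
                seg = placed.body.rsplit("_", 1)[0]
                off2 = np.asarray(frame_offsets[seg], dtype=float)
                c = placed.spec.center_offset
                center = np.array([off2[0] + c[0], off2[1] + c[1], c[2] + _FOOT_Z[side]])
                d = placed.spec.diameter
                if d not in mesh_cache:
                    mesh = build_contact_sphere(ContactSphereSpec(d))
                    mesh_cache[d] = mesh.vertices  # centred at the origin
                verts = mesh_cache[d]
                r = d / 2.0
                self.spheres.append(
                    _Sphere(foot_idx, center, verts, r, 4 * np.pi * r**2 / len(verts), side)
                )
        # concatenated contact vertex arrays for the vectorized fast path
        cv_local, cv_body, cv_area, cv_side = [], [], [], []
        for sp in self.spheres:
            pts = sp.verts + sp.center
            cv_local.append(pts)
            cv_body.extend([sp.body] * len(pts))
            cv_area.extend([sp.area] * len(pts))
            cv_side.extend([0 if sp.side == "l" else 1] * len(pts))
        self._cv_local = np.vstack(cv_local) if cv_local else np.zeros((0, 3))
        self._cv_body = np.array(cv_body, dtype=int)
        self._cv_area = np.array(cv_area, dtype=float)
        self._cv_side = np.array(cv_side, dtype=int)

    # -- pose helpers ------------------------------------------------------

    def set_pose(self, gen_q, gen_u=None, activations=None, t: float = 0.0) -> ModelState:
        """Assemble a maximal-coordinate state from generalized coordinates.

        ``gen_q``/``gen_u`` follow :data:`PLANAR_DOF_NAMES` ordering
        (pelvis x, y, rotation, then hip/knee/ankle per leg).
        """
        gq = np.asarray(gen_q, dtype=float)
        gu = np.zeros(9) if gen_u is None else np.asarray(gen_u, dtype=float)
        q = np.zeros(3 * self.n_bodies)
        u = np.zeros(3 * self.n_bodies)
        q[0:2], q[2] = gq[0:2], gq[2]
        u[0:2], u[2] = gu[0:2], gu[2]
        # chain order: the pins are listed hip, knee, ankle per leg
        gi = 3
        for p, c, pa, ca, *_ in self.pins:
            th_p, w_p = q[3 * p + 2], u[3 * p + 2]
            th_c = th_p + gq[gi]
            w_c = w_p + gu[gi]
            Rp, Rc = _rot2(th_p), _rot2(th_c)
            anchor = q[3 * p : 3 * p + 2] + Rp @ pa
            q[3 * c : 3 * c + 2] = anchor - Rc @ ca
            # velocity of the anchor point, then transfer to the child COM
            rp = Rp @ pa
            v_anchor = u[3 * p : 3 * p + 2] + w_p * np.array([-rp[1], rp[0]])
            rc = Rc @ ca
            u[3 * c : 3 * c + 2] = v_anchor - w_c * np.array([-rc[1], rc[0]])
            q[3 * c + 2], u[3 * c + 2] = th_c, w_c
            gi += 1
        act = np.zeros(len(self.muscles)) if activations is None else np.asarray(activations, float)
        return ModelState(q, u, act, t)

    def gen_coords(self, state: ModelState) -> np.ndarray:
        """Generalized-coordinate view (PLANAR_DOF_NAMES order) of the state."""
        q = state.q
        out = np.empty(9)
        out[0:3] = q[0:3]
        for gi, (p, c, *_rest) in enumerate(self.pins, start=3):
            out[gi] = q[3 * c + 2] - q[3 * p + 2]
        return out

    def gen_speeds(self, state: ModelState) -> np.ndarray:
        u = state.u
        out = np.empty(9)
        out[0:3] = u[0:3]
        for gi, (p, c, *_rest) in enumerate(self.pins, start=3):
            out[gi] = u[3 * c + 2] - u[3 * p + 2]
        return out

    def body_pose(self, state: ModelState, idx: int):
        return state.q[3 * idx : 3 * idx + 2], state.q[3 * idx + 2]

    # -- force assembly ----------------------------------------------------

    def _muscle_forces(self, state: ModelState, F: np.ndarray):
        """Apply muscle path tensions; returns per-muscle fiber forces (N).

        Fully vectorized over the flattened path points/segments; the force
        law is the same rigid-tendon Hill model as
        :func:`stairgait.muscles.muscle_force`.
        """
        q, u = state.q, state.u
        th = q[2::3]
        cth, sth = np.cos(th), np.sin(th)
        b = self._pt_body
        lx, ly = self._pt_local[:, 0], self._pt_local[:, 1]
        rx = cth[b] * lx - sth[b] * ly
        ry = sth[b] * lx + cth[b] * ly
        px = q[3 * b] + rx
        py = q[3 * b + 1] + ry
        w = u[2::3][b]
        vx = u[3 * b] - w * ry
        vy = u[3 * b + 1] + w * rx

        a, bb = self._seg_a, self._seg_b
        dx, dy = px[bb] - px[a], py[bb] - py[a]
        seg_len = np.hypot(dx, dy)
        safe = np.maximum(seg_len, 1e-12)
        ux, uy = dx / safe, dy / safe
        seg_ldot = ux * (vx[bb] - vx[a]) + uy * (vy[bb] - vy[a])

        n_mus = len(self.muscles)
        length = np.zeros(n_mus)
        ldot = np.zeros(n_mus)
        np.add.at(length, self._seg_mus, seg_len)
        np.add.at(ldot, self._seg_mus, seg_ldot)

        # rigid-tendon Hill force (vectorized curve evaluation)
        fiber = np.maximum(length - self._p_lslack, 1e-4)
        l_n = fiber / self._p_lopt
        v_n = ldot / (self._p_lopt * self._p_vmax)
        fl = np.exp(-((l_n - 1.0) ** 2) / FL_GAMMA)
        fv_short = np.clip(1.0 + v_n, 0.0, None) / (1.0 - np.minimum(v_n, 0.0) / FV_SHORTENING_A)
        gain = FV_ECCENTRIC_MAX - 1.0
        bfv = gain / (1.0 + 1.0 / FV_SHORTENING_A)
        vp = np.maximum(v_n, 0.0)
        fv = np.where(v_n < 0.0, fv_short, 1.0 + gain * vp / (vp + bfv))
        fp = np.expm1(PE_K * np.maximum(l_n - 1.0, 0.0) / PE_STRAIN) / np.expm1(PE_K)
        forces = np.maximum(
            self._p_fmax * (state.act * fl * fv + fp) * self._p_cospenn, 0.0
        )

        # point force = tension * (u_hat_next - u_hat_prev)
        T = forces[self._seg_mus]
        fpx = np.zeros(len(b))
        fpy = np.zeros(len(b))
        np.add.at(fpx, a, T * ux)
        np.add.at(fpy, a, T * uy)
        np.add.at(fpx, bb, -T * ux)
        np.add.at(fpy, bb, -T * uy)
        np.add.at(F, 3 * b, fpx)
        np.add.at(F, 3 * b + 1, fpy)
        np.add.at(F, 3 * b + 2, rx * fpy - ry * fpx)
        return forces

    def _limit_torques(self, state: ModelState, F: np.ndarray) -> np.ndarray:
        """Soft joint-limit springs plus passive viscous joint damping."""
        q, u = state.q, state.u
        out = np.zeros(self.n_pins)
        for i, (p, c, _pa, _ca, lo, hi, _name) in enumerate(self.pins):
            ang = q[3 * c + 2] - q[3 * p + 2]
            rate = u[3 * c + 2] - u[3 * p + 2]
            tau = -JOINT_DAMPING * rate
            if ang > hi:
                tau += -LIMIT_STIFFNESS * (ang - hi) - LIMIT_DAMPING * rate
            elif ang < lo:
                tau += -LIMIT_STIFFNESS * (ang - lo) - LIMIT_DAMPING * rate
            out[i] = tau
            F[3 * c + 2] += tau
            F[3 * p + 2] -= tau
        return out

    def _contact_forces(self, state: ModelState, surfaces, params: ContactParams,
                        F: np.ndarray, dt: float):
        """Vectorized elastic-foundation contact for all foot spheres.

        Damping contributions (dissipation factor and friction at low slip)
        are clamped so they cannot reverse the motion they oppose within one
        step (explicit-integration guard).
        """
        q, u = state.q, state.u
        th = q[2::3]
        cth, sth = np.cos(th), np.sin(th)
        b = self._cv_body
        loc = self._cv_local
        px = q[3 * b] + cth[b] * loc[:, 0] - sth[b] * loc[:, 1]
        py = q[3 * b + 1] + sth[b] * loc[:, 0] + cth[b] * loc[:, 1]
        pts = np.column_stack([px, py, loc[:, 2]])

        grf_f = np.zeros((2, 3))
        grf_w = np.zeros(2)
        grf_cop = np.zeros((2, 3))
        for surf in surfaces:
            inside, depth, normal = surf.query(pts)
            idx = np.nonzero(inside)[0]
            if len(idx) == 0:
                continue
            bi = b[idx]
            pw = pts[idx]
            nrm = normal[idx]
            dep = depth[idx]
            rx = pw[:, 0] - q[3 * bi]
            ry = pw[:, 1] - q[3 * bi + 1]
            w = u[2::3][bi]
            vpx = u[3 * bi] - w * ry
            vpy = u[3 * bi + 1] + w * rx
            vdotn = vpx * nrm[:, 0] + vpy * nrm[:, 1]
            rate = -vdotn
            # per-point effective mass at the contact (normal direction),
            # shared among the body's contacts this step
            r_perp = rx * nrm[:, 1] - ry * nrm[:, 0]
            m_pt = 1.0 / (1.0 / self.mass[bi] + r_perp**2 / self.inertia[bi])
            counts = np.bincount(bi, minlength=self.n_bodies)[bi]
            m_eff = m_pt / counts
            # elastic pressure plus impulse-clamped multiplicative dissipation:
            # the dissipative extra force may at most cancel the approach
            # velocity within the step (explicit-integration guard)
            f_el = params.stiffness * dep * self._cv_area[idx]
            f_damp = f_el * params.dissipation * rate
            damp_hi = 0.9 * m_eff * np.maximum(rate, 0.0) / dt
            fn = f_el + np.clip(f_damp, -f_el, damp_hi)
            # friction on the tangential slip (planar components)
            tx = vpx - vdotn * nrm[:, 0]
            ty = vpy - vdotn * nrm[:, 1]
            speed = np.hypot(tx, ty)
            s = speed / params.transition_velocity
            mu_c = np.minimum(s, 1.0) * (
                params.mu_dynamic
                + 2.0 * (params.mu_static - params.mu_dynamic) / (1.0 + s * s)
            )
            ft_mag = (mu_c + params.mu_viscous * s) * fn
            # same guard: friction may at most cancel the slip it opposes
            ft_mag = np.minimum(ft_mag, 0.9 * m_eff * speed / dt)
            with np.errstate(invalid="ignore", divide="ignore"):
                scale = np.where(speed > 1e-12, ft_mag / speed, 0.0)
            fx = fn * nrm[:, 0] - scale * tx
            fy = fn * nrm[:, 1] - scale * ty
            np.add.at(F, 3 * bi, fx)
            np.add.at(F, 3 * bi + 1, fy)
            np.add.at(F, 3 * bi + 2, rx * fy - ry * fx)
            side = self._cv_side[idx]
            np.add.at(grf_f[:, 0], side, fx)
            np.add.at(grf_f[:, 1], side, fy)
            np.add.at(grf_w, side, fn)
            np.add.at(grf_cop, side, fn[:, None] * pw)
        grf = {}
        for si, name in enumerate(("l", "r")):
            cop = grf_cop[si] / grf_w[si] if grf_w[si] > 0 else None
            grf[name] = (grf_f[si], cop)
        return grf

    # -- constraint solve --------------------------------------------------

    def _constraint_matrices(self, q: np.ndarray):
        nb3 = 3 * self.n_bodies
        J = np.zeros((2 * self.n_pins, nb3))
        C = np.zeros(2 * self.n_pins)
        for i, (p, c, pa, ca, *_rest) in enumerate(self.pins):
            Rp, Rc = _rot2(q[3 * p + 2]), _rot2(q[3 * c + 2])
            rp, rc = Rp @ pa, Rc @ ca
            row = 2 * i
            # (v_c + w_c x r_c) - (v_p + w_p x r_p) = 0
            J[row, 3 * c] = 1.0
            J[row, 3 * c + 2] = -rc[1]
            J[row, 3 * p] = -1.0
            J[row, 3 * p + 2] = rp[1]
            J[row + 1, 3 * c + 1] = 1.0
            J[row + 1, 3 * c + 2] = rc[0]
            J[row + 1, 3 * p + 1] = -1.0
            J[row + 1, 3 * p + 2] = -rp[0]
            err = (q[3 * c : 3 * c + 2] + rc) - (q[3 * p : 3 * p + 2] + rp)
            C[row : row + 2] = err
        return J, C

    # -- main step ---------------------------------------------------------

    def step(self, state: ModelState, excitations, surfaces, params: ContactParams,
             dt: float):
        """Advance one physics step; returns (new_state, StepInfo).

        ``surfaces`` is a sequence of contact query objects (terrain fields,
        flat ground); pass ``[]`` for contact-free dynamics.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        exc = np.clip(np.asarray(excitations, dtype=float), 0.0, 1.0)
        if exc.shape != state.act.shape:
            raise ValueError("excitation vector length must match the muscle count")

        # activation dynamics (exact exponential update, vectorized)
        tau = np.where(exc > state.act, self._tau_act, self._tau_deact)
        act = np.clip(exc + (state.act - exc) * np.exp(-dt / tau), 0.0, 1.0)
        work = state.copy()
        work.act = act

        F = np.zeros(3 * self.n_bodies)
        F[1::3] -= self.mass * self.gravity
        mus_f = self._muscle_forces(work, F)
        lim_t = self._limit_torques(work, F)
        grf = self._contact_forces(work, surfaces, params, F, dt) if surfaces else {}

        v_free = state.u + dt * F / self.m_diag
        if self.n_pins:
            J, C = self._constraint_matrices(state.q)
            Minv_Jt = J.T / self.m_diag[:, None]
            S = J @ Minv_Jt
            rhs = -(J @ v_free) - (BAUMGARTE / dt) * C
            lam = np.linalg.solve(S + 1e-12 * np.eye(len(S)), rhs)
            u_new = v_free + Minv_Jt @ lam
        else:
            u_new = v_free
        q_new = state.q + dt * u_new

        info = StepInfo(grf=grf, muscle_forces=mus_f, limit_torques=lim_t)
        if not (np.all(np.isfinite(q_new)) and np.all(np.isfinite(u_new))):
            info.terminated, info.reason = True, "divergence"
            return state.copy(), info
        if np.max(np.abs(u_new)) > DIVERGENCE_SPEED:
            info.terminated, info.reason = True, "divergence"
            return state.copy(), info

        new = ModelState(q_new, u_new, act, state.t + dt,
                         udot=(u_new - state.u) / dt, muscle_forces=mus_f)
        return new, info

    # -- energetics --------------------------------------------------------

    def mechanical_energy(self, state: ModelState, surfaces=(), params: ContactParams = None) -> float:
        """Kinetic + gravitational + elastic contact energy (J)."""
        u, q = state.u, state.q
        ke = 0.5 * float(np.sum(self.m_diag * u * u))
        pe = float(np.sum(self.mass * self.gravity * q[1::3]))
        ee = 0.0
        if surfaces and params is not None:
            for sp in self.spheres:
                b = sp.body
                th = q[3 * b + 2]
                c2, s2 = math.cos(th), math.sin(th)
                com = q[3 * b : 3 * b + 2]
                cx = com[0] + c2 * sp.center[0] - s2 * sp.center[1]
                cy = com[1] + s2 * sp.center[0] + c2 * sp.center[1]
                vx = cx + c2 * sp.verts[:, 0] - s2 * sp.verts[:, 1]
                vy = cy + s2 * sp.verts[:, 0] + c2 * sp.verts[:, 1]
                vz = sp.center[2] + sp.verts[:, 2]
                pts = np.column_stack([vx, vy, vz])
                for surf in surfaces:
                    _inside, depth, _n = surf.query(pts)
                    ee += 0.5 * params.stiffness * sp.area * float(np.sum(depth**2))
        return ke + pe + ee

    def linear_momentum(self, state: ModelState) -> np.ndarray:
        vx = state.u[0::3]
        vy = state.u[1::3]
        return np.array([float(np.sum(self.mass * vx)), float(np.sum(self.mass * vy))])

    def moment_arm(self, state: ModelState, muscle_idx: int, dof: str, eps: float = 1e-6) -> float:
        """Moment arm (m) of a muscle about a generalized coordinate, from the
        path-length Jacobian -dL/dq (central difference)."""
        di = PLANAR_DOF_NAMES.index(dof)
        gq = self.gen_coords(state)

        def path_len(gen_q):
            st = self.set_pose(gen_q)
            pts = []
            for b, lp in zip(self._mus_bodies[muscle_idx], self._mus_points[muscle_idx]):
                R = _rot2(st.q[3 * b + 2])
                pts.append(st.q[3 * b : 3 * b + 2] + R @ lp)
            return sum(float(np.linalg.norm(b_ - a_)) for a_, b_ in zip(pts[:-1], pts[1:]))

        qp, qm = gq.copy(), gq.copy()
        qp[di] += eps
        qm[di] -= eps
        return -(path_len(qp) - path_len(qm)) / (2 * eps)


def forward_step(engine: PlanarEngine, state: ModelState, excitations, terrain,
                 contact: ContactParams, dt: float):
    """One forward-dynamics step against a terrain (plus implicit flat ground).

    ``terrain`` may be None (flat ground only), a single surface, or a
    sequence of surfaces.  Returns ``(new_state, StepInfo)``; a non-finite or
    diverging update is flagged in ``StepInfo.terminated`` rather than
    propagated.
    """
    if terrain is None:
        surfaces = [FlatGround(0.0)]
    elif isinstance(terrain, (list, tuple)):
        surfaces = list(terrain)
    else:
        surfaces = [FlatGround(0.0), terrain]
    return engine.step(state, excitations, surfaces, contact, dt)
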