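"""Elastic-foundation foot-terrain contact with friction.

The terrain is treated as a bed of independent springs sampled at the
vertices of the foot-contact spheres: each sphere vertex that penetrates the
terrain contributes a pressure

    p = k * x * (1 + c * xdot),   clamped at 0,

where ``x`` is the penetration depth along the local terrain face normal,
``xdot`` the penetration rate, ``k`` the stiffness (Pa per metre of
penetration) and ``c`` the dissipation (s/m) applied multiplicatively
(Hunt-Crossley style).  The per-point normal force is pressure times the
tributary area (sphere surface area / vertex count).  Friction opposes the
tangential slip velocity with a Stribeck-style blend from static to dynamic
Coulomb friction across the transition velocity, plus a viscous term.

Default coefficients (shoe rubber on rigid terrain): stiffness 50 MPa/m,
dissipation 5 s/m, static/dynamic/viscous friction 0.9, transition velocity
0.1 m/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .terrain import RampSpec, StairSpec, TriMesh, validate_mesh

__all__ = [
    "ContactParams",
    "ContactPoint",
    "TerrainField",
    "FlatGround",
    "StairField",
    "RampField",
    "detect_contacts",
    "normal_pressure",
    "friction_force",
    "resultant_grf",
]


@dataclass(frozen=True)
class ContactParams:
    """Elastic-foundation coefficients.  ``stiffness`` is in Pa/m (50 MPa/m default)."""

    stiffness: float = 50e6
    dissipation: float = 5.0
    mu_static: float = 0.9
    mu_dynamic: float = 0.9
    mu_viscous: float = 0.9
    transition_velocity: float = 0.1

    def __post_init__(self) -> None:
        if self.stiffness <= 0 or self.transition_velocity <= 0:
            raise ValueError("stiffness and transition_velocity must be positive")
        if min(self.dissipation, self.mu_static, self.mu_dynamic, self.mu_viscous) < 0:
            raise ValueError("dissipation and friction coefficients must be >= 0")


@dataclass
class ContactPoint:
    """One penetrating sphere vertex: geometry plus kinematics."""

    position: np.ndarray      # world, m
    normal: np.ndarray        # outward terrain unit normal
    depth: float              # m, >= 0
    depth_rate: float         # m/s, positive while penetrating deeper
    area: float               # tributary area, m^2
    slip_velocity: np.ndarray  # tangential velocity of the vertex, m/s


class TerrainField:
    """Precomputed query structure over a validated watertight terrain mesh.

    ``query(points)`` returns, per point, whether it is inside the solid
    (parity of +Y ray crossings), the closest surface point, the face normal
    there, and the depth (distance to the closest surface point).
    """

    def __init__(self, mesh: TriMesh):
        report = validate_mesh(mesh)
        if not report.watertight:
            raise ValueError("terrain mesh is not watertight")
        self.mesh = mesh
        v, f = mesh.vertices, mesh.faces
        self.a = v[f[:, 0]]
        self.edge1 = v[f[:, 1]] - self.a
        self.edge2 = v[f[:, 2]] - self.a
        self.normals = mesh.face_normals()
        self.bbox_min = v.min(axis=0)
        self.bbox_max = v.max(axis=0)

    def _inside(self, pts: np.ndarray) -> np.ndarray:
        """Parity of vertical upward ray crossings (vectorized Moller-Trumbore)."""
        n = len(pts)
        inside = np.zeros(n, dtype=bool)
        box = np.all((pts >= self.bbox_min - 1e-12) & (pts <= self.bbox_max + 1e-12), axis=1)
        idx = np.nonzero(box)[0]
        if len(idx) == 0:
            return inside
        # tiny irrational x/z offset keeps the vertical ray off shared
        # triangle edges (would be double-counted by the parity rule)
        p = pts[idx] + np.array([1.0e-9, 0.0, 1.357e-9])
        d = np.array([0.0, 1.0, 0.0])
        # per (point, face) intersection test
        pvec = np.cross(d, self.edge2)                       # (F, 3)
        det = np.einsum("fj,fj->f", self.edge1, pvec)        # (F,)
        ok = np.abs(det) > 1e-14
        inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = p[:, None, :] - self.a[None, :, :]            # (P, F, 3)
        u = np.einsum("pfj,fj->pf", tvec, pvec) * inv_det
        qvec = np.cross(tvec, self.edge1[None, :, :])
        vpar = np.einsum("pfj,j->pf", qvec, d) * inv_det
        t = np.einsum("pfj,fj->pf", qvec, self.edge2) * inv_det
        hit = ok[None, :] & (u >= 0) & (vpar >= 0) & (u + vpar <= 1) & (t > 1e-12)
        inside[idx] = (hit.sum(axis=1) % 2) == 1
        return inside

    def _closest(self, p: np.ndarray):
        """Closest surface point/face for a single point (vectorized over faces)."""
        a, e1, e2 = self.a, self.edge1, self.edge2
        # Ericson closest-point-on-triangle, branchless over all faces
        ap = p - a
        d1 = np.einsum("fj,fj->f", e1, ap)
        d2 = np.einsum("fj,fj->f", e2, ap)
        b_ = p - (a + e1)
        d3 = np.einsum("fj,fj->f", e1, b_)
        d4 = np.einsum("fj,fj->f", e2, b_)
        c_ = p - (a + e2)
        d5 = np.einsum("fj,fj->f", e1, c_)
        d6 = np.einsum("fj,fj->f", e2, c_)

        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        denom_uv = va + vb + vc
        denom_uv = np.where(np.abs(denom_uv) < 1e-30, 1e-30, denom_uv)
        v = vb / denom_uv
        w = vc / denom_uv

        # region tests
        u_edge = np.clip(np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0), 0, 1)
        t_edge2 = np.clip(np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0), 0, 1)
        w_edge = np.clip((d4 - d3) / np.where((d4 - d3) + (d5 - d6) == 0, 1e-30, (d4 - d3) + (d5 - d6)), 0, 1)

        cand = np.empty((len(a), 3))
        # interior by default
        cand[:] = a + v[:, None] * e1 + w[:, None] * e2
        # vertex regions
        m = (d1 <= 0) & (d2 <= 0)
        cand[m] = a[m]
        m = (d3 >= 0) & (d4 <= d3)
        cand[m] = (a + e1)[m]
        m = (d6 >= 0) & (d5 <= d6)
        cand[m] = (a + e2)[m]
        # edge regions
        m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        cand[m] = a[m] + u_edge[m, None] * e1[m]
        m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        cand[m] = a[m] + t_edge2[m, None] * e2[m]
        m = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
        cand[m] = (a + e1)[m] + w_edge[m, None] * (e2 - e1)[m]

        dist2 = np.einsum("fj,fj->f", cand - p, cand - p)
        fi = int(np.argmin(dist2))
        return cand[fi], self.normals[fi], float(np.sqrt(dist2[fi]))

    def query(self, pts: np.ndarray):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inside = self._inside(pts)
        depth = np.zeros(len(pts))
        normal = np.zeros_like(pts)
        for i in np.nonzero(inside)[0]:
            _, n, d = self._closest(pts[i])
            depth[i] = d
            normal[i] = n
        return inside, depth, normal


class FlatGround:
    """Analytic horizontal half-space y <= ``height`` with the same query API."""

    def __init__(self, height: float = 0.0):
        self.height = height

    def query(self, pts: np.ndarray):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        depth = self.height - pts[:, 1]
        inside = depth > 0
        depth = np.where(inside, depth, 0.0)
        normal = np.zeros_like(pts)
        normal[:, 1] = 1.0
        return inside, depth, normal


def _segment_distances(x, y, segs):
    """Distances from (x, y) points to 2D segments; (P, S) matrix.

    ``segs`` is (S, 4): x0, y0, x1, y1 per segment.
    """
    p = np.stack([x, y], axis=1)[:, None, :]          # (P, 1, 2)
    a = segs[None, :, 0:2]
    d = segs[None, :, 2:4] - a                        # (1, S, 2)
    len2 = np.maximum((d * d).sum(axis=2), 1e-30)
    t = np.clip(((p - a) * d).sum(axis=2) / len2, 0.0, 1.0)
    proj = a + t[:, :, None] * d
    return np.linalg.norm(p - proj, axis=2), t


class StairField:
    """Analytic penetration queries against the staircase walking surface.

    Matches :func:`stairgait.terrain.build_stairs` exactly on the treads and
    risers: a point inside the solid reports the true 2D distance to the
    step-profile polyline (clamped segment projections, so re-entrant step
    corners are handled), with the outward normal of the nearest face (+Y
    for treads, -X for risers).  The bottom/side/back walls are ignored —
    feet only ever approach the walking surface from above.
    """

    def __init__(self, spec: StairSpec, origin=(0.0, 0.0, 0.0)):
        self.spec = spec
        self.origin = np.asarray(origin, dtype=float)
        segs = []
        normals = []
        h, d = spec.step_height, spec.step_depth
        for k in range(spec.n_steps):
            segs.append((k * d, k * h, k * d, (k + 1) * h))          # riser
            normals.append((-1.0, 0.0, 0.0))
            segs.append((k * d, (k + 1) * h, (k + 1) * d, (k + 1) * h))  # tread
            normals.append((0.0, 1.0, 0.0))
        self._segs = np.asarray(segs, dtype=float)
        self._normals = np.asarray(normals, dtype=float)

    def query(self, pts: np.ndarray):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        s = self.spec
        x = pts[:, 0] - self.origin[0]
        y = pts[:, 1] - self.origin[1]
        z = pts[:, 2] - self.origin[2]
        band = np.clip(np.floor(x / s.step_depth).astype(int), 0, s.n_steps - 1)
        height = (band + 1) * s.step_height
        inside = ((x > 0) & (x < s.n_steps * s.step_depth)
                  & (np.abs(z) < s.width / 2) & (y > 0) & (y < height))
        depth = np.zeros(len(pts))
        normal = np.zeros_like(pts)
        idx = np.nonzero(inside)[0]
        if len(idx):
            dists, _t = _segment_distances(x[idx], y[idx], self._segs)
            best = np.argmin(dists, axis=1)
            depth[idx] = dists[np.arange(len(idx)), best]
            normal[idx] = self._normals[best]
        return inside, depth, normal


class RampField:
    """Analytic penetration queries against the ramp's inclined surface.

    Matches :func:`stairgait.terrain.build_ramp` on the incline from (0, 0)
    to (run, rise): depth is the clamped-projection distance to that
    segment, the normal is the incline's outward normal.  Bottom/back/side
    walls are ignored (unreachable by feet from above).
    """

    def __init__(self, spec: RampSpec, origin=(0.0, 0.0, 0.0)):
        self.spec = spec
        self.origin = np.asarray(origin, dtype=float)
        angle = math.atan2(spec.rise, spec.run)
        self.normal_top = np.array([-math.sin(angle), math.cos(angle), 0.0])
        self._seg = np.array([[0.0, 0.0, spec.run, spec.rise]])

    def query(self, pts: np.ndarray):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        s = self.spec
        x = pts[:, 0] - self.origin[0]
        y = pts[:, 1] - self.origin[1]
        z = pts[:, 2] - self.origin[2]
        surf_y = x * (s.rise / s.run)
        inside = (x > 0) & (x < s.run) & (np.abs(z) < s.width / 2) & (y > 0) & (y < surf_y)
        depth = np.zeros(len(pts))
        normal = np.zeros_like(pts)
        idx = np.nonzero(inside)[0]
        if len(idx):
            dists, _t = _segment_distances(x[idx], y[idx], self._seg)
            depth[idx] = dists[:, 0]
            normal[idx] = self.normal_top
        return inside, depth, normal


def detect_contacts(sphere: TriMesh, terrain, position=None, rotation=None,
                    linear_velocity=(0.0, 0.0, 0.0), angular_velocity=(0.0, 0.0, 0.0)):
    """Contact candidates between a placed foot sphere and the terrain.

    ``sphere`` is the body-local sphere mesh; ``position``/``rotation`` (3,)
    and (3, 3) place it in the world; velocities give the rigid-body motion of
    the sphere so depth rates and slip velocities can be formed.  ``terrain``
    is a :class:`TerrainField`, :class:`FlatGround` or raw watertight
    :class:`TriMesh`.  One candidate is produced per penetrating sphere
    vertex; the tributary area is the sphere surface area divided by the
    vertex count.
    """
    if isinstance(terrain, TriMesh):
        terrain = TerrainField(terrain)
    pos = np.zeros(3) if position is None else np.asarray(position, dtype=float)
    rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    v_lin = np.asarray(linear_velocity, dtype=float)
    omega = np.asarray(angular_velocity, dtype=float)

    verts = sphere.vertices @ rot.T + pos
    # tributary area from the true sphere radius (vertices lie on the sphere)
    center = sphere.vertices.mean(axis=0)
    radius = float(np.linalg.norm(sphere.vertices - center, axis=1).mean())
    area = 4.0 * np.pi * radius**2 / len(verts)

    inside, depth, normal = terrain.query(verts)
    points = []
    for i in np.nonzero(inside)[0]:
        n = normal[i]
        r = verts[i] - pos
        v_pt = v_lin + np.cross(omega, r)
        depth_rate = float(-v_pt @ n)
        slip = v_pt - (v_pt @ n) * n
        points.append(
            ContactPoint(
                position=verts[i],
                normal=n,
                depth=float(depth[i]),
                depth_rate=depth_rate,
                area=area,
                slip_velocity=slip,
            )
        )
    return points


def normal_pressure(depth, depth_rate, params: ContactParams):
    """Elastic-foundation pressure p = k x (1 + c xdot), clamped at zero (Pa)."""
    x = np.asarray(depth, dtype=float)
    if np.any(x < 0):
        raise ValueError("penetration depth must be >= 0")
    xdot = np.asarray(depth_rate, dtype=float)
    p = params.stiffness * x * (1.0 + params.dissipation * xdot)
    p = np.maximum(p, 0.0)
    return float(p) if p.ndim == 0 else p


def friction_force(normal_force: float, slip_velocity, params: ContactParams) -> np.ndarray:
    """Tangential friction force opposing the slip velocity (N).

    Stribeck blend: with s = |v| / transition_velocity, the Coulomb
    coefficient rises from 0 through the static value at s = 1 and decays to
    the dynamic value at large s; a viscous term mu_viscous * s adds on top.
    Zero force at zero slip (continuous at rest); magnitude never exceeds
    (mu_static + mu_viscous * s) * N.
    """
    if normal_force < 0:
        raise ValueError("normal force must be >= 0")
    v = np.asarray(slip_velocity, dtype=float)
    speed = float(np.linalg.norm(v))
    if speed == 0.0 or normal_force == 0.0:
        return np.zeros_like(v)
    s = speed / params.transition_velocity
    mu_d, mu_s = params.mu_dynamic, params.mu_static
    mu_coulomb = min(s, 1.0) * (mu_d + 2.0 * (mu_s - mu_d) / (1.0 + s * s))
    mu = mu_coulomb + params.mu_viscous * s
    return -(mu * normal_force / speed) * v


@dataclass
class GRFResult:
    """Resultant ground reaction: total force and centre of pressure."""

    force: np.ndarray
    cop: np.ndarray = None  # None when there is no contact

    @property
    def defined(self) -> bool:
        return self.cop is not None


def resultant_grf(points, forces) -> GRFResult:
    """Sum per-point contact forces and find the centre of pressure.

    The centre of pressure is the normal-force-weighted mean contact
    position, the point about which the net moment of the normal force
    components vanishes.  With no contact the force is zero and the centre
    of pressure undefined (flagged as None).
    """
    if len(points) == 0:
        return GRFResult(force=np.zeros(3), cop=None)
    F = np.asarray(forces, dtype=float).reshape(len(points), 3)
    total = F.sum(axis=0)
    weights = np.array([max(float(f @ p.normal), 0.0) for f, p in zip(F, points)])
    wsum = weights.sum()
    if wsum <= 0.0:
        return GRFResult(force=total, cop=None)
    pos = np.array([p.position for p in points])
    cop = (weights[:, None] * pos).sum(axis=0) / wsum
    return GRFResult(force=total, cop=cop)


def contact_forces(points, params: ContactParams):
    """Per-point total (normal + friction) contact force vectors (N)."""
    out = []
    for p in points:
        fn = normal_pressure(p.depth, p.depth_rate, params) * p.area
        f = fn * p.normal + friction_force(fn, p.slip_velocity, params)
        out.append(f)
    return np.array(out).reshape(len(points), 3)
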