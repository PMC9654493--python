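"""Reference joint trajectories used as imitation targets.

The original training data are motion-capture recordings of stair and ramp
ascent; this module supplies (a) readers for tabular joint-trajectory files
(a TRC-like tab-separated dialect and plain CSV), (b) the backward-difference
joint velocity rule used on such data,

    v(t_k) = (p(t_k) - p(t_{k-1})) / dt,   v(0) = v(1),

and (c) a synthetic stair/ramp gait generator that replaces the external
motion-capture dataset with a reproducible, parametric gait: smooth per-cycle
pelvis progression matched to the terrain (one step depth/height per cycle on
stairs, the incline on the ramp), two-harmonic joint angle templates with the
legs in anti-phase, and the first swing taken by the left leg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import PLANAR_DOF_NAMES
from .terrain import RampSpec, StairSpec, ramp_gradient

__all__ = [
    "ReferenceTrajectory",
    "SyntheticGaitSpec",
    "finite_diff_velocity",
    "read_trajectory",
    "write_trajectory",
    "synth_gait",
]


def finite_diff_velocity(positions, dt: float) -> np.ndarray:
    """Backward-difference velocities with the boundary rule v(0) = v(1).

    ``positions`` is (m,) or (m, n_dof); needs at least two samples.  The
    final sample's velocity is its backward difference (equivalently, the
    final velocity equals the one before the end of the grid).
    """
    p = np.asarray(positions, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if p.shape[0] < 2:
        raise ValueError("need at least two samples to differentiate")
    v = np.empty_like(p)
    v[1:] = (p[1:] - p[:-1]) / dt
    v[0] = v[1]
    return v


@dataclass
class ReferenceTrajectory:
    """Time-gridded joint positions with derived velocities.

    ``times`` is a uniform grid (s); ``pos``/``vel`` are (m, n_dof) arrays in
    rad or m; ``dof_names`` labels the columns.  ``pelvis_vel`` holds the
    pelvis translational velocity (m, 2) used by the goal reward.
    """

    times: np.ndarray
    dof_names: tuple
    pos: np.ndarray
    vel: np.ndarray = None
    pelvis_vel: np.ndarray = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        self.dof_names = tuple(self.dof_names)
        if self.pos.shape != (len(self.times), len(self.dof_names)):
            raise ValueError("pos shape must be (n_times, n_dof)")
        steps = np.diff(self.times)
        if len(steps) and (np.any(steps <= 0) or np.ptp(steps) > 1e-9 * max(steps.max(), 1.0)):
            raise ValueError("time grid must be uniform and increasing")
        if self.vel is None:
            self.vel = finite_diff_velocity(self.pos, self.dt)
        if self.pelvis_vel is None:
            cols = [self.dof_names.index(n) for n in ("pelvis_tx", "pelvis_ty")
                    if n in self.dof_names]
            self.pelvis_vel = self.vel[:, cols] if cols else np.zeros((len(self.times), 0))

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def index_at(self, t: float) -> int:
        """Nearest grid index; raises IndexError past the end of the grid."""
        i = int(round((t - self.times[0]) / self.dt))
        if i < 0 or i >= len(self.times):
            raise IndexError(f"t={t} outside the reference span")
        return i

    def column(self, name: str) -> np.ndarray:
        return self.pos[:, self.dof_names.index(name)]


# ---------------------------------------------------------------------------
# file input/output

_ANGLE_SUFFIXES = ("_rot", "hip", "knee", "ankle")


def _is_angle(name: str) -> bool:
    return any(s in name for s in _ANGLE_SUFFIXES)


def write_trajectory(traj: ReferenceTrajectory, path, dialect: str = "csv") -> None:
    """Write a trajectory as CSV (SI units) or the TRC-like dialect
    (millimetres and degrees, tab-separated, with a rate header)."""
    if dialect == "csv":
        header = "time," + ",".join(traj.dof_names)
        data = np.column_stack([traj.times, traj.pos])
        np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.10g")
        return
    if dialect != "trc":
        raise ValueError("dialect must be 'csv' or 'trc'")
    rate = 1.0 / traj.dt
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\n")
        fh.write(f"{rate:.10g}\t{rate:.10g}\t{len(traj.times)}\t{len(traj.dof_names)}\tmm\t{rate:.10g}\n")
        fh.write("Frame#\tTime\t" + "\t".join(traj.dof_names) + "\n")
        for i, t in enumerate(traj.times):
            row = [f"{i + 1}", f"{t:.10g}"]
            for j, name in enumerate(traj.dof_names):
                val = traj.pos[i, j]
                row.append(f"{math.degrees(val):.10g}" if _is_angle(name) else f"{val * 1000.0:.10g}")
            fh.write("\t".join(row) + "\n")


def read_trajectory(path, dialect: str = "csv") -> ReferenceTrajectory:
    """Parse a joint-trajectory table; units are normalised to rad and m.

    CSV: a ``time`` column plus one column per degree of freedom, SI units.
    TRC dialect: tab-separated with a DataRate header line; translations in
    mm, angles in degrees.  Ragged rows, non-monotone time and a header rate
    inconsistent with the time column are rejected with the row number.
    """
    if dialect == "csv":
        with open(path) as fh:
            names = fh.readline().strip().split(",")
            if names[0] != "time":
                raise ValueError("first CSV column must be 'time'")
            rows = []
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.strip().split(",")
                if len(parts) != len(names):
                    raise ValueError(f"row {lineno}: expected {len(names)} fields, got {len(parts)}")
                rows.append([float(x) for x in parts])
        data = np.array(rows)
        times = data[:, 0]
        if np.any(np.diff(times) <= 0):
            bad = int(np.nonzero(np.diff(times) <= 0)[0][0]) + 2
            raise ValueError(f"row {bad + 1}: non-monotone time")
        return ReferenceTrajectory(times, tuple(names[1:]), data[:, 1:])

    if dialect != "trc":
        raise ValueError("dialect must be 'csv' or 'trc'")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 5:
        raise ValueError("truncated TRC file")
    meta = lines[2].split("\t")
    rate = float(meta[0])
    cols = lines[3].split("\t")
    if cols[:2] != ["Frame#", "Time"]:
        raise ValueError("row 4: expected 'Frame#\\tTime\\t...' column header")
    names = cols[2:]
    rows = []
    for lineno, line in enumerate(lines[4:], start=5):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(cols):
            raise ValueError(f"row {lineno}: expected {len(cols)} fields, got {len(parts)}")
        rows.append([float(x) for x in parts[1:]])
    data = np.array(rows)
    times = data[:, 0]
    if np.any(np.diff(times) <= 0):
        bad = int(np.nonzero(np.diff(times) <= 0)[0][0]) + 5
        raise ValueError(f"row {bad + 1}: non-monotone time")
    if len(times) > 1:
        dt = times[1] - times[0]
        if abs(dt * rate - 1.0) > 1e-6:
            raise ValueError(
                f"row 6: header DataRate {rate} inconsistent with time step {dt}"
            )
    pos = data[:, 1:].copy()
    for j, name in enumerate(names):
        pos[:, j] = np.radians(pos[:, j]) if _is_angle(name) else pos[:, j] / 1000.0
    return ReferenceTrajectory(times, tuple(names), pos)


# ---------------------------------------------------------------------------
# synthetic gait generator

#: joint-angle templates: mean, first and second harmonic amplitudes (rad)
#: and phases (rad), per DOF family.  Signs follow the model convention:
#: hip flexion +, knee flexion -, ankle dorsiflexion +.  The shapes give the
#: qualitative structure of stair/ramp ascent (knee flexion peaking in swing,
#: ankle push-off late in stance); they are configuration, not measurements.
#: phases put peak hip/knee swing flexion at the first quarter-cycle (the
#: leading leg swings first) and ankle plantarflexion at push-off near the
#: cycle boundary.
_STAIR_TEMPLATES = {
    "hip": (0.42, 0.38, 0.0, 0.06, 0.0),
    "knee": (-0.62, 0.52, math.pi, 0.10, 0.0),
    "ankle": (0.05, 0.22, -math.pi / 2, 0.06, 0.0),
}
_RAMP_TEMPLATES = {
    "hip": (0.25, 0.28, 0.0, 0.04, 0.0),
    "knee": (-0.38, 0.32, math.pi, 0.06, 0.0),
    "ankle": (0.12, 0.16, -math.pi / 2, 0.05, 0.0),
}


@dataclass
class SyntheticGaitSpec:
    """Configuration of the synthetic reference gait.

    One gait cycle (duration ``cycle_duration``) advances the pelvis by one
    step depth and height on stairs, or by the equivalent incline distance on
    the ramp.  ``lead_in`` seconds of quiet standing precede the first
    (left-leg) swing.  ``noise_sd`` adds seeded Gaussian angle noise (rad).
    """

    terrain_kind: str = "stairs"
    cycle_duration: float = 1.4
    n_cycles: int = 3
    lead_in: float = 0.3
    sample_dt: float = 0.01
    noise_sd: float = 0.0
    seed: int = 0
    templates: dict = None
    joint_limits: dict = field(default_factory=lambda: {
        "hip": (-0.70, 2.10), "knee": (-2.30, 0.02), "ankle": (-0.90, 0.70)})
    pelvis_start: tuple = (0.0, 0.94)
    terrain_offset: float = 0.35  # m, gap between start and the terrain front

    def __post_init__(self) -> None:
        if self.terrain_kind not in ("stairs", "ramp"):
            raise ValueError("terrain_kind must be 'stairs' or 'ramp'")
        if self.cycle_duration <= 0 or self.sample_dt <= 0 or self.n_cycles < 1:
            raise ValueError("cycle_duration, sample_dt, n_cycles must be positive")
        if self.templates is None:
            self.templates = _STAIR_TEMPLATES if self.terrain_kind == "stairs" else _RAMP_TEMPLATES


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def synth_gait(spec: SyntheticGaitSpec, terrain=None) -> ReferenceTrajectory:
    """Generate a synthetic stair or ramp ascent reference trajectory.

    ``terrain`` is a :class:`StairSpec`/:class:`RampSpec` (defaults match the
    task geometry).  The pelvis advances one step depth and rises one step
    height per cycle on stairs; on the ramp it advances one cycle length
    along the incline.  Joint angles follow the two-harmonic templates with
    the right leg half a cycle out of phase, so the left leg swings first.
    """
    if terrain is None:
        terrain = StairSpec() if spec.terrain_kind == "stairs" else RampSpec()
    T = spec.cycle_duration
    total = spec.lead_in + spec.n_cycles * T
    m = int(round(total / spec.sample_dt)) + 1
    times = np.arange(m) * spec.sample_dt
    rng = np.random.default_rng(spec.seed)

    # per-cycle smoothed forward progress in [0, n_cycles]
    tau = np.clip((times - spec.lead_in) / T, 0.0, spec.n_cycles)
    cycle = np.floor(np.minimum(tau, spec.n_cycles - 1e-9)).astype(int)
    frac = tau - cycle
    progress = cycle + _smoothstep(frac)

    if spec.terrain_kind == "stairs":
        dx_cycle = terrain.step_depth
        dy_cycle = terrain.step_height
    else:
        grad = math.radians(ramp_gradient(terrain))
        stride = 0.65 * T  # m per cycle along the slope at a modest ramp pace
        dx_cycle = stride * math.cos(grad)
        dy_cycle = stride * math.sin(grad)

    x0, y0 = spec.pelvis_start
    pos = np.zeros((m, len(PLANAR_DOF_NAMES)))
    names = PLANAR_DOF_NAMES
    pos[:, names.index("pelvis_tx")] = x0 + spec.terrain_offset * _smoothstep(tau) \
        + dx_cycle * progress
    pos[:, names.index("pelvis_ty")] = y0 + dy_cycle * progress
    pos[:, names.index("pelvis_rot")] = 0.0

    # gait phase in [0, 1); left leg leads (swings during the first half-cycle)
    phase = (times - spec.lead_in) / T
    active = _smoothstep(tau / 0.5)  # fade the oscillation in over the lead-in
    for side, offset in (("l", 0.0), ("r", 0.5)):
        ph = 2.0 * math.pi * (phase - offset)
        for joint in ("hip", "knee", "ankle"):
            mean, a1, p1, a2, p2 = spec.templates[joint]
            # ``active`` fades the whole pattern in from quiet standing
            series = active * (mean + a1 * np.sin(ph + p1) + a2 * np.sin(2 * ph + p2))
            if spec.noise_sd > 0:
                series = series + rng.normal(0.0, spec.noise_sd, size=m)
            lo, hi = spec.joint_limits[joint]
            pos[:, names.index(f"{joint}_{side}")] = np.clip(series, lo, hi)
    return ReferenceTrajectory(times, names, pos)
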