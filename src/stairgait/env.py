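"""Stair/ramp ascent imitation environment.

Couples the planar muscle-driven model, the terrain contact fields, a
reference trajectory and the reward into a sequential decision task with the
conventional ``reset``/``step`` interface: actions are binary per-muscle
excitation vectors held for one control interval (10 ms by default, with
1 ms physics substeps), observations are the flat state vector of
:mod:`stairgait.observation` with fixed diagonal scaling, and the per-step
reward is the weighted goal+imitation term of :mod:`stairgait.reward`.

Episodes start from the reference's initial pose and end on a fall (pelvis
below 60% of its starting height), on leaving the terrain footprint, on
numerical divergence, or when the reference runs out (truncation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contact import ContactParams, FlatGround, RampField, StairField
from .dynamics import DEFAULT_PHYSICS_DT, PlanarEngine
from .model import PLANAR_DOF_NAMES, planar_model
from .observation import observation, planar_layout
from .reference import ReferenceTrajectory, SyntheticGaitSpec, synth_gait
from .reward import (
    PenaltyPair,
    RewardWeights,
    goal_reward,
    imitation_reward,
    total_reward,
)
from .terrain import RampSpec, StairSpec

__all__ = ["AscentEnv"]

FALL_FRACTION = 0.6       # episode ends when pelvis drops below this fraction
FOOTPRINT_MARGIN = 0.5    # m beyond the terrain in x before termination


def _obs_scale(layout) -> np.ndarray:
    """Fixed diagonal scaling per component (keeps entries near unit order)."""
    scales = {
        "segment_pos": 1.0,
        "segment_rot": 1.0,
        "segment_linvel": 0.2,
        "segment_rotvel": 0.05,
        "segment_linacc": 1e-3,
        "segment_rotacc": 2e-4,
        "joint_pos": 1.0,
        "joint_vel": 0.05,
        "joint_acc": 2e-4,
        "muscle_forces": 2e-4,
        "limit_torques": 0.01,
        "grf": 1e-3,
    }
    return np.concatenate([
        np.full(size, scales.get(name, 1.0)) for name, size in layout.components
    ])


class AscentEnv:
    """Muscle-excitation control task on stairs or a ramp.

    Parameters
    ----------
    variant:
        ``"stairs"`` or ``"ramp"``; selects the model preset, terrain and
        default synthetic reference.
    reference:
        A :class:`ReferenceTrajectory`; defaults to the synthetic gait for
        the chosen terrain.
    """

    def __init__(self, variant: str = "stairs", reference: ReferenceTrajectory = None,
                 contact: ContactParams = None, weights: RewardWeights = None,
                 control_dt: float = 0.01, physics_dt: float = DEFAULT_PHYSICS_DT,
                 terrain_offset: float = 0.35, tracked=None, gait_spec=None):
        if variant not in ("stairs", "ramp"):
            raise ValueError("variant must be 'stairs' or 'ramp'")
        self.variant = variant
        self.engine = PlanarEngine(planar_model(variant))
        self.contact = contact or ContactParams()
        self.weights = weights or RewardWeights()
        self.control_dt = control_dt
        self.physics_dt = physics_dt
        self.n_substeps = max(1, int(round(control_dt / physics_dt)))
        self.terrain_offset = terrain_offset
        if variant == "stairs":
            self.terrain_spec = StairSpec()
            field = StairField(self.terrain_spec, origin=(terrain_offset, 0.0, 0.0))
            self._terrain_end = terrain_offset + self.terrain_spec.n_steps * self.terrain_spec.step_depth
        else:
            self.terrain_spec = RampSpec()
            field = RampField(self.terrain_spec, origin=(terrain_offset, 0.0, 0.0))
            self._terrain_end = terrain_offset + self.terrain_spec.run
        self.surfaces = [FlatGround(0.0), field]
        if reference is None:
            spec = gait_spec or SyntheticGaitSpec(terrain_kind=variant,
                                                  terrain_offset=terrain_offset)
            reference = synth_gait(spec, self.terrain_spec)
        self.reference = reference
        self.tracked = tuple(tracked) if tracked is not None else PLANAR_DOF_NAMES
        self.layout = planar_layout(self.engine)
        self._scale = _obs_scale(self.layout)
        self.n_muscles = self.engine.spec.n_muscles
        self._pelvis_cols = [self.reference.dof_names.index(n)
                             for n in ("pelvis_tx", "pelvis_ty")]
        self._state = None
        self._info = None
        self._y0 = None
        self._log = []

    # -- interface ---------------------------------------------------------

    @property
    def observation_size(self) -> int:
        return self.layout.total

    def reset(self, seed=None):
        """Start a new episode from the reference's initial pose."""
        ref = self.reference
        self._state = self.engine.set_pose(ref.pos[0], ref.vel[0])
        self._info = None
        self._y0 = float(self._state.q[1])
        self._log = []
        return self._observe(), {"t": 0.0}

    def _observe(self) -> np.ndarray:
        obs = observation(self._state, self.engine, self.layout, self._info) * self._scale
        # transient contact spikes would otherwise saturate the tanh layers
        return np.clip(obs, -5.0, 5.0)

    def step(self, action):
        """Apply a binary excitation vector for one control interval."""
        if self._state is None:
            raise RuntimeError("call reset() before step()")
        exc = np.clip(np.asarray(action, dtype=float), 0.0, 1.0)
        st = self._state
        info = None
        terminated = False
        reason = ""
        for _ in range(self.n_substeps):
            st, info = self.engine.step(st, exc, self.surfaces, self.contact,
                                        self.physics_dt)
            if info.terminated:
                terminated, reason = True, info.reason
                break
        self._state, self._info = st, info

        ref = self.reference
        truncated = st.t > ref.duration + 0.5 * ref.dt
        i = min(ref.index_at(min(st.t, ref.duration)), len(ref.times) - 1)
        gq = self.engine.gen_coords(st)
        gu = self.engine.gen_speeds(st)
        names = ref.dof_names
        p_pos = 0.0
        p_vel = 0.0
        for name in self.tracked:
            j = names.index(name)
            k = PLANAR_DOF_NAMES.index(name)
            p_pos += (gq[k] - ref.pos[i, j]) ** 2
            p_vel += (gu[k] - ref.vel[i, j]) ** 2
        pv_pelvis = float((gu[0] - ref.pelvis_vel[i, 0]) ** 2
                          + (gu[1] - ref.pelvis_vel[i, 1]) ** 2)
        r_goal = goal_reward(pv_pelvis, self.weights)
        r_imit = imitation_reward(PenaltyPair(p_pos, p_vel), self.weights)
        reward = total_reward(r_goal, r_imit, self.weights)

        if not terminated:
            if st.q[1] < FALL_FRACTION * self._y0:
                terminated, reason = True, "fall"
            elif not (-FOOTPRINT_MARGIN < st.q[0] < self._terrain_end + FOOTPRINT_MARGIN):
                terminated, reason = True, "out_of_footprint"

        self._log.append(self._log_row(st, info, reward, terminated, reason))
        return self._observe(), reward, terminated, truncated, {
            "t": st.t, "p_pos": p_pos, "p_vel": p_vel, "reason": reason,
            "goal": r_goal, "imitation": r_imit,
        }

    # -- logging and idealized replay --------------------------------------

    def _log_row(self, st, info, reward, terminated, reason):
        gq = self.engine.gen_coords(st)
        gu = self.engine.gen_speeds(st)
        row = {"time": st.t, "reward": reward,
               "terminated": terminated, "reason": reason}
        for k, name in enumerate(PLANAR_DOF_NAMES):
            row[name] = gq[k]
            row[name + "_u"] = gu[k]
        for k, name in enumerate(self.engine.spec.muscle_names):
            row["F_" + name] = float(st.muscle_forces[k])
        for side in ("l", "r"):
            if info is not None and info.grf:
                f, cop = info.grf[side]
                row[f"grf_{side}_x"], row[f"grf_{side}_y"] = float(f[0]), float(f[1])
                row[f"contact_{side}"] = int(cop is not None)
                row[f"cop_{side}_x"] = float(cop[0]) if cop is not None else np.nan
                row[f"cop_{side}_y"] = float(cop[1]) if cop is not None else np.nan
            else:
                row[f"grf_{side}_x"] = row[f"grf_{side}_y"] = 0.0
                row[f"contact_{side}"] = 0
                row[f"cop_{side}_x"] = row[f"cop_{side}_y"] = np.nan
        return row

    def episode_log(self) -> pd.DataFrame:
        """Columnar per-control-step trace of the current episode."""
        return pd.DataFrame(self._log)

    def replay_reference(self) -> pd.DataFrame:
        """Kinematic playback of the reference through an idealized actuator.

        The state is set directly from the reference at every control step
        (no dynamics), which by construction realises every reward's maximum;
        used as the upper anchor for reward-fraction reporting.
        """
        ref = self.reference
        self.reset()
        rows = []
        stride = max(1, int(round(self.control_dt / ref.dt)))
        for i in range(stride, len(ref.times), stride):
            st = self.engine.set_pose(ref.pos[i], ref.vel[i], t=float(ref.times[i]))
            # exact tracking: all penalties vanish by construction
            r = total_reward(goal_reward(0.0, self.weights),
                             imitation_reward(PenaltyPair(0.0, 0.0), self.weights),
                             self.weights)
            rows.append(self._log_row(st, None, r, False, ""))
        self._log = rows
        return pd.DataFrame(rows)
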