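"""Per-step reward: weighted goal and imitation terms.

The reward at each control step is

    J_t = 0.1 * J_goal + 0.9 * J_imitation
    J_goal = exp(-8 * p_vel_pelvis)
    J_imitation = 0.9 * exp(-4 * p_pos) + 0.1 * exp(-0.1 * p_vel)

where ``p_pos`` and ``p_vel`` are the sums over the tracked degrees of
freedom (pelvis, hip, knee and ankle coordinates) of the squared deviation
between the simulated and reference joint positions and velocities, and
``p_vel_pelvis`` is the squared deviation of the pelvis translational
velocity alone.  The sums inside the exponents run over the tracked
coordinates within one time step (a cumulative sum over time would drive
every reward to zero and contradict the per-step framing).  All terms lie in
(0, 1], so the total does too, reaching 1 exactly when every penalty is 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RewardWeights",
    "PenaltyPair",
    "penalties",
    "goal_reward",
    "imitation_reward",
    "total_reward",
]


@dataclass(frozen=True)
class RewardWeights:
    """Reward mixing weights and exponent gains (defaults are the fixed
    values of the reward definition)."""

    w_goal: float = 0.1
    w_imitation: float = 0.9
    w_imit_pos: float = 0.9
    w_imit_vel: float = 0.1
    k_goal: float = 8.0
    k_pos: float = 4.0
    k_vel: float = 0.1

    def __post_init__(self) -> None:
        if abs(self.w_goal + self.w_imitation - 1.0) > 1e-12:
            raise ValueError("w_goal + w_imitation must equal 1")
        if abs(self.w_imit_pos + self.w_imit_vel - 1.0) > 1e-12:
            raise ValueError("w_imit_pos + w_imit_vel must equal 1")
        if min(self.k_goal, self.k_pos, self.k_vel) <= 0:
            raise ValueError("exponent gains must be positive")


@dataclass(frozen=True)
class PenaltyPair:
    """Squared-error sums over tracked DOF positions and velocities."""

    p_pos: float
    p_vel: float

    def __post_init__(self) -> None:
        if self.p_pos < 0 or self.p_vel < 0:
            raise ValueError("penalties must be non-negative")


class ReferenceEnded(Exception):
    """Signals that the queried time lies beyond the reference span
    (an episode-end condition, not an error)."""


def penalties(obs_pos, obs_vel, ref, t: float, tracked=None) -> PenaltyPair:
    """Squared-error penalties of the tracked DOFs against the reference.

    ``obs_pos``/``obs_vel`` map DOF name to the simulated value (dict) or are
    arrays aligned with ``ref.dof_names``.  The reference is sampled at the
    nearest grid point to ``t``; a time beyond the grid raises
    :class:`ReferenceEnded`.
    """
    try:
        i = ref.index_at(t)
    except IndexError:
        raise ReferenceEnded(t)
    names = ref.dof_names if tracked is None else tuple(tracked)
    p_pos = 0.0
    p_vel = 0.0
    for name in names:
        j = ref.dof_names.index(name)
        if isinstance(obs_pos, dict):
            op, ov = obs_pos[name], obs_vel[name]
        else:
            op, ov = obs_pos[j], obs_vel[j]
        p_pos += (op - ref.pos[i, j]) ** 2
        p_vel += (ov - ref.vel[i, j]) ** 2
    return PenaltyPair(float(p_pos), float(p_vel))


def goal_reward(p_vel_pelvis: float, weights: RewardWeights = RewardWeights()) -> float:
    """exp(-k_goal * p_vel) for the pelvis-velocity penalty; in (0, 1]."""
    if p_vel_pelvis < 0:
        raise ValueError("velocity penalty must be non-negative")
    return float(np.exp(-weights.k_goal * p_vel_pelvis))


def imitation_reward(pair: PenaltyPair, weights: RewardWeights = RewardWeights()) -> float:
    """Weighted exponentials of the position and velocity penalties; (0, 1]."""
    return float(
        weights.w_imit_pos * np.exp(-weights.k_pos * pair.p_pos)
        + weights.w_imit_vel * np.exp(-weights.k_vel * pair.p_vel)
    )


def total_reward(goal: float, imitation: float,
                 weights: RewardWeights = RewardWeights()) -> float:
    """Convex combination of the goal and imitation rewards."""
    if not (0.0 < goal <= 1.0 and 0.0 < imitation <= 1.0):
        raise ValueError("component rewards must lie in (0, 1]")
    return weights.w_goal * goal + weights.w_imitation * imitation
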