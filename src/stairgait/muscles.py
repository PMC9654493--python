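"""Hill-type muscle model: excitation-activation dynamics and force generation.

Each muscle produces force

    F = f_max * [a * fL(l) * fV(v) + fP(l)] * cos(penn)

where ``a`` is the activation state, ``l`` the fiber length normalised by the
optimal fiber length, ``v`` the fiber velocity normalised by the maximum
contraction velocity, and ``penn`` the pennation angle.  The curve family is
the standard one for this class of models:

* active force-length: Gaussian ``fL(l) = exp(-(l-1)^2 / gamma)``;
* force-velocity: hyperbolic Hill shortening branch vanishing at the maximum
  shortening velocity, with a C1-matched saturating lengthening branch
  (eccentric plateau 1.5);
* passive force-length: exponential, zero at and below the optimal length.

Excitation (the neural command, here binary) drives activation through
first-order dynamics ``da/dt = (u - a)/tau`` with the faster time constant
``tau_act`` when activating (u > a) and ``tau_deact`` when deactivating.
The update is the exact exponential solution of that linear ODE, so it is
unconditionally stable and keeps activation inside [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MuscleParams",
    "activation_step",
    "muscle_force",
    "active_force_length",
    "force_velocity",
    "passive_force_length",
]

# curve shape constants (dimensionless)
FL_GAMMA = 0.45          # width of the active force-length Gaussian
FV_SHORTENING_A = 0.25   # Hill hyperbola curvature (fraction of f_max)
FV_ECCENTRIC_MAX = 1.5   # lengthening force plateau
PE_K = 4.0               # passive exponential shape factor
PE_STRAIN = 0.6          # passive strain at which fP reaches 1


@dataclass(frozen=True)
class MuscleParams:
    """Parameters of one Hill-type muscle-tendon unit.

    f_max        maximum isometric force (N)
    l_opt        optimal fiber length (m)
    l_slack      tendon slack length (m)
    v_max        maximum contraction velocity (optimal fiber lengths / s)
    penn         pennation angle (rad)
    tau_act      activation time constant (s)
    tau_deact    deactivation time constant (s)
    """

    name: str
    f_max: float
    l_opt: float
    l_slack: float
    v_max: float = 10.0
    penn: float = 0.0
    tau_act: float = 0.01
    tau_deact: float = 0.04

    def __post_init__(self) -> None:
        if not (self.f_max > 0 and self.l_opt > 0 and self.v_max > 0):
            raise ValueError(f"{self.name}: f_max, l_opt, v_max must be positive")
        if not (0.0 <= self.penn < math.pi / 2):
            raise ValueError(f"{self.name}: pennation must be in [0, pi/2)")
        if not (self.tau_act > 0 and self.tau_deact > 0):
            raise ValueError(f"{self.name}: time constants must be positive")


def activation_step(excitation, activation, dt: float, params: MuscleParams):
    """Advance activation one step of the first-order excitation dynamics.

    Uses the exact exponential update ``a' = u + (a - u) exp(-dt/tau)`` with
    ``tau = tau_act`` while activating (u > a), else ``tau_deact``.  Accepts
    scalars or equal-shaped arrays.  Result stays in [0, 1] and moves
    monotonically toward the excitation.
    """
    u = np.asarray(excitation, dtype=float)
    a = np.asarray(activation, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(a))):
        raise ValueError("non-finite excitation or activation")
    if np.any(u < 0) or np.any(u > 1) or np.any(a < 0) or np.any(a > 1):
        raise ValueError("excitation and activation must lie in [0, 1]")
    tau = np.where(u > a, params.tau_act, params.tau_deact)
    out = u + (a - u) * np.exp(-dt / tau)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def active_force_length(l_norm):
    """Gaussian active force-length curve, fL(1) = 1."""
    l = np.asarray(l_norm, dtype=float)
    return np.exp(-((l - 1.0) ** 2) / FL_GAMMA)


def force_velocity(v_norm):
    """Force-velocity curve; ``v_norm`` < 0 is shortening, in v_max units.

    Shortening branch (Hill hyperbola): (1 + v)/(1 - v/a_f), zero at
    v = -1.  Lengthening branch saturates at ``FV_ECCENTRIC_MAX`` with the
    slope matched at v = 0.
    """
    v = np.asarray(v_norm, dtype=float)
    a_f = FV_SHORTENING_A
    shortening = np.clip(1.0 + v, 0.0, None) / (1.0 - np.minimum(v, 0.0) / a_f)
    slope0 = 1.0 + 1.0 / a_f  # concentric slope at v = 0
    gain = FV_ECCENTRIC_MAX - 1.0
    b = gain / slope0  # matches d fV/dv across v = 0
    vp = np.maximum(v, 0.0)
    lengthening = 1.0 + gain * vp / (vp + b)
    out = np.where(v < 0.0, shortening, lengthening)
    return float(out) if out.ndim == 0 else out


def passive_force_length(l_norm):
    """Exponential passive curve; zero at and below the optimal length."""
    l = np.asarray(l_norm, dtype=float)
    strain = np.maximum(l - 1.0, 0.0)
    out = np.expm1(PE_K * strain / PE_STRAIN) / np.expm1(PE_K)
    return float(out) if out.ndim == 0 else out


def muscle_force(params: MuscleParams, activation, fiber_len, fiber_vel):
    """Fiber force (N) of a rigid-tendon Hill muscle.

    ``fiber_len`` in m (> 0), ``fiber_vel`` in m/s (positive = lengthening).
    Activation must lie in [0, 1].  The force is non-negative: the
    active term is clamped below by the force-velocity zero and the passive
    term is non-negative by construction.
    """
    a = np.asarray(activation, dtype=float)
    l = np.asarray(fiber_len, dtype=float)
    v = np.asarray(fiber_vel, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("activation must lie in [0, 1]")
    if np.any(l <= 0):
        raise ValueError("fiber length must be positive")
    l_norm = l / params.l_opt
    v_norm = v / (params.l_opt * params.v_max)
    f = params.f_max * (
        a * active_force_length(l_norm) * force_velocity(v_norm)
        + passive_force_length(l_norm)
    ) * math.cos(params.penn)
    f = np.maximum(f, 0.0)
    return float(f) if f.ndim == 0 else f
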