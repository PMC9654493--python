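"""Observation vector assembly.

The policy observes a flat numeric vector whose composition is declared by an
:class:`ObservationLayout`: an ordered table of named components with fixed
sizes.  The concatenation order is the layout order.  For the planar model
the components are, in order: segment positions (x, y per body), segment
rotations, linear and rotational velocities, linear and rotational
accelerations, generalized joint positions/velocities/accelerations, muscle
fiber forces, joint-limit torques, and the per-foot ground reaction force
(x, y per foot).

The full 3D source model's published layout (13+13 segment
positions/rotations, the same for velocities and accelerations, 17-entry
joint vectors, 72 muscle-related forces and 13 miscellaneous limit forces,
totalling 214) is available as :data:`PAPER_LAYOUT` for size bookkeeping; it
is not buildable from the planar state and the builder rejects the mismatch
by naming the offending component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ObservationLayout", "PAPER_LAYOUT", "planar_layout", "observation"]


@dataclass(frozen=True)
class ObservationLayout:
    """Ordered (name, size) table defining the observation vector."""

    components: tuple

    @property
    def total(self) -> int:
        return sum(size for _name, size in self.components)

    def sizes(self) -> dict:
        return dict(self.components)


#: the published full-model layout; total 214
PAPER_LAYOUT = ObservationLayout((
    ("segment_pos", 13),
    ("segment_rot", 13),
    ("segment_linvel", 13),
    ("segment_rotvel", 13),
    ("segment_linacc", 13),
    ("segment_rotacc", 13),
    ("joint_pos", 17),
    ("joint_vel", 17),
    ("joint_acc", 17),
    ("muscle_forces", 72),
    ("misc_forces", 13),
))


def planar_layout(engine) -> ObservationLayout:
    """Layout matching the planar engine's state (114 entries by default)."""
    nb = engine.n_bodies
    nm = len(engine.muscles)
    return ObservationLayout((
        ("segment_pos", 2 * nb),
        ("segment_rot", nb),
        ("segment_linvel", 2 * nb),
        ("segment_rotvel", nb),
        ("segment_linacc", 2 * nb),
        ("segment_rotacc", nb),
        ("joint_pos", 9),
        ("joint_vel", 9),
        ("joint_acc", 9),
        ("muscle_forces", nm),
        ("limit_torques", engine.n_pins),
        ("grf", 4),
    ))


def _planar_components(engine, state, info=None):
    q, u, a = state.q, state.u, state.udot
    nb = engine.n_bodies
    xy = np.arange(3 * nb).reshape(nb, 3)[:, :2].ravel()
    th = np.arange(2, 3 * nb, 3)
    gen_acc = np.empty(9)
    gen_acc[0:3] = a[0:3]
    for gi, (p, c, *_rest) in enumerate(engine.pins, start=3):
        gen_acc[gi] = a[3 * c + 2] - a[3 * p + 2]
    grf = np.zeros(4)
    lim = np.zeros(engine.n_pins)
    if info is not None:
        if info.grf:
            grf[0:2] = info.grf["l"][0][0:2]
            grf[2:4] = info.grf["r"][0][0:2]
        if info.limit_torques is not None:
            lim = np.asarray(info.limit_torques, dtype=float)
    return {
        "segment_pos": q[xy],
        "segment_rot": q[th],
        "segment_linvel": u[xy],
        "segment_rotvel": u[th],
        "segment_linacc": a[xy],
        "segment_rotacc": a[th],
        "joint_pos": engine.gen_coords(state),
        "joint_vel": engine.gen_speeds(state),
        "joint_acc": gen_acc,
        "muscle_forces": np.asarray(state.muscle_forces, dtype=float),
        "limit_torques": lim,
        "grf": grf,
    }


def observation(state, engine, layout: ObservationLayout, info=None) -> np.ndarray:
    """Assemble the flat observation vector in layout order.

    ``info`` is the :class:`~stairgait.dynamics.StepInfo` of the last step
    (ground reactions and limit torques); without it those components are
    zero.  A component whose declared size does not match what the model can
    produce is rejected with the component named.
    """
    built = _planar_components(engine, state, info)
    parts = []
    for name, size in layout.components:
        if name not in built:
            raise ValueError(f"layout component {name!r} not computable for this model")
        arr = np.asarray(built[name], dtype=float).ravel()
        if len(arr) != size:
            raise ValueError(
                f"layout component {name!r}: declared size {size}, model produces {len(arr)}"
            )
        parts.append(arr)
    return np.concatenate(parts) if parts else np.zeros(0)
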