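"""Musculoskeletal model description: bodies, joints, muscle paths, presets.

The default model is a reduced planar sagittal biped: seven bodies (a lumped
pelvis+trunk+head segment and thigh/shank/foot per leg) connected by six pin
joints plus a free planar root, giving 9 degrees of freedom, actuated by 14
Hill-type muscles (7 per leg).  The full 3D topology of the source model
(7 bodies, 14 DOF, 18 muscles) is available as a configuration preset for
description and serialization; forward dynamics is implemented for the planar
variant.

Two task presets mirror the experimental setups: ``"stairs"`` (trunk tilted
-15 deg, all maximum isometric forces increased by 80%) and ``"ramp"``
(trunk -5 deg, nominal isometric forces).

Muscle parameter values are not printed by the source model family's short
descriptions; the defaults here are approximate values typical of published
lower-limb models (they are configuration, not claims).  Optimal fiber and
tendon slack lengths are calibrated so each muscle-tendon path sits at its
optimal fiber length in the reference standing pose.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .muscles import MuscleParams

__all__ = [
    "BodySpec",
    "JointSpec",
    "MusclePath",
    "ModelSpec",
    "ModelState",
    "apply_isometric_scaling",
    "planar_model",
    "full_3d_model",
    "load_model",
    "save_model",
    "PLANAR_DOF_NAMES",
]

GRAVITY = 9.80665

#: generalized-coordinate names of the planar variant (derived view of the
#: maximal-coordinate state)
PLANAR_DOF_NAMES = (
    "pelvis_tx",
    "pelvis_ty",
    "pelvis_rot",
    "hip_l",
    "knee_l",
    "ankle_l",
    "hip_r",
    "knee_r",
    "ankle_r",
)


@dataclass(frozen=True)
class BodySpec:
    """Rigid segment: mass (kg), planar inertia about COM (kg m^2), length (m)."""

    name: str
    mass: float
    inertia: float
    length: float


@dataclass(frozen=True)
class JointSpec:
    """Joint between ``parent`` and ``child`` segments.

    ``parent_point`` / ``child_point`` are the joint centre in the respective
    COM-centred body frames (m).  ``q_min``/``q_max`` are soft coordinate
    limits (rad) enforced by a spring-damper limit torque.  Type ``free`` is
    the unconstrained planar root.
    """

    name: str
    kind: str  # "pin" | "free" | "planar"
    parent: str
    child: str
    parent_point: tuple = (0.0, 0.0)
    child_point: tuple = (0.0, 0.0)
    q_min: float = -math.inf
    q_max: float = math.inf


@dataclass(frozen=True)
class MusclePath:
    """A muscle with its straight-line path: (body, local point) attachments.

    The first point is the origin, the last the insertion; intermediate
    entries are via points.  Each path must span at least one joint.
    """

    params: MuscleParams
    points: tuple  # ((body_name, (x, y)), ...)

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError(f"{self.params.name}: path needs >= 2 points")


@dataclass
class ModelSpec:
    """Complete model description (topology + muscles + task configuration)."""

    bodies: list = field(default_factory=list)
    joints: list = field(default_factory=list)
    muscles: list = field(default_factory=list)
    trunk_pelvis_angle: float = 0.0  # deg, fixed trunk tilt of the lumped segment
    isometric_scale: float = 1.0
    name: str = "planar"

    def __post_init__(self) -> None:
        if self.isometric_scale <= 0:
            raise ValueError("isometric_scale must be positive")
        self._check_tree()

    def _check_tree(self) -> None:
        if not self.joints:
            return
        body_names = {b.name for b in self.bodies}
        children = set()
        for j in self.joints:
            if j.kind != "free" and j.parent not in body_names:
                raise ValueError(f"joint {j.name}: unknown parent {j.parent}")
            if j.child not in body_names:
                raise ValueError(f"joint {j.name}: unknown child {j.child}")
            if j.child in children:
                raise ValueError(f"body {j.child} has two parent joints (not a tree)")
            children.add(j.child)

    @property
    def muscle_names(self) -> list:
        return [m.params.name for m in self.muscles]

    @property
    def n_muscles(self) -> int:
        return len(self.muscles)

    def body_index(self, name: str) -> int:
        for i, b in enumerate(self.bodies):
            if b.name == name:
                return i
        raise KeyError(name)


@dataclass
class ModelState:
    """Dynamic state: maximal planar coordinates plus muscle activations.

    ``q``/``u`` hold (x, y, theta) position and velocity per body,
    flattened body-major (3 entries per segment).  ``act`` is the per-muscle
    activation in [0, 1]; ``t`` the simulation time.  ``udot`` caches the
    accelerations of the last dynamics step (zeros before the first step).
    """

    q: np.ndarray
    u: np.ndarray
    act: np.ndarray
    t: float = 0.0
    udot: np.ndarray = None
    muscle_forces: np.ndarray = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.act = np.asarray(self.act, dtype=float)
        if self.udot is None:
            self.udot = np.zeros_like(self.u)
        if self.muscle_forces is None:
            self.muscle_forces = np.zeros_like(self.act)
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.u))):
            raise ValueError("non-finite state")
        if np.any(self.act < 0) or np.any(self.act > 1):
            raise ValueError("activations must lie in [0, 1]")

    def copy(self) -> "ModelState":
        return ModelState(
            self.q.copy(), self.u.copy(), self.act.copy(), self.t,
            self.udot.copy(), self.muscle_forces.copy(),
        )


def apply_isometric_scaling(spec: ModelSpec, factor: float) -> ModelSpec:
    """Return a copy of ``spec`` with every muscle's f_max multiplied by ``factor``.

    All other fields are unchanged.  Composes multiplicatively.
    """
    if factor <= 0:
        raise ValueError("scaling factor must be positive")
    out = copy.deepcopy(spec)
    out.muscles = [
        MusclePath(
            params=MuscleParams(
                name=m.params.name,
                f_max=m.params.f_max * factor,
                l_opt=m.params.l_opt,
                l_slack=m.params.l_slack,
                v_max=m.params.v_max,
                penn=m.params.penn,
                tau_act=m.params.tau_act,
                tau_deact=m.params.tau_deact,
            ),
            points=m.points,
        )
        for m in spec.muscles
    ]
    return out


# ---------------------------------------------------------------------------
# planar preset

# segment dimensions (m) and masses (kg); ~74.5 kg total
_THIGH_LEN = 0.41
_SHANK_LEN = 0.41
_ANKLE_HEIGHT = 0.08
_HIP_DROP = 0.04          # hip joint below the pelvis origin
_PELVIS_HEIGHT = _THIGH_LEN + _SHANK_LEN + _ANKLE_HEIGHT + _HIP_DROP  # 0.94

_SEGMENTS = {
    "pelvis": (46.0, 2.50, 0.50),
    "thigh": (9.3, 9.3 * _THIGH_LEN**2 / 12, _THIGH_LEN),
    "shank": (3.7, 3.7 * _SHANK_LEN**2 / 12, _SHANK_LEN),
    "foot": (1.25, 0.005, 0.20),
}

# joint centres in COM-centred frames
_ANKLE_IN_FOOT = (-0.06, 0.05)
# frames of the paper's hindfoot/forefoot bodies, expressed in the planar
# single-foot frame; the contact spheres keep their printed local offsets
CALCN_IN_FOOT = (-0.115, -0.025)
TOES_IN_FOOT = (0.080, -0.0125)

# soft joint coordinate limits (rad): hip flexion +, knee flexion -, ankle
# dorsiflexion +
_LIMITS = {"hip": (-0.70, 2.10), "knee": (-2.30, 0.02), "ankle": (-0.90, 0.70)}

# per-muscle: f_max (N), l_opt (m), pennation (rad), attachment points.
# Attachments are coarse sagittal-plane anatomy giving physiological moment
# arm signs and magnitudes (a few cm).  Points on the pelvis are given
# relative to the hip joint centre (so they track the trunk-tilt-dependent
# hip anchor); all other points are in the segment's COM frame.
_T2 = _THIGH_LEN / 2
_S2 = _SHANK_LEN / 2
_PLANAR_MUSCLES = {
    # uniarticular hip
    "iliopsoas": (2000.0, 0.11, 0.0, (("pelvis", (0.05, 0.02)), ("thigh", (0.02, _T2 - 0.10)))),
    "glut_max": (1500.0, 0.16, 0.0, (("pelvis", (-0.06, 0.02)), ("thigh", (-0.03, _T2 - 0.12)))),
    # uniarticular knee (vasti via a patella point on the thigh)
    "vasti": (6000.0, 0.09, 0.087, (("thigh", (0.03, 0.0)), ("thigh", (0.045, -_T2 + 0.02)), ("shank", (0.035, _S2 - 0.05)))),
    "bifemsh": (800.0, 0.11, 0.0, (("thigh", (-0.025, 0.0)), ("shank", (-0.03, _S2 - 0.06)))),
    # biarticular hip extensor / knee flexor
    "hamstrings": (3000.0, 0.11, 0.0, (("pelvis", (-0.055, 0.0)), ("shank", (-0.033, _S2 - 0.07)))),
    # ankle
    "soleus": (4000.0, 0.055, 0.44, (("shank", (-0.025, 0.0)), ("foot", (-0.10, 0.02)))),
    "tib_ant": (1000.0, 0.07, 0.10, (("shank", (0.025, -0.05)), ("foot", (0.02, 0.01)))),
}


def _standing_pose_points(trunk_tilt_rad: float):
    """World positions of each body COM and frame in the reference standing pose."""
    hip_anchor = (-0.28 * math.sin(trunk_tilt_rad), -_HIP_DROP)
    pelvis_org = np.array([0.0, _PELVIS_HEIGHT])
    hip = pelvis_org + hip_anchor
    knee = hip + np.array([0.0, -_THIGH_LEN])
    ankle = knee + np.array([0.0, -_SHANK_LEN])
    foot_com = ankle - np.array(_ANKLE_IN_FOOT)
    frames = {
        "pelvis": pelvis_org,
        "thigh": (hip + knee) / 2,
        "shank": (knee + ankle) / 2,
        "foot": foot_com,
    }
    return frames, hip_anchor


def planar_model(variant: str = "stairs") -> ModelSpec:
    """Build the planar 7-body / 9-DOF / 14-muscle model for one task preset.

    ``variant``: ``"stairs"`` (trunk -15 deg, isometric forces x1.8) or
    ``"ramp"`` (trunk -5 deg, x1.0).
    """
    presets = {"stairs": (-15.0, 1.8), "ramp": (-5.0, 1.0)}
    if variant not in presets:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(presets)}")
    trunk_deg, iso_scale = presets[variant]
    tilt = math.radians(trunk_deg)

    bodies = [BodySpec("pelvis", *_SEGMENTS["pelvis"])]
    for side in ("l", "r"):
        for seg in ("thigh", "shank", "foot"):
            bodies.append(BodySpec(f"{seg}_{side}", *_SEGMENTS[seg]))

    frames, hip_anchor = _standing_pose_points(tilt)
    joints = [JointSpec("ground_pelvis", "free", "ground", "pelvis")]
    for side in ("l", "r"):
        joints += [
            JointSpec(f"hip_{side}", "pin", "pelvis", f"thigh_{side}",
                      hip_anchor, (0.0, _THIGH_LEN / 2), *_LIMITS["hip"]),
            JointSpec(f"knee_{side}", "pin", f"thigh_{side}", f"shank_{side}",
                      (0.0, -_THIGH_LEN / 2), (0.0, _SHANK_LEN / 2), *_LIMITS["knee"]),
            JointSpec(f"ankle_{side}", "pin", f"shank_{side}", f"foot_{side}",
                      (0.0, -_SHANK_LEN / 2), _ANKLE_IN_FOOT, *_LIMITS["ankle"]),
        ]

    muscles = []
    for side in ("l", "r"):
        for mname, (f_max, l_opt, penn, path) in _PLANAR_MUSCLES.items():
            pts = tuple(
                (b if b == "pelvis" else f"{b}_{side}",
                 (hip_anchor[0] + p[0], hip_anchor[1] + p[1]) if b == "pelvis" else tuple(p))
                for b, p in path
            )
            # standing path length -> slack length puts the fiber at l_opt
            length = 0.0
            world = [frames[b.split("_")[0] if b != "pelvis" else "pelvis"] + np.asarray(p)
                     for b, p in pts]
            for a, b in zip(world[:-1], world[1:]):
                length += float(np.linalg.norm(b - a))
            l_slack = max(length - l_opt * math.cos(penn), 0.01)
            muscles.append(
                MusclePath(
                    MuscleParams(f"{mname}_{side}", f_max, l_opt, l_slack, penn=penn),
                    pts,
                )
            )

    spec = ModelSpec(
        bodies=bodies,
        joints=joints,
        muscles=muscles,
        trunk_pelvis_angle=trunk_deg,
        isometric_scale=iso_scale,
        name=f"planar_{variant}",
    )
    return apply_isometric_scaling(spec, iso_scale) if iso_scale != 1.0 else spec


# ---------------------------------------------------------------------------
# full 3D preset (configuration/description only)

_FULL_MUSCLES_PER_LEG = (
    # 6 uniarticular + 3 biarticular, as in the source model
    "glut_max", "iliopsoas", "vasti", "bifemsh", "soleus", "tib_ant",
    "hamstrings", "rect_fem", "gastroc",
)


def full_3d_model(variant: str = "stairs") -> ModelSpec:
    """The full 14-DOF / 18-muscle topology as a configuration preset.

    Describes the complete source model (6-DOF pelvis, 2-DOF hips with
    ab/adduction, 1-DOF knees and ankles; 9 muscles per leg including
    rectus femoris and gastrocnemius).  Serializable and inspectable; the
    forward-dynamics engine integrates the planar variant only.
    """
    presets = {"stairs": (-15.0, 1.8), "ramp": (-5.0, 1.0)}
    trunk_deg, iso_scale = presets[variant]
    bodies = [BodySpec("pelvis", *_SEGMENTS["pelvis"])]
    for side in ("l", "r"):
        for seg in ("thigh", "shank", "foot"):
            bodies.append(BodySpec(f"{seg}_{side}", *_SEGMENTS[seg]))
    joints = [JointSpec("ground_pelvis", "free", "ground", "pelvis")]  # 6 DOF in 3D
    for side in ("l", "r"):
        joints += [
            JointSpec(f"hip_{side}", "planar", "pelvis", f"thigh_{side}",
                      (0.0, -_HIP_DROP), (0.0, _THIGH_LEN / 2), *_LIMITS["hip"]),  # 2 DOF
            JointSpec(f"knee_{side}", "pin", f"thigh_{side}", f"shank_{side}",
                      (0.0, -_THIGH_LEN / 2), (0.0, _SHANK_LEN / 2), *_LIMITS["knee"]),
            JointSpec(f"ankle_{side}", "pin", f"shank_{side}", f"foot_{side}",
                      (0.0, -_SHANK_LEN / 2), _ANKLE_IN_FOOT, *_LIMITS["ankle"]),
        ]
    muscles = []
    planar = {**_PLANAR_MUSCLES,
              "rect_fem": (1200.0, 0.08, 0.09, (("pelvis", (0.05, -0.03)), ("shank", (0.035, _S2 - 0.05)))),
              "gastroc": (1500.0, 0.06, 0.30, (("thigh", (-0.02, -_T2 + 0.03)), ("foot", (-0.10, 0.02))))}
    for side in ("l", "r"):
        for mname in _FULL_MUSCLES_PER_LEG:
            f_max, l_opt, penn, path = planar[mname]
            pts = tuple((b if b == "pelvis" else f"{b}_{side}", tuple(p)) for b, p in path)
            muscles.append(
                MusclePath(MuscleParams(f"{mname}_{side}", f_max, l_opt, l_opt, penn=penn), pts)
            )
    spec = ModelSpec(bodies=bodies, joints=joints, muscles=muscles,
                     trunk_pelvis_angle=trunk_deg, isometric_scale=iso_scale,
                     name=f"full3d_{variant}")
    return apply_isometric_scaling(spec, iso_scale) if iso_scale != 1.0 else spec


# ---------------------------------------------------------------------------
# serialization (YAML)


def save_model(spec: ModelSpec, path) -> None:
    doc = {
        "name": spec.name,
        "trunk_pelvis_angle": spec.trunk_pelvis_angle,
        "isometric_scale": spec.isometric_scale,
        "bodies": [asdict(b) for b in spec.bodies],
        "joints": [asdict(j) for j in spec.joints],
        "muscles": [
            {"params": asdict(m.params), "points": [[b, list(p)] for b, p in m.points]}
            for m in spec.muscles
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path) -> ModelSpec:
    """Load a ModelSpec from YAML; the string presets are accepted as paths too."""
    if str(path) in ("stairs", "ramp"):
        return planar_model(str(path))
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return ModelSpec(
        bodies=[BodySpec(**b) for b in doc["bodies"]],
        joints=[JointSpec(**{**j, "parent_point": tuple(j["parent_point"]),
                             "child_point": tuple(j["child_point"])}) for j in doc["joints"]],
        muscles=[
            MusclePath(MuscleParams(**m["params"]),
                       tuple((b, tuple(p)) for b, p in m["points"]))
            for m in doc["muscles"]
        ],
        trunk_pelvis_angle=doc.get("trunk_pelvis_angle", 0.0),
        isometric_scale=doc.get("isometric_scale", 1.0),
        name=doc.get("name", "custom"),
    )
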