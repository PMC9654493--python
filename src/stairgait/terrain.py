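"""Terrain and foot-contact geometry.

Builds the watertight triangle meshes the contact model runs against: a
staircase and a ramp sized to the experimental stair/ramp dimensions (stairs
2 m wide, 3 steps of 0.2 m rise x 0.25 m going; ramp 3.25 m run, 0.45 m rise),
and the spherical foot-contact meshes (a 50 mm heel sphere and two 25 mm toe
spheres per foot).  All meshes are minimal closed triangulations with
consistent outward winding, validated by :func:`validate_mesh`.

Coordinate convention: X forward (direction of progression), Y up, Z to the
model's right.  The pelvis starts at (0, 0.94, 0) m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriMesh",
    "StairSpec",
    "RampSpec",
    "ContactSphereSpec",
    "PlacedSphere",
    "MeshReport",
    "build_stairs",
    "build_ramp",
    "ramp_gradient",
    "ramp_length",
    "build_contact_sphere",
    "foot_geometry",
    "validate_mesh",
    "signed_volume",
    "write_obj",
    "read_obj",
]


@dataclass
class TriMesh:
    """Triangle mesh: ``vertices`` (n, 3) float64 m, ``faces`` (m, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def translated(self, offset) -> "TriMesh":
        return TriMesh(self.vertices + np.asarray(offset, dtype=float), self.faces.copy())

    def face_normals(self) -> np.ndarray:
        """Unit normals per face (right-hand rule on vertex order)."""
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        norms = np.linalg.norm(n, axis=1, keepdims=True)
        norms[norms == 0.0] = 1.0
        return n / norms


@dataclass(frozen=True)
class StairSpec:
    """Staircase: ``n_steps`` steps of ``step_height`` x ``step_depth``, ``width`` wide."""

    n_steps: int = 3
    step_height: float = 0.2
    step_depth: float = 0.25
    width: float = 2.0

    def __post_init__(self) -> None:
        if self.n_steps < 1 or min(self.step_height, self.step_depth, self.width) <= 0:
            raise ValueError("StairSpec fields must be positive")

    @property
    def total_rise(self) -> float:
        return self.n_steps * self.step_height


@dataclass(frozen=True)
class RampSpec:
    """Ramp wedge with horizontal ``run``, vertical ``rise`` and ``width`` (m)."""

    run: float = 3.25
    rise: float = 0.45
    width: float = 2.0

    def __post_init__(self) -> None:
        if min(self.run, self.rise, self.width) <= 0:
            raise ValueError("RampSpec fields must be positive")


@dataclass(frozen=True)
class ContactSphereSpec:
    """UV-sphere contact geometry attached to a foot segment.

    The default granularity (15 longitudinal segments, 8 latitudinal rings)
    triangulates to 107 vertices and 210 faces, the resolution used for the
    foot spheres.
    """

    diameter: float
    center_offset: tuple = (0.0, 0.0, 0.0)
    segments: int = 15
    rings: int = 8

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.segments < 3 or self.rings < 2:
            raise ValueError("need segments >= 3 and rings >= 2")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class PlacedSphere:
    """A contact sphere spec placed on a named foot segment frame."""

    body: str
    spec: ContactSphereSpec


# ---------------------------------------------------------------------------
# builders


def _extrude_polygon(poly_xy: np.ndarray, width: float, fan_center: int) -> TriMesh:
    """Extrude a CCW simple polygon (XY plane) symmetrically along Z.

    Caps are fan-triangulated from ``fan_center`` (polygon must be star-shaped
    from that vertex).  Winding is chosen so all normals point outward.
    """
    poly = np.asarray(poly_xy, dtype=float)
    k = len(poly)
    hw = width / 2.0
    front = np.column_stack([poly, np.full(k, hw)])   # z = +w/2
    back = np.column_stack([poly, np.full(k, -hw)])   # z = -w/2
    verts = np.vstack([front, back])

    faces = []
    c = fan_center
    order = [(c + i) % k for i in range(k)]
    # front cap (+Z): CCW seen from +Z
    for a, b in zip(order[1:-1], order[2:]):
        faces.append((c, a, b))
    # back cap (-Z): reversed winding
    for a, b in zip(order[1:-1], order[2:]):
        faces.append((k + c, k + b, k + a))
    # side walls: edge (i -> j) of the CCW polygon, outward normal to the right
    for i in range(k):
        j = (i + 1) % k
        fi, fj, bi, bj = i, j, k + i, k + j
        faces.append((fi, bj, fj))
        faces.append((fi, bi, bj))
    return TriMesh(verts, np.array(faces))


def build_stairs(spec: StairSpec, origin=(0.0, 0.0, 0.0)) -> TriMesh:
    """Watertight staircase solid rising toward +X, front face at origin x.

    The top surface is the stair profile; total rise is
    ``n_steps * step_height``; the bounding box spans ``spec.width`` in Z.
    """
    n, h, d = spec.n_steps, spec.step_height, spec.step_depth
    # CCW cross-section: along the floor, up the back, then down the steps
    pts = [(0.0, 0.0), (n * d, 0.0), (n * d, n * h)]
    for i in range(n - 1, 0, -1):
        pts.append((i * d, (i + 1) * h))
        pts.append((i * d, i * h))
    pts.append((0.0, h))
    mesh = _extrude_polygon(np.array(pts), spec.width, fan_center=1)
    return mesh.translated(origin)


def build_ramp(spec: RampSpec, origin=(0.0, 0.0, 0.0)) -> TriMesh:
    """Watertight wedge whose inclined top surface spans (0,0) -> (run, rise)."""
    pts = [(0.0, 0.0), (spec.run, 0.0), (spec.run, spec.rise)]
    mesh = _extrude_polygon(np.array(pts), spec.width, fan_center=0)
    return mesh.translated(origin)


def ramp_gradient(spec: RampSpec) -> float:
    """Slope angle atan(rise/run), in degrees."""
    return math.degrees(math.atan2(spec.rise, spec.run))


def ramp_length(spec: RampSpec) -> float:
    """Length of the inclined surface, hypot(run, rise), in metres."""
    return math.hypot(spec.run, spec.rise)


def build_contact_sphere(spec: ContactSphereSpec) -> TriMesh:
    """UV-sphere triangulation centred at ``center_offset``.

    ``segments`` longitudinal slices and ``rings`` latitudinal divisions give
    ``segments * (rings - 1) + 2`` vertices and ``2 * segments * (rings - 1)``
    faces (pole fans plus quad bands split in two).
    """
    s, r = spec.segments, spec.rings
    rad = spec.radius
    c = np.asarray(spec.center_offset, dtype=float)
    verts = [np.array([0.0, rad, 0.0])]  # top pole
    for j in range(1, r):
        theta = math.pi * j / r
        y = rad * math.cos(theta)
        rho = rad * math.sin(theta)
        for i in range(s):
            phi = 2.0 * math.pi * i / s
            verts.append(np.array([rho * math.cos(phi), y, rho * math.sin(phi)]))
    verts.append(np.array([0.0, -rad, 0.0]))  # bottom pole
    verts = np.array(verts) + c

    def ring(j: int, i: int) -> int:  # j in 1..r-1
        return 1 + (j - 1) * s + (i % s)

    bottom = len(verts) - 1
    faces = []
    for i in range(s):  # top fan; CCW seen from outside (+Y looking down)
        faces.append((0, ring(1, i + 1), ring(1, i)))
    for j in range(1, r - 1):  # quad bands
        for i in range(s):
            a, b = ring(j, i), ring(j, i + 1)
            cdn, ddn = ring(j + 1, i), ring(j + 1, i + 1)
            faces.append((a, b, ddn))
            faces.append((a, ddn, cdn))
    for i in range(s):  # bottom fan
        faces.append((bottom, ring(r - 1, i), ring(r - 1, i + 1)))
    return TriMesh(verts, np.array(faces))


#: Paper-geometry sphere placements, in the foot segment frames (m).
_HEEL_OFFSET = (0.030, 0.020, 0.0)  # relative to the hindfoot (calcn) frame
_TOE_OFFSETS = ((0.020, -0.005, -0.026), (0.020, -0.005, 0.026))  # forefoot frame
HEEL_DIAMETER = 0.050
TOE_DIAMETER = 0.025


def foot_geometry(side: str) -> list[PlacedSphere]:
    """The three contact spheres of one foot, placed in segment-local frames.

    The 50 mm heel sphere sits at (30, 20, 0) mm in the hindfoot (calcn)
    frame; the two 25 mm toe spheres at (20, -5, -/+26) mm in the forefoot
    (toes) frame.  Left and right are mirrored in Z.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    mirror = -1.0 if side == "left" else 1.0
    tag = "l" if side == "left" else "r"
    placed = [
        PlacedSphere(
            f"calcn_{tag}",
            ContactSphereSpec(HEEL_DIAMETER, _HEEL_OFFSET),
        )
    ]
    for ox, oy, oz in _TOE_OFFSETS:
        placed.append(
            PlacedSphere(
                f"toes_{tag}",
                ContactSphereSpec(TOE_DIAMETER, (ox, oy, mirror * oz)),
            )
        )
    return placed


# ---------------------------------------------------------------------------
# validation


def signed_volume(mesh: TriMesh) -> float:
    """Signed enclosed volume (positive for consistent outward winding)."""
    v = mesh.vertices
    f = mesh.faces
    return float(np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])).sum() / 6.0)


@dataclass
class MeshReport:
    """Report-only mesh validation result."""

    watertight: bool
    oriented: bool
    volume: float
    boundary_edges: list = field(default_factory=list)
    nonmanifold_edges: list = field(default_factory=list)
    duplicate_vertices: list = field(default_factory=list)
    degenerate_faces: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return (
            self.watertight
            and self.oriented
            and not self.duplicate_vertices
            and not self.degenerate_faces
        )


def validate_mesh(mesh: TriMesh, tol: float = 1e-12) -> MeshReport:
    """Check watertightness, winding consistency, duplicates and degeneracy.

    Watertight: every undirected edge shared by exactly two faces.  Oriented:
    each undirected edge appears once in each direction (consistent winding)
    and the signed volume is positive (outward normals).
    """
    f = mesh.faces
    v = mesh.vertices

    directed: dict[tuple[int, int], int] = {}
    for tri in f:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            directed[(int(a), int(b))] = directed.get((int(a), int(b)), 0) + 1

    undirected: dict[tuple[int, int], int] = {}
    for (a, b), cnt in directed.items():
        key = (min(a, b), max(a, b))
        undirected[key] = undirected.get(key, 0) + cnt

    boundary = [e for e, c in undirected.items() if c == 1]
    nonmanifold = [e for e, c in undirected.items() if c > 2]
    watertight = not boundary and not nonmanifold

    consistent = all(c == 1 for c in directed.values()) and all(
        directed.get((b, a), 0) == 1 for (a, b) in directed
    )
    vol = signed_volume(mesh)
    oriented = consistent and vol > 0

    # duplicate vertices (exact coordinate match)
    seen: dict[bytes, int] = {}
    duplicates = []
    for i, p in enumerate(v):
        key = p.tobytes()
        if key in seen:
            duplicates.append((seen[key], i))
        else:
            seen[key] = i
    areas = 0.5 * np.linalg.norm(
        np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]]), axis=1
    )
    degenerate = list(np.nonzero(areas <= tol)[0])

    return MeshReport(
        watertight=watertight,
        oriented=oriented,
        volume=vol,
        boundary_edges=boundary,
        nonmanifold_edges=nonmanifold,
        duplicate_vertices=duplicates,
        degenerate_faces=degenerate,
    )


# ---------------------------------------------------------------------------
# OBJ input/output (triangles only, 1-based indices, no materials)


def write_obj(mesh: TriMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("# stairgait terrain mesh\n")
        for x, y, z in mesh.vertices:
            fh.write(f"v {x:.17g} {y:.17g} {z:.17g}\n")
        for a, b, c in mesh.faces:
            fh.write(f"f {a + 1} {b + 1} {c + 1}\n")


def read_obj(path) -> TriMesh:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
                if len(idx) != 3:
                    raise ValueError(f"line {lineno}: only triangle faces are supported")
                faces.append(idx)
    if not verts or not faces:
        raise ValueError("OBJ file contains no triangle mesh")
    return TriMesh(np.array(verts), np.array(faces))
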