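"""Idealized venous geometries and mesh utilities.

The package analyses flow in synthetic stand-ins for the cerebral venous
outflow tract (torcular -> transverse/sigmoid sinuses -> jugular bulb):
straight tubes, torus-segment bends, Y bifurcations and a 2-D stenotic
channel.  Volume meshes are linear tetrahedra built by sweeping a graded
polar disk along the centerline; the wall surface is the boundary of the
tet mesh, so surface and volume are conforming by construction.

Units: CGS (cm).  Tube inlets face +z by convention.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "TriSurfaceMesh",
    "TetVolumeMesh",
    "PlaneSection",
    "RegionOfInterest",
    "StructuredGrid2D",
    "make_cylinder",
    "make_curved_tube",
    "make_bifurcation",
    "make_channel2d",
    "make_flat_patch",
    "cross_section_area",
    "clip_roi",
]

# boundary_id labels on surface triangles
WALL = 0
INLET = 1
OUTLET_LEFT = 2
OUTLET_RIGHT = 3
OUTLET = 2  # single-outlet shapes use the "left" slot
JUNCTION = 9  # internal coupling caps of composite shapes


# ---------------------------------------------------------------------------
# mesh containers
# ---------------------------------------------------------------------------

@dataclass
class TriSurfaceMesh:
    """Triangulated wall surface with per-triangle boundary labels."""

    nodes: np.ndarray           # (N, 3) cm
    triangles: np.ndarray       # (M, 3) node indices
    boundary_id: np.ndarray = None  # (M,) int labels; 0 = wall

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.boundary_id is None:
            self.boundary_id = np.zeros(len(self.triangles), dtype=np.int64)
        else:
            self.boundary_id = np.asarray(self.boundary_id, dtype=np.int64)
        if self.triangles.size and self.triangles.max() >= len(self.nodes):
            raise ValueError("triangle references a node index out of range")
        if self.triangles.min(initial=0) < 0:
            raise ValueError("negative node index in triangles")
        if len(self.boundary_id) != len(self.triangles):
            raise ValueError("boundary_id must have one label per triangle")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_points(self) -> np.ndarray:
        """(M, 3, 3) corner coordinates."""
        return self.nodes[self.triangles]

    def triangle_normals(self) -> np.ndarray:
        """Unit normals following the stored (outward) winding."""
        p = self.triangle_points()
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        norms = np.linalg.norm(n, axis=1, keepdims=True)
        norms[norms == 0.0] = 1.0
        return n / norms

    def triangle_areas(self) -> np.ndarray:
        p = self.triangle_points()
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def triangle_centroids(self) -> np.ndarray:
        return self.triangle_points().mean(axis=1)

    def node_normals(self) -> np.ndarray:
        """Area-weighted unit normals at nodes."""
        tn = self.triangle_normals() * self.triangle_areas()[:, None]
        out = np.zeros_like(self.nodes)
        for k in range(3):
            np.add.at(out, self.triangles[:, k], tn)
        norms = np.linalg.norm(out, axis=1, keepdims=True)
        norms[norms == 0.0] = 1.0
        return out / norms

    def select(self, boundary_id: int) -> np.ndarray:
        """Indices of triangles carrying the given boundary label."""
        return np.flatnonzero(self.boundary_id == boundary_id)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriSurfaceMesh":
        return TriSurfaceMesh(
            nodes=self.nodes @ np.asarray(rotation).T + np.asarray(translation),
            triangles=self.triangles.copy(),
            boundary_id=self.boundary_id.copy(),
        )


@dataclass
class TetVolumeMesh:
    """Linear tetrahedral volume mesh with a map onto its wall surface.

    ``wall_map[i]`` is the volume-node index of surface node ``i`` of the
    companion :class:`TriSurfaceMesh`.  All tets have positive signed volume.
    """

    nodes: np.ndarray          # (N, 3) cm
    tets: np.ndarray           # (M, 4) node indices
    wall_map: np.ndarray = None  # (n_surface_nodes,) volume node indices
    cell_region: np.ndarray = None  # optional per-tet region label

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        if self.wall_map is not None:
            self.wall_map = np.asarray(self.wall_map, dtype=np.int64)
            if len(np.unique(self.wall_map)) != len(self.wall_map):
                raise ValueError("wall_map must be injective")
        if self.cell_region is not None:
            self.cell_region = np.asarray(self.cell_region, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        return np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        ) / 6.0

    def total_volume(self) -> float:
        return float(self.tet_volumes().sum())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TetVolumeMesh":
        return TetVolumeMesh(
            nodes=self.nodes @ np.asarray(rotation).T + np.asarray(translation),
            tets=self.tets.copy(),
            wall_map=None if self.wall_map is None else self.wall_map.copy(),
            cell_region=None if self.cell_region is None else self.cell_region.copy(),
        )


@dataclass(frozen=True)
class PlaneSection:
    """An oriented cut plane defined by a point and a unit normal."""

    origin: Tuple[float, float, float]
    normal: Tuple[float, float, float]

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0.0:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "normal", tuple(n / norm))
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (p - np.asarray(self.origin)) @ np.asarray(self.normal)


@dataclass
class RegionOfInterest:
    """A subset of wall triangles (e.g. the jugular-bulb analog) with a side tag."""

    triangle_ids: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.triangle_ids = np.unique(np.asarray(self.triangle_ids, dtype=np.int64))
        if self.triangle_ids.size == 0:
            raise ValueError("region of interest is empty")


@dataclass
class StructuredGrid2D:
    """Uniform 2-D cell grid for the channel solver.

    Cells are squares of side ``spacing``; ``mask[j, i]`` is True where the
    cell is fluid.  Flow enters through the left column and leaves through the
    right column (zero-pressure outlet).
    """

    nx: int
    ny: int
    spacing: float
    mask: np.ndarray  # (ny, nx) bool

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.ny, self.nx):
            raise ValueError("mask shape must be (ny, nx)")
        if not self.mask[:, 0].any() or not self.mask[:, -1].any():
            raise ValueError("grid needs fluid cells on both the inlet and outlet columns")

    @property
    def length(self) -> float:
        return self.nx * self.spacing

    @property
    def height(self) -> float:
        return self.ny * self.spacing

    def cell_centers(self) -> np.ndarray:
        """(ny*nx, 3) cell-center coordinates (z = 0), row-major."""
        x = (np.arange(self.nx) + 0.5) * self.spacing
        y = (np.arange(self.ny) + 0.5) * self.spacing
        X, Y = np.meshgrid(x, y)
        return np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])

    def min_gap(self) -> float:
        """Smallest open fluid height across any column."""
        return float(self.mask.sum(axis=0).min() * self.spacing)


# ---------------------------------------------------------------------------
# swept-tube meshing machinery
# ---------------------------------------------------------------------------

def _disk_layout(radius: float, n_theta: int, n_r: int) -> Tuple[np.ndarray, np.ndarray]:
    """Polar triangulation of a disk: center node + n_r rings of n_theta nodes.

    Radial positions follow r_k = R sin(pi k / (2 n_r)), which grades the mesh
    toward the wall so that near-wall velocity gradients (hence WSS) are
    recovered accurately from cell-constant gradients.
    """
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    pts = [np.zeros((1, 2))]
    for k in range(1, n_r + 1):
        r = radius * np.sin(0.5 * np.pi * k / n_r)
        pts.append(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
    points = np.vstack(pts)

    tris = []
    # fan from center to ring 1
    ring1 = 1 + np.arange(n_theta)
    for j in range(n_theta):
        tris.append([0, ring1[j], ring1[(j + 1) % n_theta]])
    # annuli
    for k in range(1, n_r):
        inner = 1 + (k - 1) * n_theta + np.arange(n_theta)
        outer = 1 + k * n_theta + np.arange(n_theta)
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            tris.append([inner[j], outer[j], outer[jn]])
            tris.append([inner[j], outer[jn], inner[jn]])
    return points, np.asarray(tris, dtype=np.int64)


# Dompierre et al. indirection: rotate the prism so its smallest-index vertex
# is local vertex 0, preserving the prism structure and orientation.
_PRISM_ROTATIONS = np.array(
    [
        [0, 1, 2, 3, 4, 5],
        [1, 2, 0, 4, 5, 3],
        [2, 0, 1, 5, 3, 4],
        [3, 5, 4, 0, 2, 1],
        [4, 3, 5, 1, 0, 2],
        [5, 4, 3, 2, 1, 0],
    ],
    dtype=np.int64,
)


def _split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split prisms (n, 6) into conforming tets (3n, 4).

    Quad-face diagonals pass through each face's smallest global node index,
    which makes the splits of face-sharing prisms agree.
    """
    n = len(prisms)
    rot = _PRISM_ROTATIONS[np.argmin(prisms, axis=1)]
    p = np.take_along_axis(prisms, rot, axis=1)
    cond = np.minimum(p[:, 1], p[:, 5]) < np.minimum(p[:, 2], p[:, 4])
    tets = np.empty((n, 3, 4), dtype=np.int64)
    # case A: diagonal v1-v5
    a = cond
    tets[a, 0] = p[a][:, [0, 1, 2, 5]]
    tets[a, 1] = p[a][:, [0, 1, 5, 4]]
    tets[a, 2] = p[a][:, [0, 4, 5, 3]]
    # case B: diagonal v2-v4
    b = ~cond
    tets[b, 0] = p[b][:, [0, 1, 2, 4]]
    tets[b, 1] = p[b][:, [0, 4, 2, 5]]
    tets[b, 2] = p[b][:, [0, 4, 5, 3]]
    return tets.reshape(-1, 4)


def _fix_tet_orientation(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = nodes[tets]
    vol = np.einsum(
        "ij,ij->i",
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        p[:, 3] - p[:, 0],
    )
    flip = vol < 0
    tets = tets.copy()
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    return tets


_TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])


def boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Outward-oriented boundary triangles of a positively oriented tet mesh."""
    faces = tets[:, _TET_FACES].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def _sweep_tube(
    radius: float,
    centers: np.ndarray,     # (L, 3) centerline points
    e1: np.ndarray,          # (L, 3) first in-plane frame vector
    e2: np.ndarray,          # (L, 3) second in-plane frame vector
    n_theta: int,
    n_r: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Volume nodes + tets of a tube swept along a framed centerline."""
    disk, disk_tris = _disk_layout(radius, n_theta, n_r)
    n_layers = len(centers)
    n_disk = len(disk)
    nodes = (
        centers[:, None, :]
        + disk[None, :, 0, None] * e1[:, None, :]
        + disk[None, :, 1, None] * e2[:, None, :]
    ).reshape(-1, 3)
    prisms = []
    for layer in range(n_layers - 1):
        lo = layer * n_disk
        hi = (layer + 1) * n_disk
        prisms.append(
            np.column_stack([disk_tris + lo, disk_tris + hi])
        )
    tets = _split_prisms(np.vstack(prisms))
    tets = _fix_tet_orientation(nodes, tets)
    return nodes, tets


def _surface_from_volume(
    nodes: np.ndarray,
    tets: np.ndarray,
    classify_cap,
) -> Tuple[TriSurfaceMesh, np.ndarray]:
    """Extract the boundary surface and compacted wall_map.

    ``classify_cap(centroids, normals) -> labels`` assigns boundary ids.
    """
    faces = boundary_faces(tets)
    used = np.unique(faces)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    tri = remap[faces]
    surf_nodes = nodes[used]
    surf = TriSurfaceMesh(nodes=surf_nodes, triangles=tri)
    surf.boundary_id = classify_cap(surf.triangle_centroids(), surf.triangle_normals())
    return surf, used


def _axis_cap_classifier(axis_starts, axis_dirs, labels, z_lo, z_hi, tol=1e-6):
    """Label caps whose normals align with a tube axis at its ends."""
    def classify(centroids: np.ndarray, normals: np.ndarray) -> np.ndarray:
        out = np.full(len(centroids), WALL, dtype=np.int64)
        for start, d, (lab_lo, lab_hi), lo, hi in zip(axis_starts, axis_dirs, labels, z_lo, z_hi):
            d = np.asarray(d, float)
            s = (centroids - np.asarray(start, float)) @ d
            aligned = np.abs(normals @ d) > 1.0 - 1e-6
            out[aligned & (s < lo + tol)] = lab_lo
            out[aligned & (s > hi - tol)] = lab_hi
        return out

    return classify


def _tube_resolution(radius: float, length: float, resolution: int) -> Tuple[int, int, int]:
    n_theta = int(resolution)
    n_r = max(3, n_theta // 8)
    dz = 2.0 * np.pi * radius / n_theta
    n_z = int(np.clip(np.ceil(length / dz), 4, 64))
    return n_theta, n_r, n_z


# ---------------------------------------------------------------------------
# shape generators
# ---------------------------------------------------------------------------

def make_cylinder(
    radius: float, length: float, resolution: int = 32
) -> Tuple[TriSurfaceMesh, TetVolumeMesh]:
    """Straight tube along +z from z=0 (inlet) to z=length (outlet)."""
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be positive")
    if resolution < 8:
        raise ValueError(f"resolution must be >= 8, got {resolution}")
    n_theta, n_r, n_z = _tube_resolution(radius, length, resolution)
    z = np.linspace(0.0, length, n_z + 1)
    centers = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    e1 = np.tile([1.0, 0.0, 0.0], (len(z), 1))
    e2 = np.tile([0.0, 1.0, 0.0], (len(z), 1))
    nodes, tets = _sweep_tube(radius, centers, e1, e2, n_theta, n_r)
    surf, wall_map = _surface_from_volume(
        nodes,
        tets,
        _axis_cap_classifier(
            [(0, 0, 0)], [(0, 0, 1)], [(INLET, OUTLET)], [0.0], [length]
        ),
    )
    vol = TetVolumeMesh(nodes=nodes, tets=tets, wall_map=wall_map)
    return surf, vol


def make_curved_tube(
    radius: float,
    bend_radius: float,
    bend_angle: float,
    resolution: int = 32,
) -> Tuple[TriSurfaceMesh, TetVolumeMesh]:
    """Torus-segment tube bending in the x-z plane.

    The inlet sits at the origin facing +z; the centerline follows
    c(phi) = (Rb (1-cos phi), 0, Rb sin phi) up to ``bend_angle`` degrees,
    so a 180-degree bend places inlet and outlet 2*Rb apart.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if bend_radius <= radius:
        raise ValueError("bend_radius must exceed the tube radius")
    if not (0.0 < bend_angle <= 180.0):
        raise ValueError("bend_angle must lie in (0, 180] degrees")
    ang = np.radians(bend_angle)
    arc_len = bend_radius * ang
    n_theta, n_r, n_z = _tube_resolution(radius, arc_len, resolution)
    phi = np.linspace(0.0, ang, n_z + 1)
    centers = np.column_stack(
        [bend_radius * (1.0 - np.cos(phi)), np.zeros_like(phi), bend_radius * np.sin(phi)]
    )
    # frame: e1 radial in the bend plane, e2 = y
    e1 = np.column_stack([np.cos(phi), np.zeros_like(phi), -np.sin(phi)])
    e2 = np.tile([0.0, 1.0, 0.0], (len(phi), 1))
    nodes, tets = _sweep_tube(radius, centers, e1, e2, n_theta, n_r)

    t_in = np.array([0.0, 0.0, 1.0])
    t_out = np.array([np.sin(ang), 0.0, np.cos(ang)])
    c_in = centers[0]
    c_out = centers[-1]

    def classify(centroids: np.ndarray, normals: np.ndarray) -> np.ndarray:
        out = np.full(len(centroids), WALL, dtype=np.int64)
        # caps have normals along a tube-end tangent; assign each aligned
        # triangle to the nearest end (projection alone is ambiguous at 180°)
        aligned = (np.abs(normals @ t_in) > 1 - 1e-6) | (
            np.abs(normals @ t_out) > 1 - 1e-6
        )
        d_in = np.linalg.norm(centroids - c_in, axis=1)
        d_out = np.linalg.norm(centroids - c_out, axis=1)
        near_cap = np.minimum(d_in, d_out) < 1.5 * radius
        out[aligned & near_cap & (d_in <= d_out)] = INLET
        out[aligned & near_cap & (d_in > d_out)] = OUTLET
        return out

    surf, wall_map = _surface_from_volume(nodes, tets, classify)
    vol = TetVolumeMesh(nodes=nodes, tets=tets, wall_map=wall_map)
    return surf, vol


def make_branch_tube(
    radius: float,
    length: float,
    origin: Sequence[float],
    direction: Sequence[float],
    resolution: int = 32,
    inlet_label: int = INLET,
    outlet_label: int = OUTLET,
) -> Tuple[TriSurfaceMesh, TetVolumeMesh]:
    """Straight tube of given axis; building block for composite shapes."""
    surf, vol = make_cylinder(radius, length, resolution)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    # rotation taking +z to d
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, d)
    c = float(z @ d)
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx / (1.0 + c)
    old_bid = surf.boundary_id.copy()
    surf = surf.transformed(R, np.asarray(origin, float))
    vol2 = vol.transformed(R, np.asarray(origin, float))
    bid = np.full_like(old_bid, WALL)
    bid[old_bid == INLET] = inlet_label
    bid[old_bid == OUTLET] = outlet_label
    surf.boundary_id = bid
    vol2.wall_map = vol.wall_map
    return surf, vol2


def _merge_pieces(pieces) -> Tuple[TriSurfaceMesh, TetVolumeMesh]:
    """Concatenate (surface, volume, region_label) pieces into one mesh pair."""
    all_nodes, all_tets, all_regions = [], [], []
    s_nodes, s_tris, s_bid = [], [], []
    node_off = 0
    snode_off = 0
    wall_maps = []
    for surf, vol, region in pieces:
        all_nodes.append(vol.nodes)
        all_tets.append(vol.tets + node_off)
        all_regions.append(np.full(vol.n_tets, region, dtype=np.int64))
        s_nodes.append(surf.nodes)
        s_tris.append(surf.triangles + snode_off)
        s_bid.append(surf.boundary_id)
        wall_maps.append(vol.wall_map + node_off)
        node_off += vol.n_nodes
        snode_off += surf.n_nodes
    surf = TriSurfaceMesh(
        nodes=np.vstack(s_nodes),
        triangles=np.vstack(s_tris),
        boundary_id=np.concatenate(s_bid),
    )
    vol = TetVolumeMesh(
        nodes=np.vstack(all_nodes),
        tets=np.vstack(all_tets),
        wall_map=np.concatenate(wall_maps),
        cell_region=np.concatenate(all_regions),
    )
    return surf, vol


def make_bifurcation(
    trunk_radius: float,
    branch_radius_left: float,
    branch_radius_right: float,
    half_angle: float,
    trunk_length: Optional[float] = None,
    branch_length: Optional[float] = None,
    resolution: int = 32,
) -> Tuple[TriSurfaceMesh, TetVolumeMesh]:
    """Y geometry: one inlet trunk dividing into left/right outflow branches.

    An idealized analog of the torcular dividing into the paired transverse/
    sigmoid sinuses.  The three tube pieces meet at the trunk-top plane; the
    junction caps carry boundary label 9 and the pieces' volume meshes are
    labelled 0 (trunk), 1 (left), 2 (right) in ``cell_region``.  "Left" is
    the -x side.
    """
    for r, name in [
        (trunk_radius, "trunk_radius"),
        (branch_radius_left, "branch_radius_left"),
        (branch_radius_right, "branch_radius_right"),
    ]:
        if r <= 0:
            raise ValueError(f"{name} must be positive")
    if not (10.0 <= half_angle <= 80.0):
        raise ValueError("half_angle must lie in [10, 80] degrees")
    if trunk_length is None:
        trunk_length = 4.0 * trunk_radius
    if branch_length is None:
        branch_length = 8.0 * max(branch_radius_left, branch_radius_right)

    a = np.radians(half_angle)
    apex = np.array([0.0, 0.0, trunk_length])
    d_left = np.array([-np.sin(a), 0.0, np.cos(a)])
    d_right = np.array([np.sin(a), 0.0, np.cos(a)])

    trunk_s, trunk_v = make_cylinder(trunk_radius, trunk_length, resolution)
    # trunk outlet cap becomes an internal junction cap
    trunk_s.boundary_id[trunk_s.boundary_id == OUTLET] = JUNCTION

    left_s, left_v = make_branch_tube(
        branch_radius_left, branch_length, apex, d_left, resolution,
        inlet_label=JUNCTION, outlet_label=OUTLET_LEFT,
    )
    right_s, right_v = make_branch_tube(
        branch_radius_right, branch_length, apex, d_right, resolution,
        inlet_label=JUNCTION, outlet_label=OUTLET_RIGHT,
    )
    return _merge_pieces(
        [(trunk_s, trunk_v, 0), (left_s, left_v, 1), (right_s, right_v, 2)]
    )


def make_channel2d(
    length: float,
    height: float,
    stenosis_fraction: float = 0.0,
    stenosis_center: Optional[float] = None,
    ny: int = 32,
    bump_width: Optional[float] = None,
) -> StructuredGrid2D:
    """2-D channel with a smooth cosine-bump constriction on the bottom wall.

    The bump height is ``stenosis_fraction * height`` so the minimum gap is
    ``height * (1 - stenosis_fraction)``.
    """
    if length <= 0 or height <= 0:
        raise ValueError("length and height must be positive")
    if not (0.0 <= stenosis_fraction <= 0.8):
        raise ValueError("stenosis_fraction must lie in [0, 0.8]")
    if stenosis_center is None:
        stenosis_center = 0.5 * length
    if bump_width is None:
        bump_width = min(length / 3.0, 4.0 * height)
    h = height / ny
    nx = max(4, int(round(length / h)))
    x = (np.arange(nx) + 0.5) * h
    y = (np.arange(ny) + 0.5) * h
    amp = stenosis_fraction * height
    prof = np.where(
        np.abs(x - stenosis_center) < 0.5 * bump_width,
        0.5 * amp * (1.0 + np.cos(2.0 * np.pi * (x - stenosis_center) / bump_width)),
        0.0,
    )
    mask = y[:, None] > prof[None, :]
    return StructuredGrid2D(nx=nx, ny=ny, spacing=h, mask=mask)


def make_flat_patch(
    width: float, height: float, resolution: int = 16, origin=(0.0, 0.0, 0.0)
) -> TriSurfaceMesh:
    """Flat rectangular patch in the z=0 plane, normal +z.

    Convenience surface for planting and testing WSS critical-point patterns
    in a controlled tangent plane.
    """
    nx = ny = max(2, int(resolution))
    xs = np.linspace(-0.5 * width, 0.5 * width, nx + 1) + origin[0]
    ys = np.linspace(-0.5 * height, 0.5 * height, ny + 1) + origin[1]
    X, Y = np.meshgrid(xs, ys)
    nodes = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, origin[2])])
    tris = []
    for j in range(ny):
        for i in range(nx):
            a = j * (nx + 1) + i
            b = a + 1
            c = a + nx + 1
            d = c + 1
            # alternate diagonals so plants at grid nodes see a symmetric star
            if (i + j) % 2 == 0:
                tris.append([a, b, d])
                tris.append([a, d, c])
            else:
                tris.append([a, b, c])
                tris.append([b, d, c])
    return TriSurfaceMesh(nodes=nodes, triangles=np.asarray(tris))


# ---------------------------------------------------------------------------
# sections and regions of interest
# ---------------------------------------------------------------------------

def cross_section_area(mesh: TetVolumeMesh, plane: PlaneSection) -> float:
    """Area of the lumen polygon cut by a plane.

    Each tetrahedron straddling the plane contributes its intersection
    polygon; disconnected cuts (e.g. a stenotic throat splitting the lumen)
    are summed.  Returns 0 with a warning when the plane misses the mesh.
    """
    d = plane.signed_distance(mesh.nodes)
    # nodes exactly on the plane: nudge to one side so that a plane through a
    # mesh layer still cuts each tet exactly once (simulation of simplicity)
    scale = float(np.abs(d).max()) or 1.0
    d = np.where(d == 0.0, 1e-12 * scale, d)
    td = d[mesh.tets]
    straddle = (td.min(axis=1) < 0.0) & (td.max(axis=1) > 0.0)
    if not np.any(straddle):
        warnings.warn("plane does not intersect the mesh; area = 0", stacklevel=2)
        return 0.0
    n = np.asarray(plane.normal)
    # in-plane basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(n @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)

    edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    total = 0.0
    for tet, dist in zip(mesh.tets[straddle], td[straddle]):
        pts = []
        for i, j in edges:
            di, dj = dist[i], dist[j]
            if (di < 0) != (dj < 0):
                t = di / (di - dj)
                pts.append(mesh.nodes[tet[i]] * (1 - t) + mesh.nodes[tet[j]] * t)
            elif di == 0.0 and dj != 0.0:
                pts.append(mesh.nodes[tet[i]])
        if len(pts) < 3:
            continue
        pts = np.unique(np.round(np.asarray(pts), 12), axis=0)
        if len(pts) < 3:
            continue
        uv = np.column_stack([pts @ e1, pts @ e2])
        ctr = uv.mean(axis=0)
        order = np.argsort(np.arctan2(uv[:, 1] - ctr[1], uv[:, 0] - ctr[0]))
        uv = uv[order]
        x, y = uv[:, 0], uv[:, 1]
        total += 0.5 * abs(
            np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
        )
    return float(total)


def triangle_adjacency_components(mesh: TriSurfaceMesh, subset: np.ndarray) -> np.ndarray:
    """Connected-component label per subset triangle (edge adjacency)."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    tris = mesh.triangles[subset]
    m = len(tris)
    edges = {}
    rows, cols = [], []
    for ti in range(m):
        t = tris[ti]
        for a, b in ((0, 1), (1, 2), (2, 0)):
            key = (min(t[a], t[b]), max(t[a], t[b]))
            if key in edges:
                rows.append(edges[key])
                cols.append(ti)
            else:
                edges[key] = ti
    if rows:
        g = coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(m, m)
        )
    else:
        g = coo_matrix((m, m))
    _, labels = connected_components(g, directed=False)
    return labels


def clip_roi(
    mesh: TriSurfaceMesh,
    plane_a: PlaneSection,
    plane_b: PlaneSection,
    exclude_seed: Optional[int] = None,
    label: str = "",
    wall_only: bool = True,
) -> RegionOfInterest:
    """Wall triangles whose centroids lie in the slab between two planes.

    The slab is ``{x : d_a(x) >= 0 and d_b(x) < 0}`` with both plane normals
    pointing from plane_a toward plane_b.  If ``exclude_seed`` (a node id)
    is given, the connected component of slab triangles containing that node
    is removed — used to exclude an occipital-sinus analog from the
    jugular-bulb region.
    """
    cent = mesh.triangle_centroids()
    da = plane_a.signed_distance(cent)
    db = plane_b.signed_distance(cent)
    keep = (da >= 0.0) & (db < 0.0)
    if wall_only:
        keep &= mesh.boundary_id == WALL
    ids = np.flatnonzero(keep)
    if ids.size == 0:
        raise ValueError("the two planes bound an empty slab on this mesh")
    if exclude_seed is not None:
        labels = triangle_adjacency_components(mesh, ids)
        seed_tris = np.flatnonzero(
            np.any(mesh.triangles[ids] == exclude_seed, axis=1)
        )
        if seed_tris.size:
            bad = set(labels[seed_tris])
            ids = ids[~np.isin(labels, list(bad))]
        if ids.size == 0:
            raise ValueError("exclusion removed every triangle in the slab")
    return RegionOfInterest(triangle_ids=ids, label=label)
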