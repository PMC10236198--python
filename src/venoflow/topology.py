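"""Higher-order flow-complexity metrics: WSS critical points and vortex core lines.

A critical point is a zero of the tangential WSS vector field; near such
points the WSS direction and magnitude change drastically, which is the
endothelium-relevant signature of disturbed flow.  On a triangulated wall
the nodal vectors define a barycentric-linear 2-vector field per element;
its unique zero, when it falls strictly inside the element, is a critical
point located exactly (linear interpolation).  The local 2x2 Jacobian
classifies it: saddle (det < 0, Poincare index -1), node or focus
(sources/sinks, index +1) and, degenerately, a center.

Vortex core lines are extracted with the parallel-vectors method of Sujudi
and Haimes on linear tetrahedra: in each element whose velocity-gradient
tensor has one real and two complex-conjugate eigenvalues, the locus where
the velocity is parallel to the real eigenvector is a straight segment
clipped by the element faces.  The cycle-averaged total length ("corelen")
measures flow-pattern complexity.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .fields import SurfaceVectorSeries, TimeSeriesField
from .geometry import RegionOfInterest, TetVolumeMesh, TriSurfaceMesh

__all__ = [
    "CriticalPoint",
    "CoreLineSet",
    "TopologySummary",
    "classify_critical_point",
    "find_critical_points",
    "n_critical_points_mean",
    "extract_core_lines",
    "corelen_mean",
]

#: default magnitude prefilter on nodal |tau| for candidate elements (dyne/cm^2)
DEFAULT_THRESHOLD = 1e-5


@dataclass(frozen=True)
class CriticalPoint:
    """A located zero of the surface WSS field."""

    position: Tuple[float, float, float]
    element_id: int
    phase_index: int
    cls: str               # source node/sink node/source focus/sink focus/saddle/center
    poincare_index: int    # +1 except saddles (-1)
    jacobian_det: float = 0.0


@dataclass
class CoreLineSet:
    """Vortex core polylines at one phase."""

    polylines: List[np.ndarray]
    phase_index: int = 0

    @property
    def total_length(self) -> float:
        return float(
            sum(np.linalg.norm(np.diff(p, axis=0), axis=1).sum() for p in self.polylines)
        )

    @property
    def n_lines(self) -> int:
        return len(self.polylines)


@dataclass
class TopologySummary:
    """Cycle-characterizing topology scalars."""

    n_critical_points_mean: float
    corelen_mean: float
    per_phase_counts: List[int] = field(default_factory=list)
    per_phase_lengths: List[float] = field(default_factory=list)


def classify_critical_point(
    jacobian: np.ndarray, tolerance: float = 1e-6
) -> Tuple[str, int]:
    """Classify a 2x2 in-plane linearization.

    det < 0 -> saddle (index -1); complex eigenvalues -> focus (source/sink by
    the sign of the real part, a center when |Re| <= tolerance * |Im|); real
    eigenvalues of one sign -> node.  A near-singular Jacobian is flagged as
    ``degenerate`` (index 0) and excluded from counts.
    """
    J = np.asarray(jacobian, dtype=float)
    scale = max(np.abs(J).max(), 1e-300)
    det = float(np.linalg.det(J))
    tr = float(np.trace(J))
    if abs(det) < tolerance * scale**2:
        return "degenerate", 0
    if det < 0:
        return "saddle", -1
    disc = tr * tr - 4.0 * det
    if disc < 0:
        im = 0.5 * np.sqrt(-disc)
        re = 0.5 * tr
        if abs(re) <= tolerance * im:
            return "center", 1
        return ("source focus", 1) if re > 0 else ("sink focus", 1)
    return ("source node", 1) if tr > 0 else ("sink node", 1)


def _element_zero(p2, v2):
    """Zero of the barycentric-linear 2-vector field on one triangle.

    Returns (lambda1, lambda2, J) where J is the in-plane Jacobian, or None
    if the linear system is singular.
    """
    M = np.column_stack([v2[1] - v2[0], v2[2] - v2[0]])
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    scale = max(np.abs(M).max(), 1e-300)
    if abs(det) <= 1e-14 * scale**2:
        return None
    lam = np.linalg.solve(M, -v2[0])
    P = np.column_stack([p2[1] - p2[0], p2[2] - p2[0]])
    J = M @ np.linalg.inv(P)
    return lam[0], lam[1], J


def find_critical_points(
    series: SurfaceVectorSeries,
    phase: int,
    threshold: float = DEFAULT_THRESHOLD,
    roi: Optional[RegionOfInterest] = None,
    merge_tol_factor: float = 1e-4,
    classify_tolerance: float = 1e-6,
) -> List[CriticalPoint]:
    """Locate and classify the zeros of the WSS field at one phase.

    An element is a candidate when its minimum nodal |tau| falls below
    ``threshold`` or its three nodal vectors do not share an open half-plane
    (the sign-change test guaranteeing an interior zero of the linear field);
    the union is conservative.  Zeros on shared edges/vertices detected from
    several incident elements are merged within ``merge_tol_factor`` times the
    local edge length, keeping the classification of the element with the
    largest |det J|.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    mesh: TriSurfaceMesh = series.mesh
    vecs = series.vectors[phase]
    ids = roi.triangle_ids if roi is not None else np.arange(mesh.n_triangles)

    pts = mesh.nodes[mesh.triangles[ids]]          # (M, 3, 3)
    tvec = vecs[mesh.triangles[ids]]               # (M, 3, 3)
    e1 = pts[:, 1] - pts[:, 0]
    areas2 = np.linalg.norm(np.cross(e1, pts[:, 2] - pts[:, 0]), axis=1)
    ok = areas2 > 1e-14 * np.maximum(np.linalg.norm(e1, axis=1) ** 2, 1e-300)
    if not np.all(ok):
        warnings.warn(
            f"{int((~ok).sum())} degenerate (zero-area) triangle(s) skipped",
            stacklevel=2,
        )

    mags = np.linalg.norm(tvec, axis=2)
    candidates_mag = mags.min(axis=1) < threshold

    found = []
    lam_tol = 1e-9
    for m in np.flatnonzero(ok):
        tri_pts = pts[m]
        tri_vec = tvec[m]
        # element-plane basis
        b1 = tri_pts[1] - tri_pts[0]
        b1 = b1 / np.linalg.norm(b1)
        nrm = np.cross(tri_pts[1] - tri_pts[0], tri_pts[2] - tri_pts[0])
        nrm = nrm / np.linalg.norm(nrm)
        b2 = np.cross(nrm, b1)
        p2 = (tri_pts - tri_pts[0]) @ np.column_stack([b1, b2])
        v2 = tri_vec @ np.column_stack([b1, b2])

        sol = _element_zero(p2, v2)
        if sol is None:
            continue
        l1, l2, J = sol
        l0 = 1.0 - l1 - l2
        inside = (l0 >= -lam_tol) and (l1 >= -lam_tol) and (l2 >= -lam_tol)
        if not inside:
            continue
        # candidate-element test: magnitude prefilter OR interior sign change
        if not (candidates_mag[m] or inside):
            continue
        pos = tri_pts[0] + l1 * (tri_pts[1] - tri_pts[0]) + l2 * (
            tri_pts[2] - tri_pts[0]
        )
        cls, index = classify_critical_point(J, classify_tolerance)
        if cls == "degenerate":
            continue
        edge_len = np.linalg.norm(tri_pts[1] - tri_pts[0])
        found.append(
            (
                CriticalPoint(
                    position=tuple(pos),
                    element_id=int(ids[m]),
                    phase_index=int(phase),
                    cls=cls,
                    poincare_index=index,
                    jacobian_det=float(np.linalg.det(J)),
                ),
                edge_len,
            )
        )

    # merge duplicates on shared edges/vertices; keep largest |det J|
    found.sort(key=lambda t: -abs(t[0].jacobian_det))
    kept: List[CriticalPoint] = []
    for cp, edge_len in found:
        tol = merge_tol_factor * edge_len
        p = np.asarray(cp.position)
        if any(np.linalg.norm(p - np.asarray(k.position)) <= max(tol, 1e-12) for k in kept):
            continue
        kept.append(cp)
    return kept


def n_critical_points_mean(
    series: SurfaceVectorSeries,
    window: Optional[Sequence[int]] = None,
    threshold: float = DEFAULT_THRESHOLD,
    roi: Optional[RegionOfInterest] = None,
) -> float:
    """Arithmetic mean over phases of the per-phase critical-point count."""
    phases = list(window) if window is not None else list(range(series.n_phases))
    if not phases:
        raise ValueError("window must be nonempty")
    counts = [
        len(find_critical_points(series, k, threshold=threshold, roi=roi))
        for k in phases
    ]
    return float(np.mean(counts))


# ---------------------------------------------------------------------------
# vortex core lines (Sujudi-Haimes parallel vectors on linear tets)
# ---------------------------------------------------------------------------

def _face_parallel_point(face_pts, s_vals):
    """Zero of a linear 2-vector field on a triangular face.

    ``s_vals`` is (3, 2): the two transverse velocity components at the
    corners.  Returns a list of 3-D points (0, 1 or 2 for degenerate edges).
    """
    scale = max(np.abs(s_vals).max(), 1e-300)
    node_zero = np.linalg.norm(s_vals, axis=1) < 1e-9 * scale
    M = np.column_stack([s_vals[1] - s_vals[0], s_vals[2] - s_vals[0]])
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    if abs(det) <= 1e-12 * scale**2:
        # degenerate: zero along an edge or at corners
        pts = [face_pts[i] for i in range(3) if node_zero[i]]
        return pts
    lam = np.linalg.solve(M, -s_vals[0])
    l1, l2 = lam
    l0 = 1.0 - l1 - l2
    tol = 1e-9
    if l0 >= -tol and l1 >= -tol and l2 >= -tol:
        return [
            face_pts[0]
            + l1 * (face_pts[1] - face_pts[0])
            + l2 * (face_pts[2] - face_pts[0])
        ]
    return []


_TET_FACE_LOCAL = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]


def extract_core_lines(
    velocity: TimeSeriesField,
    volume: TetVolumeMesh,
    phase: int = 0,
    im_tolerance: float = 1e-7,
    stitch_tolerance: float = 1e-6,
    region: Optional[int] = None,
) -> CoreLineSet:
    """Vortex core lines of one velocity snapshot.

    Only elements whose velocity-gradient tensor has a genuinely complex
    eigenvalue pair (|Im| > im_tolerance * ||J||) are swirling candidates.
    Within each, the locus where v is parallel to the real eigenvector is
    intersected with the faces; identical segments shared by several
    elements (e.g. along a mesh edge on the vortex axis) are counted once.
    """
    from .wss import tet_shape_gradients

    vecs = velocity.vectors[phase]
    if not np.all(np.isfinite(vecs)):
        raise ValueError("velocity field contains non-finite values")
    tets = volume.tets
    if region is not None:
        if volume.cell_region is None:
            raise ValueError("mesh has no cell_region labels")
        tets = tets[volume.cell_region == region]
    sg = tet_shape_gradients(volume)
    if region is not None:
        sg = sg[volume.cell_region == region]
    vals = vecs[tets]                                # (M, 4, 3)
    J = np.einsum("mai,maj->mij", vals, sg)          # (M, 3, 3)
    if not np.all(np.isfinite(J)):
        bad = int(np.flatnonzero(~np.all(np.isfinite(J), axis=(1, 2)))[0])
        raise ValueError(f"non-finite velocity gradient in tet {bad}")
    scale = np.linalg.norm(J, axis=(1, 2)) + 1e-300
    eig = np.linalg.eigvals(J)
    im = np.abs(eig.imag)
    has_pair = im.max(axis=1) > im_tolerance * scale

    segments = []
    for m in np.flatnonzero(has_pair):
        Jm = J[m]
        w, V = np.linalg.eig(Jm)
        k = int(np.argmin(np.abs(w.imag)))
        e = np.real(V[:, k])
        nrm = np.linalg.norm(e)
        if nrm == 0:
            continue
        e = e / nrm
        # transverse basis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(e @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        f1 = np.cross(e, ref)
        f1 /= np.linalg.norm(f1)
        f2 = np.cross(e, f1)
        corner_ids = tets[m]
        corner_pts = volume.nodes[corner_ids]
        s = np.column_stack([vals[m] @ f1, vals[m] @ f2])  # (4, 2)
        pts = []
        for loc in _TET_FACE_LOCAL:
            fp = corner_pts[list(loc)]
            sv = s[list(loc)]
            pts.extend(_face_parallel_point(fp, sv))
        if len(pts) < 2:
            continue
        pts = np.asarray(pts)
        # drop duplicates within stitch tolerance
        uniq = [pts[0]]
        for p in pts[1:]:
            if all(np.linalg.norm(p - q) > stitch_tolerance for q in uniq):
                uniq.append(p)
        if len(uniq) < 2:
            continue
        if len(uniq) > 2:
            # keep the farthest pair (degenerate multi-hit)
            d = np.linalg.norm(
                np.asarray(uniq)[:, None] - np.asarray(uniq)[None, :], axis=2
            )
            i, j = np.unravel_index(np.argmax(d), d.shape)
            uniq = [uniq[i], uniq[j]]
        a, b = uniq
        if np.linalg.norm(a - b) <= stitch_tolerance:
            continue
        segments.append((a, b))

    # deduplicate identical segments shared by several tets
    def seg_key(a, b):
        ka = tuple(np.round(a / max(stitch_tolerance, 1e-12)).astype(np.int64))
        kb = tuple(np.round(b / max(stitch_tolerance, 1e-12)).astype(np.int64))
        return (min(ka, kb), max(ka, kb))

    unique_segs = {}
    for a, b in segments:
        unique_segs.setdefault(seg_key(a, b), (a, b))
    segments = list(unique_segs.values())

    # stitch endpoint-matching segments into polylines
    polylines = _stitch_segments(segments, stitch_tolerance)
    return CoreLineSet(polylines=polylines, phase_index=int(phase))


def _stitch_segments(segments, tol):
    polylines = []
    remaining = [list(map(np.asarray, s)) for s in segments]
    while remaining:
        a, b = remaining.pop()
        line = [a, b]
        grew = True
        while grew:
            grew = False
            for idx, (p, q) in enumerate(remaining):
                if np.linalg.norm(line[-1] - p) <= tol:
                    line.append(q)
                elif np.linalg.norm(line[-1] - q) <= tol:
                    line.append(p)
                elif np.linalg.norm(line[0] - p) <= tol:
                    line.insert(0, q)
                elif np.linalg.norm(line[0] - q) <= tol:
                    line.insert(0, p)
                else:
                    continue
                remaining.pop(idx)
                grew = True
                break
        polylines.append(np.asarray(line))
    return polylines


def corelen_mean(
    velocity: TimeSeriesField,
    volume: TetVolumeMesh,
    window: Optional[Sequence[int]] = None,
    region: Optional[int] = None,
) -> float:
    """Cycle-averaged total core-line length (cm)."""
    phases = list(window) if window is not None else list(range(velocity.n_phases))
    if not phases:
        raise ValueError("window must be nonempty")
    lengths = [
        extract_core_lines(velocity, volume, k, region=region).total_length
        for k in phases
    ]
    return float(np.mean(lengths))
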