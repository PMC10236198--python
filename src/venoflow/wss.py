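"""Wall shear stress and its first- and second-order cycle metrics.

From a time-resolved velocity field on a tetrahedral volume mesh the module
recovers the viscous traction on the wall, removes its normal component, and
computes the two classical endothelium-relevant scalars:

* time-averaged WSS magnitude (TAWSS, reported as WSSmean when additionally
  averaged over the jugular-bulb region of interest), dyne/cm^2;
* the oscillatory shear index OSI = 0.5 (1 - |cycle-mean tau| / cycle-mean
  |tau|), dimensionless in [0, 0.5]: 0 for unidirectional shear, 0.5 for
  perfectly reversing shear.

Gradients are cell-constant (linear tetrahedra) and volume-weighted onto
wall nodes, matching linear-element CFD output; time integrals use the
trapezoidal rule with periodic closure over the analysed cycle.
"""
from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .analytic import BLOOD, FluidProperties
from .fields import (
    ScalarSurfaceField,
    SurfaceVectorSeries,
    TimeSeriesField,
    periodic_trapezoid_weights,
)
from .geometry import RegionOfInterest, TetVolumeMesh, TriSurfaceMesh

__all__ = [
    "tet_gradients",
    "wall_shear_vectors",
    "tawss",
    "osi",
    "spatial_mean",
]


def tet_shape_gradients(mesh: TetVolumeMesh):
    """Per-tet gradients of the 4 linear shape functions: (M, 4, 3).

    For a linear tet the gradient of any nodal field f is
    sum_a f_a grad(N_a), constant over the element.
    """
    p = mesh.nodes[mesh.tets]  # (M, 4, 3)
    e = p[:, 1:] - p[:, :1]    # (M, 3, 3) edge matrix rows
    inv = np.linalg.inv(e)     # (M, 3, 3); columns give gradients of N1..N3
    g = np.empty((len(mesh.tets), 4, 3))
    g[:, 1:] = np.transpose(inv, (0, 2, 1))
    g[:, 0] = -g[:, 1:].sum(axis=1)
    return g


def tet_gradients(mesh: TetVolumeMesh, nodal_vectors: np.ndarray) -> np.ndarray:
    """Constant velocity-gradient tensor per tet: G[m, i, j] = du_i/dx_j."""
    g = tet_shape_gradients(mesh)           # (M, 4, 3)
    vals = nodal_vectors[mesh.tets]          # (M, 4, 3) u_i at corners
    return np.einsum("mai,maj->mij", vals, g)


def wall_shear_vectors(
    velocity: TimeSeriesField,
    volume: TetVolumeMesh,
    wall: TriSurfaceMesh,
    props: FluidProperties = BLOOD,
) -> SurfaceVectorSeries:
    """Tangential viscous traction at wall nodes for every phase.

    tau = mu (grad u + grad u^T) . n_hat with the normal component removed;
    the velocity gradient at a wall node is the volume-weighted average of
    the constant gradients of its adjacent tets.
    """
    if volume.wall_map is None:
        raise ValueError("volume mesh carries no wall_map")
    if len(volume.wall_map) != wall.n_nodes:
        raise ValueError("wall_map length does not match the wall mesh")

    shape_g = tet_shape_gradients(volume)
    vols = np.abs(volume.tet_volumes())
    normals = wall.node_normals()
    mu = props.viscosity

    # adjacency: which tets touch each wall volume-node
    wall_vol_nodes = volume.wall_map
    is_wall_node = np.zeros(volume.n_nodes, dtype=bool)
    is_wall_node[wall_vol_nodes] = True
    touch = is_wall_node[volume.tets].any(axis=1)
    if not np.all(
        np.isin(wall_vol_nodes, volume.tets[touch])
    ):
        missing = wall_vol_nodes[
            ~np.isin(wall_vol_nodes, volume.tets)
        ]
        raise ValueError(f"wall node(s) {missing[:5]} have no adjacent fluid cell")
    adj_tets = np.flatnonzero(touch)
    sg = shape_g[adj_tets]
    tv = vols[adj_tets]
    corners = volume.tets[adj_tets]

    # map volume node -> wall row
    wall_row = -np.ones(volume.n_nodes, dtype=np.int64)
    wall_row[wall_vol_nodes] = np.arange(len(wall_vol_nodes))

    out = np.zeros((velocity.n_phases, wall.n_nodes, 3))
    wsum = np.zeros(wall.n_nodes)
    # accumulate volume weights once
    for a in range(4):
        rows = wall_row[corners[:, a]]
        ok = rows >= 0
        np.add.at(wsum, rows[ok], tv[ok])

    for k in range(velocity.n_phases):
        vals = velocity.vectors[k][corners]            # (Ma, 4, 3)
        G = np.einsum("mai,maj->mij", vals, sg)         # (Ma, 3, 3)
        Gacc = np.zeros((wall.n_nodes, 3, 3))
        for a in range(4):
            rows = wall_row[corners[:, a]]
            ok = rows >= 0
            np.add.at(Gacc, rows[ok], G[ok] * tv[ok, None, None])
        Gacc /= np.maximum(wsum, 1e-300)[:, None, None]
        S = Gacc + np.transpose(Gacc, (0, 2, 1))
        traction = mu * np.einsum("nij,nj->ni", S, normals)
        tang = traction - np.einsum("ni,ni->n", traction, normals)[:, None] * normals
        out[k] = tang

    return SurfaceVectorSeries(
        mesh=wall, phases=velocity.phases.copy(), vectors=out, period=velocity.period
    )


def _cycle_weights(series: SurfaceVectorSeries) -> np.ndarray:
    period = series.effective_period()
    return periodic_trapezoid_weights(series.phases, period)


def tawss(series: SurfaceVectorSeries) -> ScalarSurfaceField:
    """Time-averaged magnitude of the WSS vector over the cycle, per node."""
    if series.n_phases < 2:
        raise ValueError("time averaging needs at least 2 phases")
    w = _cycle_weights(series)
    mags = np.linalg.norm(series.vectors, axis=2)  # (P, N)
    avg = (w[:, None] * mags).sum(axis=0) / w.sum()
    return ScalarSurfaceField(mesh=series.mesh, values=avg, name="tawss")


def osi(series: SurfaceVectorSeries) -> ScalarSurfaceField:
    """Oscillatory shear index per node, in [0, 0.5]."""
    if series.n_phases < 2:
        raise ValueError("OSI needs at least 2 phases")
    w = _cycle_weights(series)
    mean_vec = np.einsum("p,pni->ni", w, series.vectors)
    int_mag = (w[:, None] * np.linalg.norm(series.vectors, axis=2)).sum(axis=0)
    num = np.linalg.norm(mean_vec, axis=1)
    zero = int_mag <= 0.0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} node(s) with identically zero WSS; OSI set to 0",
            stacklevel=2,
        )
    ratio = np.where(zero, 1.0, num / np.where(zero, 1.0, int_mag))
    vals = 0.5 * (1.0 - np.clip(ratio, 0.0, 1.0))
    return ScalarSurfaceField(mesh=series.mesh, values=vals, name="osi")


def spatial_mean(
    field: ScalarSurfaceField, roi: Optional[RegionOfInterest] = None
) -> float:
    """Area-weighted mean of a nodal field over the region of interest.

    Nodal values are averaged per triangle and weighted by triangle area —
    node counting would bias irregular triangulations.
    """
    mesh = field.mesh
    ids = roi.triangle_ids if roi is not None else np.arange(mesh.n_triangles)
    if ids.size == 0:
        raise ValueError("empty region of interest")
    tri = mesh.triangles[ids]
    areas = mesh.triangle_areas()[ids]
    tri_vals = field.values[tri].mean(axis=1)
    total = areas.sum()
    if total <= 0:
        raise ValueError("region of interest has zero area")
    return float((tri_vals * areas).sum() / total)
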