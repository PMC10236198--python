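"""Closed-form flow fields: the oracles behind every downstream metric.

These generators stand in for patient-specific CFD output.  Each one has a
known exact answer for the quantity a downstream module computes:

* Poiseuille / Womersley tube flow -> wall shear stress magnitude and the
  pulsatile velocity profile (flux reproduces the driving waveform exactly,
  harmonic by harmonic);
* a Lamb-Oseen vortex on uniform axial flow -> a vortex core line along the
  known axis;
* planted tangential surface patterns -> WSS critical points of prescribed
  class (node/focus/saddle, source/sink) at a prescribed location.

Units: CGS.  Blood defaults are mu = 0.04 P, rho = 1.06 g/cm^3 (standard
Newtonian values for cerebrovascular CFD).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import jv

from .fields import SurfaceVectorSeries, TimeSeriesField, VelocitySampler
from .geometry import TetVolumeMesh, TriSurfaceMesh
from .waveforms import Waveform, fourier_coefficients

__all__ = [
    "FluidProperties",
    "BLOOD",
    "poiseuille_wss",
    "womersley_number",
    "womersley_velocity",
    "lamb_oseen_swirl",
    "planted_surface_field",
    "sample_on_mesh",
    "PATTERN_MATRICES",
]


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: dynamic viscosity (Poise) and density (g/cm^3)."""

    viscosity: float = 0.04
    density: float = 1.06

    def __post_init__(self) -> None:
        if self.viscosity <= 0 or self.density <= 0:
            raise ValueError("viscosity and density must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        """nu = mu / rho, cm^2/s."""
        return self.viscosity / self.density


BLOOD = FluidProperties()


def poiseuille_wss(flow: float, radius: float, props: FluidProperties = BLOOD) -> float:
    """Wall shear stress of steady Poiseuille tube flow: 4 mu Q / (pi R^3)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return 4.0 * props.viscosity * flow / (np.pi * radius**3)


def womersley_number(
    radius: float, angular_frequency: float, props: FluidProperties = BLOOD
) -> float:
    """alpha = R sqrt(omega / nu), the pulsatility parameter."""
    if radius <= 0 or angular_frequency < 0:
        raise ValueError("radius must be positive and frequency non-negative")
    return radius * np.sqrt(angular_frequency * props.density / props.viscosity)


def _local_frame(direction: Sequence[float]):
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return d, e1, e2


def womersley_velocity(
    radius: float,
    waveform: Waveform,
    props: FluidProperties = BLOOD,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    direction: Sequence[float] = (0.0, 0.0, 1.0),
) -> VelocitySampler:
    """Axial pulsatile profile in a rigid tube (Womersley solution).

    The waveform is decomposed into its Fourier harmonics; each harmonic n
    drives the profile

        u_n(r) = (Q_n / (pi R^2)) [1 - J0(beta_n r/R)/J0(beta_n)]
                 / [1 - 2 J1(beta_n) / (beta_n J0(beta_n))],

    with beta_n = i^(3/2) alpha_n and alpha_n the Womersley number of the
    n-th harmonic, so that the cross-section flux reproduces the waveform
    harmonic exactly.  The zeroth harmonic is the Poiseuille parabola.
    The harmonic count is limited by the waveform's sampling
    (floor((n_samples-1)/2)), matching sparse PC-MRI acquisitions.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    a0, a, b = fourier_coefficients(waveform)
    omega = 2.0 * np.pi / waveform.period
    nu = props.kinematic_viscosity
    d, e1, e2 = _local_frame(direction)
    origin = np.asarray(origin, dtype=float)
    area = np.pi * radius**2

    # complex amplitudes: Q(t) = Re{ sum_n c_n exp(i n omega t) }, c_0 = a0
    c = a - 1j * b
    betas = []
    shape_denoms = []
    for n in range(1, len(c) + 1):
        alpha_n = radius * np.sqrt(n * omega / nu)
        beta = alpha_n * np.exp(1j * 3.0 * np.pi / 4.0)
        j0b = jv(0, beta)
        denom = 1.0 - 2.0 * jv(1, beta) / (beta * j0b)
        betas.append(beta)
        shape_denoms.append(denom * j0b)

    def evaluate(points: np.ndarray, t: float) -> np.ndarray:
        rel = points - origin
        x1 = rel @ e1
        x2 = rel @ e2
        r = np.sqrt(x1**2 + x2**2)
        rr = np.minimum(r / radius, 1.0)
        u = (a0 / area) * 2.0 * (1.0 - rr**2)
        for n in range(1, len(c) + 1):
            beta = betas[n - 1]
            j0b = jv(0, beta)
            denom = 1.0 - 2.0 * jv(1, beta) / (beta * j0b)
            profile = (1.0 - jv(0, beta * rr) / j0b) / denom / area
            u = u + np.real(c[n - 1] * profile * np.exp(1j * n * omega * t))
        return u[:, None] * d

    return VelocitySampler(
        evaluator=evaluate,
        metadata={
            "type": "womersley",
            "radius": radius,
            "period": waveform.period,
            "mean_flow": a0,
            "n_harmonics": len(c),
            "origin": tuple(origin),
            "direction": tuple(d),
        },
    )


def lamb_oseen_swirl(
    circulation: float,
    core_radius: float,
    axial_speed: float = 0.0,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    direction: Sequence[float] = (0.0, 0.0, 1.0),
) -> VelocitySampler:
    """Lamb-Oseen vortex superposed on uniform axial flow.

    Azimuthal speed u_theta(r) = Gamma/(2 pi r) (1 - exp(-(r/r_c)^2)); the
    vortex axis is the unique swirl center, giving a known core line for the
    extraction algorithm.  The field is divergence-free.
    """
    if core_radius <= 0:
        raise ValueError("core_radius must be positive")
    d, e1, e2 = _local_frame(direction)
    origin = np.asarray(origin, dtype=float)

    def evaluate(points: np.ndarray, t: float) -> np.ndarray:
        rel = points - origin
        x1 = rel @ e1
        x2 = rel @ e2
        r2 = x1**2 + x2**2
        # u_theta / r, finite at the axis (limit Gamma / (2 pi r_c^2))
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(
                r2 > 0,
                circulation / (2.0 * np.pi * r2) * (1.0 - np.exp(-r2 / core_radius**2)),
                circulation / (2.0 * np.pi * core_radius**2),
            )
        # theta-hat * u_theta = factor * (-x2 e1 + x1 e2)
        vel = (
            (-x2 * factor)[:, None] * e1
            + (x1 * factor)[:, None] * e2
            + axial_speed * d
        )
        return vel

    return VelocitySampler(
        evaluator=evaluate,
        metadata={
            "type": "lamb_oseen",
            "circulation": circulation,
            "core_radius": core_radius,
            "axial_speed": axial_speed,
            "origin": tuple(origin),
            "direction": tuple(d),
        },
    )


#: canonical in-plane linearizations of the five critical-point classes
PATTERN_MATRICES = {
    "source-node": np.array([[1.0, 0.0], [0.0, 1.0]]),
    "sink-node": np.array([[-1.0, 0.0], [0.0, -1.0]]),
    "source-focus": np.array([[1.0, -1.0], [1.0, 1.0]]),
    "sink-focus": np.array([[-1.0, -1.0], [1.0, -1.0]]),
    "saddle": np.array([[1.0, 0.0], [0.0, -1.0]]),
}


def planted_surface_field(
    mesh: TriSurfaceMesh,
    pattern: str,
    location: Optional[Sequence[float]] = None,
    background: Sequence[float] = (0.0, 0.0, 0.0),
    window_radius: Optional[float] = None,
    strength: Optional[float] = None,
    phases: Optional[np.ndarray] = None,
) -> SurfaceVectorSeries:
    """Tangential surface field with a critical point of prescribed class.

    The pattern is defined in the tangent plane at the mesh node nearest
    ``location``.  With a nonzero background it is blended in with a C^1
    radial window w(s) = (1 - s^2)^2, so the planted zero and its Jacobian are
    exact at the plant while the background carries the far field; with a zero
    background the pure linear pattern extends over the whole mesh (windowing
    a zero background would null the far field and seed spurious zeros at the
    window rim).  ``pattern='none'`` returns the pure background field
    (nowhere zero provided the background is transverse to every node normal).

    ``background`` may be a single 3-vector, an (n_nodes, 3) array, or an
    (n_phases, n_nodes, 3) array (e.g. a computed WSS series into which the
    pattern is planted phase by phase).
    """
    background = np.asarray(background, dtype=float)
    n_nodes = mesh.n_nodes
    normals = mesh.node_normals()
    if phases is None:
        phases = np.array([0.0])
    phases = np.asarray(phases, dtype=float)
    n_phases = phases.size
    # broadcast background to (n_phases, n_nodes, 3), tangentially projected
    if background.ndim == 1:
        bg = np.broadcast_to(background, (n_phases, n_nodes, 3))
    elif background.ndim == 2:
        bg = np.broadcast_to(background[None], (n_phases, n_nodes, 3))
    else:
        bg = background
        if bg.shape != (n_phases, n_nodes, 3):
            raise ValueError("background shape must broadcast to (n_phases, n_nodes, 3)")
    bg = bg - np.einsum("pni,ni->pn", bg, normals)[:, :, None] * normals[None]

    if pattern == "none":
        field = bg
    else:
        if pattern not in PATTERN_MATRICES:
            raise ValueError(
                f"unknown pattern {pattern!r}; choose from "
                f"{sorted(PATTERN_MATRICES)} or 'none'"
            )
        if location is None:
            raise ValueError("a location on the mesh is required for a plant")
        location = np.asarray(location, dtype=float)
        dists = np.linalg.norm(mesh.nodes - location, axis=1)
        idx = int(np.argmin(dists))
        extent = np.linalg.norm(np.ptp(mesh.nodes, axis=0))
        if dists[idx] > 0.05 * extent:
            raise ValueError("location is not on the mesh")
        x0 = mesh.nodes[idx]
        n0 = normals[idx]
        # tangent basis at the plant
        ref = np.array([1.0, 0.0, 0.0])
        if abs(n0 @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(n0, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n0, e1)

        if window_radius is None:
            window_radius = 0.25 * extent
        bnorm = float(np.linalg.norm(bg, axis=2).max())
        if strength is None:
            strength = 1.0 if bnorm == 0 else 8.0 * bnorm / window_radius

        A = strength * PATTERN_MATRICES[pattern]
        rel = mesh.nodes - x0
        xi = np.column_stack([rel @ e1, rel @ e2])
        v2 = xi @ A.T
        v3 = v2[:, 0:1] * e1 + v2[:, 1:2] * e2
        if bnorm == 0:
            field = np.broadcast_to(v3, (n_phases, n_nodes, 3)).copy()
        else:
            s = np.linalg.norm(rel, axis=1) / window_radius
            w = np.where(s < 1.0, (1.0 - np.minimum(s, 1.0) ** 2) ** 2, 0.0)
            field = w[None, :, None] * v3[None] + (1.0 - w)[None, :, None] * bg
        # keep the field tangential node by node
        field = field - np.einsum("pni,ni->pn", field, normals)[:, :, None] * normals[None]
        # the plant itself is exactly zero
        field[:, idx] = 0.0

    vectors = np.array(field, dtype=float, copy=True).reshape(n_phases, n_nodes, 3)
    return SurfaceVectorSeries(mesh=mesh, phases=phases, vectors=vectors)


def sample_on_mesh(
    sampler: VelocitySampler, mesh: TetVolumeMesh, phases: Sequence[float]
) -> TimeSeriesField:
    """Evaluate a closed-form velocity field at mesh nodes over phases."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("phases must be nonempty")
    snapshots = []
    for t in phases:
        v = sampler(mesh.nodes, float(t))
        bad = ~np.all(np.isfinite(v), axis=1)
        if np.any(bad):
            raise ValueError(
                f"sampler produced non-finite velocity at node {int(np.flatnonzero(bad)[0])}"
            )
        snapshots.append(v)
    return TimeSeriesField(
        mesh=mesh,
        phases=phases,
        vectors=np.stack(snapshots),
        metadata=dict(sampler.metadata),
    )
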