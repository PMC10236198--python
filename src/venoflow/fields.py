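"""Shared containers for time-resolved vector fields on meshes and grids.

Units are CGS throughout: lengths in cm, times in s, velocities in cm/s and
wall shear stress in dyne/cm^2.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Optional

import numpy as np

__all__ = [
    "TimeSeriesField",
    "SurfaceVectorSeries",
    "ScalarSurfaceField",
    "VelocitySampler",
    "periodic_trapezoid_weights",
]


def periodic_trapezoid_weights(times: np.ndarray, period: float) -> np.ndarray:
    """Quadrature weights for the trapezoidal rule on one period.

    Samples are treated as periodic: the gap between the last sample and the
    first sample of the next cycle closes the integral.  Weights sum to
    ``period`` exactly.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need at least two phase samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("phase times must be strictly increasing")
    if t[-1] - t[0] >= period:
        raise ValueError("phase samples must span less than one period")
    # midpoint spacing, wrapping the cycle
    ext = np.concatenate([[t[-1] - period], t, [t[0] + period]])
    return 0.5 * (ext[2:] - ext[:-2])


@dataclass
class TimeSeriesField:
    """Velocity vectors attached to mesh/grid nodes at a sequence of times.

    ``vectors`` has shape (n_phases, n_nodes, 3).  ``mesh`` is the carrier
    (a :class:`~venoflow.geometry.TetVolumeMesh` or a
    :class:`~venoflow.geometry.StructuredGrid2D`); the field does not copy it.
    """

    mesh: Any
    phases: np.ndarray
    vectors: np.ndarray
    period: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.phases.ndim != 1 or self.phases.size == 0:
            raise ValueError("phases must be a nonempty 1-D array")
        if np.any(np.diff(self.phases) <= 0):
            raise ValueError("phases must be strictly increasing")
        if self.vectors.ndim != 3 or self.vectors.shape[0] != self.phases.size:
            raise ValueError(
                "vectors must have shape (n_phases, n_nodes, 3); got "
                f"{self.vectors.shape} for {self.phases.size} phases"
            )
        if self.vectors.shape[2] != 3:
            raise ValueError("vectors must be 3-vectors (pad 2-D fields with 0)")

    @property
    def n_phases(self) -> int:
        return int(self.phases.size)

    @property
    def n_nodes(self) -> int:
        return int(self.vectors.shape[1])

    def snapshot(self, phase: int) -> np.ndarray:
        return self.vectors[phase]

    def window(self, t_start: float, t_stop: float) -> "TimeSeriesField":
        """Sub-series with t_start <= t < t_stop."""
        keep = (self.phases >= t_start - 1e-12) & (self.phases < t_stop - 1e-12)
        if not np.any(keep):
            raise ValueError("requested window contains no snapshots")
        return TimeSeriesField(
            mesh=self.mesh,
            phases=self.phases[keep],
            vectors=self.vectors[keep],
            period=self.period,
            metadata=dict(self.metadata),
        )


@dataclass
class SurfaceVectorSeries:
    """Tangential wall-shear-stress vectors per wall node per cardiac phase.

    ``vectors`` has shape (n_phases, n_nodes, 3) in dyne/cm^2 and must be
    tangential to the wall surface at each node.
    """

    mesh: Any  # TriSurfaceMesh
    phases: np.ndarray
    vectors: np.ndarray
    period: Optional[float] = None

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.phases.ndim != 1 or self.phases.size == 0:
            raise ValueError("phases must be a nonempty 1-D array")
        if self.phases.size > 1 and np.any(np.diff(self.phases) <= 0):
            raise ValueError("phases must be strictly increasing")
        n_nodes = self.mesh.nodes.shape[0] if hasattr(self.mesh, "nodes") else None
        if self.vectors.ndim != 3 or self.vectors.shape[0] != self.phases.size:
            raise ValueError("vectors must have shape (n_phases, n_nodes, 3)")
        if n_nodes is not None and self.vectors.shape[1] != n_nodes:
            raise ValueError(
                f"field has {self.vectors.shape[1]} nodes, mesh has {n_nodes}"
            )

    @property
    def n_phases(self) -> int:
        return int(self.phases.size)

    def effective_period(self) -> float:
        if self.period is not None:
            return float(self.period)
        t = self.phases
        if t.size < 2:
            raise ValueError("cannot infer a period from a single phase")
        # assume uniform sampling of one full cycle
        return float(t[-1] - t[0] + (t[1] - t[0]))


@dataclass
class ScalarSurfaceField:
    """A scalar value per wall node (e.g. time-averaged WSS or OSI)."""

    mesh: Any
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D (one per node)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar surface field contains non-finite values")


@dataclass
class VelocitySampler:
    """A closed-form velocity field: (points, t) -> velocity vectors.

    ``evaluator`` maps an (N, 3) array of positions (cm) and a time (s) to an
    (N, 3) array of velocities (cm/s).  ``metadata`` records the construction
    parameters for provenance.
    """

    evaluator: Callable[[np.ndarray, float], np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __call__(self, points: np.ndarray, t: float) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.asarray(self.evaluator(points, float(t)), dtype=float)
        if out.shape != points.shape:
            raise ValueError("sampler returned wrong shape")
        return out

    def __add__(self, other: "VelocitySampler") -> "VelocitySampler":
        def _sum(points: np.ndarray, t: float) -> np.ndarray:
            return self(points, t) + other(points, t)

        return VelocitySampler(
            evaluator=_sum,
            metadata={"type": "superposition", "parts": [self.metadata, other.metadata]},
        )
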