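"""Bilateral comparison of jugular-bulb hemodynamics and pipeline orchestration.

The clinical observation this package reproduces on synthetic inputs: the two
venous outflow channels of a single model can carry similar first-order
metrics (WSSmean, OSImean within ~1.3-fold) while the higher-order
flow-complexity metrics (core-line length, mean critical-point count) differ
several-fold, and the side with the greater mean critical-point count is the
side that goes on to develop jugular bulb stenosis.

``run_pipeline`` wires the whole chain together on an idealized bifurcation:
geometry -> inflow boundary condition -> per-branch pulsatile field ->
WSS/OSI -> topology metrics -> bilateral report, with optional planted
asymmetries (a Lamb-Oseen vortex plus its wall-footprint focus pattern) to
emulate a disturbed side.
"""
from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__ as _version
from .analytic import (
    BLOOD,
    FluidProperties,
    lamb_oseen_swirl,
    planted_surface_field,
    sample_on_mesh,
    womersley_velocity,
)
from .fields import SurfaceVectorSeries
from .geometry import (
    OUTLET_LEFT,
    OUTLET_RIGHT,
    PlaneSection,
    RegionOfInterest,
    TriSurfaceMesh,
    cross_section_area,
    make_cylinder,
)
from .topology import corelen_mean, n_critical_points_mean
from .waveforms import Waveform, synth_waveform
from .wss import osi, spatial_mean, tawss, wall_shear_vectors

__all__ = [
    "SideMetrics",
    "ComparisonReport",
    "PipelineConfig",
    "fold_ratio",
    "percent_area_change",
    "bilateral_report",
    "run_pipeline",
]

REPORT_SCHEMA = "venoflow_report_v1"
UNDEFINED_RATIO = "undefined (contralateral zero)"


@dataclass(frozen=True)
class SideMetrics:
    """The four hemodynamic metrics of one jugular-bulb analog."""

    label: str
    wss_mean: float          # dyne/cm^2
    osi_mean: float          # dimensionless, <= 0.5
    corelen: float           # cm
    n_cr_points_mean: float  # dimensionless

    def __post_init__(self) -> None:
        vals = (self.wss_mean, self.osi_mean, self.corelen, self.n_cr_points_mean)
        if not all(math.isfinite(v) and v >= 0 for v in vals):
            raise ValueError("metrics must be finite and non-negative")
        if self.osi_mean > 0.5 + 1e-12:
            raise ValueError("osi_mean cannot exceed 0.5")


def fold_ratio(numerator: float, denominator: float) -> Optional[float]:
    """numerator / denominator, with zero denominators flagged.

    Returns None (the "undefined (contralateral zero)" flag) when only the
    denominator vanishes — a ratio against a zero contralateral metric is
    reported as the raw pair, as the source tables do.  When both sides are
    zero the metrics are equal and the ratio is 1.
    """
    if numerator < 0 or denominator < 0:
        raise ValueError("fold ratios are defined for non-negative metrics")
    if denominator == 0.0:
        return 1.0 if numerator == 0.0 else None
    return numerator / denominator


def percent_area_change(before: float, after: float) -> int:
    """Percent reduction in cross-sectional area, rounded to nearest integer
    (half away from zero).  Negative values mean the area grew."""
    if before <= 0:
        raise ValueError("'before' area must be positive")
    if after < 0:
        raise ValueError("'after' area cannot be negative")
    pct = 100.0 * (before - after) / before
    return int(math.floor(pct + 0.5)) if pct >= 0 else -int(math.floor(-pct + 0.5))


def _ratio_entry(num: float, den: float) -> dict:
    r = fold_ratio(num, den)
    entry = {"value": r, "pair": [num, den]}
    if r is None:
        entry["flag"] = UNDEFINED_RATIO
    return entry


@dataclass
class ComparisonReport:
    """Machine-readable bilateral comparison."""

    sides: Dict[str, SideMetrics]
    ratios: Dict[str, dict]
    area_change_percent: Dict[str, Optional[int]]
    lateralization: str            # "left" | "right" | "none"
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema": REPORT_SCHEMA,
            "sides": {k: asdict(v) for k, v in self.sides.items()},
            "ratios": self.ratios,
            "area_change_percent": self.area_change_percent,
            "lateralization": self.lateralization,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def summary_frame(self) -> pd.DataFrame:
        """Tabular layout: one row per metric, columns per side + ratio."""
        rows = []
        pred = self.lateralization if self.lateralization != "none" else "left"
        other = "right" if pred == "left" else "left"
        for metric in ("wss_mean", "corelen", "n_cr_points_mean", "osi_mean"):
            entry = self.ratios[metric]
            rows.append(
                {
                    "metric": metric,
                    f"{pred} (predicted stenosis)": getattr(self.sides[pred], metric),
                    other: getattr(self.sides[other], metric),
                    "fold_ratio": entry["value"],
                }
            )
        return pd.DataFrame(rows)


def bilateral_report(
    left: SideMetrics,
    right: SideMetrics,
    areas: Optional[Dict[str, Tuple[float, float]]] = None,
    provenance: Optional[dict] = None,
) -> ComparisonReport:
    """Fold ratios, area changes and the lateralization call.

    The predicted-stenosis side is the one with the greater mean
    critical-point count — the only metric consistently greater on the
    stenosing side; ratios are reported predicted-side / contralateral.
    Ties yield no lateralization and left/right ratios.
    """
    if left.n_cr_points_mean > right.n_cr_points_mean:
        lateralization = "left"
    elif right.n_cr_points_mean > left.n_cr_points_mean:
        lateralization = "right"
    else:
        lateralization = "none"
    pred = lateralization if lateralization != "none" else "left"
    other = "right" if pred == "left" else "left"
    sides = {"left": left, "right": right}
    ratios = {
        metric: _ratio_entry(getattr(sides[pred], metric), getattr(sides[other], metric))
        for metric in ("wss_mean", "osi_mean", "corelen", "n_cr_points_mean")
    }
    area_pct: Dict[str, Optional[int]] = {"left": None, "right": None}
    if areas:
        for side, (before, after) in areas.items():
            area_pct[side] = percent_area_change(before, after)
    return ComparisonReport(
        sides=sides,
        ratios=ratios,
        area_change_percent=area_pct,
        lateralization=lateralization,
        provenance=provenance or {},
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run description for the idealized bifurcation study.

    Geometry: a Y bifurcation (torcular analog) with branch tubes acting as
    the paired venous outflow channels; each branch is modelled as a straight
    tube carrying a Womersley-profile share of the inflow.  ``swirl_side``
    plants a Lamb-Oseen vortex along that branch plus a focus-type WSS
    pattern at the vortex wall footprint — the synthetic analog of the
    disturbed, recirculating side.  ``stenosis_area_factor`` optionally
    emulates follow-up lumen narrowing per side for the area-change report.
    """

    branch_radius: float = 0.25          # cm
    branch_length: float = 3.0           # cm
    resolution: int = 24
    mean_flow: float = 8.0               # mL/s total inflow (VOGM-scale, ~480 mL/min)
    pulsatility: float = 0.4
    period: float = 0.5                  # s  (HR 120, neonatal range)
    n_phases: int = 10                   # PC-MRI-like sampling of the cycle
    split_left: float = 0.5
    swirl_side: Optional[str] = None     # "left" | "right" | None
    swirl_circulation: float = 30.0      # cm^2/s
    swirl_core_radius: float = 0.08      # cm
    seed: int = 0
    stenosis_area_factor: Optional[Dict[str, float]] = None

    def canonical(self) -> dict:
        d = asdict(self)
        return d


def _branch_metrics(
    side: str,
    config: PipelineConfig,
    inflow: Waveform,
    props: FluidProperties,
) -> SideMetrics:
    """Metrics of one outflow branch modelled in its own straight frame."""
    frac = config.split_left if side == "left" else 1.0 - config.split_left
    branch_flow = Waveform(
        times=inflow.times, flows=inflow.flows * frac, period=inflow.period
    )
    surf, vol = make_cylinder(
        config.branch_radius, config.branch_length, config.resolution
    )
    phases = inflow.period * np.arange(config.n_phases) / config.n_phases

    sampler = womersley_velocity(config.branch_radius, branch_flow, props)
    plant_surface = config.swirl_side == side
    if plant_surface:
        sampler = sampler + lamb_oseen_swirl(
            config.swirl_circulation,
            config.swirl_core_radius,
            axial_speed=0.0,
            origin=(0.0, 0.0, 0.0),
            direction=(0.0, 0.0, 1.0),
        )
    field = sample_on_mesh(sampler, vol, phases)

    series = wall_shear_vectors(field, vol, surf, props)
    roi = _lateral_band_roi(surf, config)

    if plant_surface:
        # the vortex's wall signature: a focus-type WSS zero at its footprint
        foot = (
            config.branch_radius * np.cos(0.3),
            config.branch_radius * np.sin(0.3),
            0.5 * config.branch_length,
        )
        series = planted_surface_field(
            surf,
            "source-focus",
            location=foot,
            background=series.vectors,
            window_radius=0.5 * config.branch_radius,
            phases=series.phases,
        )
        series.period = inflow.period

    wss_mean = spatial_mean(tawss(series), roi)
    osi_mean = spatial_mean(osi(series), roi)
    n_cr = n_critical_points_mean(series, roi=roi)
    corelen = corelen_mean(field, vol)
    return SideMetrics(
        label=side,
        wss_mean=wss_mean,
        osi_mean=osi_mean,
        corelen=corelen,
        n_cr_points_mean=n_cr,
    )


def _lateral_band_roi(surf: TriSurfaceMesh, config: PipelineConfig) -> RegionOfInterest:
    lo = PlaneSection((0, 0, 0.15 * config.branch_length), (0, 0, 1))
    hi = PlaneSection((0, 0, 0.85 * config.branch_length), (0, 0, 1))
    from .geometry import clip_roi

    return clip_roi(surf, lo, hi, label="jugular-bulb analog")


def run_pipeline(
    config: PipelineConfig,
    out_dir: Optional[str] = None,
    props: FluidProperties = BLOOD,
) -> ComparisonReport:
    """Run geometry -> BC -> fields -> metrics -> bilateral report.

    Deterministic for a given (config, seed); rerunning writes byte-identical
    report JSON.  With ``out_dir`` set, the report, a Table-style CSV summary
    and a run log are written there.
    """
    inflow = synth_waveform(
        mean_flow=config.mean_flow,
        pulsatility=config.pulsatility,
        period=config.period,
        seed=config.seed,
    )
    left = _branch_metrics("left", config, inflow, props)
    right = _branch_metrics("right", config, inflow, props)

    areas = None
    if config.stenosis_area_factor:
        surf, vol = make_cylinder(
            config.branch_radius, config.branch_length, config.resolution
        )
        mid = PlaneSection((0, 0, 0.5 * config.branch_length), (0, 0, 1))
        before = cross_section_area(vol, mid)
        areas = {
            side: (before, before * factor)
            for side, factor in sorted(config.stenosis_area_factor.items())
        }

    cfg_json = json.dumps(config.canonical(), sort_keys=True)
    provenance = {
        "config": config.canonical(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "venoflow_version": _version,
    }
    report = bilateral_report(left, right, areas=areas, provenance=provenance)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            fh.write(report.to_json())
        report.summary_frame().to_csv(
            os.path.join(out_dir, "summary.csv"), index=False
        )
        with open(os.path.join(out_dir, "run.log"), "w") as fh:
            fh.write(
                f"venoflow {_version}\nseed {config.seed}\n"
                f"config_sha256 {provenance['config_sha256']}\n"
                f"lateralization {report.lateralization}\n"
            )
    return report
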