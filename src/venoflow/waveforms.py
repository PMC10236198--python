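"""Inflow boundary conditions for venous outflow models.

Three sources of pulsatile inflow are supported, mirroring clinical practice
for neonatal arteriovenous shunts:

* echocardiogram arithmetic — stroke volume, cardiac output and the excess
  (shunt) flow above the body-surface-area reference;
* phase-contrast MRI style waveforms — flow-rate samples over one cardiac
  cycle at 5-10 phases, averaged between measurement sites and split between
  the left and right transverse sinuses;
* fully synthetic waveforms with controlled mean and pulsatility.

Waveforms carry volumetric flow rate in mL/s; echo quantities use the
clinical units (mL, bpm, mL/min).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "EchoRecord",
    "Waveform",
    "FlowSplit",
    "stroke_volume",
    "cardiac_output",
    "excess_flow",
    "average_waveforms",
    "resample_waveform",
    "synth_waveform",
    "flow_split",
    "fourier_coefficients",
    "ML_MIN_TO_ML_S",
]

ML_MIN_TO_ML_S = 1.0 / 60.0

#: below this many samples per cycle trigonometric interpolation is used;
#: clinical PC-MRI acquisitions have 5 (4D flow) or 10 (2D PC) cardiac phases,
#: where piecewise-linear interpolation badly distorts cycle integrals.
TRIG_INTERP_MAX_SAMPLES = 10


@dataclass(frozen=True)
class EchoRecord:
    """Echocardiogram parameters used to derive boundary conditions.

    ``ref_cardiac_output`` is the body-surface-area-referenced mean cardiac
    output (mL/min); it is a clinical input, not computed here.
    """

    heart_rate: float        # bpm
    edv: float               # end-diastolic volume, mL
    esv: float               # end-systolic volume, mL
    bsa: Optional[float] = None              # m^2
    ref_cardiac_output: Optional[float] = None  # mL/min

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ValueError("heart rate must be positive")
        if self.esv < 0 or self.edv < self.esv:
            raise ValueError("volumes must satisfy EDV >= ESV >= 0")

    @property
    def period(self) -> float:
        """Cardiac period in seconds."""
        return 60.0 / self.heart_rate


def stroke_volume(record: EchoRecord) -> float:
    """Stroke volume SV = EDV - ESV, in mL."""
    return record.edv - record.esv


def cardiac_output(record: EchoRecord) -> float:
    """Cardiac output CO = HR x SV, in mL/min."""
    return record.heart_rate * stroke_volume(record)


def excess_flow(record: EchoRecord) -> float:
    """Flow above the BSA-referenced cardiac output, presumed to supply the
    malformation (mL/min).  Negative values are allowed but flagged."""
    if record.ref_cardiac_output is None:
        raise ValueError("record has no reference cardiac output")
    out = cardiac_output(record) - record.ref_cardiac_output
    if out < 0:
        warnings.warn(
            "cardiac output below reference: no shunt excess", stacklevel=2
        )
    return out


@dataclass(frozen=True)
class Waveform:
    """One cardiac cycle of volumetric flow rate.

    ``times`` (s) are strictly increasing within [0, period); ``flows`` are in
    mL/s.  Retrograde (negative) samples are allowed.  Five samples per cycle
    is the practical minimum (the coarsest clinical acquisition); three is the
    hard floor for resampling round trips.
    """

    times: np.ndarray
    flows: np.ndarray
    period: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        q = np.asarray(self.flows, dtype=float)
        if t.ndim != 1 or t.size < 3:
            raise ValueError("waveform needs at least 3 samples per cycle")
        if q.shape != t.shape:
            raise ValueError("times and flows must have the same length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if t[0] < 0 or t[-1] >= self.period:
            raise ValueError("times must lie in [0, period)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "flows", q)
        object.__setattr__(self, "period", float(self.period))

    def __len__(self) -> int:
        return self.times.size

    @classmethod
    def constant(cls, value: float, period: float = 1.0, n: int = 16) -> "Waveform":
        t = period * np.arange(n) / n
        return cls(times=t, flows=np.full(n, float(value)), period=period)

    def cycle_integral(self) -> float:
        """Integral of Q over one period (mL), periodic trapezoid."""
        t = np.concatenate([self.times, [self.times[0] + self.period]])
        q = np.concatenate([self.flows, [self.flows[0]]])
        return float(np.trapezoid(q, t))

    def cycle_mean(self) -> float:
        """Cycle-averaged flow rate (mL/s)."""
        return self.cycle_integral() / self.period

    def pulsatility(self) -> float:
        """(max - min) / mean over the sampled cycle."""
        m = self.cycle_mean()
        if m == 0:
            raise ValueError("pulsatility undefined for zero-mean waveform")
        return float((self.flows.max() - self.flows.min()) / m)

    def evaluate(self, t) -> np.ndarray:
        """Periodic interpolation at arbitrary times.

        Trigonometric interpolation for sparse cycles (<= 10 samples), linear
        otherwise.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float)) % self.period
        if len(self) <= TRIG_INTERP_MAX_SAMPLES:
            a0, a, b = fourier_coefficients(self)
            omega = 2.0 * np.pi / self.period
            out = np.full_like(t, a0)
            for k in range(1, len(a) + 1):
                out += a[k - 1] * np.cos(k * omega * t) + b[k - 1] * np.sin(
                    k * omega * t
                )
            return out
        tt = np.concatenate([self.times, [self.times[0] + self.period]])
        qq = np.concatenate([self.flows, [self.flows[0]]])
        return np.interp(t, tt, qq)


def fourier_coefficients(w: Waveform, n_harmonics: Optional[int] = None):
    """Least-squares real Fourier coefficients (a0, a[1..N], b[1..N]).

    For a uniform sample grid this is the discrete Fourier transform; for
    non-uniform phases it is the trigonometric least-squares fit.  The default
    harmonic count floor((n-1)/2) makes the fit interpolatory (odd n) or
    near-interpolatory (even n).
    """
    n = len(w)
    if n_harmonics is None:
        n_harmonics = (n - 1) // 2
    n_harmonics = int(min(n_harmonics, (n - 1) // 2))
    omega = 2.0 * np.pi / w.period
    cols = [np.ones(n)]
    for k in range(1, n_harmonics + 1):
        cols.append(np.cos(k * omega * w.times))
        cols.append(np.sin(k * omega * w.times))
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, w.flows, rcond=None)
    a0 = float(coef[0])
    a = coef[1::2]
    b = coef[2::2]
    return a0, a, b


def resample_waveform(w: Waveform, n_phases: int) -> Waveform:
    """Periodic interpolation onto a uniform grid of ``n_phases`` samples."""
    if n_phases < 3:
        raise ValueError("n_phases must be >= 3")
    t = w.period * np.arange(n_phases) / n_phases
    return Waveform(times=t, flows=w.evaluate(t), period=w.period)


def average_waveforms(a: Waveform, b: Waveform) -> Waveform:
    """Pointwise mean of two waveforms after resampling to a common grid.

    This is how two PC-MRI measurement sites along the same sinus are fused
    into a single inflow boundary condition.  Periods must agree within 1%.
    """
    if abs(a.period - b.period) > 0.01 * max(a.period, b.period):
        raise ValueError(
            f"periods differ by more than 1%: {a.period} vs {b.period}"
        )
    period = 0.5 * (a.period + b.period)
    n = max(len(a), len(b))
    t = period * np.arange(n) / n
    qa = Waveform(a.times, a.flows, period).evaluate(t)
    qb = Waveform(b.times, b.flows, period).evaluate(t)
    return Waveform(times=t, flows=0.5 * (qa + qb), period=period)


def synth_waveform(
    mean_flow: float,
    pulsatility: float,
    n_harmonics: int = 4,
    period: float = 1.0,
    seed: int = 0,
    n_samples: int = 100,
) -> Waveform:
    """Random band-limited pulsatile waveform with exact mean and pulsatility.

    The fluctuation is a sum of ``n_harmonics`` harmonics with 1/k amplitude
    decay and seeded random phases, normalized on the sample grid so that the
    cycle mean equals ``mean_flow`` (to machine precision under the periodic
    trapezoid rule) and (max-min)/mean equals ``pulsatility``.
    """
    if mean_flow <= 0:
        raise ValueError("mean_flow must be positive")
    if not (0.0 <= pulsatility <= 1.0):
        raise ValueError("pulsatility must lie in [0, 1]")
    if n_harmonics < 1 or n_samples < 2 * n_harmonics + 2:
        raise ValueError("need n_harmonics >= 1 and n_samples > 2*n_harmonics+1")
    t = period * np.arange(n_samples) / n_samples
    if pulsatility == 0.0:
        return Waveform(times=t, flows=np.full(n_samples, mean_flow), period=period)
    rng = np.random.default_rng(seed)
    g = np.zeros(n_samples)
    for k in range(1, n_harmonics + 1):
        amp = 1.0 / k
        phase = rng.uniform(0.0, 2.0 * np.pi)
        g += amp * np.cos(2.0 * np.pi * k * t / period + phase)
    g -= g.mean()  # zero mean on the uniform grid (hence zero cycle integral)
    g /= g.max() - g.min()  # range exactly 1
    q = mean_flow * (1.0 + pulsatility * g)
    if np.any(q < 0):
        raise ValueError("parameters produced negative flow")
    return Waveform(times=t, flows=q, period=period)


@dataclass(frozen=True)
class FlowSplit:
    """Fractional division of cycle-integrated flow between two outflows."""

    fraction_left: float
    fraction_right: float

    def __post_init__(self) -> None:
        fl, fr = self.fraction_left, self.fraction_right
        if not (0.0 <= fl <= 1.0 and 0.0 <= fr <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(fl + fr - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def flow_split(left: Waveform, right: Waveform) -> FlowSplit:
    """Left/right division of cycle-integrated flow between the transverse
    sinuses: fraction_left = oint Q_L dt / (oint Q_L dt + oint Q_R dt)."""
    if abs(left.period - right.period) > 1e-9 * max(left.period, right.period):
        raise ValueError("waveforms must share a period")
    il = left.cycle_integral()
    ir = right.cycle_integral()
    tot = il + ir
    if tot == 0.0:
        raise ValueError("both cycle integrals are zero; split undefined")
    fl = il / tot
    return FlowSplit(fraction_left=fl, fraction_right=1.0 - fl)
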