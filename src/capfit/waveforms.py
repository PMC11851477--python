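"""Pulsatile flow waveform synthesis and sampled-signal I/O.

The circuit is driven by a systolic pulse: within each cardiac cycle of
period TH the flow is a sine lobe during systole, Q(t) = Q0*sin(2*pi*t/Ts)
for t in (0, Ts), and zero during diastole (Ts, TH).  The default rhythm
is 72 beats per minute (TH = 60/72 s) with a systolic fraction of 2/5
(Ts = 0.4*TH).  The target (capillary exit) signal is the same pulse
delayed by a configurable phase — 90 degrees of the systolic sine, i.e.
Ts/4 — and rescaled so its peak equals the ABI-derived capillary flow.

``full_sine`` follows the printed 2*pi argument literally (the diastolic
half-lobe is negative); ``half_sine`` replaces it with a single positive
lobe, sin(pi*t/Ts), for users who consider retrograde diastolic flow
unphysiological.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, SignalParseError

#: Cardiac period for 72 beats per minute, seconds.
DEFAULT_HEART_PERIOD = 60.0 / 72.0

#: Fraction of the cycle spent in systole (Ts = fraction * TH).
DEFAULT_SYSTOLIC_FRACTION = 2.0 / 5.0


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled time series starting at t = 0.

    ``times`` must be strictly increasing and uniformly spaced; ``values``
    must be finite and the same length.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise InvalidInputError("times and values must be 1-D arrays of equal length")
        if times.size < 2:
            raise InvalidInputError("a sampled signal needs at least two samples")
        diffs = np.diff(times)
        if np.any(diffs <= 0):
            raise InvalidInputError("times must be strictly increasing")
        dt = diffs[0]
        if not np.allclose(diffs, dt, rtol=1e-6, atol=1e-12 * max(dt, 1.0)):
            raise InvalidInputError("times must form a uniform grid")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("signal values must be finite")

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        """Total record length in seconds."""
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class WaveformSpec:
    """Specification of the periodic systolic pulse train.

    Parameters
    ----------
    peak_flow : float
        Pulse amplitude Q0 (m^3/s, or abstract units for the unit-agnostic
        circuit layer).  Must be nonnegative.
    heart_period : float
        Cardiac period TH in seconds; default 60/72 (72 BPM).
    systolic_fraction : float
        Ts / TH, strictly between 0 and 1; default 2/5.
    n_cycles : int
        Number of cardiac cycles in the record; default 3.
    dt : float or None
        Sampling interval; defaults to TH/1000.  Must resolve the systolic
        lobe (dt < Ts/20).
    phase_shift_deg : float
        Delay of the target pulse, in degrees of the systolic sine period
        (90 degrees = Ts/4).
    shape : {"full_sine", "half_sine"}
        Systolic lobe shape, see module docstring.
    """

    peak_flow: float
    heart_period: float = DEFAULT_HEART_PERIOD
    systolic_fraction: float = DEFAULT_SYSTOLIC_FRACTION
    n_cycles: int = 3
    dt: float | None = None
    phase_shift_deg: float = 90.0
    shape: Literal["full_sine", "half_sine"] = "full_sine"

    def __post_init__(self) -> None:
        if self.peak_flow < 0:
            raise InvalidInputError("peak flow must be nonnegative")
        if self.heart_period <= 0:
            raise InvalidInputError("heart period must be positive")
        if not 0.0 < self.systolic_fraction < 1.0:
            raise InvalidInputError("systolic fraction must lie in (0, 1)")
        if self.n_cycles < 1:
            raise InvalidInputError("need at least one cycle")
        if self.shape not in ("full_sine", "half_sine"):
            raise InvalidInputError(f"unknown pulse shape {self.shape!r}")
        if self.grid_dt >= self.systolic_period / 20.0:
            raise InvalidInputError("dt too coarse: must be < Ts/20 to resolve the systolic lobe")

    @property
    def systolic_period(self) -> float:
        """Ts = systolic_fraction * TH, seconds."""
        return self.systolic_fraction * self.heart_period

    @property
    def grid_dt(self) -> float:
        """Effective sampling interval (TH/1000 unless overridden)."""
        return self.dt if self.dt is not None else self.heart_period / 1000.0

    @property
    def phase_delay(self) -> float:
        """Target delay in seconds: (phase_shift_deg/360) * Ts."""
        return self.phase_shift_deg / 360.0 * self.systolic_period


def _pulse_values(t: np.ndarray, spec: WaveformSpec, amplitude: float) -> np.ndarray:
    """Evaluate the periodic pulse train at times ``t`` (zero for t < 0)."""
    th, ts = spec.heart_period, spec.systolic_period
    tau = np.mod(t, th)
    in_record = (t >= 0.0) & (t <= spec.n_cycles * th)
    systole = in_record & (tau < ts)
    out = np.zeros_like(t)
    if spec.shape == "full_sine":
        out[systole] = amplitude * np.sin(2.0 * math.pi * tau[systole] / ts)
    else:
        out[systole] = amplitude * np.sin(math.pi * tau[systole] / ts)
    return out


def systolic_pulse(spec: WaveformSpec) -> SampledSignal:
    """Synthesize the pulsatile input flow signal for ``spec.n_cycles`` beats."""
    dt = spec.grid_dt
    n = int(round(spec.n_cycles * spec.heart_period / dt)) + 1
    times = np.arange(n) * dt
    return SampledSignal(times=times, values=_pulse_values(times, spec, spec.peak_flow))


def phase_shifted_target(
    input_signal: SampledSignal, spec: WaveformSpec, amplitude: float
) -> SampledSignal:
    """Delayed, rescaled copy of the pulse train on the input's grid.

    The pulse is delayed by ``spec.phase_delay`` and its peak set to
    ``amplitude``; samples before the delayed support are zero-filled.
    """
    if amplitude < 0:
        raise InvalidInputError("amplitude must be nonnegative")
    values = _pulse_values(input_signal.times - spec.phase_delay, spec, amplitude)
    return SampledSignal(times=input_signal.times.copy(), values=values)


def read_signal(path: str | Path) -> SampledSignal:
    """Read a two-column ``time_s,value`` CSV into a :class:`SampledSignal`."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SignalParseError(f"cannot parse signal file {path}: {exc}") from exc
    if list(df.columns[:2]) != ["time_s", "value"]:
        raise SignalParseError(f"{path}: expected header 'time_s,value', got {list(df.columns)}")
    if df.isna().any().any():
        raise SignalParseError(f"{path}: ragged rows or missing values")
    try:
        return SampledSignal(times=df["time_s"].to_numpy(), values=df["value"].to_numpy())
    except InvalidInputError as exc:
        raise SignalParseError(f"{path}: {exc}") from exc


def write_signal(signal: SampledSignal, path: str | Path) -> None:
    """Write a signal as a ``time_s,value`` CSV (round-trips to ~1e-12 relative)."""
    pd.DataFrame({"time_s": signal.times, "value": signal.values}).to_csv(
        path, index=False, float_format="%.17g"
    )
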