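"""Raw surface-EMG reduction to averaged, normalized gait-cycle envelopes.

The chain mirrors standard clinical-gait EMG conditioning: zero-phase
Butterworth band-pass (20-350 Hz) on the raw signal, full-wave
rectification followed by a zero-phase 9 Hz Butterworth low-pass (the
linear envelope), stride segmentation from foot-strike events with linear
resampling of each stride onto the 101-point cycle grid, pointwise
averaging across valid strides, and amplitude normalization to a cycle
mean of 100 (percent-of-mean units).

Both filters are 4th-order and applied forward-backward (``sosfiltfilt``)
so envelope timing features are not phase-shifted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core import N_GRID, EmgEnvelope
from .errors import (DegenerateSignalError, InsufficientDataError,
                     SamplingRateError)

logger = logging.getLogger(__name__)

BAND_HZ = (20.0, 350.0)
LOWPASS_HZ = 9.0
FILTER_ORDER = 4
MIN_FS = 2.0 * BAND_HZ[1]  # Nyquist bound for the band-pass upper edge


@dataclass
class RawEmgTrace:
    """A raw signed EMG series with its gait events.

    ``events`` is an ordered list of ``(type, time_s)`` with type
    ``foot_strike`` or ``foot_off``; strides are delimited by consecutive
    foot strikes.
    """

    samples: np.ndarray
    fs: float
    events: list[tuple[str, float]]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        times = [t for _, t in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")


def bandpass_filter(trace: RawEmgTrace) -> np.ndarray:
    """Zero-phase 20-350 Hz Butterworth band-pass of the raw signal."""
    if trace.fs <= MIN_FS:
        raise SamplingRateError(
            f"fs={trace.fs} Hz cannot represent the {BAND_HZ[1]} Hz band edge"
        )
    sos = butter(FILTER_ORDER, BAND_HZ, btype="bandpass", fs=trace.fs, output="sos")
    return sosfiltfilt(sos, trace.samples)


def rectify_and_smooth(filtered: np.ndarray, fs: float) -> np.ndarray:
    """Full-wave rectification then zero-phase 9 Hz low-pass; clipped at 0."""
    sos = butter(FILTER_ORDER, LOWPASS_HZ, btype="lowpass", fs=fs, output="sos")
    return np.clip(sosfiltfilt(sos, np.abs(filtered)), 0.0, None)


def _complete_strides(events: list[tuple[str, float]]) -> list[tuple[float, float, float]]:
    """(strike, foot_off, next_strike) triples for strides with exactly
    one interior foot-off; others are dropped with a warning."""
    strikes = [t for e, t in events if e == "foot_strike"]
    offs = np.array([t for e, t in events if e == "foot_off"])
    strides = []
    for a, b in zip(strikes, strikes[1:]):
        inside = offs[(offs > a) & (offs < b)]
        if len(inside) != 1:
            logger.warning("stride %.3f-%.3f s has %d interior foot-offs; excluded",
                           a, b, len(inside))
            continue
        strides.append((a, float(inside[0]), b))
    return strides


def segment_and_average_strides(envelope: np.ndarray, fs: float,
                                events: list[tuple[str, float]]) -> tuple[np.ndarray, float]:
    """Average the linear envelope across valid strides on the 101-grid.

    Each foot-strike-to-foot-strike stride is linearly resampled to 101
    points; valid strides (exactly one interior foot-off, duration within
    3 SD of the median stride duration) are averaged pointwise.  Returns
    the averaged cycle (raw scale) and the mean foot-off percentage.
    """
    strides = _complete_strides(events)
    if not strides:
        raise InsufficientDataError("no complete stride (foot_strike -> foot_strike)")
    durations = np.array([b - a for a, _, b in strides])
    if len(durations) >= 3:
        med, sd = np.median(durations), durations.std(ddof=1)
        keep = np.abs(durations - med) <= 3.0 * sd if sd > 0 else np.ones(len(durations), bool)
        if not keep.all():
            logger.warning("excluding %d stride(s) with outlying duration", (~keep).sum())
        strides = [s for s, k in zip(strides, keep) if k]
    t = np.arange(len(envelope)) / fs
    grid = np.linspace(0.0, 1.0, N_GRID)
    cycles, foot_offs = [], []
    for a, off, b in strides:
        cycles.append(np.interp(a + grid * (b - a), t, envelope))
        foot_offs.append(100.0 * (off - a) / (b - a))
    return np.mean(cycles, axis=0), float(np.mean(foot_offs))


def amplitude_normalize(cycle: np.ndarray, foot_off_pct: float = 60.0,
                        subject_id: str = "", side: str = "",
                        group: str = "") -> EmgEnvelope:
    """Scale a 101-sample cycle so its mean is exactly 100."""
    cycle = np.asarray(cycle, dtype=float)
    m = cycle.mean()
    if m <= 0:
        raise DegenerateSignalError(f"cycle mean {m} is not positive")
    return EmgEnvelope(values=cycle * (100.0 / m), foot_off_pct=foot_off_pct,
                       subject_id=subject_id, side=side, group=group)


def process_trace(trace: RawEmgTrace, subject_id: str = "", side: str = "",
                  group: str = "") -> EmgEnvelope:
    """Full chain: band-pass, rectify + smooth, stride-average, normalize."""
    filtered = bandpass_filter(trace)
    env = rectify_and_smooth(filtered, trace.fs)
    cycle, foot_off_pct = segment_and_average_strides(env, trace.fs, trace.events)
    return amplitude_normalize(cycle, foot_off_pct, subject_id, side, group).validate()
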