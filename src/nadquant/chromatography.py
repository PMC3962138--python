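"""SRM trace processing: noise estimation, peak integration, peak selection.

A chromatogram here is a single SRM channel's time/intensity table.  Peaks
are integrated with the trapezoidal rule above a zero baseline, signal to
noise is peak *height* over a robust (MAD-based) baseline noise scale, and
the peak belonging to an analyte is chosen purely by retention-time
proximity — the mechanism that rejects crosstalk peaks, which sit at the
source metabolite's retention time rather than the analyte's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "TransitionTrace",
    "Peak",
    "estimate_noise",
    "detect_and_integrate",
    "select_peak",
    "capacity_factor",
    "DEFAULT_RT_WINDOW",
    "DEFAULT_NOISE_FLOOR",
    "DEFAULT_DETECTION_SNR",
]

#: Retention-time window (+/- minutes) for assigning a peak to an analyte.
#: The tightest crosstalk pair on the panel is cytidine (11.14 min) bleeding
#: into uridine (11.50 min), 0.36 min apart, so +/-0.3 min separates them.
DEFAULT_RT_WINDOW = 0.3

#: Noise scale reported for a perfectly constant trace (counts).
DEFAULT_NOISE_FLOOR = 1.0

#: Local maxima below this multiple of the noise are not called as peaks.
DEFAULT_DETECTION_SNR = 3.0

#: Peak boundaries stop at the first point below this fraction of apex height.
_BOUND_FRACTION = 0.02

#: Moving-average width (samples) for the smoothed copy used to place bounds.
_SMOOTH_POINTS = 5


@dataclass(frozen=True)
class TransitionTrace:
    """One SRM channel's chromatogram: strictly increasing times, counts >= 0."""

    channel_id: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intensities)
        if times.ndim != 1 or times.shape != intensities.shape:
            raise ValueError("times and intensities must be equal-length 1-D arrays")
        if times.size < 2:
            raise ValueError("trace needs at least two points")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class Peak:
    """An integrated chromatographic peak on one channel."""

    apex_rt: float          # minutes
    left_bound: float       # minutes
    right_bound: float      # minutes
    area: float             # counts * min
    height: float           # counts
    noise: float            # counts
    s2n: float              # dimensionless, height / noise

    def __post_init__(self) -> None:
        if not self.left_bound < self.apex_rt < self.right_bound:
            raise ValueError("peak bounds must bracket the apex")
        if self.area < 0:
            raise ValueError("peak area must be non-negative")


def estimate_noise(
    trace: TransitionTrace,
    exclusion_windows: list[tuple[float, float]] | None = None,
    floor: float = DEFAULT_NOISE_FLOOR,
) -> float:
    """Robust baseline noise scale of a trace, in counts.

    Computes 1.4826 x the median absolute deviation of intensities outside
    the exclusion windows (typically windows around every expected analyte
    peak), which estimates the Gaussian sigma of the baseline.  A constant
    trace returns ``floor`` so that signal-to-noise stays finite.
    """
    mask = np.ones(trace.times.size, dtype=bool)
    for lo, hi in exclusion_windows or []:
        mask &= ~((trace.times >= lo) & (trace.times <= hi))
    if mask.sum() < 10:
        raise ValueError("fewer than 10 baseline points outside exclusion windows")
    baseline = trace.intensities[mask]
    mad = np.median(np.abs(baseline - np.median(baseline)))
    noise = 1.4826 * mad
    return float(noise) if noise > 0 else float(floor)


def detect_and_integrate(
    trace: TransitionTrace,
    noise: float | None = None,
    threshold_snr: float = DEFAULT_DETECTION_SNR,
    exclusion_windows: list[tuple[float, float]] | None = None,
) -> list[Peak]:
    """Find local maxima above ``threshold_snr x noise`` and integrate them.

    Peak boundaries extend from the apex to the nearer of the flanking local
    minimum and the first point below 2% of apex height; the area is the
    trapezoidal integral between the bounds above a zero baseline.  A flat
    trace yields no peaks.  Single-sample spikes are not called (a genuine
    chromatographic peak spans several samples at any sensible sampling
    rate), which keeps baseline noise excursions out of the peak list.
    """
    if noise is None:
        noise = estimate_noise(trace, exclusion_windows)
    y = trace.intensities
    t = trace.times
    height_thr = threshold_snr * noise
    idx, _ = find_peaks(y, height=height_thr, prominence=height_thr, width=2)
    # Boundaries are walked on a lightly smoothed copy so that baseline noise
    # neither fakes a local minimum nor dips below the 2%-of-apex cutoff
    # prematurely; the area is still integrated on the raw trace (zero-mean
    # noise integrates to nothing) so heights and areas stay unbiased.
    ys = _smooth(y, _SMOOTH_POINTS)
    noise_s = noise / math.sqrt(_SMOOTH_POINTS)
    peaks: list[Peak] = []
    for apex in idx:
        lo = _walk_bound(ys, apex, step=-1, noise=noise_s)
        hi = _walk_bound(ys, apex, step=+1, noise=noise_s)
        if lo == apex or hi == apex:
            continue
        area = float(np.trapezoid(y[lo : hi + 1], t[lo : hi + 1]))
        peaks.append(
            Peak(
                apex_rt=float(t[apex]),
                left_bound=float(t[lo]),
                right_bound=float(t[hi]),
                area=max(area, 0.0),
                height=float(y[apex]),
                noise=float(noise),
                s2n=float(y[apex] / noise) if noise > 0 else float("inf"),
            )
        )
    peaks.sort(key=lambda p: p.apex_rt)
    return peaks


def _smooth(y: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average with edge padding."""
    kernel = np.ones(w) / w
    padded = np.concatenate([np.full(w // 2, y[0]), y, np.full(w // 2, y[-1])])
    return np.convolve(padded, kernel, mode="valid")[: y.size]


def _walk_bound(y: np.ndarray, apex: int, step: int, noise: float = 0.0) -> int:
    """March from the apex to the nearer of a genuine local minimum and the
    first point below 2% of apex height.

    A minimum only counts as a boundary once the trace has risen at least
    three noise scales back above it — a real valley before an adjacent
    peak, not a baseline wiggle.
    """
    cutoff = _BOUND_FRACTION * y[apex]
    i = apex
    min_i = apex
    while True:
        j = i + step
        if j < 0 or j >= y.size:
            return min_i if min_i != apex else i
        if y[j] <= cutoff:
            return j
        if y[j] < y[min_i]:
            min_i = j
        elif y[j] > y[min_i] + 3.0 * noise and min_i != apex:
            return min_i  # valley between overlapping peaks
        i = j


def select_peak(
    peaks: list[Peak],
    expected_rt: float,
    window: float = DEFAULT_RT_WINDOW,
) -> Peak | None:
    """Pick the analyte's peak: nearest apex within +/-``window`` minutes.

    Ties in apex distance go to the larger area.  Returns ``None`` when no
    apex falls in the window (crosstalk peaks at another analyte's retention
    time are rejected here).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    candidates = [p for p in peaks if abs(p.apex_rt - expected_rt) <= window]
    if not candidates:
        return None
    return min(candidates, key=lambda p: (abs(p.apex_rt - expected_rt), -p.area))


def capacity_factor(rt: float, t0: float) -> float:
    """Chromatographic capacity factor k' = (rt - t0) / t0.

    ``t0`` is the column void time in minutes; an analyte eluting before the
    void marker is unphysical and raises.
    """
    if t0 <= 0:
        raise ValueError("void time t0 must be positive")
    if rt < t0:
        raise ValueError("retention time earlier than the void time")
    return (rt - t0) / t0
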