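"""Twitch contraction analysis: low-pass filtering, per-twitch peak
torque and rise slope, and series averages.

"Rise time" is reported here, as is conventional in evoked-force work,
as the slope of the ascending limb between 30% and 70% of the twitch
peak, in Nm/s — a rate, despite the name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import ParameterError
from .segment import ContractionWindow, ForceTrace

__all__ = [
    "lowpass_filter",
    "TwitchFeatures",
    "twitch_features",
    "TwitchSeriesSummary",
    "summarize_twitch_series",
]


def lowpass_filter(trace: ForceTrace, cutoff: float = 15.0, order: int = 4) -> ForceTrace:
    """Zero-phase Butterworth low-pass filter of the whole trace.

    The filter is applied forward and backward (``filtfilt``), so the
    passband is distortion- and delay-free; ``order`` is the order of a
    single pass.  Metadata is preserved.
    """
    if cutoff >= trace.sampling_rate / 2:
        raise ParameterError("cutoff must be below the Nyquist frequency")
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    b, a = butter(order, cutoff, btype="low", fs=trace.sampling_rate)
    filtered = filtfilt(b, a, trace.samples)
    out = dc_replace(trace, samples=filtered)
    out.meta = dict(trace.meta, lowpass_cutoff_hz=cutoff)
    return out


@dataclass(frozen=True)
class TwitchFeatures:
    """Features of one twitch: baseline-corrected peak torque (Nm), the
    30-70% rise slope (Nm/s), and the peak time (s, trace clock).
    Invalid twitches (peak indistinguishable from noise, or crossings
    not found) carry ``valid=False`` and NaN features."""

    peak_torque: float
    rise_slope: float
    t_peak: float
    t30: float
    t70: float
    baseline: float
    valid: bool


_INVALID = dict(rise_slope=float("nan"), t30=float("nan"), t70=float("nan"), valid=False)


def twitch_features(
    trace: ForceTrace,
    window: ContractionWindow,
    baseline_duration: float = 0.05,
    noise_factor: float = 3.0,
) -> TwitchFeatures:
    """Peak torque and 30-70% rise slope of one twitch window.

    The local baseline is the mean of ``baseline_duration`` s
    immediately preceding the onset (robust to slow drift); the noise
    floor is the SD of that segment, and a twitch whose peak does not
    exceed ``noise_factor`` times the noise floor is flagged invalid.
    Crossing times are linearly interpolated between samples on the
    ascending limb.
    """
    if window.kind != "twitch":
        raise ParameterError("twitch_features requires a twitch window")
    fs = trace.sampling_rate
    i_on = trace.index_at(window.onset)
    i_off = min(trace.index_at(window.offset), trace.n_samples)
    if i_off <= i_on:
        raise ParameterError("twitch window lies outside the trace")

    i_base = max(0, i_on - int(round(baseline_duration * fs)))
    base_seg = trace.samples[i_base:i_on]
    baseline = float(np.mean(base_seg)) if base_seg.size else 0.0
    noise_sd = float(np.std(base_seg, ddof=1)) if base_seg.size > 1 else 0.0

    y = trace.samples[i_on:i_off] - baseline
    ipk = int(np.argmax(y))
    peak = float(y[ipk])
    t_peak = window.onset + ipk / fs

    def invalid() -> TwitchFeatures:
        return TwitchFeatures(peak_torque=max(peak, 0.0), t_peak=t_peak,
                              baseline=baseline, **_INVALID)

    if peak <= 0.0 or ipk == 0 or peak <= noise_factor * noise_sd:
        return invalid()

    rising = y[: ipk + 1]

    def crossing(level: float) -> float | None:
        idx = np.flatnonzero(rising >= level)
        if idx.size == 0:
            return None
        i = int(idx[0])
        if i == 0:
            return 0.0
        frac = (level - rising[i - 1]) / (rising[i] - rising[i - 1])
        return (i - 1 + frac) / fs

    t30 = crossing(0.3 * peak)
    t70 = crossing(0.7 * peak)
    if t30 is None or t70 is None or not t70 > t30:
        return invalid()
    rise_slope = 0.4 * peak / (t70 - t30)
    return TwitchFeatures(
        peak_torque=peak,
        rise_slope=rise_slope,
        t_peak=t_peak,
        t30=window.onset + t30,
        t70=window.onset + t70,
        baseline=baseline,
        valid=True,
    )


@dataclass(frozen=True)
class TwitchSeriesSummary:
    """Averages over the valid twitches of one series (phase 'initial'
    before the tetanic phase, 'final' after it)."""

    phase: str
    mean_peak_torque: float
    mean_rise_slope: float
    n_valid: int

    def __post_init__(self) -> None:
        if self.phase not in ("initial", "final"):
            raise ParameterError(f"unknown twitch phase {self.phase!r}")


def summarize_twitch_series(
    features: list[TwitchFeatures], phase: str
) -> TwitchSeriesSummary:
    """Arithmetic means of peak torque and rise slope over valid twitches.

    With zero valid twitches the means are NaN and ``n_valid`` is 0."""
    if not features:
        raise ParameterError("empty twitch series")
    valid = [f for f in features if f.valid]
    if not valid:
        return TwitchSeriesSummary(phase, math.nan, math.nan, 0)
    return TwitchSeriesSummary(
        phase=phase,
        mean_peak_torque=float(np.mean([f.peak_torque for f in valid])),
        mean_rise_slope=float(np.mean([f.rise_slope for f in valid])),
        n_valid=len(valid),
    )
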