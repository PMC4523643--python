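"""Force-trace container, contraction-window location, and tetanic torque extraction.

Time convention: all times are seconds from the start of the trace
(``start_time``); sample ``i`` covers the half-open interval
``[i/fs, (i+1)/fs)`` and windows are half-open ``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BoundsError, ParameterError
from .protocol import StimulationProtocol

__all__ = [
    "ForceTrace",
    "ContractionWindow",
    "TetanicTorqueSeries",
    "segment_by_protocol",
    "segment_by_threshold",
    "tetanic_torque",
    "extract_torque_series",
    "peak_tetanic_torque",
]


@dataclass
class ForceTrace:
    """A uniformly sampled torque recording (Nm) with session metadata.

    ``motor_threshold_vm_ma`` / ``motor_threshold_vl_ma`` carry the
    stimulation thresholds of the vastus medialis / lateralis channels
    (mA); they are plain metadata and never enter the signal analysis.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    subject_id: str = ""
    session_id: str = ""
    side: str = ""
    motor_threshold_vm_ma: float | None = None
    motor_threshold_vl_ma: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ParameterError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Sample index whose interval starts closest to time ``t``."""
        return int(round((t - self.start_time) * self.sampling_rate))

    def slice(self, onset: float, offset: float) -> np.ndarray:
        """Samples covering ``[onset, offset)``."""
        i0 = self.index_at(onset)
        i1 = self.index_at(offset)
        if i0 < 0 or i1 > self.n_samples or i1 <= i0:
            raise BoundsError(
                f"window [{onset:g}, {offset:g}) s outside trace of {self.duration:g} s"
            )
        return self.samples[i0:i1]


@dataclass(frozen=True)
class ContractionWindow:
    """One contraction's location: ``kind`` is 'twitch' or 'tetanic',
    ``index`` the 1-based ordinal within that kind."""

    kind: str
    index: int
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if self.kind not in ("twitch", "tetanic"):
            raise ParameterError(f"unknown window kind {self.kind!r}")
        if not self.offset > self.onset:
            raise ParameterError("window offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class TetanicTorqueSeries:
    """Per-contraction tetanic torque values (Nm) with onset times (s)."""

    values: np.ndarray
    onset_times: np.ndarray
    contraction_indices: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        self.contraction_indices = np.asarray(self.contraction_indices, dtype=int)
        if not (len(self.values) == len(self.onset_times) == len(self.contraction_indices)):
            raise ParameterError("values, onset_times and contraction_indices must align")
        if len(self.onset_times) > 1 and not np.all(np.diff(self.onset_times) > 0):
            raise ParameterError("onset_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)


def segment_by_protocol(
    trace: ForceTrace, protocol: StimulationProtocol, t0: float | None = None
) -> list[ContractionWindow]:
    """Derive contraction windows from the known stimulus schedule.

    ``t0`` is the onset of the first pre-twitch, in trace time.  When
    omitted it is taken from the trace metadata (``meta['t0']``) or
    defaults to the protocol lead-in.  Tetanic windows span the
    on-phase; twitch windows span up to one inter-twitch interval,
    capped at 1 s.
    """
    if t0 is None:
        t0 = float(trace.meta.get("t0", protocol.lead_in))
    if not (trace.start_time <= t0 <= trace.start_time + trace.duration):
        raise BoundsError(f"t0={t0:g} s lies outside the trace")

    twitch_len = min(protocol.inter_twitch_interval, 1.0)
    windows: list[ContractionWindow] = []
    n_twitch = 0
    for onset in protocol.pre_twitch_onsets(t0):
        n_twitch += 1
        windows.append(ContractionWindow("twitch", n_twitch, onset, onset + twitch_len))
    for k, onset in enumerate(protocol.tetanic_onsets(t0), start=1):
        windows.append(ContractionWindow("tetanic", k, onset, onset + protocol.on_duration))
    for onset in protocol.post_twitch_onsets(t0):
        n_twitch += 1
        windows.append(ContractionWindow("twitch", n_twitch, onset, onset + twitch_len))

    end = trace.start_time + trace.duration
    if windows and windows[-1].offset > end + 0.5 / trace.sampling_rate:
        raise BoundsError(
            f"schedule extends to {windows[-1].offset:g} s but trace ends at {end:g} s"
        )
    return windows


def segment_by_threshold(
    trace: ForceTrace,
    threshold_fraction: float = 0.05,
    min_duration: float = 0.05,
    merge_gap: float = 0.02,
    tetanic_min_duration: float = 1.0,
) -> list[ContractionWindow]:
    """Locate contractions from the signal alone (stimulus timing unknown).

    The baseline is the median of the first 0.5 s; runs of samples
    exceeding ``threshold_fraction`` of the baseline-subtracted maximum
    are contraction candidates.  Runs separated by less than
    ``merge_gap`` s are merged (crossing jitter), runs shorter than
    ``min_duration`` are discarded, and runs of at least
    ``tetanic_min_duration`` s are classified as tetanic.  A flat trace
    yields an empty list.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ParameterError("threshold_fraction must lie in (0, 1)")
    fs = trace.sampling_rate
    n_base = max(1, int(round(0.5 * fs)))
    baseline = float(np.median(trace.samples[:n_base]))
    x = trace.samples - baseline
    peak = float(np.max(x))
    if peak <= 0.0:
        return []
    above = x > threshold_fraction * peak
    if not above.any():
        return []

    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    stops = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(above))

    # merge runs separated by sub-merge_gap dips
    gap = int(round(merge_gap * fs))
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts, stops):
        if merged and s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    windows: list[ContractionWindow] = []
    counters = {"twitch": 0, "tetanic": 0}
    for s, e in merged:
        dur = (e - s) / fs
        if dur < min_duration:
            continue
        kind = "tetanic" if dur >= tetanic_min_duration else "twitch"
        counters[kind] += 1
        onset = trace.start_time + s / fs
        windows.append(ContractionWindow(kind, counters[kind], onset, onset + dur))
    return windows


def tetanic_torque(trace: ForceTrace, window: ContractionWindow) -> float:
    """Plateau torque of a tetanic contraction: mean over the last second
    of the on-phase (``round(fs)`` samples before the window offset)."""
    if window.kind != "tetanic":
        raise ParameterError("tetanic_torque requires a tetanic window")
    if window.duration < 1.0 - 0.5 / trace.sampling_rate:
        raise ParameterError("tetanic window must be at least 1 s long")
    return float(np.mean(trace.slice(window.offset - 1.0, window.offset)))


def extract_torque_series(
    trace: ForceTrace, windows: list[ContractionWindow]
) -> TetanicTorqueSeries:
    """Per-contraction torque for every tetanic window of a trace."""
    tet = [w for w in windows if w.kind == "tetanic"]
    return TetanicTorqueSeries(
        values=[tetanic_torque(trace, w) for w in tet],
        onset_times=[w.onset for w in tet],
        contraction_indices=[w.index for w in tet],
    )


def peak_tetanic_torque(series: TetanicTorqueSeries, interval) -> float:
    """Highest per-contraction torque within an interval of the series."""
    mask = (series.contraction_indices >= interval.first_contraction) & (
        series.contraction_indices <= interval.last_contraction
    )
    if not mask.any():
        raise ParameterError(f"interval {interval.name} covers no contractions")
    return float(np.max(series.values[mask]))
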