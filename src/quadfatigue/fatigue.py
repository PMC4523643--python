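"""Fatigue Index and slope-of-regression metrics over contraction intervals.

The tetanic phase is subdivided into four conventional intervals:
interval 1 = contractions 1-15 (first minute), interval 2 = 16-30
(second minute), interval 3 = 1-30 (first two minutes), interval 4 =
1-40 (the whole 160 s period).  Within an interval, the Fatigue Index
(FI) is the mean torque of its final three contractions divided by the
mean of its first three; the slope of regression (SOR) is the ordinary
least-squares slope of torque against time (or ordinal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, UndefinedResultError
from .segment import TetanicTorqueSeries, peak_tetanic_torque
from .twitch import TwitchSeriesSummary

__all__ = [
    "IntervalDefinition",
    "INTERVALS",
    "fatigue_index",
    "slope_of_regression",
    "SessionSummary",
    "summarize_session",
]


@dataclass(frozen=True)
class IntervalDefinition:
    """A contiguous range of tetanic contractions (1-based, inclusive)."""

    name: str
    first_contraction: int
    last_contraction: int
    nominal_duration: float  # s, at the default 4 s cycle

    def __post_init__(self) -> None:
        if self.last_contraction < self.first_contraction or self.first_contraction < 1:
            raise ParameterError("invalid interval bounds")

    @property
    def n_contractions(self) -> int:
        return self.last_contraction - self.first_contraction + 1


INTERVALS: dict[str, IntervalDefinition] = {
    "interval1": IntervalDefinition("interval1", 1, 15, 60.0),
    "interval2": IntervalDefinition("interval2", 16, 30, 60.0),
    "interval3": IntervalDefinition("interval3", 1, 30, 120.0),
    "interval4": IntervalDefinition("interval4", 1, 40, 160.0),
}


def _interval_slice(series: TetanicTorqueSeries, interval: IntervalDefinition):
    mask = (series.contraction_indices >= interval.first_contraction) & (
        series.contraction_indices <= interval.last_contraction
    )
    return series.values[mask], series.onset_times[mask], series.contraction_indices[mask]


def fatigue_index(series: TetanicTorqueSeries, interval: IntervalDefinition) -> float:
    """Mean torque of the interval's final three contractions over the
    mean of its first three (both taken within the interval).

    A value of 1 means no decline; lower values mean more fatigue.
    """
    values, _, _ = _interval_slice(series, interval)
    if len(values) < 6:
        raise ParameterError(
            f"{interval.name} holds {len(values)} contractions; at least 6 required"
        )
    first = float(np.mean(values[:3]))
    last = float(np.mean(values[-3:]))
    if first <= 0.0:
        raise UndefinedResultError("fatigue index undefined: nonpositive initial torque")
    return last / first


def slope_of_regression(
    series: TetanicTorqueSeries,
    interval: IntervalDefinition,
    time_axis: str = "seconds",
) -> float:
    """OLS slope of per-contraction torque over the interval.

    ``time_axis='seconds'`` regresses on elapsed time at contraction
    onset (Nm/s); ``'contraction_index'`` regresses on the 1-based
    ordinal (Nm per contraction).  With onsets 4 s apart the two differ
    by exactly a factor of 4.
    """
    values, onsets, indices = _interval_slice(series, interval)
    if len(values) < 2:
        raise ParameterError("slope of regression needs at least 2 contractions")
    if time_axis == "seconds":
        x = onsets
    elif time_axis == "contraction_index":
        x = indices.astype(float)
    else:
        raise ParameterError(f"unknown time_axis {time_axis!r}")
    slope, _ = np.polyfit(x, values, 1)
    return float(slope)


@dataclass
class SessionSummary:
    """Per-session outcome variables of one fatigability test.

    ``first_peak_torque`` is the torque of the very first tetanic
    contraction (the value used to calibrate stimulation intensity on
    the retest day); ``peak_torque`` is the maximum per-contraction
    torque over the whole tetanic phase.  ``fi`` and the two ``sor``
    dicts are keyed by interval name.
    """

    subject_id: str
    session_id: str
    side: str = ""
    first_peak_torque: float = float("nan")
    peak_torque: float = float("nan")
    fi: dict[str, float] = field(default_factory=dict)
    sor_seconds: dict[str, float] = field(default_factory=dict)
    sor_index: dict[str, float] = field(default_factory=dict)
    twitch_initial: TwitchSeriesSummary | None = None
    twitch_final: TwitchSeriesSummary | None = None
    motor_threshold_vm_ma: float | None = None
    motor_threshold_vl_ma: float | None = None


def summarize_session(
    series: TetanicTorqueSeries,
    twitch_initial: TwitchSeriesSummary | None = None,
    twitch_final: TwitchSeriesSummary | None = None,
    *,
    subject_id: str = "",
    session_id: str = "",
    side: str = "",
    motor_threshold_vm_ma: float | None = None,
    motor_threshold_vl_ma: float | None = None,
    intervals: dict[str, IntervalDefinition] = INTERVALS,
    expected_contractions: int | None = 40,
) -> SessionSummary:
    """Assemble the session's fatigue metrics and twitch summaries."""
    if expected_contractions is not None and len(series) != expected_contractions:
        raise ParameterError(
            f"series holds {len(series)} contractions, protocol expects {expected_contractions}"
        )
    full = IntervalDefinition(
        "full", 1, int(series.contraction_indices.max()), float("nan")
    )
    summary = SessionSummary(
        subject_id=subject_id,
        session_id=session_id,
        side=side,
        first_peak_torque=float(series.values[0]),
        peak_torque=peak_tetanic_torque(series, full),
        twitch_initial=twitch_initial,
        twitch_final=twitch_final,
        motor_threshold_vm_ma=motor_threshold_vm_ma,
        motor_threshold_vl_ma=motor_threshold_vl_ma,
    )
    n_max = int(series.contraction_indices.max())
    for name, interval in intervals.items():
        if interval.last_contraction > n_max:
            continue  # interval not covered by a scaled-down protocol
        summary.fi[name] = fatigue_index(series, interval)
        summary.sor_seconds[name] = slope_of_regression(series, interval, "seconds")
        summary.sor_index[name] = slope_of_regression(series, interval, "contraction_index")
    return summary
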