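"""End-to-end analysis of one trace: segmentation, twitch analysis, and
the session summary."""

from __future__ import annotations

from .errors import ParameterError
from .fatigue import SessionSummary, summarize_session
from .protocol import StimulationProtocol
from .segment import (
    ForceTrace,
    extract_torque_series,
    segment_by_protocol,
    segment_by_threshold,
)
from .twitch import lowpass_filter, summarize_twitch_series, twitch_features

__all__ = ["analyze_trace"]


def analyze_trace(
    trace: ForceTrace,
    protocol: StimulationProtocol | None = None,
    lowpass_cutoff: float = 15.0,
) -> SessionSummary:
    """Segment a recording and compute its session summary.

    When the stimulus schedule is known (passed explicitly or stored in
    the trace's protocol fingerprint) windows come from the schedule;
    otherwise they are detected from the signal by threshold crossing.
    Twitch features are computed on the low-pass-filtered trace; tetanic
    plateau means are taken from the raw trace, to which a 15 Hz
    low-pass is numerically irrelevant.
    """
    if protocol is None and "protocol" in trace.meta:
        protocol = StimulationProtocol.from_dict(trace.meta["protocol"])
    if protocol is not None:
        windows = segment_by_protocol(trace, protocol)
        n_tet = protocol.n_tetanic
        n_pre = protocol.n_pre_twitches
    else:
        windows = segment_by_threshold(trace)
        n_tet = sum(1 for w in windows if w.kind == "tetanic")
        tet_onsets = [w.onset for w in windows if w.kind == "tetanic"]
        n_pre = sum(
            1 for w in windows if w.kind == "twitch" and tet_onsets and w.onset < tet_onsets[0]
        )
        if n_tet == 0:
            raise ParameterError("no tetanic contractions detected in trace")

    series = extract_torque_series(trace, windows)

    twitch_windows = [w for w in windows if w.kind == "twitch"]
    twitch_initial = twitch_final = None
    if twitch_windows:
        filtered = lowpass_filter(trace, cutoff=lowpass_cutoff)
        features = [twitch_features(filtered, w) for w in twitch_windows]
        initial = features[:n_pre]
        final = features[n_pre:]
        if initial:
            twitch_initial = summarize_twitch_series(initial, "initial")
        if final:
            twitch_final = summarize_twitch_series(final, "final")

    return summarize_session(
        series,
        twitch_initial,
        twitch_final,
        subject_id=trace.subject_id,
        session_id=trace.session_id,
        side=trace.side,
        motor_threshold_vm_ma=trace.motor_threshold_vm_ma,
        motor_threshold_vl_ma=trace.motor_threshold_vl_ma,
        expected_contractions=n_tet,
    )
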