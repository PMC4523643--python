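"""Synthetic evoked-force recordings with known ground truth.

Single sessions and paired test-retest cohorts are generated with the
timing of the standard protocol (ten twitches, forty 35 Hz tetanic
trains of 3 s separated by 1 s, ten twitches) and the statistical
structure needed for reliability studies: between-subject heterogeneity
of baseline torque and fatigability, a between-session variance
component, white measurement noise, and baseline drift.

Force is built by linear summation of twitch impulse responses
``A * (t/Tc) * exp(1 - t/Tc)`` at the train frequency; per-contraction
amplitudes follow a two-exponential fatigue decay, giving the convex
torque decline seen in evoked fatigue tests (roughly 30% of initial
torque remaining after 40 contractions under the defaults).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, fields, replace as dc_replace

import numpy as np

from . import fatigue as _fatigue
from .errors import ParameterError
from .protocol import StimulationProtocol, DEFAULT_PROTOCOL
from .segment import ForceTrace

__all__ = [
    "SubjectParams",
    "PopulationSpec",
    "GroundTruth",
    "SessionRecord",
    "twitch_kernel",
    "fatigue_multiplier",
    "generate_session",
    "generate_cohort",
    "simulate_paired_values",
]

# tails shorter than exp(-7) of the pulse amplitude are truncated
_KERNEL_SUPPORT_TC = 8.0


def twitch_kernel(t, amplitude: float, contraction_time: float):
    """Twitch impulse response ``A * (t/Tc) * exp(1 - t/Tc)`` for t >= 0.

    Unimodal, nonnegative, zero at onset, with its maximum ``amplitude``
    reached exactly at ``t = contraction_time`` (the time to peak, Tc).
    Accepts scalars or arrays of times.
    """
    if contraction_time <= 0:
        raise ParameterError("contraction_time must be > 0")
    t = np.asarray(t, dtype=float)
    u = t / contraction_time
    out = np.where(t > 0, amplitude * u * np.exp(1.0 - u), 0.0)
    return float(out) if out.ndim == 0 else out


def fatigue_multiplier(
    n, fast_fraction: float, tau_fast: float, tau_slow: float
):
    """Relative torque of contraction ``n`` (1-based) under the
    two-exponential fatigue law, normalised so contraction 1 equals 1:

        m(n) = f * exp(-(n-1)/tau_fast) + (1-f) * exp(-(n-1)/tau_slow)
    """
    if not (0.0 <= fast_fraction <= 1.0):
        raise ParameterError("fast_fraction must lie in [0, 1]")
    if tau_fast <= 0 or tau_slow <= 0:
        raise ParameterError("fatigue time constants must be > 0")
    n = np.asarray(n, dtype=float)
    m = fast_fraction * np.exp(-(n - 1) / tau_fast) + (1 - fast_fraction) * np.exp(
        -(n - 1) / tau_slow
    )
    return float(m) if m.ndim == 0 else m


@dataclass(frozen=True)
class SubjectParams:
    """Generator ground-truth parameters for one subject-session.

    Amplitudes are in Nm, time constants of the fatigue law in
    contraction counts, ``contraction_time`` (twitch time to peak) in s.
    ``noise_sd`` is additive white Gaussian noise; ``drift_rate`` a
    linear baseline ramp (Nm/s) with an optional random-walk component
    of per-sample step SD ``drift_walk_sd`` — both emulate the slow
    baseline wander of a strap-and-strain-gauge rig.  ``subject_sd`` and
    ``session_effect_sd`` are the between-subject and between-session
    SDs of baseline torque used when this object serves as a cohort
    template.
    """

    baseline_amplitude: float = 27.0
    twitch_amplitude: float = 2.63
    contraction_time: float = 0.1
    fatigue_fast_fraction: float = 0.45
    fatigue_tau_fast: float = 6.0
    fatigue_tau_slow: float = 50.0
    post_tetanic_twitch_factor: float = 0.47
    noise_sd: float = 0.1
    drift_rate: float = 0.005
    drift_walk_sd: float = 0.0
    session_effect_sd: float = 2.5
    subject_sd: float = 14.0

    def __post_init__(self) -> None:
        for name in ("baseline_amplitude", "twitch_amplitude", "noise_sd",
                     "drift_walk_sd", "session_effect_sd", "subject_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.contraction_time <= 0:
            raise ParameterError("contraction_time must be > 0")
        if not (0.0 <= self.fatigue_fast_fraction <= 1.0):
            raise ParameterError("fatigue_fast_fraction must lie in [0, 1]")
        if self.fatigue_tau_fast <= 0 or self.fatigue_tau_slow <= 0:
            raise ParameterError("fatigue time constants must be > 0")
        if not (0.0 < self.post_tetanic_twitch_factor <= 1.0):
            raise ParameterError("post_tetanic_twitch_factor must lie in (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown subject parameters: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class PopulationSpec:
    """Between-subject / between-session distribution of a cohort.

    ``template`` holds the population-mean subject; subjects then differ
    in baseline torque (SD ``template.subject_sd``), fatigability
    (``fraction_sd``, ``tau_fast_sd``, ``tau_slow_sd``) and twitch time
    to peak (``tc_sd``).  Sessions of one subject differ by the additive
    baseline component ``template.session_effect_sd`` and by session
    jitter of the fatigue parameters equal to ``fatigue_session_frac``
    of their between-subject SDs.  Twitch amplitude scales with the
    session baseline.  Motor thresholds (mA) are drawn per subject with
    session jitter and carried as metadata only.  ``calibrated_retest``
    matches the session-2 baseline to session 1's first-contraction
    torque within ``calibration_error_sd`` Nm, emulating intensity
    recalibration on the retest day.
    """

    template: SubjectParams = field(default_factory=SubjectParams)
    fraction_sd: float = 0.08
    tau_fast_sd: float = 1.5
    tau_slow_sd: float = 12.0
    fatigue_session_frac: float = 0.6
    tc_sd: float = 0.012
    tc_session_frac: float = 0.25
    threshold_vm_mean: float = 16.3
    threshold_vm_sd: float = 4.5
    threshold_vl_ratio: float = 1.15
    threshold_vl_extra_sd: float = 1.5
    threshold_session_sd: float = 1.0
    calibrated_retest: bool = False
    calibration_error_sd: float = 0.5

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown population parameters: {sorted(unknown)}")
        if "template" in d and isinstance(d["template"], dict):
            d["template"] = SubjectParams.from_dict(d["template"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Programmed (noise-free) quantities of one generated session.

    ``programmed_fi`` / ``programmed_sor`` are computed from the
    programmed plateau torques by the same formulas the analysis
    pipeline applies, so parameter-recovery tests can compare like with
    like."""

    plateau_torques: list[float]
    pre_twitch_peaks: list[float]
    post_twitch_peaks: list[float]
    programmed_fi: dict[str, float]
    programmed_sor_seconds: dict[str, float]
    programmed_sor_index: dict[str, float]
    variance_components: dict[str, float]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


@dataclass(frozen=True)
class SessionRecord:
    subject_id: str
    session_id: str
    trace: ForceTrace
    ground_truth: GroundTruth


def _unit_tetanic_cycle(protocol: StimulationProtocol, contraction_time: float) -> np.ndarray:
    """One on+off cycle of unit-amplitude pulses summed at the train
    frequency, sampled on the protocol grid."""
    fs = protocol.sampling_rate
    n = int(round(protocol.cycle_duration * fs))
    t = np.arange(n) / fs
    wave = np.zeros(n)
    n_pulses = int(round(protocol.on_duration * protocol.train_frequency))
    support = _KERNEL_SUPPORT_TC * contraction_time
    for p in range(n_pulses):
        tp = p / protocol.train_frequency
        i0 = int(math.ceil(tp * fs))
        i1 = min(n, int(math.ceil((tp + support) * fs)))
        if i1 > i0:
            wave[i0:i1] += twitch_kernel(t[i0:i1] - tp, 1.0, contraction_time)
    return wave


def _add_twitch(samples: np.ndarray, fs: float, onset: float, amplitude: float,
                contraction_time: float) -> None:
    support = min(_KERNEL_SUPPORT_TC * contraction_time, 1.0)
    i0 = int(math.ceil(onset * fs))
    i1 = min(samples.size, int(math.ceil((onset + support) * fs)))
    if i1 > i0:
        t = np.arange(i0, i1) / fs - onset
        samples[i0:i1] += twitch_kernel(t, amplitude, contraction_time)


def generate_session(
    subject: SubjectParams,
    protocol: StimulationProtocol = DEFAULT_PROTOCOL,
    seed: int | np.random.Generator = 0,
    *,
    subject_id: str = "s01",
    session_id: str = "1",
    side: str = "",
    motor_threshold_vm_ma: float | None = None,
    motor_threshold_vl_ma: float | None = None,
) -> tuple[ForceTrace, GroundTruth]:
    """Generate one session's force trace and its ground truth.

    The tetanic waveform of each contraction is the unit pulse-train
    cycle scaled so that the mean of the last on-phase second equals the
    programmed plateau torque exactly; noise and drift are then added on
    top.  ``seed`` may be an integer or an existing ``numpy`` Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = protocol.sampling_rate
    n = int(math.ceil(protocol.total_duration * fs))
    samples = np.zeros(n)
    t0 = protocol.lead_in

    # programmed amplitudes
    idx = np.arange(1, protocol.n_tetanic + 1)
    plateaus = subject.baseline_amplitude * fatigue_multiplier(
        idx, subject.fatigue_fast_fraction, subject.fatigue_tau_fast, subject.fatigue_tau_slow
    ) if protocol.n_tetanic else np.zeros(0)
    pre_peaks = [subject.twitch_amplitude] * protocol.n_pre_twitches
    post_peaks = [
        subject.twitch_amplitude * subject.post_tetanic_twitch_factor
    ] * protocol.n_post_twitches

    # twitches
    for onset, amp in zip(protocol.pre_twitch_onsets(t0), pre_peaks):
        _add_twitch(samples, fs, onset, amp, subject.contraction_time)
    for onset, amp in zip(protocol.post_twitch_onsets(t0), post_peaks):
        _add_twitch(samples, fs, onset, amp, subject.contraction_time)

    # tetanic phase: identical cycle waveform, rescaled per contraction
    if protocol.n_tetanic:
        unit = _unit_tetanic_cycle(protocol, subject.contraction_time)
        j1 = int(round(protocol.on_duration * fs))
        j0 = j1 - int(round(fs))
        unit_plateau = float(np.mean(unit[j0:j1]))
        for k, onset in enumerate(protocol.tetanic_onsets(t0)):
            i0 = int(round(onset * fs))
            i1 = min(n, i0 + unit.size)
            samples[i0:i1] += unit[: i1 - i0] * (plateaus[k] / unit_plateau)

    # drift and noise
    t = np.arange(n) / fs
    if subject.drift_rate:
        samples += subject.drift_rate * t
    if subject.drift_walk_sd:
        samples += np.cumsum(rng.normal(0.0, subject.drift_walk_sd, n))
    if subject.noise_sd:
        samples += rng.normal(0.0, subject.noise_sd, n)

    # programmed metrics via the pipeline's own formulas
    from .segment import TetanicTorqueSeries  # local to avoid cycle at import time

    programmed_fi: dict[str, float] = {}
    programmed_sor_s: dict[str, float] = {}
    programmed_sor_i: dict[str, float] = {}
    if protocol.n_tetanic >= 6:
        gt_series = TetanicTorqueSeries(
            values=plateaus,
            onset_times=protocol.tetanic_onsets(t0),
            contraction_indices=idx,
        )
        for name, interval in _fatigue.INTERVALS.items():
            if interval.last_contraction <= protocol.n_tetanic:
                programmed_fi[name] = _fatigue.fatigue_index(gt_series, interval)
                programmed_sor_s[name] = _fatigue.slope_of_regression(
                    gt_series, interval, "seconds"
                )
                programmed_sor_i[name] = _fatigue.slope_of_regression(
                    gt_series, interval, "contraction_index"
                )

    trace = ForceTrace(
        samples=samples,
        sampling_rate=fs,
        subject_id=subject_id,
        session_id=session_id,
        side=side,
        motor_threshold_vm_ma=motor_threshold_vm_ma,
        motor_threshold_vl_ma=motor_threshold_vl_ma,
        meta={"t0": t0, "protocol": protocol.to_dict()},
    )
    gt = GroundTruth(
        plateau_torques=[float(v) for v in plateaus],
        pre_twitch_peaks=[float(v) for v in pre_peaks],
        post_twitch_peaks=[float(v) for v in post_peaks],
        programmed_fi=programmed_fi,
        programmed_sor_seconds=programmed_sor_s,
        programmed_sor_index=programmed_sor_i,
        variance_components={
            "subject_sd": subject.subject_sd,
            "session_effect_sd": subject.session_effect_sd,
            "noise_sd": subject.noise_sd,
        },
    )
    return trace, gt


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float = math.inf) -> float:
    """Gaussian draw redrawn until it lands in [low, high]."""
    if sd == 0.0:
        return float(min(max(mean, low), high))
    for _ in range(1000):
        x = float(rng.normal(mean, sd))
        if low <= x <= high:
            return x
    return float(min(max(mean, low), high))


def generate_cohort(
    n_subjects: int,
    population: PopulationSpec | None = None,
    protocol: StimulationProtocol = DEFAULT_PROTOCOL,
    n_sessions: int = 2,
    seed: int = 0,
) -> list[SessionRecord]:
    """Generate a test-retest cohort of force recordings.

    Subject-level parameters are drawn once per subject and session
    effects per session, all from deterministic child streams of
    ``seed``.  Returns one record per subject-session, sessions labelled
    "1", "2", ...
    """
    if n_subjects < 2:
        raise ParameterError("a cohort needs at least 2 subjects")
    if n_sessions < 1:
        raise ParameterError("n_sessions must be >= 1")
    pop = population or PopulationSpec()
    tpl = pop.template
    streams = np.random.SeedSequence(seed).spawn(n_subjects)

    records: list[SessionRecord] = []
    for i in range(n_subjects):
        sub_rng = np.random.default_rng(streams[i])
        subject_id = f"s{i + 1:02d}"

        baseline_i = _truncated_normal(
            sub_rng, tpl.baseline_amplitude, tpl.subject_sd, low=1.0
        )
        frac_i = _truncated_normal(
            sub_rng, tpl.fatigue_fast_fraction, pop.fraction_sd, 0.0, 1.0
        )
        tau_fast_i = _truncated_normal(sub_rng, tpl.fatigue_tau_fast, pop.tau_fast_sd, 0.5)
        tau_slow_i = _truncated_normal(sub_rng, tpl.fatigue_tau_slow, pop.tau_slow_sd, 5.0)
        tc_i = _truncated_normal(sub_rng, tpl.contraction_time, pop.tc_sd, 0.02)
        thr_vm_i = _truncated_normal(sub_rng, pop.threshold_vm_mean, pop.threshold_vm_sd, 1.0)
        thr_vl_i = _truncated_normal(
            sub_rng, thr_vm_i * pop.threshold_vl_ratio, pop.threshold_vl_extra_sd, 1.0
        )

        first_session_baseline: float | None = None
        for s in range(1, n_sessions + 1):
            if pop.calibrated_retest and s > 1 and first_session_baseline is not None:
                baseline_is = _truncated_normal(
                    sub_rng, first_session_baseline, pop.calibration_error_sd, 0.5
                )
            else:
                baseline_is = _truncated_normal(
                    sub_rng, baseline_i, tpl.session_effect_sd, 0.5
                )
            if s == 1:
                first_session_baseline = baseline_is
            frac_is = _truncated_normal(
                sub_rng, frac_i, pop.fatigue_session_frac * pop.fraction_sd, 0.0, 1.0
            )
            tau_fast_is = _truncated_normal(
                sub_rng, tau_fast_i, pop.fatigue_session_frac * pop.tau_fast_sd, 0.5
            )
            tau_slow_is = _truncated_normal(
                sub_rng, tau_slow_i, pop.fatigue_session_frac * pop.tau_slow_sd, 5.0
            )
            tc_is = _truncated_normal(
                sub_rng, tc_i, pop.tc_session_frac * pop.tc_sd, 0.02
            )
            thr_vm_is = _truncated_normal(sub_rng, thr_vm_i, pop.threshold_session_sd, 0.5)
            thr_vl_is = _truncated_normal(sub_rng, thr_vl_i, pop.threshold_session_sd, 0.5)

            params = dc_replace(
                tpl,
                baseline_amplitude=baseline_is,
                twitch_amplitude=tpl.twitch_amplitude
                * baseline_is
                / tpl.baseline_amplitude,
                contraction_time=tc_is,
                fatigue_fast_fraction=frac_is,
                fatigue_tau_fast=tau_fast_is,
                fatigue_tau_slow=tau_slow_is,
            )
            trace, gt = generate_session(
                params,
                protocol,
                sub_rng,
                subject_id=subject_id,
                session_id=str(s),
                motor_threshold_vm_ma=thr_vm_is,
                motor_threshold_vl_ma=thr_vl_is,
            )
            records.append(SessionRecord(subject_id, str(s), trace, gt))
    return records


def simulate_paired_values(
    n_subjects: int,
    mu: float,
    between_sd: float,
    within_sd: float,
    rng: np.random.Generator,
    n_sessions: int = 2,
) -> np.ndarray:
    """Draw an (n_subjects, n_sessions) matrix from the additive
    variance-component model ``y_ij = mu + b_i + e_ij`` with
    ``b ~ N(0, between_sd^2)`` and ``e ~ N(0, within_sd^2)``.

    The consistency intraclass correlation of such data has true value
    ``between_sd^2 / (between_sd^2 + within_sd^2)``; this helper is the
    workhorse of the estimator parameter-recovery checks.
    """
    b = rng.normal(0.0, between_sd, size=(n_subjects, 1))
    e = rng.normal(0.0, within_sd, size=(n_subjects, n_sessions))
    return mu + b + e
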