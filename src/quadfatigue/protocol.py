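"""Stimulation protocol description and its event schedule.

The default protocol is the one used for nonvolitional quadriceps
fatigability testing: ten single-twitch stimuli, forty tetanic
contractions evoked by 35 Hz pulse trains (3 s on, 1 s off, i.e. fifteen
contractions per minute), and a final series of ten twitches, with the
force signal sampled at 1 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

from .errors import ParameterError

__all__ = ["StimulationProtocol", "DEFAULT_PROTOCOL"]


@dataclass(frozen=True)
class StimulationProtocol:
    """Counts and timing of twitch and tetanic stimulation events.

    Parameters
    ----------
    n_pre_twitches, n_post_twitches
        Number of single-twitch stimuli before/after the tetanic phase.
    n_tetanic
        Number of tetanic contractions.
    train_frequency
        Pulse rate of the tetanic train, Hz.
    on_duration, off_duration
        Seconds of stimulation and pause per tetanic cycle.
    inter_twitch_interval
        Spacing of consecutive twitch stimuli, s.  The source protocol
        does not state this; 2 s is a conventional choice that leaves the
        twitch fully relaxed before the next stimulus.
    pulse_width_us
        Pulse width metadata, microseconds (carried, not modelled).
    sampling_rate
        Force sampling rate, Hz.
    lead_in, tail
        Quiet baseline recorded before the first and after the last
        stimulus, s (recording-layout plumbing, not stimulation).
    """

    n_pre_twitches: int = 10
    n_tetanic: int = 40
    train_frequency: float = 35.0
    on_duration: float = 3.0
    off_duration: float = 1.0
    n_post_twitches: int = 10
    inter_twitch_interval: float = 2.0
    pulse_width_us: float = 300.0
    sampling_rate: float = 1000.0
    lead_in: float = 1.0
    tail: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_pre_twitches", "n_tetanic", "n_post_twitches"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in (
            "train_frequency",
            "on_duration",
            "off_duration",
            "inter_twitch_interval",
            "sampling_rate",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.lead_in < 0 or self.tail < 0:
            raise ParameterError("lead_in and tail must be >= 0")

    # -- derived timing ------------------------------------------------

    @property
    def cycle_duration(self) -> float:
        """One tetanic on+off cycle, s."""
        return self.on_duration + self.off_duration

    @property
    def tetanic_phase_duration(self) -> float:
        """Total duration of the tetanic phase, s."""
        return self.n_tetanic * self.cycle_duration

    @property
    def contractions_per_minute(self) -> float:
        return 60.0 / self.cycle_duration

    @property
    def total_duration(self) -> float:
        """Recording length implied by the schedule, s (incl. lead-in/tail)."""
        return (
            self.lead_in
            + self.n_pre_twitches * self.inter_twitch_interval
            + self.tetanic_phase_duration
            + self.n_post_twitches * self.inter_twitch_interval
            + self.tail
        )

    # -- event schedule (times in s, relative to t0 = first stimulus) --

    def pre_twitch_onsets(self, t0: float = 0.0) -> list[float]:
        return [t0 + k * self.inter_twitch_interval for k in range(self.n_pre_twitches)]

    def tetanic_start(self, t0: float = 0.0) -> float:
        return t0 + self.n_pre_twitches * self.inter_twitch_interval

    def tetanic_onsets(self, t0: float = 0.0) -> list[float]:
        start = self.tetanic_start(t0)
        return [start + k * self.cycle_duration for k in range(self.n_tetanic)]

    def post_twitch_start(self, t0: float = 0.0) -> float:
        return self.tetanic_start(t0) + self.tetanic_phase_duration

    def post_twitch_onsets(self, t0: float = 0.0) -> list[float]:
        start = self.post_twitch_start(t0)
        return [start + k * self.inter_twitch_interval for k in range(self.n_post_twitches)]

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationProtocol":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown protocol fields: {sorted(unknown)}")
        return cls(**d)


DEFAULT_PROTOCOL = StimulationProtocol()
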