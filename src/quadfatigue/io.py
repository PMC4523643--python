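"""Trace file format, ground-truth side-cars, and run configuration.

Traces are plain delimited text: a commented ``# key: value`` header
block (subject/session identifiers, sampling rate, protocol
fingerprint, optional motor thresholds) followed by a CSV body with
columns ``time_s,torque_nm``.  Recordings are small (a few hundred
thousand samples), so no binary format is needed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError
from .protocol import StimulationProtocol
from .segment import ForceTrace
from .synth import GroundTruth, PopulationSpec

__all__ = [
    "write_trace",
    "read_trace",
    "write_ground_truth",
    "read_ground_truth",
    "RunConfig",
    "load_config",
]

_SCALAR_META = (
    "subject_id",
    "session_id",
    "side",
    "motor_threshold_vm_ma",
    "motor_threshold_vl_ma",
)


def write_trace(trace: ForceTrace, path: str | Path) -> None:
    """Write a trace as commented-header CSV (lossless to < 1e-9 Nm)."""
    path = Path(path)
    header = {
        "format": "quadfatigue-trace-v1",
        "sampling_rate_hz": trace.sampling_rate,
        "start_time_s": trace.start_time,
        "n_samples": trace.n_samples,
    }
    for key in _SCALAR_META:
        val = getattr(trace, key)
        if val not in (None, ""):
            header[key] = val
    for key, val in trace.meta.items():
        header[f"meta.{key}"] = json.dumps(val) if isinstance(val, (dict, list)) else val

    times = trace.times
    with open(path, "w") as fh:
        for key, val in header.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("time_s,torque_nm\n")
        for t, v in zip(times, trace.samples):
            fh.write(f"{t:.6f},{v:.12g}\n")


def _parse_header(path: Path) -> tuple[dict, int]:
    header: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if ":" not in body:
                raise FormatError(f"{path}: malformed header line {n_header}: {line!r}")
            key, _, val = body.partition(":")
            header[key.strip()] = val.strip()
    return header, n_header


def read_trace(path: str | Path) -> ForceTrace:
    """Read a trace file, validating the header and the time grid."""
    path = Path(path)
    header, n_header = _parse_header(path)
    if "sampling_rate_hz" not in header:
        raise FormatError(f"{path}: missing sampling_rate_hz in header")
    fs = float(header["sampling_rate_hz"])
    start_time = float(header.get("start_time_s", 0.0))

    body = pd.read_csv(path, comment="#")
    if list(body.columns) != ["time_s", "torque_nm"]:
        raise FormatError(
            f"{path}: expected columns time_s,torque_nm, found {list(body.columns)}"
        )
    times = body["time_s"].to_numpy(dtype=float)
    if times.size == 0:
        raise FormatError(f"{path}: empty trace body")
    dt = np.diff(times)
    step = 1.0 / fs
    bad = np.flatnonzero(np.abs(dt - step) > max(1e-5, 0.01 * step))
    if bad.size:
        line = n_header + 2 + int(bad[0]) + 1  # 1-based line of the offending sample
        raise FormatError(
            f"{path}: non-uniform or non-increasing time step at line {line}"
        )

    meta: dict = {}
    for key, val in header.items():
        if key.startswith("meta."):
            name = key[5:]
            try:
                meta[name] = json.loads(val)
            except json.JSONDecodeError:
                meta[name] = val

    def _opt_float(key: str) -> float | None:
        return float(header[key]) if key in header else None

    return ForceTrace(
        samples=body["torque_nm"].to_numpy(dtype=float),
        sampling_rate=fs,
        start_time=start_time,
        subject_id=header.get("subject_id", ""),
        session_id=header.get("session_id", ""),
        side=header.get("side", ""),
        motor_threshold_vm_ma=_opt_float("motor_threshold_vm_ma"),
        motor_threshold_vl_ma=_opt_float("motor_threshold_vl_ma"),
        meta=meta,
    )


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(gt.to_dict(), fh, indent=1)


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_dict(json.load(fh))


class RunConfig:
    """Validated run configuration (YAML/JSON).

    Recognised top-level keys: ``seed``, ``n_subjects``, ``n_sessions``,
    ``protocol`` (field overrides), ``population`` (see
    :class:`~quadfatigue.synth.PopulationSpec`; its ``template`` holds
    subject parameters), ``analysis`` (``sor_mode``, ``sem_method``,
    ``average_sides``).  Unknown keys are rejected.
    """

    _TOP_KEYS = {"seed", "n_subjects", "n_sessions", "protocol", "population", "analysis"}
    _ANALYSIS_KEYS = {"sor_mode", "sem_method", "average_sides"}

    def __init__(self, raw: dict | None = None):
        raw = dict(raw or {})
        unknown = set(raw) - self._TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        self.seed = int(raw.get("seed", 0))
        self.n_subjects = int(raw.get("n_subjects", 12))
        self.n_sessions = int(raw.get("n_sessions", 2))
        try:
            self.protocol = StimulationProtocol.from_dict(
                {**StimulationProtocol().to_dict(), **raw.get("protocol", {})}
            )
            self.population = PopulationSpec.from_dict(raw.get("population", {}))
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        analysis = dict(raw.get("analysis", {}))
        unknown = set(analysis) - self._ANALYSIS_KEYS
        if unknown:
            raise ConfigError(f"unknown analysis keys: {sorted(unknown)}")
        self.sor_mode = analysis.get("sor_mode", "seconds")
        self.sem_method = analysis.get("sem_method", "difference")
        self.average_sides = bool(analysis.get("average_sides", True))


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML (or JSON — a YAML subset) config; None gives defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return RunConfig(raw)
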