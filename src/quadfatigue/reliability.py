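"""Test-retest reliability battery.

For each outcome variable measured on two occasions this module
computes: a paired t-test for systematic bias; the intraclass
correlation ICC(3,1) — two-way mixed-effects model, consistency
definition, single measures — with its 95% F-based confidence interval
and the Shrout qualitative class; the standard error of measurement
(SEM) with the conventional published-style 95% band; the minimal
detectable change MDC95 = 1.96 * sqrt(2) * SEM; and a Bland-Altman
agreement analysis with a heteroscedasticity check (Pearson correlation
of |difference| against pair mean).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, UndefinedResultError
from .fatigue import SessionSummary

__all__ = [
    "PairedMeasurements",
    "TTestResult",
    "IccResult",
    "BlandAltmanResult",
    "ReliabilityResult",
    "paired_t_test",
    "icc_3_1",
    "classify_icc",
    "sem",
    "sem_ci",
    "mdc95",
    "bland_altman",
    "compute_reliability",
    "summaries_to_frame",
    "reliability_table",
    "report_frame",
    "REPORT_VARIABLES",
]

logger = logging.getLogger(__name__)

MDC_FACTOR = 1.96 * math.sqrt(2.0)


@dataclass
class PairedMeasurements:
    """Matched test/retest values of one variable, listwise complete."""

    variable_name: str
    subject_ids: list[str]
    test_values: np.ndarray
    retest_values: np.ndarray

    def __post_init__(self) -> None:
        self.test_values = np.asarray(self.test_values, dtype=float)
        self.retest_values = np.asarray(self.retest_values, dtype=float)
        if not (len(self.subject_ids) == len(self.test_values) == len(self.retest_values)):
            raise ParameterError("test and retest lists must be matched")
        if self.n < 2:
            raise ParameterError("at least 2 paired measurements required")
        if not (np.all(np.isfinite(self.test_values)) and np.all(np.isfinite(self.retest_values))):
            raise ParameterError("paired measurements must be complete (no NaN)")

    @property
    def n(self) -> int:
        return len(self.test_values)

    @property
    def differences(self) -> np.ndarray:
        return self.retest_values - self.test_values

    @property
    def means(self) -> np.ndarray:
        return (self.retest_values + self.test_values) / 2.0


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    p_value: float
    degenerate: bool = False


def paired_t_test(pairs: PairedMeasurements) -> TTestResult:
    """Two-sided paired t-test on the retest-minus-test differences
    (df = n - 1).

    Identical sessions give t = 0, p = 1.  A constant nonzero shift has
    zero difference variance, so t is undefined; the result is flagged
    degenerate with NaN statistics.
    """
    d = pairs.differences
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if float(np.mean(d)) == 0.0:
            return TTestResult(0.0, 1.0)
        return TTestResult(math.nan, math.nan, degenerate=True)
    res = stats.ttest_rel(pairs.retest_values, pairs.test_values)
    return TTestResult(float(res.statistic), float(res.pvalue))


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def icc_3_1(pairs: PairedMeasurements, confidence: float = 0.95) -> IccResult:
    """ICC(3,1): two-way mixed-effects, consistency, single measures.

    From the two-way ANOVA decomposition with n subjects and k = 2
    sessions,

        ICC = (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error),

    where MS_error is the residual (subject x session interaction) mean
    square after removing the session main effect.  The confidence
    interval is the Shrout-Fleiss F-based interval with df (n-1) and
    (n-1)(k-1).  All-identical subjects make the statistic undefined
    (degenerate flag); a zero residual mean square yields ICC = 1 with a
    collapsed interval.
    """
    data = np.column_stack([pairs.test_values, pairs.retest_values])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_subjects = k * float(np.sum((row_means - grand) ** 2))
    ss_sessions = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((data - grand) ** 2))
    ss_error = max(ss_total - ss_subjects - ss_sessions, 0.0)
    df_subjects = n - 1
    df_error = (n - 1) * (k - 1)
    msb = ss_subjects / df_subjects
    mse = ss_error / df_error
    if msb == 0.0:
        return IccResult(math.nan, math.nan, math.nan, degenerate=True)
    if mse == 0.0:
        return IccResult(1.0, 1.0, 1.0)
    icc = (msb - mse) / (msb + (k - 1) * mse)
    alpha = 1.0 - confidence
    fobs = msb / mse
    f_low = fobs / stats.f.ppf(1 - alpha / 2, df_subjects, df_error)
    f_high = fobs * stats.f.ppf(1 - alpha / 2, df_error, df_subjects)
    ci_low = (f_low - 1) / (f_low + k - 1)
    ci_high = (f_high - 1) / (f_high + k - 1)
    return IccResult(float(icc), float(ci_low), float(ci_high))


def classify_icc(icc: float) -> str:
    """Shrout qualitative class of an ICC value.

    Bands: fair 0.41-0.60, moderate 0.61-0.80, substantial >= 0.81,
    below-fair under 0.41.  The published bands leave (0.60, 0.61) and
    (0.80, 0.81) uncovered; they are interpreted on values rounded to
    two decimals, which closes the gaps.
    """
    if not math.isfinite(icc):
        raise ParameterError("icc must be finite")
    r = round(icc, 2)
    if r < 0.41:
        return "below-fair"
    if r <= 0.60:
        return "fair"
    if r <= 0.80:
        return "moderate"
    return "substantial"


def sem(pairs: PairedMeasurements, method: str = "difference") -> float:
    """Standard error of measurement, in the variable's units.

    ``method='difference'`` (default) uses SEM = SD(differences)/sqrt(2),
    which needs no ICC estimate.  ``method='icc'`` uses the classical
    SEM = SD_pooled * sqrt(1 - ICC) with the pooled between-subject SD
    of both sessions.
    """
    sd_diff = float(np.std(pairs.differences, ddof=1))
    if method == "difference":
        return sd_diff / math.sqrt(2.0)
    if method == "icc":
        icc = icc_3_1(pairs)
        if icc.degenerate:
            raise UndefinedResultError("ICC-based SEM undefined for identical subjects")
        pooled_sd = float(
            np.sqrt(
                (np.var(pairs.test_values, ddof=1) + np.var(pairs.retest_values, ddof=1)) / 2
            )
        )
        return pooled_sd * math.sqrt(max(1.0 - icc.icc, 0.0))
    raise ParameterError(f"unknown SEM method {method!r}")


def sem_ci(sem_value: float) -> tuple[float, float]:
    """The conventional published-style 95% band around the SEM,
    ``sem * (1 -/+ 1.96)``.

    The lower bound is negative for any positive SEM; that is how these
    bands appear in print, and they are reproduced as such (flagged as
    an as-published convention in report output)."""
    if sem_value < 0:
        raise ParameterError("sem must be >= 0")
    return (sem_value * (1 - 1.96), sem_value * (1 + 1.96))


def mdc95(sem_value: float) -> float:
    """Minimal detectable change at 95% confidence:
    ``1.96 * sqrt(2) * SEM``."""
    if sem_value < 0:
        raise ParameterError("sem must be >= 0")
    return MDC_FACTOR * sem_value


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    hetero_r: float
    hetero_p: float


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Bland-Altman agreement analysis.

    Bias is the mean retest-minus-test difference, limits of agreement
    are bias +/- 1.96 SD(differences), and heteroscedasticity — error
    magnitude growing with the measured value — is quantified as the
    Pearson correlation between |difference| and pair mean with its
    two-sided p-value (NaN when either has zero variance).
    """
    if pairs.n < 3:
        raise ParameterError("Bland-Altman needs at least 3 pairs")
    d = pairs.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    abs_d = np.abs(d)
    m = pairs.means
    if np.std(abs_d) == 0.0 or np.std(m) == 0.0:
        return BlandAltmanResult(bias, loa_low, loa_high, math.nan, math.nan)
    r, p = stats.pearsonr(abs_d, m)
    return BlandAltmanResult(bias, loa_low, loa_high, float(r), float(p))


@dataclass
class ReliabilityResult:
    """One report row: descriptives and the full reliability battery for
    one variable.  ``sem_ci_convention`` records that the SEM band
    follows the as-published ``sem*(1 -/+ 1.96)`` form."""

    variable: str
    n: int
    mean_test: float
    sd_test: float
    mean_retest: float
    sd_retest: float
    mean_diff: float
    sd_diff: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    icc_class: str
    sem: float
    sem_ci_low: float
    sem_ci_high: float
    mdc95: float
    t_statistic: float
    t_p_value: float
    bias: float
    loa_low: float
    loa_high: float
    hetero_r: float
    hetero_p: float
    degenerate: bool = False
    sem_ci_convention: str = "as-published: sem*(1 -/+ 1.96)"

    def to_dict(self) -> dict:
        return asdict(self)


def compute_reliability(
    pairs: PairedMeasurements, sem_method: str = "difference"
) -> ReliabilityResult:
    """Run the whole battery on one variable's paired measurements."""
    icc_res = icc_3_1(pairs)
    t_res = paired_t_test(pairs)
    ba = bland_altman(pairs)
    s = sem(pairs, method=sem_method)
    lo, hi = sem_ci(s)
    return ReliabilityResult(
        variable=pairs.variable_name,
        n=pairs.n,
        mean_test=float(np.mean(pairs.test_values)),
        sd_test=float(np.std(pairs.test_values, ddof=1)),
        mean_retest=float(np.mean(pairs.retest_values)),
        sd_retest=float(np.std(pairs.retest_values, ddof=1)),
        mean_diff=float(np.mean(pairs.differences)),
        sd_diff=float(np.std(pairs.differences, ddof=1)),
        icc=icc_res.icc,
        icc_ci_low=icc_res.ci_low,
        icc_ci_high=icc_res.ci_high,
        icc_class="undefined" if icc_res.degenerate else classify_icc(icc_res.icc),
        sem=s,
        sem_ci_low=lo,
        sem_ci_high=hi,
        mdc95=mdc95(s),
        t_statistic=t_res.t_statistic,
        t_p_value=t_res.p_value,
        bias=ba.bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        hetero_r=ba.hetero_r,
        hetero_p=ba.hetero_p,
        degenerate=icc_res.degenerate or t_res.degenerate,
    )


# Default report: thresholds, first/peak torque, four FIs, four SORs,
# and the four twitch variables — 16 rows.
REPORT_VARIABLES: list[str] = [
    "motor_threshold_vm_ma",
    "motor_threshold_vl_ma",
    "first_peak_torque",
    "peak_torque",
    "fi_interval1",
    "fi_interval2",
    "fi_interval3",
    "fi_interval4",
    "sor_interval1",
    "sor_interval2",
    "sor_interval3",
    "sor_interval4",
    "twitch_initial_peak_torque",
    "twitch_initial_rise_slope",
    "twitch_final_peak_torque",
    "twitch_final_rise_slope",
]


def _summary_variables(s: SessionSummary, sor_mode: str) -> dict[str, float]:
    sor = s.sor_seconds if sor_mode == "seconds" else s.sor_index
    out = {
        "first_peak_torque": s.first_peak_torque,
        "peak_torque": s.peak_torque,
    }
    if s.motor_threshold_vm_ma is not None:
        out["motor_threshold_vm_ma"] = s.motor_threshold_vm_ma
    if s.motor_threshold_vl_ma is not None:
        out["motor_threshold_vl_ma"] = s.motor_threshold_vl_ma
    for name, v in s.fi.items():
        out[f"fi_{name}"] = v
    for name, v in sor.items():
        out[f"sor_{name}"] = v
    other = s.sor_index if sor_mode == "seconds" else s.sor_seconds
    suffix = "index" if sor_mode == "seconds" else "seconds"
    for name, v in other.items():
        out[f"sor_{suffix}_{name}"] = v
    for phase, tw in (("initial", s.twitch_initial), ("final", s.twitch_final)):
        if tw is not None:
            out[f"twitch_{phase}_peak_torque"] = tw.mean_peak_torque
            out[f"twitch_{phase}_rise_slope"] = tw.mean_rise_slope
    return out


def summaries_to_frame(
    summaries: list[SessionSummary], sor_mode: str = "seconds"
) -> pd.DataFrame:
    """Tidy long frame of session summaries: one observation per row
    (subject_id, session_id, side, variable, value)."""
    if sor_mode not in ("seconds", "contraction_index", "index"):
        raise ParameterError(f"unknown sor_mode {sor_mode!r}")
    mode = "seconds" if sor_mode == "seconds" else "index"
    rows = []
    for s in summaries:
        for var, val in _summary_variables(s, mode).items():
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "session_id": str(s.session_id),
                    "side": s.side,
                    "variable": var,
                    "value": val,
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "session_id", "side", "variable", "value"])


def reliability_table(
    cohort: list[SessionSummary] | pd.DataFrame,
    variables: list[str] | None = None,
    sem_method: str = "difference",
    sor_mode: str = "seconds",
    average_sides: bool = True,
) -> list[ReliabilityResult]:
    """The full test-retest report over a two-session cohort.

    ``cohort`` is either a list of session summaries or the tidy frame
    from :func:`summaries_to_frame`.  Left/right sides are averaged per
    subject-session before the statistics (the convention when no
    side-to-side difference is found); subjects missing either session
    are dropped with a logged warning.
    """
    frame = (
        cohort
        if isinstance(cohort, pd.DataFrame)
        else summaries_to_frame(cohort, sor_mode=sor_mode)
    )
    required = {"subject_id", "session_id", "variable", "value"}
    if not required.issubset(frame.columns):
        raise ParameterError(f"cohort frame must have columns {sorted(required)}")
    sessions = sorted(frame["session_id"].astype(str).unique())
    if len(sessions) != 2:
        raise ParameterError(f"exactly 2 sessions required, found {sessions}")
    if variables is None:
        present = set(frame["variable"].unique())
        variables = [v for v in REPORT_VARIABLES if v in present]

    frame = frame.copy()
    frame["session_id"] = frame["session_id"].astype(str)
    if average_sides:
        frame = (
            frame.groupby(["subject_id", "session_id", "variable"], as_index=False)["value"]
            .mean()
        )

    results: list[ReliabilityResult] = []
    for var in variables:
        sub = frame[frame["variable"] == var]
        if sub.empty:
            raise ParameterError(f"variable {var!r} absent from cohort")
        wide = sub.pivot_table(
            index="subject_id", columns="session_id", values="value", aggfunc="mean"
        ).reindex(columns=sessions)
        complete = wide.dropna()
        dropped = sorted(set(wide.index) - set(complete.index))
        if dropped:
            logger.warning(
                "variable %s: dropping subjects missing a session: %s", var, dropped
            )
        if len(complete) < 3:
            raise ParameterError(
                f"variable {var!r}: fewer than 3 subjects with both sessions"
            )
        pairs = PairedMeasurements(
            variable_name=var,
            subject_ids=list(complete.index),
            test_values=complete[sessions[0]].to_numpy(),
            retest_values=complete[sessions[1]].to_numpy(),
        )
        results.append(compute_reliability(pairs, sem_method=sem_method))
    return results


def report_frame(results: list[ReliabilityResult]) -> pd.DataFrame:
    """Report rows as a DataFrame (one variable per row), ready for TSV."""
    return pd.DataFrame([r.to_dict() for r in results])
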