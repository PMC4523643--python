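import numpy as np
import pytest

import quadfatigue as qf


@pytest.fixture(scope="session")
def protocol():
    return qf.DEFAULT_PROTOCOL


@pytest.fixture(scope="session")
def clean_subject():
    """Deterministic subject: no noise, no drift."""
    return qf.SubjectParams(noise_sd=0.0, drift_rate=0.0)


@pytest.fixture(scope="session")
def clean_session(clean_subject, protocol):
    """One noiseless, drift-free default-protocol session."""
    return qf.generate_session(clean_subject, protocol, seed=11)


@pytest.fixture(scope="session")
def noisy_session(protocol):
    """Default measurement noise, no drift (drift is a deterministic
    bias, handled separately from noise propagation)."""
    subject = qf.SubjectParams(noise_sd=0.1, drift_rate=0.0)
    return qf.generate_session(subject, protocol, seed=13)


def icc31_anova_oracle(test, retest):
    """Brute-force two-way ANOVA mean squares for the consistency ICC,
    written with explicit loops, independently of the implementation."""
    data = [[float(a), float(b)] for a, b in zip(test, retest)]
    n, k = len(data), 2
    grand = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((data[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_rows = ss_rows / (n - 1)
    ms_err = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)


@pytest.fixture(scope="session")
def icc_oracle():
    return icc31_anova_oracle
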