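"""Reliability battery: t-test, ICC(3,1), SEM/MDC, Bland-Altman, report."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import quadfatigue as qf
from quadfatigue.errors import ParameterError


def pairs_of(test, retest, name="v"):
    return qf.PairedMeasurements(
        name, [f"s{i}" for i in range(len(test))], np.asarray(test, float),
        np.asarray(retest, float),
    )


class TestPairedTTest:
    def test_identical_sessions(self):
        res = qf.paired_t_test(pairs_of([1, 2, 3], [1, 2, 3]))
        assert res.t_statistic == 0.0 and res.p_value == 1.0 and not res.degenerate

    def test_constant_shift_is_degenerate(self):
        res = qf.paired_t_test(pairs_of([1, 2, 3], [2, 3, 4]))
        assert res.degenerate and math.isnan(res.t_statistic)

    def test_hand_computed_t(self):
        # diffs {1, 2, 2}: t = (5/3) / (0.5774/sqrt(3)) = 5.0
        res = qf.paired_t_test(pairs_of([1, 2, 3], [2, 4, 5]))
        assert res.t_statistic == pytest.approx(5.0, rel=1e-6)
        assert 0 < res.p_value < 1

    def test_null_p_values_are_uniform(self):
        """Under exchangeable sessions the p-value is U(0,1): the KS
        statistic over 2000 simulated null cohorts stays small."""
        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(2000):
            y = qf.simulate_paired_values(12, 10.0, 3.0, 1.0, rng)
            pvals.append(qf.paired_t_test(pairs_of(y[:, 0], y[:, 1])).p_value)
        pvals = np.sort(pvals)
        ks = np.max(np.abs(pvals - (np.arange(1, 2001) - 0.5) / 2000))
        assert ks < 0.05


class TestIcc31:
    def test_additive_session_offset_gives_one(self):
        res = qf.icc_3_1(pairs_of([1, 2, 3], [3, 4, 5]))
        assert res.icc == pytest.approx(1.0)

    def test_perfect_agreement_gives_one(self):
        res = qf.icc_3_1(pairs_of([1, 2, 3], [1, 2, 3]))
        assert res.icc == pytest.approx(1.0)

    def test_matches_brute_force_anova_oracle(self, icc_oracle):
        test, retest = [1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 3.0, 4.0]
        res = qf.icc_3_1(pairs_of(test, retest))
        assert res.icc == pytest.approx(icc_oracle(test, retest), abs=1e-12)

    def test_matches_oracle_on_random_cohorts(self, icc_oracle):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(3, 7))
            y = rng.normal(10, 3, size=(n, 2))
            res = qf.icc_3_1(pairs_of(y[:, 0], y[:, 1]))
            assert res.icc == pytest.approx(icc_oracle(y[:, 0], y[:, 1]), abs=1e-12)
            assert res.ci_low <= res.icc <= res.ci_high

    def test_matches_pingouin_reference(self):
        """Cross-check against an independent published implementation
        (ICC3 single-measures, consistency) including the 95% CI."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(21)
        y = qf.simulate_paired_values(12, 20.0, 5.0, 2.0, rng)
        res = qf.icc_3_1(pairs_of(y[:, 0], y[:, 1]))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile([0, 1], 12),
                "y": y.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, "subject", "rater", "y")
        mask = ref["Type"].isin(["ICC3", "ICC(C,1)"])
        row = ref[mask].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        assert res.ci_low == pytest.approx(row[ci_col][0], abs=0.01)
        assert res.ci_high == pytest.approx(row[ci_col][1], abs=0.01)

    def test_identical_subjects_degenerate(self):
        res = qf.icc_3_1(pairs_of([5, 5, 5], [5, 5, 5]))
        assert res.degenerate

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        shift=st.floats(min_value=-50, max_value=50),
        scale=st.floats(min_value=0.01, max_value=100),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_shift_and_scale_invariance(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(10, 3, size=(8, 2))
        base = qf.icc_3_1(pairs_of(y[:, 0], y[:, 1])).icc
        shifted = qf.icc_3_1(pairs_of(y[:, 0], y[:, 1] + shift)).icc
        scaled = qf.icc_3_1(pairs_of(scale * y[:, 0], scale * y[:, 1])).icc
        assert shifted == pytest.approx(base, abs=1e-8)
        assert scaled == pytest.approx(base, abs=1e-8)


class TestClassifyIcc:
    @pytest.mark.parametrize(
        "icc,label",
        [
            (0.84, "substantial"),
            (0.81, "substantial"),
            (0.805, "substantial"),  # rounds to 0.81
            (0.80, "moderate"),
            (0.61, "moderate"),
            (0.604, "fair"),  # rounds to 0.60
            (0.51, "fair"),
            (0.41, "fair"),
            (0.40, "below-fair"),
            (-0.2, "below-fair"),
        ],
    )
    def test_bands(self, icc, label):
        assert qf.classify_icc(icc) == label

    def test_nonfinite_rejected(self):
        with pytest.raises(ParameterError):
            qf.classify_icc(float("nan"))


class TestSemAndMdc:
    def test_identical_sessions_zero(self):
        assert qf.sem(pairs_of([1, 2, 3], [1, 2, 3])) == 0.0

    def test_difference_formula(self):
        p = pairs_of([0, 0, 0], [0, 0, 0])
        # direct formula check: sd_diff = 2 -> sem = sqrt(2)
        assert qf.mdc95(0.0) == 0.0
        sd2 = pairs_of([0.0, 2.0, 4.0], [2.0, 2.0, 2.0])  # diffs 2, 0, -2 -> sd 2
        assert qf.sem(sd2) == pytest.approx(2.0 / math.sqrt(2.0), rel=1e-12)

    def test_published_rounding_consistency(self):
        # sd_diff = 3.90 gives 2.758; tables built from unrounded inputs
        # print 2.70 — agreement within 3%
        rng = np.random.default_rng(0)
        base = rng.normal(25, 10, 12)
        d = rng.normal(0, 1, 12)
        d = (d - d.mean()) / d.std(ddof=1) * 3.90
        p = pairs_of(base, base + d + 2.25)
        assert qf.sem(p) == pytest.approx(3.90 / math.sqrt(2), rel=1e-9)
        assert qf.sem(p) == pytest.approx(2.70, rel=0.03)

    def test_icc_method_agrees_at_high_reliability(self):
        rng = np.random.default_rng(5)
        y = qf.simulate_paired_values(500, 20.0, 5.0, 1.0, rng)
        p = pairs_of(y[:, 0], y[:, 1])
        a, b = qf.sem(p, "difference"), qf.sem(p, "icc")
        assert a == pytest.approx(b, rel=0.15)

    def test_sem_ci_published_convention(self):
        lo, hi = qf.sem_ci(2.70)
        assert lo == pytest.approx(-2.592, abs=1e-9)
        assert hi == pytest.approx(7.992, abs=1e-9)
        assert qf.sem_ci(0.0) == (0.0, 0.0)
        lo, hi = qf.sem_ci(1.29)
        assert round(lo, 2) == -1.24 and round(hi, 2) == 3.82

    def test_mdc_identity(self):
        for s in [0.0, 0.04, 1.29, 2.70, 6.61]:
            assert qf.mdc95(s) == pytest.approx(1.96 * math.sqrt(2) * s, rel=1e-12)


class TestBlandAltman:
    def test_exact_agreement(self):
        res = qf.bland_altman(pairs_of([1, 2, 3], [1, 2, 3]))
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_proportional_error_is_heteroscedastic(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = qf.bland_altman(pairs_of(t, 1.5 * t))
        assert res.hetero_r == pytest.approx(1.0, abs=1e-9)

    def test_homoscedastic_null_keeps_r_small(self):
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(100):
            y = qf.simulate_paired_values(500, 20.0, 5.0, 1.0, rng)
            res = qf.bland_altman(pairs_of(y[:, 0], y[:, 1]))
            hits += abs(res.hetero_r) < 0.15
        assert hits >= 95

    def test_loa_symmetry(self):
        rng = np.random.default_rng(3)
        y = rng.normal(10, 2, size=(10, 2))
        res = qf.bland_altman(pairs_of(y[:, 0], y[:, 1]))
        assert res.loa_high - res.bias == pytest.approx(res.bias - res.loa_low, rel=1e-9)


@pytest.fixture(scope="module")
def cohort_results():
    recs = qf.generate_cohort(12, seed=31)
    summaries = [qf.analyze_trace(r.trace) for r in recs]
    return qf.reliability_table(summaries)


class TestReliabilityTable:
    def test_sixteen_report_rows(self, cohort_results):
        assert len(cohort_results) == 16
        assert [r.variable for r in cohort_results] == qf.reliability.REPORT_VARIABLES

    def test_mdc_sem_identity_across_report(self, cohort_results):
        for r in cohort_results:
            assert r.mdc95 == pytest.approx(1.96 * math.sqrt(2) * r.sem, rel=1e-12)

    def test_icc_within_bounds_and_classified(self, cohort_results):
        for r in cohort_results:
            assert r.icc <= 1.0 + 1e-12
            assert r.icc_ci_low <= r.icc <= r.icc_ci_high
            assert r.icc_class in {"below-fair", "fair", "moderate", "substantial"}

    def test_perfect_duplicate_cohort(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(6):
            v = float(rng.normal(25, 5))
            for sess in ("1", "2"):
                rows.append({"subject_id": f"s{i}", "session_id": sess, "side": "",
                             "variable": "peak_torque", "value": v})
        import pandas as pd

        results = qf.reliability_table(pd.DataFrame(rows), variables=["peak_torque"])
        assert results[0].icc == pytest.approx(1.0)
        assert results[0].sem == 0.0

    def test_missing_session_subject_dropped_with_warning(self, caplog):
        import pandas as pd

        rows = []
        rng = np.random.default_rng(4)
        for i in range(5):
            for sess in ("1", "2"):
                if i == 0 and sess == "2":
                    continue
                rows.append({"subject_id": f"s{i}", "session_id": sess, "side": "",
                             "variable": "peak_torque",
                             "value": float(rng.normal(25, 5))})
        with caplog.at_level("WARNING"):
            results = qf.reliability_table(pd.DataFrame(rows), variables=["peak_torque"])
        assert results[0].n == 4
        assert any("s0" in rec.message for rec in caplog.records)

    def test_sides_averaged_before_statistics(self):
        import pandas as pd

        rows = []
        rng = np.random.default_rng(14)
        for i in range(5):
            for sess in ("1", "2"):
                v = float(rng.normal(25, 5))
                for side, off in (("left", -1.0), ("right", 1.0)):
                    rows.append({"subject_id": f"s{i}", "session_id": sess,
                                 "side": side, "variable": "peak_torque",
                                 "value": v + off})
        frame = pd.DataFrame(rows)
        averaged = qf.reliability_table(frame, variables=["peak_torque"])[0]
        means = frame.groupby(["subject_id", "session_id"]).value.mean().reset_index()
        means["variable"] = "peak_torque"
        means["side"] = ""
        direct = qf.reliability_table(means, variables=["peak_torque"])[0]
        assert averaged.mean_test == pytest.approx(direct.mean_test, rel=1e-12)
        assert averaged.icc == pytest.approx(direct.icc, abs=1e-12)
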