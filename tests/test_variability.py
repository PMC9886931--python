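"""Unit and property tests for the LCV variability layer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dysreg import variability as vb
from dysreg.variability import DegenerateSeriesError


class TestLcv:
    def test_hand_example(self):
        # population SD of {90,100,110} = sqrt(200/3)
        res = vb.lcv([90, 100, 110])
        assert res.M == pytest.approx(100.0)
        assert res.CV == pytest.approx(np.sqrt(200 / 3) / 100, abs=1e-7)
        assert res.LCV == pytest.approx(-1.0880, abs=1e-4)

    def test_population_sd_convention(self):
        # n-divisor: SD of {0,1} is exactly 0.5, so CV = 0.5/0.5 = 1, LCV = 0
        res = vb.lcv([0.0, 1.0])
        assert res.CV == pytest.approx(1.0, abs=1e-12)
        assert res.LCV == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "values,err",
        [
            ([5, 5, 5], DegenerateSeriesError),
            ([7], ValueError),
            ([-3, 1, 1], ValueError),  # mean <= 0
            ([1, np.nan, 2], ValueError),
        ],
    )
    def test_degenerate_inputs_raise(self, values, err):
        with pytest.raises(err):
            vb.lcv(values)

    @given(
        values=st.lists(st.floats(1.0, 1e4), min_size=3, max_size=40),
        scale=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_scale_invariance(self, values, scale):
        """CV and LCV are invariant under positive rescaling (unit changes)."""
        x = np.asarray(values)
        if x.std(ddof=0) / x.mean() < 1e-9:  # numerically degenerate
            return
        base = vb.lcv(x)
        scaled = vb.lcv(x * scale)
        assert scaled.CV == pytest.approx(base.CV, rel=1e-6)
        assert scaled.LCV == pytest.approx(base.LCV, abs=1e-6)


def _toy_records():
    dates = [f"2020-{m:02d}-{d:02d}" for m in range(1, 13) for d in (5, 19)]
    vals = 100 + np.arange(24, dtype=float)
    return pd.DataFrame(
        {"patient_id": "p1", "date": dates, "biomarker": "BUN", "value": vals}
    )


class TestAggregate:
    def test_window_counts(self):
        rec = _toy_records()
        monthly = vb.aggregate(rec, "month")
        yearly = vb.aggregate(rec, "year")
        assert len(monthly) == 12  # two values per calendar month
        assert len(yearly) == 1

    def test_yearly_equals_pooled_computation(self):
        rec = _toy_records()
        yearly = vb.aggregate(rec, "year").iloc[0]
        direct = vb.lcv(rec["value"])
        assert yearly.M == pytest.approx(direct.M)
        assert yearly.CV == pytest.approx(direct.CV)
        assert yearly.LCV == pytest.approx(direct.LCV)

    def test_short_or_constant_windows_omitted(self, caplog):
        rec = _toy_records()
        rec = pd.concat(
            [
                rec,
                pd.DataFrame(
                    {
                        "patient_id": "p2",
                        "date": ["2020-01-05", "2020-02-05", "2020-02-19"],
                        "biomarker": "BUN",
                        "value": [50.0, 60.0, 60.0],
                    }
                ),
            ]
        )
        with caplog.at_level("WARNING"):
            monthly = vb.aggregate(rec, "month")
        p2 = monthly[monthly.patient_id == "p2"]
        # Jan (1 value) and Feb (zero variance) both omitted
        assert len(p2) == 0
        assert "omitted" in caplog.text

    def test_monthly_means_track_injected_seasonal_cycle(self):
        # noise-free cosine input: monthly M profile reproduces it exactly
        amp, peak = 6.0, 2
        rows = []
        for m in range(1, 13):
            for d in (5, 19):
                rows.append(
                    ("p1", f"2020-{m:02d}-{d:02d}", "SBP",
                     150.0 + amp * np.cos(2 * np.pi * (m - peak) / 12) + (0.1 if d == 19 else -0.1))
                )
        rec = pd.DataFrame(rows, columns=["patient_id", "date", "biomarker", "value"])
        monthly = vb.aggregate(rec, "month").set_index("window")
        prof = monthly["M"] - 150.0
        expect = amp * np.cos(2 * np.pi * (np.arange(1, 13) - peak) / 12)
        assert np.allclose(prof.to_numpy(), expect, atol=1e-9)


class TestEligibility:
    def _meta(self, sessions, tests, vintage):
        return pd.DataFrame(
            {"n_sessions": [sessions], "n_blood_tests": [tests], "vintage_years": [vintage]},
            index=["p1"],
        )

    @pytest.mark.parametrize(
        "sessions,tests,vintage,included",
        [
            (100, 24, 2.0, False),  # strictly more than 100 sessions
            (101, 24, 2.0, True),
            (150, 21, 2.0, False),  # strictly more than 21 tests
            (150, 22, 2.0, True),
            (150, 22, 0.4, False),  # vintage below half a year
            (150, 22, 0.5, True),
        ],
    )
    def test_boundaries(self, sessions, tests, vintage, included):
        kept = vb.eligibility_filter(self._meta(sessions, tests, vintage))
        assert ("p1" in kept) == included

    def test_missing_field_named(self):
        meta = self._meta(150, 22, 2.0).drop(columns=["vintage_years"])
        with pytest.raises(KeyError, match="vintage_years"):
            vb.eligibility_filter(meta)


class TestPairedMonthTest:
    def _summaries(self, a_vals, b_vals):
        rows = []
        for i, v in enumerate(a_vals):
            rows.append((f"p{i}", "SBP", "2020-02", v))
        for i, v in enumerate(b_vals):
            rows.append((f"p{i}", "SBP", "2020-08", v))
        df = pd.DataFrame(rows, columns=["patient_id", "biomarker", "window", "M"])
        df["LCV"] = -1.0
        return df

    def test_identical_months_give_null(self):
        s = self._summaries([150, 140, 160], [150, 140, 160])
        t, p, _ = vb.paired_month_test(s, "2020-02", "2020-08", "M")
        assert t == 0.0 and p == 1.0

    def test_zero_variance_nonzero_difference_raises(self):
        s = self._summaries([151, 141, 161], [150, 140, 160])
        with pytest.raises(ValueError, match="zero-variance"):
            vb.paired_month_test(s, "2020-02", "2020-08", "M")

    def test_too_few_paired_patients(self):
        s = self._summaries([150], [150])
        with pytest.raises(ValueError, match=">= 2 patients"):
            vb.paired_month_test(s, "2020-02", "2020-08", "M")

    def test_detects_winter_bp_peak_in_cohort(self, cohort):
        """The generated SBP seasonal cycle yields a strong Feb-vs-Aug contrast."""
        sbp = cohort.records[cohort.records.biomarker == "SBP"]
        monthly = vb.aggregate(sbp, "month")
        t, p, means = vb.paired_month_test(monthly, "2020-02", "2020-08", "M")
        feb, aug = means["2020-02"][0], means["2020-08"][0]
        assert feb - aug == pytest.approx(7.8, abs=2.0)
        assert p < 1e-3


class TestKsNormality:
    def test_exact_normal_quantiles_not_rejected(self):
        x = np.array(
            [float(q) for q in __import__("scipy.stats", fromlist=["norm"]).norm.ppf(
                (np.arange(1, 101) - 0.5) / 100
            )]
        )
        _, p, rejected = vb.ks_normality(x)
        assert not rejected

    def test_skewed_sample_rejected(self):
        rng = np.random.default_rng(0)
        x = np.exp(rng.normal(0, 1.0, size=334))
        _, _, rejected = vb.ks_normality(x)
        assert rejected

    def test_null_rejection_rate_conservative(self):
        """With estimated parameters the classical KS test rejects < 5% under the null."""
        rng = np.random.default_rng(1)
        rejections = sum(
            vb.ks_normality(rng.normal(size=334))[2] for _ in range(200)
        )
        assert rejections / 200 < 0.05

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            vb.ks_normality([1.0] * 20)
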