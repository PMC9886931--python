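"""Tests for the synthetic hemodialysis cohort generator."""

import numpy as np
import pandas as pd
import pytest

from dysreg import synthetic_cohort as sc
from dysreg import variability as vb


class TestDefaultSpec:
    def test_panel_marginals_and_schedules(self, gen_spec):
        assert len(gen_spec.biomarkers) == 22
        assert gen_spec.schedule["WBC"] == 24
        assert gen_spec.schedule["TP"] == 12
        assert gen_spec.schedule["AST"] == 6
        assert gen_spec.schedule["SBP"] == 147
        assert gen_spec.level_mean["SBP"] == pytest.approx(150.8)
        assert gen_spec.level_sd["SBP"] == pytest.approx(18.3)

    def test_factor_correlation_is_valid(self, gen_spec):
        phi = gen_spec.phi
        assert np.allclose(np.diag(phi), 1.0)
        assert np.allclose(phi, phi.T)
        assert np.linalg.eigvalsh(phi).min() > 0

    def test_implied_lcv_sd_matches_targets_exactly(self, gen_spec):
        """sqrt((Lambda Phi Lambda' + Theta)_jj) equals the marginal LCV SD."""
        targets = pd.Series({b: sc._MARGINALS[b][4] for b in gen_spec.biomarkers})
        assert np.allclose(gen_spec.implied_lcv_sd(), targets, atol=1e-6)

    def test_group_fractions_and_offsets(self, gen_spec):
        assert sum(g.fraction for g in gen_spec.groups) == pytest.approx(1.0)
        dm = gen_spec.groups[1]
        assert dm.label == "diabetic"
        # marker-scale contrast on metabolism: latent offset * BUN loading
        bun_lam = gen_spec.loadings.loc["BUN", "metabolism"]
        assert dm.factor_mean_offset[0] * bun_lam == pytest.approx(0.049, abs=1e-9)

    def test_validation_rejects_bad_specs(self, gen_spec):
        import dataclasses

        bad = dataclasses.replace(gen_spec)
        bad.phi = gen_spec.phi.copy()
        bad.phi[0, 1] = 0.9
        with pytest.raises(ValueError, match="symmetric"):
            bad.validate()
        bad2 = dataclasses.replace(gen_spec)
        bad2.lcv_residual_sd = gen_spec.lcv_residual_sd * 0.0
        with pytest.raises(ValueError, match="lcv_residual_sd"):
            bad2.validate()


class TestGenerateCohort:
    def test_seed_required(self, gen_spec):
        with pytest.raises(ValueError, match="seed"):
            sc.generate_cohort(gen_spec, seed=None)

    def test_determinism(self, gen_spec):
        small = sc.default_spec(n_patients=20)
        a = sc.generate_cohort(small, seed=5)
        b = sc.generate_cohort(small, seed=5)
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        c = sc.generate_cohort(small, seed=6)
        assert not a.records["value"].equals(c.records["value"])

    def test_values_positive_and_dates_in_year(self, cohort):
        assert (cohort.records["value"] > 0).all()
        years = pd.to_datetime(cohort.records["date"]).dt.year
        assert (years == cohort.spec.year).all()

    def test_schedule_counts(self, cohort):
        counts = cohort.records.groupby(["biomarker", "patient_id"]).size()
        for bm in ("BUN", "WBC"):
            assert (counts.loc[bm] == 24).all()
        assert (counts.loc["TP"] == 12).all()
        assert (counts.loc["AST"] == 6).all()
        # hemodynamic markers share the per-patient session dates
        assert (counts.loc["SBP"] == cohort.metadata["n_sessions"]).all()
        assert (counts.loc["DBP"] == counts.loc["SBP"]).all()
        med = cohort.metadata["n_sessions"].median()
        assert 135 <= med <= 156

    def test_degenerate_noise_free_case(self):
        """All loadings zero, tiny residual: realized LCV equals nu."""
        spec = sc.default_spec(n_patients=30)
        spec.loadings.iloc[:, :] = 0.0
        spec.lcv_residual_sd.iloc[:] = 1e-8
        lcv, _ = sc.sample_lcv_matrix(spec, seed=1)
        for b in spec.biomarkers:
            assert np.allclose(lcv[b], spec.lcv_intercepts[b], atol=1e-6)

    def test_marginal_recovery_within_4_se(self, gen_spec, truth_lcv):
        """Latent LCV sample mean and SD track the marginal targets."""
        n = len(truth_lcv)
        alpha_bar = sum(g.fraction * g.factor_mean_offset for g in gen_spec.groups)
        for b in gen_spec.biomarkers:
            sd = gen_spec.implied_lcv_sd()[b]
            target_mean = gen_spec.lcv_intercepts[b] + float(
                gen_spec.loadings.loc[b].to_numpy() @ alpha_bar
            )
            se_mean = sd / np.sqrt(n)
            se_sd = sd / np.sqrt(2 * n)
            assert abs(truth_lcv[b].mean() - target_mean) < 4 * se_mean, b
            assert abs(truth_lcv[b].std() - sd) < 4 * se_sd, b

    def test_correlation_recovery(self, gen_spec, truth_lcv):
        """Sample correlations of true LCVs reproduce Lambda Phi Lambda' + Theta."""
        pop = gen_spec.implied_lcv_corr().to_numpy()
        sample = np.corrcoef(truth_lcv.to_numpy(), rowvar=False)
        n = len(truth_lcv)
        off = ~np.eye(len(pop), dtype=bool)
        assert np.max(np.abs(sample - pop)[off]) < 4 / np.sqrt(n)

    def test_two_indicator_population_correlation(self):
        """lambda=0.8 on one factor for two indicators: corr = 0.64 +/- 0.02."""
        spec = sc.default_spec(n_patients=20000)
        spec.biomarkers = ["A", "B"]
        spec.factors = ["f"]
        spec.phi = np.eye(1)
        spec.loadings = pd.DataFrame({"f": [0.8, 0.8]}, index=["A", "B"])
        spec.lcv_intercepts = pd.Series([0.0, 0.0], index=["A", "B"])
        spec.lcv_residual_sd = pd.Series([0.6, 0.6], index=["A", "B"])  # unit total
        spec.level_mean = pd.Series([1.0, 1.0], index=["A", "B"])
        spec.level_sd = pd.Series([0.1, 0.1], index=["A", "B"])
        spec.schedule = {"A": 24, "B": 24}
        spec.seasonal = {}
        spec.hemodynamic = []
        spec.groups = [sc.GroupSpec("all", 1.0, np.zeros(1))]
        lcv, _ = sc.sample_lcv_matrix(spec, seed=9)
        r = np.corrcoef(lcv["A"], lcv["B"])[0, 1]
        assert r == pytest.approx(0.64, abs=0.02)

    def test_computed_sbp_lcv_tracks_table_marginal(self, lcv_wide):
        """Pipeline-computed SBP LCVs center on the -0.99 population mean."""
        se = 0.10 / np.sqrt(len(lcv_wide))
        assert abs(lcv_wide["SBP"].mean() - (-0.99)) < 3 * se

    def test_lognormal_noise_option(self, gen_spec):
        import dataclasses

        spec = sc.default_spec(n_patients=10)
        spec.noise = "lognormal"
        coh = sc.generate_cohort(spec, seed=2)
        assert (coh.records["value"] > 0).all()


class TestSeasonal:
    def _flat_records(self):
        rows = [
            ("p1", f"2020-{m:02d}-05", "SBP", 150.0) for m in range(1, 13)
        ] + [("p1", f"2020-{m:02d}-05", "PR", 75.0) for m in range(1, 13)]
        return pd.DataFrame(rows, columns=["patient_id", "date", "biomarker", "value"])

    def test_zero_amplitude_is_identity(self):
        rec = self._flat_records()
        out = sc.add_seasonal_component(rec, "SBP", 0.0)
        pd.testing.assert_frame_equal(out, rec)

    def test_feb_minus_aug_difference(self):
        out = sc.add_seasonal_component(self._flat_records(), "SBP", 3.9, peak_month=2)
        vals = out[out.biomarker == "SBP"].set_index(
            pd.to_datetime(out[out.biomarker == "SBP"]["date"]).dt.month
        )["value"]
        assert vals[2] - vals[8] == pytest.approx(7.8, abs=1e-9)

    def test_summer_peak_flips_sign(self):
        out = sc.add_seasonal_component(self._flat_records(), "SBP", 3.9, peak_month=8)
        vals = out[out.biomarker == "SBP"].set_index(
            pd.to_datetime(out[out.biomarker == "SBP"]["date"]).dt.month
        )["value"]
        assert vals[2] - vals[8] == pytest.approx(-7.8, abs=1e-9)

    def test_other_biomarkers_untouched(self):
        rec = self._flat_records()
        out = sc.add_seasonal_component(rec, "SBP", 3.9)
        assert (out[out.biomarker == "PR"]["value"] == 75.0).all()

    def test_unknown_biomarker_rejected(self):
        with pytest.raises(ValueError, match="unknown biomarker"):
            sc.add_seasonal_component(self._flat_records(), "XX", 1.0)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            sc.add_seasonal_component(self._flat_records(), "SBP", -1.0)


def test_cohort_roundtrip_to_csv(tmp_path, gen_spec):
    coh = sc.generate_cohort(sc.default_spec(n_patients=5), seed=3)
    coh.write(tmp_path)
    rec = pd.read_csv(tmp_path / "records.csv")
    assert set(rec.columns) == {"patient_id", "date", "biomarker", "value"}
    meta = pd.read_csv(tmp_path / "metadata.csv", index_col=0)
    assert len(meta) == 5
    eta = pd.read_csv(tmp_path / "truth_eta.csv", index_col=0)
    assert list(eta.columns) == sc.FACTORS


def test_spec_from_config_overrides(tmp_path):
    import yaml

    cfg = {
        "n_patients": 40,
        "seasonal": {"SBP": [5.0, 8]},
        "groups": [
            {"label": "a", "fraction": 0.5},
            {"label": "b", "fraction": 0.5, "factor_mean_offset": [0.3, 0, 0, 0, 0, 0]},
        ],
    }
    path = tmp_path / "spec.yml"
    path.write_text(yaml.safe_dump(cfg))
    spec = sc.spec_from_config(str(path))
    assert spec.n_patients == 40
    assert spec.seasonal["SBP"] == (5.0, 8)
    assert spec.groups[1].factor_mean_offset[0] == pytest.approx(0.3)
    sc.generate_cohort(spec, seed=1)  # still a valid generator
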