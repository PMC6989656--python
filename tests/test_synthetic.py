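"""Generator contracts: determinism, inversion, calibration, truth audit."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chronosurvey import GeneratorConfig, SyntheticSurvey, generate, score_bundle, truth_audit
from chronosurvey.normalization import DEFAULT_CURVES


def zero_effects():
    return {k: 0.0 for k in GeneratorConfig().effects}


class TestConfig:
    def test_defaults_load_from_shipped_yaml(self):
        cfg = GeneratorConfig.from_yaml(GeneratorConfig.default_path())
        assert cfg == GeneratorConfig()

    def test_infeasible_correlation_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            GeneratorConfig(target_corr_msfsc_bamid=1.0)

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(p_dog=1.4)

    def test_unknown_yaml_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("n_subjects: 10\nnot_a_key: 1\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            GeneratorConfig.from_yaml(path)

    def test_infeasible_variance_rejected(self):
        cfg = GeneratorConfig(n_subjects=500, target_msfsc_sd=0.3)
        with pytest.raises(ValueError, match="infeasible calibration"):
            generate(cfg, seed=0)


class TestDeterminism:
    def test_same_config_seed_identical_bundle(self):
        cfg = GeneratorConfig(n_subjects=300)
        a = generate(cfg, seed=5)
        b = generate(cfg, seed=5)
        for name in ("mctq", "alertness", "diary", "demographics", "biomarkers", "truth"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))

    def test_different_seed_differs(self):
        cfg = GeneratorConfig(n_subjects=300)
        a, b = generate(cfg, seed=5), generate(cfg, seed=6)
        assert not a.mctq.equals(b.mctq)

    def test_write_read_roundtrip_lossless(self, tmp_path):
        cfg = GeneratorConfig(n_subjects=200)
        survey = generate(cfg, seed=9)
        survey.write(tmp_path)
        back = SyntheticSurvey.read(tmp_path)
        pd.testing.assert_frame_equal(
            survey.mctq.astype(str), back.mctq.astype(str))
        assert back.config == cfg


class TestInversion:
    def test_scoring_reproduces_truth_exactly(self, small_survey, small_scored):
        """Scoring the emitted questionnaire items returns the truth table's
        mid-sleep values to machine precision."""
        el = small_scored["scores"].query("eligible == 1")
        merged = el.merge(small_survey.truth[["subject_id", "msfsc_true"]],
                          on="subject_id")
        assert np.abs(merged["msfsc"] - merged["msfsc_true"]).max() < 1e-9

    def test_bamid_reproduces_truth_exactly(self, small_survey, small_scored):
        merged = small_scored["alertness_scores"].merge(
            small_survey.truth[["subject_id", "bamid_true"]], on="subject_id")
        assert np.abs(merged["bamid"] - merged["bamid_true"]).max() < 1e-9

    def test_zero_noise_zero_effects_lies_on_decay_curve(self):
        """With no covariate effects, no noise and no recalibration the
        latent chronotype equals the age/sex decay prediction, and scoring
        recovers it to within half a minute of rounding."""
        cfg = GeneratorConfig(
            n_subjects=120, effects=zero_effects(),
            target_msfsc_mean=None, target_msfsc_sd=None, latent_noise_sd=0.0,
        )
        survey = generate(cfg, seed=3)
        demo = survey.demographics
        base = np.where(
            demo["sex"] == "women",
            DEFAULT_CURVES["women"].predict(demo["age"].to_numpy(dtype=float)),
            DEFAULT_CURVES["men"].predict(demo["age"].to_numpy(dtype=float)),
        )
        merged = survey.truth.merge(demo, on="subject_id")
        # demographics round age to 0.1 y; regenerate from the truth latent
        assert merged["latent_msfsc"].to_numpy() == pytest.approx(base, abs=0.02)
        scored = score_bundle(survey)["scores"]
        m2 = scored.merge(survey.truth, on="subject_id", suffixes=("", "_t"))
        el = m2[m2["eligible"] == 1]
        assert np.abs(el["msfsc"] - el["latent_msfsc"]).max() <= 0.5 / 60.0 + 1e-9


class TestCalibration:
    def test_marginals_and_correlation(self, small_survey, small_scored):
        """At n=1200 the scored marginals sit near the configured targets
        (coarse bound; the acceptance suite checks the full-size run)."""
        cfg = small_survey.config
        el = small_scored["scores"].query("eligible == 1")
        assert el["msfsc"].mean() == pytest.approx(cfg.target_msfsc_mean, abs=0.15)
        assert el["msfsc"].std() == pytest.approx(cfg.target_msfsc_sd, abs=0.15)
        ba = small_scored["alertness_scores"]["bamid"]
        assert ba.mean() == pytest.approx(cfg.target_bamid_mean, abs=0.35)
        assert ba.std() == pytest.approx(cfg.target_bamid_sd, abs=0.35)
        assert stats.skew(ba) > 0  # slightly asymmetric toward later types

    def test_eligible_fraction_matches_design(self, small_survey):
        frac = small_survey.truth["eligible"].mean()
        cfg = small_survey.config
        expected = (1 - cfg.p_alarm_free) + cfg.p_alarm_free * cfg.p_wakes_before_given_alarm
        assert frac == pytest.approx(expected, abs=0.05)


class TestTruthAudit:
    def test_scored_run_reports_near_zero_bias(self, small_survey, small_scored):
        scores = small_scored["scores"].query("eligible == 1")[["subject_id", "msfsc"]]
        report = truth_audit(small_survey, scores)
        assert abs(report["msfsc_bias"]) < 1e-9
        assert report["msfsc_rmse"] < 1e-9

    def test_diary_error_within_discretization_bound(self, small_survey, small_scored):
        """Every uncensored diary mid-sleep is within half a slot (0.25 h)
        of the true mid-sleep of the rendered interval."""
        diary = small_scored["diary_scores"].rename(columns={"midsleep": "diary_midsleep"})
        report = truth_audit(small_survey, diary[["subject_id", "diary_midsleep"]])
        assert report["diary_midsleep_max_abs_err"] <= 0.25 + 1e-9

    def test_censored_fraction_bookkeeping(self, small_survey, small_scored):
        report = truth_audit(small_survey, small_scored["scores"][["subject_id", "msfsc"]])
        assert report["diary_censored_fraction"] == pytest.approx(
            small_survey.truth["diary_censored"].mean())

    def test_misaligned_ids_rejected(self, small_survey):
        bogus = pd.DataFrame({"subject_id": [999_999], "msfsc": [3.0]})
        with pytest.raises(ValueError):
            truth_audit(small_survey, bogus)
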