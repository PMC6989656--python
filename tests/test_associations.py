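"""Correlations, group tests, binned profiles, biomarker contrasts."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chronosurvey import GeneratorConfig, generate, score_bundle
from chronosurvey.associations import (
    AssociationBattery,
    binned_profile,
    biomarker_contrast,
    group_compare,
    pearson,
)
from chronosurvey.workbench import build_subject_table


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(20.0)
        res = pearson(x, 2 * x + 1)
        assert res.estimate == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        res = pearson([1, 2, 3], [1, 2, 4])
        assert res.estimate == pytest.approx(0.981981, abs=1e-5)

    def test_null_case_near_zero(self):
        rng = np.random.default_rng(4)
        res = pearson(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(res.estimate) < 0.03

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(8)
        for n in (5, 12, 60):
            x, y = rng.normal(size=n), rng.normal(size=n)
            res = pearson(x, y)
            r_sp, p_sp = stats.pearsonr(x, y)
            assert res.estimate == pytest.approx(r_sp, abs=1e-12)
            assert res.p_value == pytest.approx(p_sp, rel=1e-8)

    def test_missing_pairs_dropped_and_counted(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.1, np.nan, 3.0, 4.2, 5.1]
        res = pearson(x, y)
        assert res.n == {"pairs": 3}


class TestGroupCompare:
    def test_identical_groups(self):
        vals = np.concatenate([np.arange(10.0), np.arange(10.0)])
        groups = ["a"] * 10 + ["b"] * 10
        res = group_compare(vals, groups, "ttest")
        assert res.estimate == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_ttest_matches_scipy_and_permutation_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 6)
        y = rng.normal(1, 1, 6)
        vals = np.concatenate([x, y])
        groups = ["a"] * 6 + ["b"] * 6
        res = group_compare(vals, groups, "ttest")
        t_sp, p_sp = stats.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(t_sp)
        assert res.p_value == pytest.approx(p_sp)
        # exhaustive permutation reference on the mean difference
        obs = abs(x.mean() - y.mean())
        count = total = 0
        for idx in itertools.combinations(range(12), 6):
            sel = np.zeros(12, dtype=bool)
            sel[list(idx)] = True
            diff = abs(vals[sel].mean() - vals[~sel].mean())
            count += diff >= obs - 1e-12
            total += 1
        assert res.p_value == pytest.approx(count / total, abs=0.05)

    def test_anova_tukey_flags_only_shifted_group(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(0, 1, 50),
                               rng.normal(5, 1, 50)])
        groups = ["g1"] * 50 + ["g2"] * 50 + ["g3"] * 50
        res = group_compare(vals, groups, "anova_tukey")
        assert res.p_value < 1e-10
        pw = res.pairwise.set_index(["group1", "group2"])
        assert not pw.loc[("g1", "g2"), "reject"]
        assert pw.loc[("g1", "g3"), "reject"] and pw.loc[("g2", "g3"), "reject"]

    def test_welch_available(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 30), rng.normal(0, 5, 8)
        vals = np.concatenate([x, y])
        groups = ["a"] * 30 + ["b"] * 8
        res = group_compare(vals, groups, "ttest", equal_var=False)
        t_sp, p_sp = stats.ttest_ind(x, y, equal_var=False)
        assert res.p_value == pytest.approx(p_sp)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0, 3.0], ["a", "a", "b"], "ttest")

    def test_zero_variance_pair_flagged(self):
        res = group_compare([1.0, 1.0, 2.0, 3.0], ["a", "a", "b", "b"], "ttest")
        assert "zero-variance" in res.notes


class TestBinnedProfile:
    def test_constant_response(self):
        x = np.linspace(0, 1, 100)
        profile, _ = binned_profile(x, np.full(100, 7.0), n_bins=10)
        assert np.allclose(profile["mean"], 7.0)
        assert np.allclose(profile["sd"], 0.0)

    def test_identity_reproduces_bin_centres(self):
        x = np.linspace(0, 10, 160)
        profile, coeffs = binned_profile(x, x, n_bins=16, poly_order=1)
        assert profile["mean"].to_numpy() == pytest.approx(
            profile["bin_centre"].to_numpy())
        assert coeffs == pytest.approx([1.0, 0.0], abs=1e-9)

    def test_quartic_recovery(self):
        rng = np.random.default_rng(9)
        true = np.array([0.3, -1.0, 0.5, 2.0, -1.0])
        x = rng.uniform(-2, 2, 4000)
        y = np.polyval(true, x) + rng.normal(0, 0.3, 4000)
        _, coeffs = binned_profile(x, y, n_bins=16, poly_order=4)
        assert coeffs == pytest.approx(true, abs=0.1)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            binned_profile([1, 2, 3], [1, 2, 3], n_bins=1)
        with pytest.raises(ValueError):
            binned_profile([1, 2, 3], [1, 2, 3], n_bins=5)

    def test_equal_count_bins(self):
        rng = np.random.default_rng(10)
        profile, _ = binned_profile(rng.normal(size=1600), rng.normal(size=1600),
                                    n_bins=16)
        assert (profile["n"] == 100).all()


@pytest.fixture(scope="module")
def analysis_table():
    """Scored subject table with biomarkers for everybody (n=2000)."""
    cfg = dataclasses.replace(
        GeneratorConfig.from_yaml(GeneratorConfig.default_path()),
        n_subjects=2000, seed=21, biomarker_fraction=1.0,
    )
    survey = generate(cfg)
    scored = score_bundle(survey)
    return build_subject_table(
        scored["scores"], scored["alertness_scores"],
        survey.demographics, survey.biomarkers,
    ), survey


class TestBiomarkerContrast:
    def test_women_hdl_effect_detected_men_null(self, analysis_table):
        table, _ = analysis_table
        out = biomarker_contrast(table)
        assert out["hdl_extreme_vs_non_extreme_women"].p_value < 0.05
        # women with extreme chronotype have lower HDL
        assert out["hdl_extreme_vs_non_extreme_women"].estimate < 0
        assert out["hdl_extreme_vs_non_extreme_men"].p_value > 0.05
        assert out["hdl_by_category"].p_value < 0.05

    def test_ratio_is_rowwise_quotient(self, analysis_table):
        table, _ = analysis_table
        sub = table.dropna(subset=["hdl", "ldl"])
        assert (sub["ldl"] / sub["hdl"] > 0).all()

    def test_small_strata_skipped_with_log(self):
        table = pd.DataFrame({
            "sex": ["women"] * 4,
            "category": ["non_extreme"] * 4,
            "hdl": [1.0, 1.2, 1.1, 0.9],
            "ldl": [3.0, 2.5, 2.8, 3.1],
        })
        log = []
        out = biomarker_contrast(table, log=log)
        assert "ldl_hdl_ratio_early_vs_late" not in out
        assert any("skipped" in entry for entry in log)


class TestBattery:
    def test_recovers_every_configured_effect_sign(self, analysis_table):
        table, survey = analysis_table
        results = AssociationBattery(table).run()
        frame = results.to_frame().set_index("analysis")
        effects = survey.config.effects
        expectations = {
            "latitude_msfsc": +1, "longitude_msfsc": -1,
            "settlement_msfsc": +1, "outdoor_msfsc": -1,
            "children_msfsc": -1, "partner_msfsc": -1, "dog_msfsc": +1,
            "smoking_msfsc": +1, "alcohol_msfsc": +1, "fruitveg_msfsc": +1,
            "bmi_msfsasc_women": +1,
        }
        for name, sign in expectations.items():
            assert np.sign(frame.loc[name, "estimate"]) == sign, name

    def test_longitude_effect_magnitude(self, analysis_table):
        """The longitude gradient measured by the battery reproduces the
        configured effect size in hours per degree."""
        table, survey = analysis_table
        sub = table.dropna(subset=["msfsc", "longitude"])
        slope = np.polyfit(sub["longitude"], sub["msfsc"], 1)[0]
        assert slope == pytest.approx(survey.config.effects["longitude"], abs=0.025)

    def test_reported_n_reconciles_with_missingness(self, analysis_table):
        table, _ = analysis_table
        results = AssociationBattery(table).run()
        res = results["latitude_msfsc"]
        expected = int(table.dropna(subset=["latitude", "msfsc"]).shape[0])
        assert res.n == {"pairs": expected}
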