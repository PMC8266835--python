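"""ROI-level statistics: mixed model, chi-square, t tests, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nigra import roi_stats
from nigra.roi_stats import (
    clinical_correlations,
    fit_lmm_skewness,
    pearson_chi_square,
    roi_triple_interaction,
    two_sample_t,
)

ROIS = ["sn_medial_left", "sn_medial_right", "sn_lateral_left", "sn_lateral_right"]


def _skew_table(n_per_group=10, group_shift=0.0, roi_effects=None, subj_sd=0.1,
                resid_sd=0.05, seed=0):
    rng = np.random.default_rng(seed)
    roi_effects = roi_effects or {r: 0.0 for r in ROIS}
    rows = []
    for g, prefix in (("PD", "pd"), ("HC", "hc")):
        for i in range(n_per_group):
            intercept = rng.normal(0, subj_sd)
            for roi in ROIS:
                val = intercept + roi_effects[roi] + rng.normal(0, resid_sd)
                if g == "PD":
                    val += group_shift
                rows.append(
                    {"subject_id": f"{prefix}{i}", "group": g, "roi": roi, "skewness": val}
                )
    return pd.DataFrame(rows)


class TestLmm:
    def test_null_data_gives_small_effects(self):
        res = fit_lmm_skewness(_skew_table(group_shift=0.0, seed=3))
        assert abs(res.ls_means["PD"] - res.ls_means["HC"]) < 0.1
        group_p = res.fixed_effects.set_index("term").loc["group", "p"]
        assert group_p > 0.01

    def test_pure_shift_recovered_exactly(self):
        """Balanced data: LS-mean difference equals the raw group-mean
        difference exactly."""
        table = _skew_table(group_shift=-0.2, seed=4)
        res = fit_lmm_skewness(table)
        raw_diff = (
            table[table.group == "PD"]["skewness"].mean()
            - table[table.group == "HC"]["skewness"].mean()
        )
        assert res.ls_means["PD"] - res.ls_means["HC"] == pytest.approx(raw_diff, abs=1e-6)

    def test_group_df_is_n_subjects_minus_2(self):
        res = fit_lmm_skewness(_skew_table(n_per_group=23))
        assert res.group_contrast_df == 44

    def test_tukey_with_two_groups_matches_t(self):
        from scipy import stats

        res = fit_lmm_skewness(_skew_table(group_shift=-0.15, seed=6))
        p_t = 2 * stats.t.sf(abs(res.group_contrast_t), res.group_contrast_df)
        assert res.group_contrast_p_tukey == pytest.approx(p_t, rel=1e-4)

    def test_detects_calibrated_gap_in_most_replicates(self):
        """Monte-Carlo power: a 0.2 gap against subject-mean SD ~0.11 at
        n = 12 per group has ~0.99 power (ncp ~ 4.7 on 22 df), so the
        Tukey-adjusted contrast rejects in >= 80% of replicates. The
        phantom's configured gap (~0.37 at default severities) is larger
        still, so this is the conservative end of the study conditions."""
        hits = 0
        n_rep = 15
        for k in range(n_rep):
            res = fit_lmm_skewness(_skew_table(n_per_group=12, group_shift=-0.2, seed=100 + k))
            hits += res.group_contrast_p_tukey < 0.05
        assert hits >= 0.8 * n_rep

    def test_missing_columns_error(self):
        with pytest.raises(ValueError, match="misses columns"):
            fit_lmm_skewness(pd.DataFrame({"subject_id": [], "group": []}))


class TestChiSquare:
    def test_printed_sex_table(self):
        chi2, df, p = pearson_chi_square([[13, 10], [11, 12]])
        assert chi2 == pytest.approx(0.3485, abs=5e-5)
        assert df == 1
        assert p == pytest.approx(0.5550, abs=5e-4)

    def test_independent_table_is_zero(self):
        chi2, _, p = pearson_chi_square([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        """Expected-count oracle: [[20,10],[10,20]] -> 20/3."""
        chi2, _, _ = pearson_chi_square([[20, 10], [10, 20]])
        assert chi2 == pytest.approx(20.0 / 3.0)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi_square([[0, 0], [5, 5]])

    def test_agrees_with_brute_force_over_small_tables(self):
        """Exhaustive small-instance oracle: sum (O-E)^2/E directly."""
        for a, b, c, d in itertools.product(range(1, 7), repeat=4):
            table = np.array([[a, b], [c, d]], dtype=float)
            n = table.sum()
            expected = np.outer(table.sum(1), table.sum(0)) / n
            brute = ((table - expected) ** 2 / expected).sum()
            chi2, _, _ = pearson_chi_square(table)
            assert chi2 == pytest.approx(brute, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.tuples(*[st.integers(1, 50)] * 4))
    def test_brute_force_property_up_to_margin_50(self, cells):
        table = np.array(cells, dtype=float).reshape(2, 2)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        brute = ((table - expected) ** 2 / expected).sum()
        chi2, _, _ = pearson_chi_square(table)
        assert chi2 == pytest.approx(brute, rel=1e-12)


class TestTwoSampleT:
    def test_identical_groups(self):
        x = [1.0, 2.0, 3.0]
        t, df, p = two_sample_t(x=x, y=x)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_printed_age_summaries(self):
        """Pooled-variance oracle on the published age summaries; the
        rounded means/SDs imply t = -0.138 on 44 df."""
        t, df, p = two_sample_t(x_summary=(67.3, 9.9, 23), y_summary=(67.7, 9.7, 23))
        assert t == pytest.approx(-0.1384, abs=1e-4)
        assert df == 44
        assert p == pytest.approx(0.89, abs=0.01)

    def test_swap_antisymmetry(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        t1, _, p1 = two_sample_t(x=x, y=y)
        t2, _, p2 = two_sample_t(x=y, y=x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_pooled_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            two_sample_t(x=[1.0, 1.0], y=[1.0, 1.0])


class TestClinicalCorrelations:
    def test_perfect_linear_relation(self):
        scores = pd.DataFrame({"updrs3": [10.0, 20.0, 30.0, 40.0, 50.0]})
        table = clinical_correlations(2 * scores["updrs3"].to_numpy(), scores,
                                      score_names=("updrs3",))
        assert table["r"].item() == pytest.approx(1.0)

    def test_null_metric_uncorrelated(self, rng):
        n = 23
        scores = pd.DataFrame({s: rng.normal(size=n) for s in roi_stats.CLINICAL_SCORES})
        table = clinical_correlations(rng.normal(size=n), scores)
        assert (table["r"].abs() < 0.6).all()

    def test_attenuated_correlation_within_analytic_band(self):
        """Oracle: attenuation r = 1/sqrt(1 + sigma^2/var(duration))."""
        rng = np.random.default_rng(8)
        duration = rng.uniform(1, 15, size=500)
        sigma = 3.0
        metric = -duration + sigma * rng.standard_normal(500)
        expected = 1.0 / np.sqrt(1.0 + sigma**2 / duration.var())
        table = clinical_correlations(metric, pd.DataFrame({"duration_years": duration}),
                                      score_names=("duration_years",))
        assert abs(table["r"].item()) == pytest.approx(expected, abs=0.08)

    def test_missing_scores_dropped_pairwise(self):
        scores = pd.DataFrame({"ledd": [100.0, np.nan, 300.0, 400.0, 500.0, 250.0]})
        table = clinical_correlations(np.arange(6.0), scores, score_names=("ledd",))
        assert table["n"].item() == 5


def _tri_table(pd_slope_post=-0.001, pd_slope_ant=0.0, n=12, seed=0, noise=1e-4):
    rng = np.random.default_rng(seed)
    rows = []
    for g, prefix in (("PD", "pd"), ("HC", "hc")):
        for i in range(n):
            r2 = rng.uniform(28, 36)
            for roi, slope in (("anterior", pd_slope_ant), ("posterior", pd_slope_post)):
                ki = 0.012 + (slope * (r2 - 32) if g == "PD" else 0.0)
                rows.append({"subject_id": f"{prefix}{i}", "group": g, "roi": roi,
                             "ki": ki + rng.normal(0, noise), "r2star_lat": r2})
    return pd.DataFrame(rows)


class TestTripleInteraction:
    def test_identical_rois_give_null_three_way(self):
        table = _tri_table(pd_slope_post=-0.001, pd_slope_ant=-0.001, seed=1)
        res = roi_triple_interaction(table)
        assert res["p"] > 0.05

    def test_steeper_posterior_slope_detected(self):
        table = _tri_table(pd_slope_post=-0.001, pd_slope_ant=0.0, seed=2)
        res = roi_triple_interaction(table)
        assert res["p"] < 0.01
        assert res["coef"] < 0  # PD posterior slope more negative

    def test_permuted_labels_give_uniform_p(self):
        rng = np.random.default_rng(4)
        ps = []
        for k in range(40):
            table = _tri_table(pd_slope_post=-0.001, pd_slope_ant=0.0, seed=k, noise=2e-4)
            perm = rng.permutation(table["subject_id"].unique())
            mapping = dict(zip(table["subject_id"].unique(), perm))
            relabeled = table.copy()
            grp = table.drop_duplicates("subject_id").set_index("subject_id")["group"]
            relabeled["group"] = relabeled["subject_id"].map(lambda s: grp[mapping[s]])
            ps.append(roi_triple_interaction(relabeled)["p"])
        # roughly uniform: mean near 0.5, not piled at 0
        assert 0.25 < np.mean(ps) < 0.75
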