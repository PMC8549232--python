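import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lemocot import (
    fit_group_leg_model,
    holm_adjust,
    log_transform,
    null_cohort_profile,
    simulate_cohort,
    spearman_assoc,
    speed_accuracy_residuals,
    validate_counts,
    validate_observation_table,
)


def two_leg_table(n_subjects=30, slope=1.0, intercept=0.0, subject_sd=0.0,
                  noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        u = rng.normal(0, subject_sd)
        for leg in ("dominant", "non-dominant"):
            script = int(rng.integers(8, 50))
            manual = intercept + slope * script + u + rng.normal(0, noise_sd)
            rows.append(dict(subject=f"s{s:03d}", group="control", leg=leg,
                             in_count=script, manual_count=manual))
    return pd.DataFrame(rows)


class TestValidateCounts:
    def test_perfect_agreement_fixed_point(self):
        df = two_leg_table(10, seed=1)
        r = validate_counts(df)
        assert r.slope == pytest.approx(1.0, abs=1e-8)
        assert r.intercept == pytest.approx(0.0, abs=1e-8)
        assert r.conditional_pseudo_r2 == pytest.approx(1.0, abs=1e-8)
        assert r.median_difference == 0.0
        assert r.limits_of_agreement == (0.0, 0.0)

    def test_constant_bias_detected(self):
        df = two_leg_table(10, intercept=2.0, subject_sd=0.5, noise_sd=0.3, seed=2)
        r = validate_counts(df)
        assert r.slope == pytest.approx(1.0, abs=0.05)
        assert r.intercept == pytest.approx(2.0, abs=0.6)
        assert r.median_difference == pytest.approx(2.0, abs=0.6)
        assert r.slope_ci[0] <= r.slope <= r.slope_ci[1]
        assert r.intercept_ci[0] <= r.intercept <= r.intercept_ci[1]

    def test_pseudo_r2_matches_variance_components(self):
        su, se = 2.0, 1.5
        df = two_leg_table(80, subject_sd=su, noise_sd=se, seed=3)
        r = validate_counts(df)
        vf = np.var(df["in_count"].astype(float))
        expected = (vf + su**2) / (vf + su**2 + se**2)
        assert r.conditional_pseudo_r2 == pytest.approx(expected, abs=0.01)
        assert r.model == "mixed"

    def test_count_dependent_bias_slope(self):
        df = two_leg_table(40, subject_sd=0.3, noise_sd=0.3, seed=4)
        df["manual_count"] = df["manual_count"] + 0.1 * df["in_count"]
        r = validate_counts(df)
        assert r.difference_vs_count_slope == pytest.approx(0.1, abs=0.04)
        assert r.difference_vs_count_p < 0.01

    def test_single_row_per_subject_falls_back_to_ols(self):
        df = two_leg_table(10, noise_sd=0.5, seed=5)
        df = df[df["leg"] == "dominant"]
        r = validate_counts(df)
        assert r.model == "ols_fallback"
        assert r.slope == pytest.approx(1.0, abs=0.1)

    def test_missing_manual_count_rejected(self):
        df = two_leg_table(5).drop(columns="manual_count")
        with pytest.raises(ValueError, match="manual_count"):
            validate_counts(df)


class TestLogTransform:
    def test_basic_values(self):
        assert log_transform([1.0])[0] == 0.0
        assert log_transform([np.e])[0] == pytest.approx(1.0)

    def test_monotone(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0.1, 50, 100)
        assert np.array_equal(np.argsort(v), np.argsort(log_transform(v)))

    def test_nonpositive_named_row(self):
        with pytest.raises(ValueError, match="row 2"):
            log_transform([1.0, 2.0, 0.0, 3.0], name="surface_cm2")


class TestResiduals:
    def test_recovers_control_law_and_orthogonality(self):
        prof = dataclasses.replace(null_cohort_profile(), count_slope_log=0.02)
        df = simulate_cohort(100, 100, prof, seed=7)
        m = speed_accuracy_residuals(df, "abs_err_ep_mm")
        assert abs(m.slope - 0.02) <= 2 * m.slope_se
        ctrl = (df["group"] == "control").to_numpy()
        assert abs(m.residuals[ctrl].mean()) < 1e-10
        rho, _, _ = spearman_assoc(m.residuals[ctrl], df.loc[ctrl, "in_count"])
        assert abs(rho) < 0.05

    def test_injected_stroke_offset_recovered(self):
        prof = dataclasses.replace(null_cohort_profile(), count_slope_log=0.02)
        df = simulate_cohort(100, 100, prof, seed=8)
        delta = 0.5
        stroke = df["group"] == "stroke"
        df.loc[stroke, "abs_err_ep_mm"] *= np.exp(delta)
        m = speed_accuracy_residuals(df, "abs_err_ep_mm")
        assert m.residuals[stroke].mean() == pytest.approx(delta, rel=0.10)

    def test_degenerate_zero_slope(self):
        df = two_leg_table(20, seed=9)
        df["param"] = 5.0
        m = speed_accuracy_residuals(df, "param")
        assert m.slope == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(m.residuals, 0.0)

    def test_too_few_controls_rejected(self):
        df = two_leg_table(20, seed=9)
        df["group"] = "stroke"
        df["param"] = 5.0
        with pytest.raises(ValueError, match="control"):
            speed_accuracy_residuals(df, "param")


class TestGroupLegModel:
    def test_group_shift_detected_interaction_null(self):
        df = simulate_cohort(15, 15, null_cohort_profile(), seed=11)
        df["dv"] = log_transform(df["abs_err_ep_mm"])
        df.loc[df["group"] == "stroke", "dv"] += 1.0  # strong pure group shift
        res = fit_group_leg_model(df, "dv")
        a = res.anova.set_index("effect")
        assert a.loc["group", "p"] < 0.001
        assert a.loc["group", "df1"] == 1
        emm = res.emmeans.set_index(["group", "leg2"])
        assert emm.loc[("stroke", "leg_a"), "mean"] > emm.loc[("control", "leg_a"), "mean"]

    def test_paretic_leg_effect_detected(self):
        df = simulate_cohort(20, 20, null_cohort_profile(), seed=12)
        df["dv"] = log_transform(df["var_err_ep_mm"])
        df.loc[df["leg"] == "paretic", "dv"] += 1.0
        res = fit_group_leg_model(df, "dv")
        a = res.anova.set_index("effect")
        assert a.loc["group:leg", "p"] < 0.01  # paretic-only shift is an interaction
        ph = res.posthoc.set_index("contrast")
        assert ph.loc["stroke:leg_a - stroke:leg_b", "p_holm"] < 0.01
        assert ph.loc["control:leg_a - control:leg_b", "p_raw"] > 0.01

    def test_constant_outcome_degenerate_path(self):
        df = simulate_cohort(5, 5, seed=13)
        df["dv"] = 3.0
        res = fit_group_leg_model(df, "dv")
        assert (res.anova["F"] == 0.0).all()
        assert (res.posthoc["p_holm"] == 1.0).all()

    def test_subject_missing_one_leg_dropped(self):
        df = simulate_cohort(5, 5, seed=14)
        df["dv"] = log_transform(df["abs_err_ep_mm"])
        df = df.drop(df[(df["subject"] == df["subject"].iloc[0])
                        & (df["leg"] == "paretic")].index)
        res = fit_group_leg_model(df, "dv")
        assert res.n_subjects == 9

    def test_table_invariants_enforced(self):
        df = simulate_cohort(5, 5, seed=15)
        bad = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="more than two rows"):
            validate_observation_table(bad)
        df2 = df.copy()
        df2.loc[0, "leg"] = "left"
        with pytest.raises(ValueError, match="unknown leg"):
            validate_observation_table(df2)

    def test_full_pipeline_recovers_doubled_paretic_scatter(self):
        """simulate → detect → score → stats finds the within-stroke leg effect."""
        base = null_cohort_profile()
        paretic = dataclasses.replace(base.stroke_paretic,
                                      endpoint_scatter_sd_mm=2.0
                                      * base.stroke_paretic.endpoint_scatter_sd_mm)
        prof = dataclasses.replace(base, stroke_paretic=paretic,
                                   trial_duration_s=10.0)
        hits = 0
        reps = 5
        for rep in range(reps):
            df = simulate_cohort(6, 6, prof, seed=300 + rep, render=True)
            df["dv"] = log_transform(df["var_err_ep_mm"])
            res = fit_group_leg_model(df, "dv")
            ph = res.posthoc.set_index("contrast")
            if ph.loc["stroke:leg_a - stroke:leg_b", "p_raw"] < 0.05:
                hits += 1
        assert hits >= 4  # >= 80% of replicates


class TestHolmAndSpearman:
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_holm_dominates_raw_and_is_monotone(self, pvals):
        adj = holm_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_holm_matches_hand_computation(self):
        # step-down: sorted p (0.01, 0.02, 0.04) * (3, 2, 1), cummax
        adj = holm_adjust([0.04, 0.01, 0.02])
        assert np.allclose(adj, [0.04, 0.03, 0.04])

    def test_spearman_perfect_monotone(self):
        x = np.arange(10.0)
        rho, p, label = spearman_assoc(x, x**3)
        assert rho == pytest.approx(1.0)
        assert label == "large"
        rho2, _, label2 = spearman_assoc(x, -x)
        assert rho2 == pytest.approx(-1.0) and label2 == "large"

    def test_spearman_ties_match_rank_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0, 6.0])
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        rho, _, _ = spearman_assoc(x, y)
        assert rho == pytest.approx(oracle, rel=1e-12)

    @pytest.mark.parametrize("r,expected", [
        (0.05, "negligible"), (0.15, "small"), (-0.35, "medium"), (0.6, "large"),
    ])
    def test_effect_labels(self, r, expected):
        # bivariate normal with Pearson r has |Spearman rho| just below |r|
        rng = np.random.default_rng(0)
        n = 4000
        x = rng.normal(size=n)
        y = r * x + np.sqrt(1 - r**2) * rng.normal(size=n)
        _, _, label = spearman_assoc(x, y)
        assert label == expected

    def test_constant_input_flagged(self):
        rho, p, label = spearman_assoc([1.0] * 6, [1, 2, 3, 4, 5, 6])
        assert np.isnan(rho) and "constant" in label
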