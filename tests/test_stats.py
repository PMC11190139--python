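"""ANCOVA, Kendall correlation, gating and lateralization checks."""

import numpy as np
import pandas as pd
import pytest

from laminarq import (
    EffectConfig,
    ancova_group_test,
    case_control_tests,
    generate_cohort,
    kendall_correlation,
    lateralization_test,
    simulate_profile_cohort,
    within_patient_analyses,
)
from laminarq.phantom import cohort_frame
from laminarq.pipeline import average_hemispheres_frame, metrics_frame
from laminarq.stats import DesignError


def toy_dataset():
    """Six subjects, integer covariates: well-conditioned for the oracle."""
    return pd.DataFrame(
        {
            "group": ["MDD", "MDD", "MDD", "HC", "HC", "HC"],
            "age": [30.0, 40.0, 50.0, 35.0, 45.0, 25.0],
            "sex": ["F", "M", "F", "M", "F", "F"],
            "value": [1900.0, 1950.0, 1880.0, 1830.0, 1870.0, 1840.0],
        }
    )


def oracle_partitioned_f(df):
    """Partial F for the group term via explicit normal equations."""
    y = df["value"].to_numpy()
    g = (df["group"] == "MDD").to_numpy(float)
    age = df["age"].to_numpy(float)
    male = (df["sex"] == "M").to_numpy(float)
    ones = np.ones(len(df))
    X_full = np.column_stack([ones, g, age, male])
    X_red = np.column_stack([ones, age, male])

    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    df_resid = len(df) - X_full.shape[1]
    return (rss(X_red) - rss(X_full)) / (rss(X_full) / df_resid)


class TestAncova:
    def test_identical_values_give_null_f_and_p_one(self):
        df = toy_dataset()
        df["value"] = 1850.0
        res = ancova_group_test(df)
        assert res.F == 0.0
        assert res.p == 1.0

    def test_six_subject_toy_matches_normal_equations_oracle(self):
        df = toy_dataset()
        res = ancova_group_test(df)
        assert res.F == pytest.approx(oracle_partitioned_f(df), rel=1e-10)
        assert res.df == (1, 2)

    def test_denominator_df_is_n_minus_4_for_58_subjects(self):
        eff = EffectConfig()
        cohort = generate_cohort(48, 10, eff, master_seed=21)
        df = cohort_frame(cohort).rename(columns={"t1_profile_shift": "value"})
        res = ancova_group_test(df)
        assert res.df == (1, 54)
        assert res.n_case == 48 and res.n_control == 10

    def test_f_invariant_under_affine_rescaling_of_age_and_metric(self):
        df = toy_dataset()
        base = ancova_group_test(df).F
        scaled = df.copy()
        scaled["age"] = 3.0 * scaled["age"] - 17.0
        scaled["value"] = 0.2 * scaled["value"] + 1000.0
        assert ancova_group_test(scaled).F == pytest.approx(base, rel=1e-9)

    def test_ci_direction_is_control_minus_case(self):
        rng = np.random.default_rng(5)
        n = 200
        df = pd.DataFrame(
            {
                "group": ["MDD"] * n + ["HC"] * n,
                "age": rng.uniform(20, 55, 2 * n),
                "sex": rng.choice(["F", "M"], 2 * n),
                "value": np.r_[rng.normal(100, 5, n), rng.normal(50, 5, n)],
            }
        )
        res = ancova_group_test(df)
        # cases higher => control-minus-case interval entirely negative
        assert res.ci_95[0] < res.ci_95[1] < 0
        assert res.cohens_d_pooled > 0

    def test_single_sex_design_is_fine_but_collinear_design_raises(self):
        df = toy_dataset()
        df["sex"] = "F"  # sex indicator constant -> collinear with intercept
        with pytest.raises(DesignError):
            ancova_group_test(df)

    def test_too_few_subjects_per_group_rejected(self):
        df = toy_dataset().iloc[:4]
        with pytest.raises(DesignError):
            ancova_group_test(df)


def oracle_tau_b(x, y):
    """O(n^2) concordant/discordant pair counting with tie correction."""
    n = len(x)
    c = d = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                c += 1
            else:
                d += 1
    n0 = n * (n - 1) / 2
    return (c - d) / np.sqrt((n0 - tx) * (n0 - ty))


class TestKendall:
    def test_perfectly_concordant_pairs_give_tau_one(self):
        x = np.arange(10.0)
        res = kendall_correlation(x, 2 * x + 1, n_boot=50)
        assert res.tau == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        x = rng.integers(0, 8, n).astype(float)  # heavy ties
        y = x + rng.integers(-3, 4, n)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        res = kendall_correlation(x, y, n_boot=10, seed=seed)
        assert res.tau == pytest.approx(oracle_tau_b(x, y), abs=1e-12)

    def test_bootstrap_ci_brackets_tau_and_is_seeded(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        a = kendall_correlation(x, y, n_boot=200, seed=9)
        b = kendall_correlation(x, y, n_boot=200, seed=9)
        assert a.ci_95 == b.ci_95
        assert a.ci_95[0] < a.tau < a.ci_95[1]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kendall_correlation([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
        with pytest.raises(ValueError):
            kendall_correlation([1, 2, 3], [1, 2, 3])

    def test_pairwise_complete_observations_used(self):
        x = np.array([1.0, 2, 3, 4, 5, np.nan, 7])
        y = np.array([1.0, 2, 3, 4, 5, 6, np.nan])
        res = kendall_correlation(x, y)
        assert res.n == 5
        assert res.tau == pytest.approx(1.0)


def _metrics_for(cohort, eff, seed, **kw):
    prof = simulate_profile_cohort(cohort, eff, seed=seed, **kw)
    avg = average_hemispheres_frame(prof)
    return metrics_frame(avg, cohort_frame(cohort))


class TestGating:
    def test_no_stage1_significance_yields_empty_stage2(self):
        eff = EffectConfig(group_shift_d=0.0)
        cohort = generate_cohort(12, 8, eff, master_seed=2)
        metrics = _metrics_for(cohort, eff, seed=3, rois=("lOFC",), contrasts=("T1",))
        stage1 = case_control_tests(metrics, alpha=1e-12)  # nothing can pass
        assert not stage1["significant"].any()
        stage2 = within_patient_analyses(metrics, stage1, n_boot=20)
        assert stage2.empty

    def test_stage2_runs_only_for_gated_cells(self):
        eff = EffectConfig(group_shift_d=2.5)  # strong effect to force gating
        cohort = generate_cohort(24, 24, eff, master_seed=4)
        metrics = _metrics_for(cohort, eff, seed=5)
        stage1 = case_control_tests(metrics, alpha=0.05)
        gated = stage1[stage1["significant"]]
        assert {"lOFC"} <= set(gated["roi"])
        stage2 = within_patient_analyses(metrics, stage1, n_boot=20, seed=0)
        stage2_cells = set(zip(stage2["roi"], stage2["contrast"], stage2["metric"]))
        gated_cells = set(zip(gated["roi"], gated["contrast"], gated["metric"]))
        assert stage2_cells <= gated_cells
        analyses = set(stage2["analysis"])
        assert {"ids", "ctq", "antidepressants", "anxiety"} <= analyses

    def test_severity_correlation_recovered_positive_at_large_n(self):
        eff = EffectConfig()
        cohort = generate_cohort(200, 10, eff, master_seed=6, n_missing_ids=0)
        metrics = _metrics_for(
            cohort, eff, seed=7, rois=("lOFC",), contrasts=("T1",)
        )
        cell = metrics[(metrics.metric == "mean") & (metrics.group == "MDD")]
        res = kendall_correlation(cell["ids_score"], cell["value"], n_boot=100)
        assert res.tau > 0
        assert res.p < 0.05


class TestLateralization:
    def test_identical_hemispheres_give_t_zero_p_one(self):
        eff = EffectConfig(profile_noise_sd_t1=0.0, profile_noise_sd_t2s=0.0)
        cohort = generate_cohort(6, 4, eff, master_seed=8)
        prof = simulate_profile_cohort(cohort, eff, seed=9)
        table = lateralization_test(prof)
        assert (table["t"] == 0.0).all()
        assert (table["p"] == 1.0).all()
        assert not table["significant"].any()

    def test_30ms_left_only_shift_detected_at_n58(self):
        eff = EffectConfig()  # between-subject SD 70 ms
        cohort = generate_cohort(48, 10, eff, master_seed=10)
        prof = simulate_profile_cohort(
            cohort, eff, seed=11, lateralized_shift=30.0
        )
        table = lateralization_test(prof)
        row = table[(table.roi == "lOFC") & (table.contrast == "T1")].iloc[0]
        assert row["p"] < 0.05
        others = table[~((table.roi == "lOFC") & (table.contrast == "T1"))]
        assert (others["p"] > 0.05).all()

    def test_symmetric_cohort_engages_averaging_path(self):
        eff = EffectConfig()
        cohort = generate_cohort(20, 10, eff, master_seed=12)
        prof = simulate_profile_cohort(cohort, eff, seed=13)
        table = lateralization_test(prof)
        # under hemispheric symmetry only chance rejections occur
        # (P(>3 of 8 at alpha = .05) ~ 7e-4)
        assert int(table["significant"].sum()) <= 3
        avg = average_hemispheres_frame(prof)
        assert set(avg["hemisphere"]) == {"averaged"}
        # averaged value equals the left/right mean, depthwise
        one = prof[
            (prof.subject_id == "sub-001")
            & (prof.roi == "lOFC")
            & (prof.contrast == "T1")
        ]
        lr = one.pivot(index="depth_bin", columns="hemisphere", values="value")
        got = avg[
            (avg.subject_id == "sub-001")
            & (avg.roi == "lOFC")
            & (avg.contrast == "T1")
        ].sort_values("depth_bin")["value"].to_numpy()
        assert np.allclose(got, lr[["left", "right"]].mean(axis=1).to_numpy())
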