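import numpy as np
import pandas as pd
import pytest

import myofat as mf


def planted_pair(table):
    x = table["psoas_total_fat_ml"].to_numpy(dtype=float)
    y = table["max_bmi_change"].to_numpy(dtype=float)
    return x, y


class TestGenerateCohort:
    def test_three_subjects_reproducible(self):
        spec = mf.CohortSpec(n_subjects=3, seed=9)
        a1, m1 = mf.generate_cohort(spec)
        a2, m2 = mf.generate_cohort(spec)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(m1, m2)
        assert a1["subject_id"].nunique() == 3

    def test_anthro_columns_and_units(self):
        anthro, _ = mf.generate_cohort(mf.CohortSpec(n_subjects=20, seed=1))
        for col in ("subject_id", "scan_date_offset_days", "age", "sex", "bmi",
                    "weight_kg", "height_m", "self_reported_weight_loss_kg"):
            assert col in anthro.columns
        base = anthro[anthro.scan_date_offset_days == 0]
        assert np.allclose(base.bmi, base.weight_kg / base.height_m**2)

    def test_age_and_bmi_distributions(self):
        anthro, _ = mf.generate_cohort(mf.CohortSpec(n_subjects=4000, seed=2))
        base = anthro[anthro.scan_date_offset_days == 0]
        assert base.age.mean() == pytest.approx(63.0, abs=0.8)
        assert base.age.std() == pytest.approx(11.8, abs=0.8)
        assert base.bmi.mean() == pytest.approx(25.4, abs=0.4)

    def test_zero_correlation_cohort(self):
        spec = mf.CohortSpec(n_subjects=5000, true_corr_fatvol_bmichange=0.0,
                             age_effect_fatvol=0.0, age_effect_bmichange=0.0, seed=3)
        anthro, metrics = mf.generate_cohort(spec)
        table = mf.build_cohort_table(anthro, metrics)
        x, y = planted_pair(table)
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.05

    def test_volume_loss_over_followups(self):
        _, metrics = mf.generate_cohort(mf.CohortSpec(n_subjects=300, seed=4))
        vol = metrics[(metrics.metric == "volume_ml") & (metrics.section == "total")
                      & (metrics.muscle == "psoas")]
        base = vol[vol.day_offset == 0].groupby("subject_id")["value"].first()
        last = vol.sort_values("day_offset").groupby("subject_id")["value"].last()
        rel = (last / base - 1.0) * 100
        assert rel.mean() < -3.0  # net volume loss on average

    def test_sections_sum_to_whole(self):
        _, metrics = mf.generate_cohort(mf.CohortSpec(n_subjects=10, seed=5))
        wide = metrics.pivot_table(index=["subject_id", "day_offset", "muscle", "metric"],
                                   columns="section", values="value")
        additive = wide.reset_index().query("metric in ('volume_ml', 'fat_ml', 'contractile_ml')")
        lhs = additive[["proximal", "middle", "distal"]].sum(axis=1)
        assert np.allclose(lhs, additive["total"])

    def test_infeasible_correlation_rejected(self):
        with pytest.raises(ValueError):
            mf.CohortSpec(n_subjects=10, true_corr_fatvol_bmichange=1.5)
        with pytest.raises(ValueError):
            # marginal r and age effects implying |partial| > 1
            mf.CohortSpec(n_subjects=10, true_corr_fatvol_bmichange=-0.99,
                          age_effect_fatvol=0.9, age_effect_bmichange=0.9)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            mf.CohortSpec(n_subjects=2)


class TestParameterRecovery:
    def test_planted_marginal_correlation_recovered(self):
        spec = mf.CohortSpec(n_subjects=5000, true_corr_fatvol_bmichange=-0.5, seed=11)
        anthro, metrics = mf.generate_cohort(spec)
        table = mf.build_cohort_table(anthro, metrics)
        x, y = planted_pair(table)
        assert -0.55 < np.corrcoef(x, y)[0, 1] < -0.45

    def test_recovery_within_fisher_interval_across_seeds(self):
        """~95% of per-seed sample correlations fall in the planted value's
        Fisher-z 95% interval."""
        true_r = -0.5
        n = 300
        hits = 0
        for seed in range(100):
            spec = mf.CohortSpec(n_subjects=n, true_corr_fatvol_bmichange=true_r, seed=seed)
            anthro, metrics = mf.generate_cohort(spec)
            base = metrics[(metrics.day_offset == 0) & (metrics.muscle == "psoas")
                           & (metrics.section == "total") & (metrics.metric == "fat_ml")]
            fat = base.sort_values("subject_id")["value"].to_numpy()
            bmi = anthro.sort_values(["subject_id", "scan_date_offset_days"])
            change = (bmi.groupby("subject_id")["bmi"].last()
                      - bmi.groupby("subject_id")["bmi"].first()).to_numpy()
            r = np.corrcoef(fat, change)[0, 1]
            z = np.arctanh(r)
            z_true = np.arctanh(true_r)
            if abs(z - z_true) <= 1.96 / np.sqrt(n - 3):
                hits += 1
        assert hits >= 88  # binomial(100, 0.95) lower tail

    def test_planted_partial_correlation_recovered(self):
        spec = mf.CohortSpec(n_subjects=5000, true_corr_fatvol_bmichange=-0.5, seed=13)
        anthro, metrics = mf.generate_cohort(spec)
        table = mf.build_cohort_table(anthro, metrics)
        x, y = planted_pair(table)
        res = mf.partial_correlation(x, y, table["age"].to_numpy())
        z_err = abs(np.arctanh(res.estimate) - np.arctanh(spec.true_partial_corr))
        assert z_err <= 1.96 / np.sqrt(len(x) - 3)


@pytest.fixture(scope="module")
def table():
    spec = mf.CohortSpec(n_subjects=400, seed=21)
    anthro, metrics = mf.generate_cohort(spec)
    return mf.build_cohort_table(anthro, metrics)


class TestStudyBattery:
    def test_correlation_table_has_32_rows(self, table):
        res = mf.run_study_battery(table)
        corr = res["correlations"]
        assert len(corr) == 2 * 4 * 4  # muscles x sections(total+3) x metrics
        assert set(corr.method) <= {"pearson", "pearson_log", "spearman", "missing"}

    def test_missing_column_yields_marked_row_not_crash(self, table):
        broken = table.drop(columns=["erector_distal_fat_ml"])
        res = mf.run_study_battery(broken)
        row = res["correlations"].query(
            "muscle == 'erector' and section == 'distal' and metric == 'fat_ml'").iloc[0]
        assert row["method"] == "missing" and np.isnan(row["r"])

    def test_group_comparisons_and_anovas_present(self, table):
        res = mf.run_study_battery(table)
        assert len(res["group_comparisons"]) == 8  # 2 muscles x 4 metrics
        assert len(res["section_anovas"]) == 8
        assert np.all(res["section_anovas"]["df_between"] == 2)

    def test_null_cohort_type_one_error_controlled(self):
        """With no planted effect the battery's plain correlation p-values are
        uniform: about 5% fall below 0.05."""
        rng = np.random.default_rng(31)
        n = 60
        pvals = []
        for _ in range(300):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            pvals.append(mf.pearson(x, y).p_value)
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert 0.02 < frac < 0.09
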