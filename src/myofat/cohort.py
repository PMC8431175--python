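"""Synthetic longitudinal oncology cohorts with known statistical structure.

The generator emulates the cohort the analysis assumes: subjects with
baseline anthropometrics (age ~ N(63.0, 11.8) years, BMI ~ N(25.4, 4.4)
kg/m2), per-muscle baseline measurements on the scale of the study's
descriptive table, one to four follow-up scans at 44-239 day offsets,
progressive muscle-volume loss, and -- the key planted effect -- a
prescribed correlation between baseline psoas fat volume and the maximum
BMI change over follow-up.

Construction of the planted effect: with a, b the age loadings of fat
volume and BMI change, standardised scores are built as

    fat_z = a * age_z + sqrt(1 - a^2) * u
    bmi_z = b * age_z + sqrt(1 - b^2) * v,   corr(u, v) = r_partial

so the age-partial correlation equals ``r_partial`` exactly and the
marginal correlation equals ``a b + sqrt((1-a^2)(1-b^2)) r_partial``.
Given a requested marginal correlation the generator solves for
``r_partial``; both the marginal and the partial value are therefore known
ground truth (`CohortSpec.true_partial_corr`).

BMI trajectories interpolate linearly from baseline to the drawn maximum
change at the last follow-up, so the pipeline's maximum-change computation
recovers the planted value exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .longitudinal import classify_cachexia, max_change, weight_history_from_self_report

__all__ = ["CohortSpec", "generate_cohort", "build_cohort_table"]

# Baseline scale parameters (mean, SD) per muscle: whole-muscle fat volume
# and total volume in mL, matching the study population's descriptive scale.
_MUSCLE_SCALE = {
    "psoas": {"fat": (28.5, 11.1), "total": (294.1, 115.3)},
    "erector": {"fat": (124.7, 45.0), "total": (804.7, 243.4)},
}
# Fractions of whole-muscle volume / fat in the proximal, middle, distal
# thirds (middle section carries the muscle belly).
_SECTION_FRACS = {
    "psoas": {"total": (0.255, 0.567, 0.178), "fat": (0.284, 0.554, 0.162)},
    "erector": {"total": (0.266, 0.520, 0.264), "fat": (0.237, 0.451, 0.312)},
}
# Number-of-follow-up weights for 1..4 follow-ups (study: 15/5/1/1 of 22).
_N_FOLLOWUP_WEIGHTS = np.array([15.0, 5.0, 1.0, 1.0]) / 22.0
# Relative atrophy rate per section (proximal, middle, distal): middle and
# distal thirds lose disproportionately more volume over follow-up.
_SECTION_LOSS_PROFILE = np.array([0.6, 1.0, 1.6])


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    ``true_corr_fatvol_bmichange`` is the marginal Pearson correlation
    planted between baseline psoas fat volume and maximum BMI change;
    ``age_effect_fatvol`` / ``age_effect_bmichange`` are the age loadings of
    the two variables (standardised scale).  ``volume_loss_per100d`` is the
    (mean, SD) of the relative whole-muscle volume loss in percent per 100
    days of follow-up.
    """

    n_subjects: int = 56
    age_mean: float = 63.0
    age_sd: float = 11.8
    bmi_mean: float = 25.4
    bmi_sd: float = 4.4
    true_corr_fatvol_bmichange: float = -0.5
    age_effect_fatvol: float = 0.45
    age_effect_bmichange: float = -0.20
    bmi_change_mean: float = -2.11
    bmi_change_sd: float = 1.99
    volume_loss_per100d: tuple[float, float] = (7.5, 5.0)
    followup_day_range: tuple[float, float] = (44.0, 239.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError(f"need at least 3 subjects, got {self.n_subjects}")
        if abs(self.true_corr_fatvol_bmichange) > 1:
            raise ValueError("correlation must lie in [-1, 1]")
        for a in (self.age_effect_fatvol, self.age_effect_bmichange):
            if abs(a) >= 1:
                raise ValueError("age effects must lie in (-1, 1)")
        if abs(self.true_partial_corr) > 1:
            raise ValueError(
                "infeasible combination: the requested marginal correlation and age "
                "effects imply a partial correlation outside [-1, 1]"
            )

    @property
    def true_partial_corr(self) -> float:
        """Age-partial correlation of psoas fat volume and max BMI change."""
        a, b = self.age_effect_fatvol, self.age_effect_bmichange
        return (self.true_corr_fatvol_bmichange - a * b) / np.sqrt((1 - a**2) * (1 - b**2))


def _correlated_pair(rng: np.random.Generator, n: int, r: float) -> tuple[np.ndarray, np.ndarray]:
    u = rng.standard_normal(n)
    w = rng.standard_normal(n)
    v = r * u + np.sqrt(max(0.0, 1.0 - r * r)) * w
    return u, v


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic cohort.

    Returns
    -------
    (anthro, metrics)
        ``anthro``: one row per subject per scan with columns subject_id,
        scan_date_offset_days, age, sex, bmi, weight_kg, height_m,
        self_reported_weight_loss_kg.
        ``metrics``: long-format muscle measurements with columns
        subject_id, day_offset, muscle, section, metric, value (metrics
        pdff_pct, volume_ml, fat_ml, contractile_ml).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    a, b = spec.age_effect_fatvol, spec.age_effect_bmichange
    r_partial = spec.true_partial_corr

    age_z = rng.standard_normal(n)
    u, v = _correlated_pair(rng, n, r_partial)
    fat_z = a * age_z + np.sqrt(1 - a**2) * u
    bmi_change_z = b * age_z + np.sqrt(1 - b**2) * v

    age = np.clip(spec.age_mean + spec.age_sd * age_z, 25.0, 95.0)
    sex = rng.choice(["f", "m"], size=n, p=[21 / 58, 37 / 58])
    bmi0 = np.clip(spec.bmi_mean + spec.bmi_sd * rng.standard_normal(n), 14.0, 45.0)
    height = np.clip(rng.normal(1.72, 0.09, size=n), 1.45, 2.05)
    max_bmi_change = spec.bmi_change_mean + spec.bmi_change_sd * bmi_change_z
    self_loss = np.clip(rng.normal(4.3, 5.5, size=n), 0.0, 20.0)

    fat_m, fat_sd = _MUSCLE_SCALE["psoas"]["fat"]
    psoas_fat = np.clip(fat_m + fat_sd * fat_z, 1.0, None)
    tot_m, tot_sd = _MUSCLE_SCALE["psoas"]["total"]
    # total volume shares variance with fat volume (bigger muscles carry
    # more fat) but is not the planted variable
    psoas_total = np.clip(
        tot_m + tot_sd * (0.5 * fat_z + np.sqrt(0.75) * rng.standard_normal(n)),
        60.0, None,
    )
    psoas_total = np.maximum(psoas_total, psoas_fat * 2.5)

    e_fat_m, e_fat_sd = _MUSCLE_SCALE["erector"]["fat"]
    e_fat = np.clip(
        e_fat_m + e_fat_sd * (0.4 * age_z + np.sqrt(1 - 0.16) * rng.standard_normal(n)),
        5.0, None,
    )
    e_tot_m, e_tot_sd = _MUSCLE_SCALE["erector"]["total"]
    e_total = np.clip(e_tot_m + e_tot_sd * rng.standard_normal(n), 200.0, None)
    e_total = np.maximum(e_total, e_fat * 2.5)

    wholes = {"psoas": (psoas_total, psoas_fat), "erector": (e_total, e_fat)}

    n_followups = rng.choice([1, 2, 3, 4], size=n, p=_N_FOLLOWUP_WEIGHTS)
    loss_mean, loss_sd = spec.volume_loss_per100d
    loss_rate = rng.normal(loss_mean, loss_sd, size=n)  # % per 100 days, can be negative

    anthro_rows = []
    metric_rows = []
    for i in range(n):
        sid = f"S{i + 1:04d}"
        d_lo, d_hi = spec.followup_day_range
        days = [0.0, float(np.round(rng.uniform(d_lo, d_hi)))]
        for _ in range(int(n_followups[i]) - 1):
            days.append(days[-1] + float(np.round(rng.uniform(40.0, 120.0))))
        days = np.asarray(days)
        max_day = days[-1]

        # Section baselines: Table-like fractions with a little jitter,
        # renormalised so sections sum exactly to the whole.
        base = {}
        for muscle, (total_i, fat_i) in ((m, (wholes[m][0][i], wholes[m][1][i])) for m in wholes):
            fr_t = np.asarray(_SECTION_FRACS[muscle]["total"])
            fr_f = np.asarray(_SECTION_FRACS[muscle]["fat"])
            jt = np.clip(fr_t * np.exp(0.10 * rng.standard_normal(3)), 0.05, None)
            jf = np.clip(fr_f * np.exp(0.10 * rng.standard_normal(3)), 0.05, None)
            sec_total = total_i * jt / jt.sum()
            sec_fat = fat_i * jf / jf.sum()
            sec_fat = np.minimum(sec_fat, 0.9 * sec_total)
            base[muscle] = (sec_total, sec_fat)

        for j, day in enumerate(days):
            bmi_t = bmi0[i] + max_bmi_change[i] * (day / max_day if max_day > 0 else 0.0)
            bmi_t = max(bmi_t, 10.0)
            weight = bmi_t * height[i] ** 2
            anthro_rows.append({
                "subject_id": sid,
                "scan_date_offset_days": float(day),
                "age": float(age[i]),
                "sex": sex[i],
                "bmi": float(bmi_t),
                "weight_kg": float(weight),
                "height_m": float(height[i]),
                "self_reported_weight_loss_kg": float(self_loss[i]),
            })

            # Volumes shrink with follow-up time; loss is strongest in the
            # middle/distal sections (regional variation of atrophy) and fat
            # shrinks slightly slower than total so PDFF drifts only a little.
            sec_rate = loss_rate[i] * _SECTION_LOSS_PROFILE + rng.normal(0.0, 1.0, size=3)
            shrink = np.clip(1.0 - (sec_rate / 100.0) * (day / 100.0), 0.2, None)
            fat_shrink = np.clip(1.0 - 0.8 * (sec_rate / 100.0) * (day / 100.0), 0.2, None)
            for muscle, (sec_total, sec_fat) in base.items():
                tot_t = sec_total * shrink
                fat_t = np.minimum(sec_fat * fat_shrink, 0.95 * tot_t)
                whole_tot = tot_t.sum()
                whole_fat = fat_t.sum()
                for section, t_v, f_v in (
                    ("total", whole_tot, whole_fat),
                    ("proximal", tot_t[0], fat_t[0]),
                    ("middle", tot_t[1], fat_t[1]),
                    ("distal", tot_t[2], fat_t[2]),
                ):
                    for metric, value in (
                        ("volume_ml", t_v),
                        ("fat_ml", f_v),
                        ("contractile_ml", t_v - f_v),
                        ("pdff_pct", 100.0 * f_v / t_v),
                    ):
                        metric_rows.append({
                            "subject_id": sid, "day_offset": float(day),
                            "muscle": muscle, "section": section,
                            "metric": metric, "value": float(value),
                        })

    return pd.DataFrame(anthro_rows), pd.DataFrame(metric_rows)


def _group_arrays(keys: np.ndarray, values: np.ndarray, days: np.ndarray):
    """Group (already day-sorted) values and days by key; yields aligned lists."""
    order = np.argsort(keys, kind="stable")
    keys, values, days = keys[order], values[order], days[order]
    uniq, starts = np.unique(keys, return_index=True)
    bounds = np.append(starts, keys.size)
    vals_list = [values[bounds[i]:bounds[i + 1]] for i in range(uniq.size)]
    days_list = [days[bounds[i]:bounds[i + 1]] for i in range(uniq.size)]
    return uniq, vals_list, days_list


def build_cohort_table(anthro: pd.DataFrame, metrics: pd.DataFrame) -> pd.DataFrame:
    """Derive the subject-level analysis table from longitudinal records.

    One row per subject: age, sex, baseline BMI, baseline Fearon cachexia
    classification (from the self-reported pre-baseline loss plus measured
    weights), maximum BMI change over follow-ups, baseline muscle metrics
    as ``{muscle}_{section}_{metric}`` columns, and relative maximum-change
    columns ``maxchange_{muscle}_{section}_{metric}`` for volume metrics
    (absolute change for PDFF) where follow-ups exist.
    """
    rows = []
    metrics_by_subject = dict(tuple(metrics.groupby("subject_id", sort=True)))
    for sid, grp in anthro.groupby("subject_id", sort=True):
        grp = grp.sort_values("scan_date_offset_days")
        days = grp["scan_date_offset_days"].to_numpy(dtype=float)
        bmis = grp["bmi"].to_numpy(dtype=float)
        base = grp.iloc[0]
        row = {
            "subject_id": sid,
            "age": float(base["age"]),
            "sex": base["sex"],
            "baseline_bmi": float(base["bmi"]),
        }
        history = weight_history_from_self_report(
            float(base["weight_kg"]), float(base["self_reported_weight_loss_kg"])
        ) + [(float(d), float(w)) for d, w in zip(days[1:], grp["weight_kg"].to_numpy()[1:])]
        cachectic, criterion = classify_cachexia(history, bmi=float(base["bmi"]))
        row["cachectic"] = cachectic
        row["cachexia_criterion"] = criterion
        if days.size >= 2:
            row["max_bmi_change"] = max_change(days, bmis, mode="absolute").absolute_change
        else:
            row["max_bmi_change"] = np.nan

        sub = metrics_by_subject.get(sid)
        if sub is not None:
            sub = sub.sort_values("day_offset")
            keys = sub["muscle"] + "_" + sub["section"] + "_" + sub["metric"]
            for key, vals, mdays in zip(
                *(arr for arr in _group_arrays(keys.to_numpy(),
                                               sub["value"].to_numpy(dtype=float),
                                               sub["day_offset"].to_numpy(dtype=float)))
            ):
                row[key] = vals[0]
                if vals.size >= 2:
                    if key.endswith("pdff_pct"):
                        rec = max_change(mdays, vals, mode="absolute")
                        row[f"maxchange_{key}"] = rec.absolute_change
                    else:
                        rec = max_change(mdays, vals, mode="relative")
                        row[f"maxchange_{key}"] = rec.relative_change_pct
        rows.append(row)
    return pd.DataFrame(rows)
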