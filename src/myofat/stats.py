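"""The study's statistical battery.

Normality is screened with a Lilliefors-type Kolmogorov-Smirnov test
(parameters estimated from the sample); variables that fail but whose
logarithm passes are log-transformed before Pearson correlation, and
Spearman's rank correlation is used when a variable is normal on neither
scale.  Group comparisons use the classical pooled-variance independent
t-test (Welch optional), location-against-zero the one-sample t-test, and
section comparisons one-way ANOVA.  Age-adjusted associations use the
first-order partial correlation; in the Spearman branch the partial
correlation is computed on rank-transformed data.  All p-values are
two-sided and no multiple-testing correction is applied.

scipy.stats provides the classical tests; the partial correlation and the
battery orchestration are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "TestResult",
    "normality_gate",
    "one_sample_t",
    "independent_t",
    "one_way_anova",
    "pearson",
    "spearman",
    "partial_correlation",
    "correlate_auto",
    "run_study_battery",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test.

    ``estimate`` is the effect measure (correlation coefficient or mean
    difference) where one exists; ``transform`` records any variable
    transformation applied ("none", "log", "rank").
    """

    statistic: float
    p_value: float
    df: "float | tuple[float, float]"
    n: int
    estimate: float | None = None
    transform: str = "none"
    method: str = ""


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


def normality_gate(x, alpha: float = 0.05, pvalmethod: str = "table") -> str:
    """Classify a sample as ``normal``, ``lognormal`` or ``neither``.

    A Lilliefors Kolmogorov-Smirnov test (mean and SD estimated from the
    sample) is run on x; if normality is rejected at ``alpha`` and all
    values are positive, the test is repeated on log(x).  The first
    non-rejected scale wins.

    Raises ``ValueError`` for n < 5 or a degenerate (constant) sample.
    """
    x = _clean(x)
    if x.size < 5:
        raise ValueError(f"need at least 5 observations, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample: normality undefined")
    _, p = lilliefors(x, dist="norm", pvalmethod=pvalmethod)
    if p >= alpha:
        return "normal"
    if np.all(x > 0):
        _, p_log = lilliefors(np.log(x), dist="norm", pvalmethod=pvalmethod)
        if p_log >= alpha:
            return "lognormal"
    return "neither"


def one_sample_t(x, mu0: float = 0.0) -> TestResult:
    """One-sample t-test of the mean against ``mu0`` (two-sided).

    A zero-variance sample with mean different from ``mu0`` is reported as
    an infinite statistic with p = 0.
    """
    x = _clean(x)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0:
        if x[0] == mu0:
            return TestResult(0.0, 1.0, n - 1, n, estimate=0.0, method="one_sample_t")
        stat = np.inf if x[0] > mu0 else -np.inf
        return TestResult(float(stat), 0.0, n - 1, n, estimate=float(x[0] - mu0), method="one_sample_t")
    res = sps.ttest_1samp(x, popmean=mu0)
    return TestResult(
        float(res.statistic), float(res.pvalue), n - 1, n,
        estimate=float(x.mean() - mu0), method="one_sample_t",
    )


def independent_t(x, y, equal_var: bool = True) -> TestResult:
    """Independent-samples t-test (pooled variance by default, Welch optional)."""
    x, y = _clean(x), _clean(y)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    df = float(res.df) if hasattr(res, "df") else x.size + y.size - 2
    return TestResult(
        float(res.statistic), float(res.pvalue), df, x.size + y.size,
        estimate=float(x.mean() - y.mean()),
        method="independent_t_pooled" if equal_var else "independent_t_welch",
    )


def one_way_anova(*groups) -> TestResult:
    """One-way ANOVA across k groups; F with (k - 1, N - k) df."""
    cleaned = [_clean(g) for g in groups]
    if len(cleaned) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in cleaned):
        raise ValueError("each group needs at least 2 observations")
    n_total = sum(g.size for g in cleaned)
    k = len(cleaned)
    res = sps.f_oneway(*cleaned)
    return TestResult(
        float(res.statistic), float(res.pvalue), (k - 1, n_total - k), n_total,
        method="one_way_anova",
    )


def _corr_pvalue(r: float, n: int, dof: int) -> float:
    """Two-sided p for a correlation via the t approximation with ``dof`` df."""
    if dof <= 0:
        return np.nan
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(dof / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), dof))


def _pairwise(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson(x, y, log_x: bool = False, log_y: bool = False) -> TestResult:
    """Pearson correlation, optionally on log-transformed variables."""
    x, y = _pairwise(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if log_x:
        if np.any(x <= 0):
            raise ValueError("log transform requires positive values")
        x = np.log(x)
    if log_y:
        if np.any(y <= 0):
            raise ValueError("log transform requires positive values")
        y = np.log(y)
    r, p = sps.pearsonr(x, y)
    transform = "log" if (log_x or log_y) else "none"
    return TestResult(
        float(r), float(p), x.size - 2, x.size, estimate=float(r),
        transform=transform, method="pearson_log" if transform == "log" else "pearson",
    )


def spearman(x, y) -> TestResult:
    """Spearman rank correlation (mid-ranks for ties), t-approximation p."""
    x, y = _pairwise(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    r = float(sps.spearmanr(x, y).statistic)
    p = _corr_pvalue(r, x.size, x.size - 2)
    return TestResult(r, p, x.size - 2, x.size, estimate=r, transform="rank", method="spearman")


def partial_correlation(x, y, z, method: str = "pearson") -> TestResult:
    """First-order partial correlation of x and y controlling for z.

    ``r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))``, equal
    to the correlation of the residuals of x and y after least-squares
    adjustment for z.  p-value via the t approximation with n - 3 df.  With
    ``method="spearman"`` all three variables are rank-transformed first.

    Raises ``ValueError`` when x or y is (anti)perfectly correlated with z,
    where the partial correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.size == y.size == z.size):
        raise ValueError("samples must have equal length")
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[keep], y[keep], z[keep]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete observations")
    if method == "spearman":
        x, y, z = (sps.rankdata(v) for v in (x, y, z))
    elif method != "pearson":
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")

    r_xy = float(np.corrcoef(x, y)[0, 1])
    r_xz = float(np.corrcoef(x, z)[0, 1])
    r_yz = float(np.corrcoef(y, z)[0, 1])
    if (1.0 - r_xz**2) < 1e-10 or (1.0 - r_yz**2) < 1e-10:
        raise ValueError("partial correlation undefined: a variable is collinear with the control")
    denom_sq = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    r = (r_xy - r_xz * r_yz) / np.sqrt(denom_sq)
    r = float(min(max(r, -1.0), 1.0))
    p = _corr_pvalue(r, n, n - 3)
    return TestResult(
        r, p, n - 3, n, estimate=r,
        transform="rank" if method == "spearman" else "none",
        method=f"partial_{method}",
    )


def correlate_auto(
    x, y, z=None, alpha: float = 0.05,
) -> tuple[TestResult, TestResult | None]:
    """Correlation with the study's normality-gated method choice.

    Each variable is screened with :func:`normality_gate`: variables normal
    on the raw scale stay raw, log-normal variables are log-transformed, and
    if either variable is normal on neither scale Spearman's rank
    correlation is used instead.  When a control variable ``z`` is given the
    matching partial correlation (Pearson on the possibly-transformed data,
    or rank-based) is returned as well.
    """
    x, y = _pairwise(x, y)
    labels = []
    for v in (x, y):
        try:
            labels.append(normality_gate(v, alpha=alpha))
        except ValueError:
            labels.append("neither")

    if "neither" in labels:
        plain = spearman(x, y)
        partial = None
        if z is not None:
            partial = partial_correlation(x, y, np.asarray(z, dtype=float), method="spearman")
        return plain, partial

    tx = np.log(x) if labels[0] == "lognormal" else x
    ty = np.log(y) if labels[1] == "lognormal" else y
    logged = "lognormal" in labels
    r, p = sps.pearsonr(tx, ty)
    plain = TestResult(
        float(r), float(p), x.size - 2, x.size, estimate=float(r),
        transform="log" if logged else "none",
        method="pearson_log" if logged else "pearson",
    )
    partial = None
    if z is not None:
        partial = partial_correlation(tx, ty, np.asarray(z, dtype=float), method="pearson")
    return plain, partial


# ---------------------------------------------------------------------------
# Study battery
# ---------------------------------------------------------------------------

MUSCLES = ("psoas", "erector")
SECTIONS = ("total", "proximal", "middle", "distal")
METRICS = ("pdff_pct", "volume_ml", "fat_ml", "contractile_ml")


def _baseline_col(muscle: str, section: str, metric: str) -> str:
    return f"{muscle}_{section}_{metric}"


def run_study_battery(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> dict[str, pd.DataFrame]:
    """Run the study's full statistical battery over a cohort table.

    Expects one row per subject with columns ``age``, ``max_bmi_change``,
    ``cachectic`` (bool), baseline metrics named
    ``{muscle}_{section}_{metric}`` for muscle in psoas/erector, section in
    total/proximal/middle/distal, metric in pdff_pct/volume_ml/fat_ml/
    contractile_ml, and (optionally) maximum-change columns
    ``maxchange_{muscle}_{section}_{metric}``.

    Returns a dict of DataFrames:

    ``correlations``
        One row per muscle x section x metric (32 rows): correlation of the
        baseline metric with maximum BMI change, plain and age-controlled,
        with the normality-gated method recorded.  Missing or degenerate
        columns yield a row with NaN results rather than an error.
    ``group_comparisons``
        Baseline cachectic vs non-cachectic independent t-tests per
        whole-muscle metric.
    ``section_anovas``
        One-way ANOVA of maximum change across the three sections, per
        muscle and metric, where maximum-change columns are present.

    No multiple-testing correction is applied; p-values are two-sided.
    """
    corr_rows = []
    bmi_change = cohort["max_bmi_change"].to_numpy(dtype=float)
    age = cohort["age"].to_numpy(dtype=float)
    for muscle in MUSCLES:
        for section in SECTIONS:
            for metric in METRICS:
                col = _baseline_col(muscle, section, metric)
                row = {"muscle": muscle, "section": section, "metric": metric}
                if col not in cohort.columns:
                    row.update(r=np.nan, p=np.nan, r_age_controlled=np.nan,
                               p_age_controlled=np.nan, n=0, method="missing")
                else:
                    x = cohort[col].to_numpy(dtype=float)
                    keep = np.isfinite(x) & np.isfinite(bmi_change) & np.isfinite(age)
                    if keep.sum() < 5 or np.ptp(x[keep]) == 0:
                        row.update(r=np.nan, p=np.nan, r_age_controlled=np.nan,
                                   p_age_controlled=np.nan, n=int(keep.sum()), method="missing")
                    else:
                        plain, partial = correlate_auto(
                            x[keep], bmi_change[keep], z=age[keep], alpha=alpha
                        )
                        row.update(
                            r=plain.estimate, p=plain.p_value,
                            r_age_controlled=partial.estimate,
                            p_age_controlled=partial.p_value,
                            n=plain.n, method=plain.method,
                        )
                corr_rows.append(row)
    correlations = pd.DataFrame(corr_rows)

    group_rows = []
    if "cachectic" in cohort.columns:
        cach = cohort["cachectic"].astype(bool).to_numpy()
        for muscle in MUSCLES:
            for metric in METRICS:
                col = _baseline_col(muscle, "total", metric)
                if col not in cohort.columns:
                    continue
                x = cohort.loc[cach, col].dropna().to_numpy(dtype=float)
                y = cohort.loc[~cach, col].dropna().to_numpy(dtype=float)
                if x.size < 2 or y.size < 2:
                    continue
                res = independent_t(x, y, equal_var=equal_var)
                group_rows.append({
                    "muscle": muscle, "metric": metric,
                    "mean_cachectic": float(x.mean()), "mean_non_cachectic": float(y.mean()),
                    "t": res.statistic, "df": res.df, "p": res.p_value,
                    "n_cachectic": x.size, "n_non_cachectic": y.size,
                })
    group_comparisons = pd.DataFrame(group_rows)

    anova_rows = []
    for muscle in MUSCLES:
        for metric in METRICS:
            cols = [f"maxchange_{muscle}_{s}_{metric}" for s in ("proximal", "middle", "distal")]
            if not all(c in cohort.columns for c in cols):
                continue
            groups = [cohort[c].dropna().to_numpy(dtype=float) for c in cols]
            if any(g.size < 2 for g in groups):
                continue
            res = one_way_anova(*groups)
            anova_rows.append({
                "muscle": muscle, "metric": metric,
                "F": res.statistic, "df_between": res.df[0], "df_within": res.df[1],
                "p": res.p_value, "n": res.n,
            })
    section_anovas = pd.DataFrame(anova_rows)

    return {
        "correlations": correlations,
        "group_comparisons": group_comparisons,
        "section_anovas": section_anovas,
    }
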