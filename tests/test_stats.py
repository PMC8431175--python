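"""Statistical battery vs. independent brute-force reference implementations."""

import math

import numpy as np
import pytest
from scipy import stats as sps

import myofat as mf


# --- brute-force references (explicit sums only) ---------------------------

def bf_one_sample_t(x, mu0=0.0):
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / (n - 1)
    t = (mean - mu0) / math.sqrt(var / n)
    return t, 2 * sps.t.sf(abs(t), n - 1)


def bf_pooled_t(x, y):
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    sx = sum((v - mx) ** 2 for v in x)
    sy = sum((v - my) ** 2 for v in y)
    sp2 = (sx + sy) / (nx + ny - 2)
    t = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    return t, 2 * sps.t.sf(abs(t), nx + ny - 2)


def bf_anova(groups):
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    return f, sps.f.sf(f, dfb, dfw)


def bf_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def bf_midranks(x):
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def bf_spearman(x, y):
    return bf_pearson(bf_midranks(x), bf_midranks(y))


def bf_partial_via_residuals(x, y, z):
    """Correlate residuals of x ~ z and y ~ z (least squares with intercept)."""
    def residuals(v, z):
        n = len(v)
        mz, mv = sum(z) / n, sum(v) / n
        beta = sum((a - mz) * (b - mv) for a, b in zip(z, v)) / sum((a - mz) ** 2 for a in z)
        alpha = mv - beta * mz
        return [b - (alpha + beta * a) for a, b in zip(z, v)]
    return bf_pearson(residuals(x, z), residuals(y, z))


# --- oracle equivalence -----------------------------------------------------

@pytest.fixture(scope="module")
def samples():
    rng = np.random.default_rng(123)
    out = []
    for _ in range(8):
        n = int(rng.integers(5, 51))
        x = rng.normal(size=n) + rng.uniform(-2, 2)
        y = 0.5 * x + rng.normal(size=n)
        z = rng.normal(size=n)
        out.append((list(x), list(y), list(z)))
    return out


class TestOracleEquivalence:
    def test_one_sample_t_matches_brute_force(self, samples):
        for x, _, _ in samples:
            res = mf.one_sample_t(x, mu0=0.3)
            t, p = bf_one_sample_t(x, 0.3)
            assert res.statistic == pytest.approx(t, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)
            assert res.df == len(x) - 1

    def test_independent_t_matches_brute_force(self, samples):
        (x, _, _), (y, _, _) = samples[0], samples[1]
        res = mf.independent_t(x, y)
        t, p = bf_pooled_t(x, y)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_anova_matches_brute_force(self, samples):
        groups = [s[0] for s in samples[:3]]
        res = mf.one_way_anova(*groups)
        f, p = bf_anova(groups)
        assert res.statistic == pytest.approx(f, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert res.df == (2, sum(len(g) for g in groups) - 3)

    def test_pearson_matches_brute_force(self, samples):
        for x, y, _ in samples:
            res = mf.pearson(x, y)
            assert res.estimate == pytest.approx(bf_pearson(x, y), abs=1e-10)

    def test_spearman_matches_brute_force_with_ties(self, samples):
        rng = np.random.default_rng(7)
        for x, y, _ in samples:
            # inject ties
            x = [round(v, 1) for v in x]
            y = [round(v, 1) for v in y]
            res = mf.spearman(x, y)
            assert res.estimate == pytest.approx(bf_spearman(x, y), abs=1e-10)

    def test_partial_matches_residual_regression(self, samples):
        for x, y, z in samples:
            res = mf.partial_correlation(x, y, z)
            assert res.estimate == pytest.approx(bf_partial_via_residuals(x, y, z), abs=1e-10)


# --- classical identities and edge cases ------------------------------------

class TestClassicalProperties:
    def test_symmetric_sample_t_zero_p_one(self):
        res = mf.one_sample_t([-1.0, 1.0])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_constant_sample_infinite_t(self):
        res = mf.one_sample_t([5.0, 5.0, 5.0])
        assert np.isinf(res.statistic) and res.p_value == 0.0

    def test_identical_groups_t_zero(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mf.independent_t(x, list(x))
        assert res.statistic == pytest.approx(0.0)

    def test_two_group_anova_is_t_squared(self, samples):
        (x, _, _), (y, _, _) = samples[2], samples[3]
        f = mf.one_way_anova(x, y).statistic
        t = mf.independent_t(x, y).statistic
        assert f == pytest.approx(t**2, rel=1e-10)

    def test_perfect_linear_relation_r_one(self):
        x = [1.0, 2.0, 3.0, 5.0, 8.0]
        res = mf.pearson(x, [2 * v + 3 for v in x])
        assert res.estimate == pytest.approx(1.0)

    def test_spearman_equals_pearson_on_ranks_no_ties(self):
        rng = np.random.default_rng(11)
        x = list(rng.normal(size=30))
        y = list(rng.normal(size=30))
        assert mf.spearman(x, y).estimate == pytest.approx(
            bf_pearson(bf_midranks(x), bf_midranks(y)), abs=1e-12)

    def test_partial_reduces_to_plain_when_controls_uncorrelated(self):
        # project z out of span{x, y} (after centering) so r_xz = r_yz = 0
        rng = np.random.default_rng(13)
        x = rng.normal(size=40)
        y = 0.6 * x + rng.normal(size=40)
        z = rng.normal(size=40)
        basis = np.column_stack([x - x.mean(), y - y.mean()])
        zc = z - z.mean()
        z = zc - basis @ np.linalg.lstsq(basis, zc, rcond=None)[0]
        r_plain = mf.pearson(x, y).estimate
        r_partial = mf.partial_correlation(x, y, z).estimate
        assert r_partial == pytest.approx(r_plain, abs=1e-10)

    def test_partial_invariant_to_affine_transform_of_control(self):
        rng = np.random.default_rng(17)
        x, y, z = rng.normal(size=(3, 50))
        r1 = mf.partial_correlation(x, y, z).estimate
        r2 = mf.partial_correlation(x, y, 3.5 * z - 7.0).estimate
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_partial_with_collinear_control_rejected(self):
        x = np.arange(10.0)
        y = np.random.default_rng(1).normal(size=10)
        with pytest.raises(ValueError):
            mf.partial_correlation(x, y, x)


class TestNormalityGate:
    def test_normal_sample_passes_raw(self):
        rng = np.random.default_rng(42)
        assert mf.normality_gate(rng.normal(size=200)) == "normal"

    def test_lognormal_sample_routed_to_log(self):
        rng = np.random.default_rng(42)
        assert mf.normality_gate(np.exp(rng.normal(size=200))) == "lognormal"

    def test_heavy_bimodal_sample_is_neither(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(0, 0.05, 300), rng.normal(8, 0.05, 300)]) + 10
        assert mf.normality_gate(x) == "neither"

    def test_nonpositive_values_block_log_branch(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([np.exp(rng.normal(size=200)), [-1.0]])
        assert mf.normality_gate(x) == "neither"

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            mf.normality_gate([2.0] * 10)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            mf.normality_gate([1.0, 2.0, 3.0])


class TestCorrelateAuto:
    def test_lognormal_variable_triggers_log_pearson(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=300)
        x = np.exp(z + 0.3 * rng.normal(size=300))
        y = z + 0.5 * rng.normal(size=300)
        plain, _ = mf.correlate_auto(x, y)
        assert plain.method == "pearson_log"
        assert plain.estimate == pytest.approx(
            bf_pearson(list(np.log(x)), list(y)), abs=1e-10)

    def test_non_normal_variable_triggers_spearman(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 0.05, 150), rng.normal(8, 0.05, 150)])
        y = rng.normal(size=300)
        plain, partial = mf.correlate_auto(x, y, z=rng.normal(size=300))
        assert plain.method == "spearman"
        assert partial.transform == "rank"
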