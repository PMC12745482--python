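"""Agreement statistics vs independent moment / optimization oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from tibiaqct.agreement import (agreement_report, bland_altman, cv_percent,
                                deming, descriptive_table, lin_ccc,
                                normality_check, pearson_r)


@pytest.fixture()
def noisy_pairs(rng):
    x = rng.normal(1100, 200, 20)
    y = 120 + 0.5 * x + rng.normal(0, 60, 20)
    return x, y


class TestPearson:
    def test_perfect_positive_line(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative_line(self):
        x = np.arange(10.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, _ = pearson_r([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestLinCcc:
    def test_identity_is_perfect_concordance(self, rng):
        x = rng.normal(700, 100, 25)
        res = lin_ccc(x, x.copy())
        assert res.ccc == pytest.approx(1.0)
        assert res.cb == pytest.approx(1.0)

    def test_constant_offset_closed_form(self, rng):
        x = rng.normal(0, 1, 50)
        c = 2.0
        res = lin_ccc(x, x + c)
        s2 = x.var(ddof=0)
        assert res.ccc == pytest.approx(2 * s2 / (2 * s2 + c * c), abs=1e-12)

    def test_matches_direct_moment_formula(self, noisy_pairs):
        x, y = noisy_pairs
        res = lin_ccc(x, y)
        n = x.size
        sxy = ((x - x.mean()) * (y - y.mean())).sum() / n
        expect = 2 * sxy / (x.var(ddof=0) + y.var(ddof=0)
                            + (x.mean() - y.mean()) ** 2)
        assert res.ccc == pytest.approx(expect, abs=1e-12)

    def test_ccc_is_r_times_cb(self, noisy_pairs):
        x, y = noisy_pairs
        res = lin_ccc(x, y)
        r, _ = pearson_r(x, y)
        assert res.ccc == pytest.approx(r * res.cb, abs=1e-12)
        assert abs(res.ccc) <= abs(r) + 1e-12
        assert 0 < res.cb <= 1

    def test_ci_brackets_the_estimate(self, noisy_pairs):
        res = lin_ccc(*noisy_pairs)
        assert res.ci_low < res.ccc < res.ci_high


class TestBlandAltman:
    def test_identical_methods(self, rng):
        x = rng.normal(700, 50, 12)
        res = bland_altman(x, x.copy())
        assert res.mean_bias == 0.0
        assert res.loa_lower == res.loa_upper == 0.0
        assert res.constant_diff

    def test_constant_offset(self, rng):
        x = rng.normal(1100, 150, 30)
        res = bland_altman(x, x - 458.0)
        assert res.mean_bias == pytest.approx(-458.0)
        assert res.loa_lower == pytest.approx(-458.0)
        assert res.slope == pytest.approx(0.0, abs=1e-9)

    def test_matches_direct_formula(self, noisy_pairs):
        x, y = noisy_pairs
        res = bland_altman(x, y)
        d = y - x
        assert res.mean_bias == pytest.approx(d.mean(), abs=1e-12)
        sd = d.std(ddof=1)
        assert res.loa_upper == pytest.approx(d.mean() + 1.96 * sd, abs=1e-12)
        fit = stats.linregress((x + y) / 2, d)
        assert res.slope == pytest.approx(fit.slope, abs=1e-12)

    def test_limits_symmetric_about_bias(self, noisy_pairs):
        res = bland_altman(*noisy_pairs)
        assert res.loa_lower + res.loa_upper == pytest.approx(
            2 * res.mean_bias, abs=1e-9)


def deming_loss_oracle(x, y, lam, beta):
    """Profile Deming loss at slope beta (alpha profiled out)."""
    alpha = y.mean() - beta * x.mean()
    return np.sum((y - alpha - beta * x) ** 2) / (lam + beta ** 2)


class TestDeming:
    def test_noiseless_line_recovered_for_any_lambda(self):
        x = np.linspace(0, 10, 15)
        y = 2 * x + 1
        for lam in (0.25, 1.0, 4.0):
            res = deming(x, y, lam=lam, ci=False)
            assert res.beta == pytest.approx(2.0)
            assert res.alpha == pytest.approx(1.0)

    def test_slope_minimizes_the_deming_loss(self, rng):
        x = rng.normal(0, 1, 15)
        y = 0.8 * x + rng.normal(0, 0.5, 15)
        res = deming(x, y, lam=1.0, ci=False)
        opt = minimize_scalar(lambda b: deming_loss_oracle(x, y, 1.0, b),
                              bounds=(0.01, 10), method="bounded",
                              options={"xatol": 1e-10})
        assert res.beta == pytest.approx(opt.x, abs=1e-6)

    def test_swap_inverts_slope_at_unit_lambda(self, rng):
        x = rng.normal(0, 1, 40)
        y = x + rng.normal(0, 0.3, 40)
        b_xy = deming(x, y, lam=1.0, ci=False).beta
        b_yx = deming(y, x, lam=1.0, ci=False).beta
        assert b_xy == pytest.approx(1 / b_yx, abs=1e-9)

    def test_scale_invariance(self, noisy_pairs):
        x, y = noisy_pairs
        base = deming(x, y, ci=False)
        scaled = deming(3.0 * x, 3.0 * y, ci=False)
        assert scaled.beta == pytest.approx(base.beta, abs=1e-9)
        assert scaled.alpha == pytest.approx(3.0 * base.alpha, rel=1e-9)

    def test_large_lambda_limit_approaches_ols(self, noisy_pairs):
        x, y = noisy_pairs
        res = deming(x, y, lam=1e8, ci=False)
        ols = stats.linregress(x, y)
        assert res.beta == pytest.approx(ols.slope, rel=1e-4)

    def test_jackknife_ci_brackets_estimate(self, noisy_pairs):
        res = deming(*noisy_pairs)
        assert res.beta_ci[0] < res.beta < res.beta_ci[1]
        assert res.alpha_ci[0] < res.alpha < res.alpha_ci[1]

    def test_zero_covariance_rejected(self):
        with pytest.raises(ValueError):
            deming([1.0, 2.0, 1.0, 2.0], [5.0, 5.0, 6.0, 6.0], ci=False)


class TestCvPercent:
    def test_moment_form(self):
        assert cv_percent(100.0, 5.0) == pytest.approx(5.0)

    def test_vector_form_uses_sample_sd(self, rng):
        v = rng.normal(50, 5, 40)
        assert cv_percent(v) == pytest.approx(100 * v.std(ddof=1) / v.mean())

    def test_constant_vector_is_zero(self):
        assert cv_percent([7.0, 7.0, 7.0]) == 0.0

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cv_percent([-1.0, 1.0])


class TestDescriptiveTable:
    def test_single_bone_constant_replicates(self):
        df = pd.DataFrame({"bone_id": [1, 1, 1], "method": "M1",
                           "region": ["proximal", "medial", "distal"],
                           "bmd": [700.0, 700.0, 700.0]})
        out = descriptive_table(df)
        overall = out[out.region == "overall"].iloc[0]
        assert overall["mean"] == 700.0 and overall["cv_pct"] == 0.0

    def test_two_bone_arithmetic(self):
        df = pd.DataFrame({"bone_id": [1, 2], "method": "M2",
                           "region": ["medial", "medial"],
                           "bmd": [700.0, 900.0]})
        row = descriptive_table(df).query("region == 'medial'").iloc[0]
        assert row["mean"] == 800.0
        assert row["sd"] == pytest.approx(np.sqrt(2) * 100, abs=0.01)

    def test_matches_groupby_oracle(self, small_result):
        table = descriptive_table(small_result.region_summary)
        region = small_result.region_summary
        for _, row in table[table.region != "overall"].iterrows():
            sub = region[(region.method == row["method"])
                         & (region.region == row["region"])]["bmd"]
            assert row["mean"] == pytest.approx(sub.mean())
            assert row["sd"] == pytest.approx(sub.std(ddof=1))


def test_agreement_report_bundles_consistently(noisy_pairs):
    x, y = noisy_pairs
    rep = agreement_report(x, y)
    assert rep.ccc == pytest.approx(rep.pearson_r * rep.cb, abs=1e-12)
    assert rep.loa_lower + rep.loa_upper == pytest.approx(2 * rep.mean_bias,
                                                          abs=1e-9)
    assert rep.mean_bias == pytest.approx(y.mean() - x.mean())
    assert rep.cv_x == pytest.approx(100 * x.std(ddof=1) / x.mean())


def test_normality_check_warns_only(rng):
    skewed = rng.exponential(1.0, 80) ** 3
    with pytest.warns(UserWarning, match="non-normality"):
        p = normality_check(skewed, label="skewed")
    assert p < 0.05
    assert normality_check(rng.normal(0, 1, 80)) > 0.0
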