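"""Method-comparison statistics for paired BMD measurements.

Given per-bone paired values (x = M1 quadrant-ROI BMD, y = M2 whole-bone
BMD) this module computes the standard agreement suite:

* Pearson correlation with its t-based p-value (precision),
* Lin's concordance correlation coefficient
  ccc = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2) with the bias-correction
  factor Cb = ccc / r (accuracy) and a Fisher-z confidence interval using
  Lin's asymptotic standard error,
* Bland-Altman mean bias (y - x), 95% limits of agreement
  bias +/- 1.96 SD(d), and the proportional-bias regression of the
  difference on the pair mean,
* Deming errors-in-variables regression of y on x with error-variance ratio
  lambda (default 1, orthogonal case) and leave-one-out jackknife CIs,
* coefficients of variation and descriptive per-method / per-region tables.

Moment conventions: population moments (divisor n) inside the CCC formula,
sample moments (n-1) for descriptive SD/CV and the Bland-Altman SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CccResult", "BlandAltmanResult", "DemingResult", "AgreementReport",
           "pearson_r", "lin_ccc", "bland_altman", "deming", "cv_percent",
           "descriptive_table", "agreement_report", "normality_check",
           "bland_altman_plot", "deming_plot"]


def _pairs(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed within pairs")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    return x, y


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation and its two-sided p (t transform, n-2 df)."""
    x, y = _pairs(x, y)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CccResult:
    ccc: float
    cb: float           # accuracy / bias-correction factor, ccc = r * cb
    r: float
    ci_low: float
    ci_high: float
    n: int


def lin_ccc(x, y, alpha: float = 0.05) -> CccResult:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    The point estimate uses population (divisor n) moments; the CI uses
    Lin's asymptotic variance of the z-transformed estimate.
    """
    x, y = _pairs(x, y)
    n = x.size
    sx2 = float(x.var(ddof=0))
    sy2 = float(y.var(ddof=0))
    if sx2 == 0 and sy2 == 0:
        raise ValueError("CCC undefined: both variances zero")
    sxy = float(np.cov(x, y, ddof=0)[0, 1])
    dmean = float(x.mean() - y.mean())
    ccc = 2.0 * sxy / (sx2 + sy2 + dmean * dmean)
    r = sxy / np.sqrt(sx2 * sy2) if sx2 > 0 and sy2 > 0 else np.nan
    cb = ccc / r if r not in (0.0,) and np.isfinite(r) else np.nan
    # Lin (1989, corrigendum 2000) asymptotic variance of atanh(ccc)
    u2 = dmean * dmean / np.sqrt(sx2 * sy2) if sx2 > 0 and sy2 > 0 else np.inf
    if np.isfinite(r) and abs(ccc) < 1 and abs(r) > 0:
        var_z = ((1 - r * r) * ccc * ccc / ((1 - ccc * ccc) * r * r)
                 + 2 * ccc ** 3 * (1 - ccc) * u2 / (r * (1 - ccc * ccc) ** 2)
                 - ccc ** 4 * u2 * u2 / (2 * r * r * (1 - ccc * ccc) ** 2)
                 ) / (n - 2)
        se_z = np.sqrt(max(var_z, 0.0))
        zq = stats.norm.ppf(1 - alpha / 2)
        z = np.arctanh(ccc)
        lo, hi = np.tanh(z - zq * se_z), np.tanh(z + zq * se_z)
    else:
        lo = hi = np.nan
    return CccResult(ccc=float(ccc), cb=float(cb), r=float(r),
                     ci_low=float(lo), ci_high=float(hi), n=n)


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_bias: float    # mean of d = y - x
    loa_lower: float
    loa_upper: float
    sd_diff: float      # sample SD of d
    slope: float        # OLS slope of d on (x + y) / 2 (proportional bias)
    slope_p: float
    constant_diff: bool
    n: int


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman agreement: bias, 95% limits, proportional-bias slope."""
    x, y = _pairs(x, y)
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_lo, loa_hi = bias - 1.96 * sd, bias + 1.96 * sd
    m = (x + y) / 2.0
    constant = sd == 0 or m.std() == 0
    if constant:
        slope, slope_p = 0.0, float("nan")
    else:
        fit = stats.linregress(m, d)
        slope, slope_p = float(fit.slope), float(fit.pvalue)
    return BlandAltmanResult(mean_bias=bias, loa_lower=float(loa_lo),
                             loa_upper=float(loa_hi), sd_diff=sd,
                             slope=slope, slope_p=slope_p,
                             constant_diff=bool(constant), n=x.size)


@dataclass(frozen=True)
class DemingResult:
    alpha: float
    beta: float
    alpha_ci: tuple[float, float]
    beta_ci: tuple[float, float]
    lam: float
    n: int


def _deming_point(x, y, lam):
    sxx = x.var(ddof=1)
    syy = y.var(ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxy == 0:
        raise ValueError("Deming slope degenerate: zero covariance")
    beta = ((syy - lam * sxx) + np.sqrt((syy - lam * sxx) ** 2
                                        + 4 * lam * sxy * sxy)) / (2 * sxy)
    alpha = y.mean() - beta * x.mean()
    return float(alpha), float(beta)


def deming(x, y, lam: float = 1.0, ci: bool = True,
           alpha_level: float = 0.05) -> DemingResult:
    """Deming errors-in-variables regression of y on x.

    ``lam`` is the ratio of measurement-error variances (error_y / error_x);
    lam = 1 is orthogonal regression.  Confidence intervals come from the
    leave-one-out jackknife with a t(n-2) quantile.
    """
    x, y = _pairs(x, y)
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    n = x.size
    a_hat, b_hat = _deming_point(x, y, lam)
    if not ci:
        nan2 = (float("nan"), float("nan"))
        return DemingResult(a_hat, b_hat, nan2, nan2, lam, n)
    alphas = np.empty(n)
    betas = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        alphas[i], betas[i] = _deming_point(x[keep], y[keep], lam)
    tq = stats.t.ppf(1 - alpha_level / 2, df=n - 2)

    def jack_ci(stat, loo):
        se = np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2))
        return (float(stat - tq * se), float(stat + tq * se))

    return DemingResult(alpha=a_hat, beta=b_hat,
                        alpha_ci=jack_ci(a_hat, alphas),
                        beta_ci=jack_ci(b_hat, betas), lam=lam, n=n)


def cv_percent(values, sd: float | None = None) -> float:
    """Coefficient of variation in percent: 100 * sample SD / mean.

    Either pass a vector of values, or a (mean, sd) pair as
    ``cv_percent(mean, sd)``.
    """
    if sd is not None:
        mean = float(values)
    else:
        v = np.asarray(values, dtype=float)
        if v.size < 1:
            raise ValueError("empty vector")
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * sd / mean


def descriptive_table(bone_summary: pd.DataFrame,
                      value_col: str = "bmd") -> pd.DataFrame:
    """Per-method overall and per-region mean, sample SD, CV% and n.

    Expects one row per (bone_id, method, region) with the region-level BMD
    (already averaged over replicates); the overall row for a method
    averages each bone's three region values first, matching the pooling
    order used for whole-bone values.
    """
    rows = []
    for method, g in bone_summary.groupby("method", sort=True):
        whole = g.groupby("bone_id", sort=True)[value_col].mean()
        rows.append({"method": method, "region": "overall",
                     "mean": whole.mean(), "sd": whole.std(ddof=1),
                     "cv_pct": cv_percent(whole.to_numpy()), "n": whole.size})
        for region, gr in g.groupby("region", sort=False):
            vals = gr.set_index("bone_id")[value_col]
            if vals.empty:
                continue
            rows.append({"method": method, "region": region,
                         "mean": vals.mean(), "sd": vals.std(ddof=1),
                         "cv_pct": cv_percent(vals.to_numpy()), "n": vals.size})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AgreementReport:
    """The full comparison bundle for one paired sample (x = M1, y = M2)."""

    n: int
    pearson_r: float
    pearson_p: float
    ccc: float
    ccc_ci: tuple[float, float]
    cb: float
    mean_bias: float
    loa_lower: float
    loa_upper: float
    ba_slope: float
    ba_slope_p: float
    deming_alpha: float
    deming_alpha_ci: tuple[float, float]
    deming_beta: float
    deming_beta_ci: tuple[float, float]
    deming_lambda: float
    mean_x: float
    sd_x: float
    cv_x: float
    mean_y: float
    sd_y: float
    cv_y: float
    ci_method: str = "CCC: Fisher z with Lin's asymptotic SE; Deming: leave-one-out jackknife, t(n-2)"

    def to_dict(self) -> dict:
        return asdict(self)


def agreement_report(x, y, lam: float = 1.0) -> AgreementReport:
    """Compute every agreement indicator for one paired sample."""
    x, y = _pairs(x, y)
    r, p = pearson_r(x, y)
    ccc = lin_ccc(x, y)
    ba = bland_altman(x, y)
    dem = deming(x, y, lam=lam)
    return AgreementReport(
        n=x.size, pearson_r=r, pearson_p=p,
        ccc=ccc.ccc, ccc_ci=(ccc.ci_low, ccc.ci_high), cb=ccc.cb,
        mean_bias=ba.mean_bias, loa_lower=ba.loa_lower, loa_upper=ba.loa_upper,
        ba_slope=ba.slope, ba_slope_p=ba.slope_p,
        deming_alpha=dem.alpha, deming_alpha_ci=dem.alpha_ci,
        deming_beta=dem.beta, deming_beta_ci=dem.beta_ci, deming_lambda=lam,
        mean_x=float(x.mean()), sd_x=float(x.std(ddof=1)),
        cv_x=cv_percent(x),
        mean_y=float(y.mean()), sd_y=float(y.std(ddof=1)),
        cv_y=cv_percent(y))


def normality_check(values, label: str = "sample", alpha: float = 0.05) -> float:
    """Shapiro-Wilk screen; warns (never gates) on evidence of non-normality."""
    w, p = stats.shapiro(np.asarray(values, dtype=float))
    if p < alpha:
        warnings.warn(f"Shapiro-Wilk suggests non-normality for {label} "
                      f"(W={w:.3f}, p={p:.3g})", stacklevel=2)
    return float(p)


def bland_altman_plot(x, y, path):
    """Write a Bland-Altman scatter (difference vs mean) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    x, y = _pairs(x, y)
    ba = bland_altman(x, y)
    m, d = (x + y) / 2, y - x
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(m, d, s=18, alpha=0.8)
    for val, style in ((ba.mean_bias, "-"), (ba.loa_lower, "--"), (ba.loa_upper, "--")):
        ax.axhline(val, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of methods (mgHA/cm$^3$)")
    ax.set_ylabel("difference M2 $-$ M1 (mgHA/cm$^3$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def deming_plot(x, y, path, lam: float = 1.0):
    """Write a scatter of the pairs with the Deming line to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    x, y = _pairs(x, y)
    dem = deming(x, y, lam=lam, ci=False)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=18, alpha=0.8)
    xs = np.linspace(x.min(), x.max(), 10)
    ax.plot(xs, dem.alpha + dem.beta * xs, "k-", linewidth=1,
            label=f"Deming: y = {dem.alpha:.1f} + {dem.beta:.2f} x")
    ax.plot(xs, xs, "k:", linewidth=1, label="identity")
    ax.set_xlabel("M1 BMD (mgHA/cm$^3$)")
    ax.set_ylabel("M2 BMD (mgHA/cm$^3$)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
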