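"""Method-agreement statistics for predicted vs reference fat-free mass.

Implements the full validation suite used when comparing a BIA prediction
equation against a reference method (DXA): paired comparison with a
conditional log10 transform, calibration regression (adjusted R^2, SEE),
pure error, Lin's concordance correlation with its precision/accuracy
decomposition, Bland–Altman limits of agreement with a proportional-bias
trend test, and test–retest reliability (TEM, CV%).

Conventions
-----------
Differences are predicted minus reference throughout.  The pure error uses
an n divisor; the SEE uses n-2 (residual degrees of freedom of the
calibration regression).  Limits of agreement use the 1.96 multiplier.
All statistics are computed at full floating precision; rounding happens
only in the report formatter (kg and % to 1 dp, rho and C_b to 4 dp, CCC
and R^2 to 2 dp).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._errors import InputValidationError, StatisticalError

__all__ = [
    "AgreementReport",
    "ReliabilityReport",
    "difference_summary",
    "paired_comparison",
    "lin_ccc",
    "pure_error",
    "calibration_fit",
    "bland_altman",
    "technical_error",
    "build_report",
    "reports_to_frame",
    "format_report_table",
    "bland_altman_plot",
]

LOA_MULTIPLIER = 1.96  # 95% limits of agreement


@dataclass(frozen=True)
class AgreementReport:
    """All agreement statistics for one prediction method vs the reference."""

    equation_id: str
    n: int
    mean_pred: float
    sd_pred: float
    min_pred: float
    max_pred: float
    mean_diff: float          # kg, predicted - reference
    sd_diff: float
    pct_diff: float           # |mean_diff| as % of the reference mean
    paired_t: float
    paired_p: float
    log_transformed: bool
    ccc: float
    precision_rho: float
    accuracy_cb: float
    r2_adj: float
    see: float
    pure_error: float
    loa_lower: float
    loa_upper: float
    trend_r: float
    trend_p: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ReliabilityReport:
    """Test–retest reliability: technical error of measurement and CV%."""

    tem: float
    cv_pct: float
    n_pairs: int


def _paired_arrays(pred, ref, min_n: int = 2):
    p = np.asarray(pred, dtype=float).ravel()
    r = np.asarray(ref, dtype=float).ravel()
    if p.shape != r.shape:
        raise InputValidationError(
            f"length mismatch: {p.shape[0]} predictions vs {r.shape[0]} references"
        )
    if p.size < min_n:
        raise StatisticalError(f"need at least {min_n} paired observations")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(r))):
        raise InputValidationError("non-finite values in paired series")
    return p, r


def difference_summary(pred, ref):
    """Mean difference, its sample SD, and |mean diff| as % of reference mean."""
    p, r = _paired_arrays(pred, ref)
    d = p - r
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    pct_diff = abs(mean_diff) / float(np.mean(r)) * 100.0
    return mean_diff, sd_diff, pct_diff


def _normality_p(x: np.ndarray) -> float:
    # Shapiro-Wilk; a constant series carries no evidence against normality.
    if np.ptp(x) == 0:
        return 1.0
    return float(stats.shapiro(x).pvalue)


def paired_comparison(pred, ref, normality_alpha: float = 0.05):
    """Paired t-test, log10-transforming both series if either is non-normal.

    Each series is screened with Shapiro–Wilk at ``normality_alpha``; if
    either fails, both series are log10-transformed (they must then be
    strictly positive) before the two-sided paired t-test.  Returns
    ``(statistic, p, log_transformed)``.  Identical series give (0, 1).
    """
    p, r = _paired_arrays(pred, ref, min_n=3)
    if not 0 < normality_alpha < 1:
        raise InputValidationError("normality_alpha must be in (0, 1)")
    log_transformed = (
        _normality_p(p) < normality_alpha or _normality_p(r) < normality_alpha
    )
    if log_transformed:
        if np.any(p <= 0) or np.any(r <= 0):
            raise InputValidationError(
                "log10 transform triggered by non-normality, but the series "
                "contain non-positive values"
            )
        p, r = np.log10(p), np.log10(r)
    d = p - r
    if np.ptp(d) == 0 and d[0] == 0:
        return 0.0, 1.0, log_transformed
    t, pval = stats.ttest_rel(p, r)
    return float(t), float(pval), log_transformed


def lin_ccc(pred, ref):
    """Lin's concordance correlation with precision/accuracy decomposition.

    CCC = 2*cov / (var_pred + var_ref + (mean_pred - mean_ref)^2), using
    sample (n-1) moments.  Returns ``(ccc, precision_rho, accuracy_cb)``
    where ``precision_rho`` is the Pearson correlation and
    ``accuracy_cb = ccc / rho``, so ccc = rho * C_b holds exactly.
    """
    p, r = _paired_arrays(pred, ref)
    var_p = float(np.var(p, ddof=1))
    var_r = float(np.var(r, ddof=1))
    if var_p == 0 or var_r == 0:
        raise StatisticalError("zero variance: concordance undefined")
    cov = float(np.cov(p, r, ddof=1)[0, 1])
    mean_gap = float(np.mean(p) - np.mean(r))
    ccc = 2.0 * cov / (var_p + var_r + mean_gap**2)
    rho = cov / np.sqrt(var_p * var_r)
    cb = ccc / rho
    return float(ccc), float(rho), float(cb)


def pure_error(pred, ref):
    """Root mean squared prediction error, divisor n."""
    p, r = _paired_arrays(pred, ref, min_n=1)
    return float(np.sqrt(np.mean((p - r) ** 2)))


def calibration_fit(pred, ref):
    """Adjusted R^2 and SEE of the simple regression of reference on predicted.

    Ordinary least squares of the reference values on the predictions;
    SEE is the residual standard deviation with an n-2 divisor.
    """
    p, r = _paired_arrays(pred, ref, min_n=3)
    if np.ptp(p) == 0:
        raise StatisticalError("zero predictor variance: regression undefined")
    model = sm.OLS(r, sm.add_constant(p)).fit()
    see = float(np.sqrt(model.ssr / (len(p) - 2)))
    return float(model.rsquared_adj), see


def bland_altman(pred, ref):
    """Bias, 95% limits of agreement, and the proportional-bias trend test.

    The trend is the Pearson correlation of the differences (pred - ref)
    against the pairwise means; a significant correlation indicates that
    the bias depends on the magnitude of fat-free mass.
    """
    p, r = _paired_arrays(pred, ref, min_n=3)
    d = p - r
    m = (p + r) / 2.0
    bias = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    loa_lower = bias - LOA_MULTIPLIER * sd_diff
    loa_upper = bias + LOA_MULTIPLIER * sd_diff
    if np.ptp(d) == 0 or np.ptp(m) == 0:
        trend_r, trend_p = 0.0, 1.0
    else:
        res = stats.pearsonr(d, m)
        trend_r, trend_p = float(res.statistic), float(res.pvalue)
    return bias, loa_lower, loa_upper, trend_r, trend_p


def technical_error(test, retest):
    """Technical error of measurement and CV% from test–retest pairs.

    TEM = sqrt(sum(d^2) / (2n)) over the within-subject differences d.
    CV% is the within-subject SD (identical to the TEM) expressed as a
    percentage of the grand mean of all measurements.
    """
    t, r = _paired_arrays(test, retest, min_n=1)
    d = t - r
    tem = float(np.sqrt(np.sum(d**2) / (2 * len(d))))
    grand_mean = float(np.mean(np.concatenate([t, r])))
    if grand_mean == 0:
        raise StatisticalError("grand mean is zero: CV% undefined")
    return ReliabilityReport(tem=tem, cv_pct=tem / abs(grand_mean) * 100.0, n_pairs=len(d))


def build_report(
    equation_id: str, pred, ref, normality_alpha: float = 0.05
) -> AgreementReport:
    """Assemble the full agreement report for one equation vs the reference."""
    p, r = _paired_arrays(pred, ref, min_n=3)
    mean_diff, sd_diff, pct_diff = difference_summary(p, r)
    t_stat, p_value, log_flag = paired_comparison(p, r, normality_alpha)
    if np.ptp(p) == 0 or np.ptp(r) == 0:
        raise StatisticalError(
            f"{equation_id}: zero variance in predictions or reference"
        )
    ccc, rho, cb = lin_ccc(p, r)
    r2_adj, see = calibration_fit(p, r)
    bias, loa_lower, loa_upper, trend_r, trend_p = bland_altman(p, r)
    return AgreementReport(
        equation_id=equation_id,
        n=len(p),
        mean_pred=float(np.mean(p)),
        sd_pred=float(np.std(p, ddof=1)),
        min_pred=float(np.min(p)),
        max_pred=float(np.max(p)),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        pct_diff=pct_diff,
        paired_t=t_stat,
        paired_p=p_value,
        log_transformed=log_flag,
        ccc=ccc,
        precision_rho=rho,
        accuracy_cb=cb,
        r2_adj=r2_adj,
        see=see,
        pure_error=pure_error(p, r),
        loa_lower=loa_lower,
        loa_upper=loa_upper,
        trend_r=trend_r,
        trend_p=trend_p,
    )


def reports_to_frame(reports, *, rounded: bool = False) -> pd.DataFrame:
    """Tabulate agreement reports, one row per equation.

    With ``rounded=True`` the presentation rounding is applied (kg and %
    to 1 dp, rho/C_b to 4 dp, CCC and adjusted R^2 to 2 dp) and a
    significance flag marks equations whose paired test differs from the
    reference at p < 0.05.
    """
    frame = pd.DataFrame([rep.to_dict() for rep in reports])
    if not rounded:
        return frame
    out = frame.copy()
    for col in (
        "mean_pred", "sd_pred", "min_pred", "max_pred", "mean_diff",
        "sd_diff", "pct_diff", "see", "pure_error", "loa_lower", "loa_upper",
    ):
        out[col] = out[col].round(1)
    for col in ("precision_rho", "accuracy_cb"):
        out[col] = out[col].round(4)
    for col in ("ccc", "r2_adj"):
        out[col] = out[col].round(2)
    for col in ("paired_t", "trend_r"):
        out[col] = out[col].round(2)
    for col in ("paired_p", "trend_p"):
        out[col] = out[col].round(4)
    out.insert(
        len(out.columns), "significant_vs_reference", frame["paired_p"] < 0.05
    )
    return out


def format_report_table(reports, fmt: str = "markdown") -> str:
    """Render a report table as ``markdown`` or ``csv`` text."""
    frame = reports_to_frame(reports, rounded=True)
    if fmt == "markdown":
        return frame.to_markdown(index=False)
    if fmt == "csv":
        return frame.to_csv(index=False)
    raise InputValidationError(f"unknown report format: {fmt!r}")


def bland_altman_plot(pred, ref, *, title: str = "", ax=None):
    """Draw a Bland–Altman plot: bias line, 95% limits, and trend line."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    p, r = _paired_arrays(pred, ref, min_n=3)
    d = p - r
    m = (p + r) / 2.0
    bias, lo, hi, trend_r, trend_p = bland_altman(p, r)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(m, d, s=10, alpha=0.5, color="0.3")
    ax.axhline(bias, color="black", lw=1.5, label=f"bias {bias:.1f} kg")
    for y in (lo, hi):
        ax.axhline(y, color="black", lw=1, ls="--")
    slope, intercept = np.polyfit(m, d, 1)
    xs = np.array([m.min(), m.max()])
    ax.plot(xs, slope * xs + intercept, color="gray", lw=1,
            label=f"trend r={trend_r:.2f} (p={trend_p:.3f})")
    ax.set_xlabel("mean of methods (kg)")
    ax.set_ylabel("difference, predicted - reference (kg)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax
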