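"""Method-agreement statistics for paired calcium scores.

Implements the validation machinery used to compare length-adjusted
calcium scores between two measurement conditions (contrast vs.
noncontrast, two observers, two slice thicknesses):

* intraclass correlation (single rating, two-way model) with a 95%
  F-distribution confidence interval and the conventional reliability
  labels (poor < 0.5 <= moderate <= 0.75 < good <= 0.9 < excellent);
* Bland–Altman mean difference and 95% limits of agreement;
* paired rank tests (Wilcoxon signed-rank by default, Mann–Whitney U as a
  variant) for non-normally distributed scores;
* the linear-regression correction factor converting contrast-derived
  scores to their noncontrast equivalents (through-origin by default — a
  zero-calcium artery must map to a zero corrected score).

ICC formulas follow the standard two-way ANOVA mean-squares construction
(single rating): consistency ICC(3,1) and absolute-agreement ICC(2,1),
with the usual F-based confidence bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateTestError, UndefinedICCError, ValidationError

__all__ = [
    "AgreementResult",
    "BlandAltmanResult",
    "validate_ratings_table",
    "icc_single_two_way_mixed",
    "reliability_label",
    "bland_altman",
    "paired_rank_test",
    "correction_factor",
    "agreement_analysis",
]


def validate_ratings_table(table: np.ndarray) -> np.ndarray:
    """Validate an (n subjects x k raters/methods) ratings table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("ratings table must be 2-D (subjects x raters)")
    n, k = arr.shape
    if n < 3:
        raise ValidationError(f"need >= 3 subjects, got {n}")
    if k < 2:
        raise ValidationError(f"need >= 2 raters/methods, got {k}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("ratings table contains non-finite values")
    return arr


def _mean_squares(arr: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares: (rows/subjects, columns/raters, error)."""
    n, k = arr.shape
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((arr - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)  # guard tiny negatives
    return float(msr), float(msc), float(mse)


def icc_single_two_way_mixed(
    table: np.ndarray,
    definition: str = "consistency",
    confidence: float = 0.95,
) -> tuple[float, float, float]:
    """Single-rating two-way mixed-model ICC with its confidence interval.

    ``definition="consistency"`` gives ICC(3,1); ``"absolute_agreement"``
    gives ICC(2,1).  Returns ``(icc, ci_low, ci_high)``.  Identical columns
    yield exactly ``(1.0, 1.0, 1.0)``; zero between-subject variance raises
    :class:`~lacs.errors.UndefinedICCError`.
    """
    if definition not in ("consistency", "absolute_agreement"):
        raise ValidationError(f"unknown ICC definition {definition!r}")
    arr = validate_ratings_table(table)
    n, k = arr.shape
    msr, msc, mse = _mean_squares(arr)
    if msr <= 0 or np.allclose(arr.mean(axis=1), arr.mean(axis=1)[0]):
        raise UndefinedICCError(
            "zero between-subject variance; ICC is undefined"
        )
    alpha = 1.0 - confidence
    if mse == 0.0 and msc == 0.0:
        # identical columns: perfect agreement under either definition
        return 1.0, 1.0, 1.0
    if definition == "consistency":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0.0:
            return 1.0, 1.0, 1.0
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (f_l - 1) / (f_l + k - 1)
        hi = (f_u - 1) / (f_u + k - 1)
        return float(icc), float(lo), float(hi)
    # absolute agreement, ICC(2,1)
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return 1.0, 1.0, 1.0
    b = 1 + k * icc * (n - 1) / (n * (1 - icc))
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f1 * mse) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi = n * (f2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr
    )
    return float(icc), float(lo), float(hi)


def reliability_label(icc: float) -> str:
    """Conventional reliability bin of an ICC value.

    ``poor`` below 0.5; ``moderate`` on [0.5, 0.75]; ``good`` on
    (0.75, 0.9]; ``excellent`` above 0.9.
    """
    if not np.isfinite(icc):
        raise ValidationError("ICC must be finite")
    if icc < 0.5:
        return "poor"
    if icc <= 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland–Altman agreement summary plus the scatter payload."""

    mean_difference: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    differences: np.ndarray

    def __iter__(self):
        # allow tuple-unpacking of the three summary numbers
        return iter((self.mean_difference, self.loa_low, self.loa_high))


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltmanResult:
    """Bland–Altman analysis of two paired score series.

    Differences are ``x - y``; limits of agreement are
    mean ± 1.96 x sample SD of the differences.  The per-pair means and
    differences are returned for plotting.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be 1-D series of equal length")
    if xa.size < 2:
        raise ValidationError("need >= 2 pairs")
    d = xa - ya
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        mean_difference=mean_d,
        loa_low=mean_d - 1.96 * sd_d,
        loa_high=mean_d + 1.96 * sd_d,
        means=(xa + ya) / 2.0,
        differences=d,
    )


def paired_rank_test(
    x: np.ndarray, y: np.ndarray, variant: str = "wilcoxon_signed_rank"
) -> float:
    """Two-sided nonparametric comparison of two score series.

    The default Wilcoxon signed-rank test treats the series as paired
    (same subjects under two conditions); ``variant="mann_whitney_u"``
    compares them as independent samples.  Returns the two-sided p-value.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if variant == "wilcoxon_signed_rank":
        if xa.shape != ya.shape or xa.ndim != 1:
            raise ValidationError("paired series must have equal length")
        d = xa - ya
        if np.all(d == 0):
            raise DegenerateTestError(
                "all paired differences are zero; signed-rank test undefined"
            )
        method = "exact" if xa.size <= 25 and not np.any(d == 0) else "auto"
        return float(stats.wilcoxon(xa, ya, alternative="two-sided", method=method).pvalue)
    if variant == "mann_whitney_u":
        if xa.size < 1 or ya.size < 1:
            raise ValidationError("need >= 1 observation per group")
        method = "exact" if max(xa.size, ya.size) <= 12 else "auto"
        return float(
            stats.mannwhitneyu(xa, ya, alternative="two-sided", method=method).pvalue
        )
    raise ValidationError(f"unknown rank-test variant {variant!r}")


def correction_factor(
    contrast_lacs: np.ndarray,
    noncontrast_lacs: np.ndarray,
    intercept: str = "through_origin",
) -> tuple[float, float]:
    """Regression slope converting contrast LACS to noncontrast LACS.

    Regresses noncontrast on contrast.  ``through_origin`` (default)
    constrains the fit through zero, so a calcium-free artery maps to a
    zero corrected score; ``free`` fits an ordinary intercept and returns
    the slope.  Returns ``(factor, r_squared)``; R^2 is uncentered for the
    through-origin fit, the ordinary coefficient of determination
    otherwise.
    """
    xa = np.asarray(contrast_lacs, dtype=float)
    ya = np.asarray(noncontrast_lacs, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("series must be 1-D and of equal length")
    if xa.size < 3:
        raise ValidationError("need >= 3 pairs for the regression")
    if np.ptp(xa) == 0:
        raise ValidationError("contrast series is constant; slope undefined")
    if intercept == "through_origin":
        slope = float(np.dot(xa, ya) / np.dot(xa, xa))
        resid = ya - slope * xa
        ss_tot = float(np.dot(ya, ya))
        r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 1.0
    elif intercept == "free":
        slope, b0 = np.polyfit(xa, ya, 1)
        slope = float(slope)
        resid = ya - (slope * xa + b0)
        ss_tot = float(np.sum((ya - ya.mean()) ** 2))
        r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 1.0
    else:
        raise ValidationError(f"unknown intercept mode {intercept!r}")
    return slope, float(r2)


@dataclass(frozen=True)
class AgreementResult:
    """Combined agreement analysis of two paired score series."""

    icc: float
    ci_low: float
    ci_high: float
    reliability: str
    bland_altman: BlandAltmanResult
    p_value: float | None

    def to_dict(self) -> dict:
        ba = self.bland_altman
        return {
            "icc": self.icc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "reliability": self.reliability,
            "bland_altman": {
                "mean_difference": ba.mean_difference,
                "loa_low": ba.loa_low,
                "loa_high": ba.loa_high,
            },
            "p_value": self.p_value,
        }


def agreement_analysis(
    x: np.ndarray,
    y: np.ndarray,
    icc_definition: str = "consistency",
    rank_variant: str = "wilcoxon_signed_rank",
) -> AgreementResult:
    """One-call agreement summary: ICC + label, Bland–Altman, rank test.

    The rank-test p-value is ``None`` when the test is degenerate
    (identical series).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    icc, lo, hi = icc_single_two_way_mixed(
        np.column_stack([xa, ya]), definition=icc_definition
    )
    try:
        p = paired_rank_test(xa, ya, variant=rank_variant)
    except DegenerateTestError:
        p = None
    return AgreementResult(
        icc=icc,
        ci_low=lo,
        ci_high=hi,
        reliability=reliability_label(icc),
        bland_altman=bland_altman(xa, ya),
        p_value=p,
    )
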