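"""Method-comparison statistics for paired Cobb-angle measurements.

Implements the standard agreement toolkit for two raters or methods
measuring the same subjects: Bland–Altman bias and limits of agreement,
the intraclass correlation ICC(2,1) (two-way random effects, absolute
agreement, single measurement) with its F-based 95% confidence
interval, and the paired error summaries MAD (median absolute
difference), MAE (mean absolute error) and their SD companion. The
classic one-sample MAD (median absolute deviation from the median) is
provided separately under its own name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

from .errors import UndefinedICCError

__all__ = [
    "BlandAltman",
    "AgreementReport",
    "bland_altman",
    "icc_2_1",
    "paired_error_summary",
    "one_sample_mad",
    "agreement_report",
]

LOA_MULTIPLIER = 1.96  # conventional 95% limits of agreement


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size != b.size:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("measurements must be finite")
    return a, b


@dataclass(frozen=True)
class BlandAltman:
    """Bias and limits of agreement, with per-pair plot coordinates."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    means: np.ndarray
    diffs: np.ndarray


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement summary between two measurement methods."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    icc: float
    icc_ci: tuple[float, float]
    mad: float
    mae: float
    sd_abs_diff: float
    n: int


def bland_altman(a, b) -> BlandAltman:
    """Bland–Altman analysis of paired measurements a_i − b_i.

    Bias is the mean difference, sd_diff the sample (n−1) standard
    deviation of the differences, and the limits of agreement are
    bias ± 1.96·sd_diff.
    """
    a, b = _paired(a, b)
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = a - b
    means = (a + b) / 2.0
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltman(
        bias=bias,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        sd_diff=sd,
        means=means,
        diffs=diffs,
    )


def icc_2_1(a, b, confidence: float = 0.95) -> tuple[float, tuple[float, float]]:
    """ICC(2,1) with an F-based confidence interval for two raters.

    Two-way random effects, absolute agreement, single measurement. The
    point estimate and interval follow the standard single-score
    formulas from the two-way ANOVA mean squares (between-subject MSR,
    between-rater MSC, residual MSE):

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

    with the interval obtained from F quantiles at the
    Satterthwaite-approximated denominator degrees of freedom.
    """
    a, b = _paired(a, b)
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 subjects for a nondegenerate ICC CI")
    data = np.column_stack([a, b])
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise UndefinedICCError("all measurements identical: ICC undefined")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((data - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse <= 1e-300 and msc <= 1e-300:
        return float(icc), (float(icc), float(icc))  # perfect agreement
    a_coef = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b_coef = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    v = (a_coef * msc + b_coef * mse) ** 2 / (
        (a_coef * msc) ** 2 / (k - 1) + (b_coef * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_low = f_dist.ppf(1 - alpha / 2, n - 1, v)
    f_up = f_dist.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    return float(icc), (float(lower), float(upper))


def paired_error_summary(a, b) -> tuple[float, float, float]:
    """(MAD, MAE, SD) of the absolute paired differences |a_i − b_i|.

    MAD is the median and MAE the mean of the absolute differences; the
    SD is the sample (n−1) standard deviation of the absolute
    differences — the "± SD" companion usually printed next to them.
    """
    a, b = _paired(a, b)
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    u = np.abs(a - b)
    return float(np.median(u)), float(np.mean(u)), float(np.std(u, ddof=1))


def one_sample_mad(x) -> float:
    """Classic median absolute deviation: median(|x_i − median(x)|)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one value")
    return float(np.median(np.abs(x - np.median(x))))


def agreement_report(a, b, confidence: float = 0.95) -> AgreementReport:
    """Assemble the full agreement summary between two methods."""
    ba = bland_altman(a, b)
    icc, ci = icc_2_1(a, b, confidence=confidence)
    mad, mae, sd_abs = paired_error_summary(a, b)
    return AgreementReport(
        bias=ba.bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        sd_diff=ba.sd_diff,
        icc=icc,
        icc_ci=ci,
        mad=mad,
        mae=mae,
        sd_abs_diff=sd_abs,
        n=int(np.asarray(a).size),
    )
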