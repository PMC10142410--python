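"""Method-comparison statistics: Bland–Altman agreement and regression.

Given paired volumes from a reference method (e.g. echocardiographic EDV)
and a test method (calculated EDV), this module computes the bias (mean of
reference − test differences), the sample SD of the differences, the limits
of agreement bias ± m·SD, the percentage error

    PE = 100 · m·SD(differences) / mean(reference),

and an ordinary-least-squares regression of test on reference.  Agreement
is flagged clinically acceptable when PE <= 30% (the Critchley–Critchley
criterion for cardiac-output method comparison).  The limits-of-agreement
multiplier m defaults to 2; 1.96 is available via the argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "PE_ACCEPTABLE_LIMIT",
    "bland_altman",
    "regression_summary",
    "format_report",
]

# Percentage-error acceptability cutoff (percent).
PE_ACCEPTABLE_LIMIT = 30.0


@dataclass(frozen=True)
class AgreementReport:
    """Bland–Altman and regression summary for paired volume series.

    All volume fields in ml; ``percentage_error`` in percent.  Regression
    fields are ``None`` when the reference series has no variance or fewer
    than 3 pairs.
    """

    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    percentage_error: float
    loa_multiplier: float
    acceptable: bool
    r_squared: Optional[float] = None
    slope: Optional[float] = None
    intercept: Optional[float] = None


def _as_finite_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def regression_summary(
    reference: Sequence[float], test: Sequence[float]
) -> tuple[float, float, float]:
    """OLS of test on reference: returns (r_squared, slope, intercept).

    ``r_squared`` is the squared Pearson correlation.  Requires at least 3
    pairs and nonzero variance in the reference series.
    """
    ref = _as_finite_array(reference, "reference")
    tst = _as_finite_array(test, "test")
    if ref.shape != tst.shape:
        raise ValueError(f"length mismatch: {ref.size} reference vs {tst.size} test")
    if ref.size < 3:
        raise ValueError(f"need at least 3 pairs for regression, got {ref.size}")
    if np.ptp(ref) == 0:
        raise ValueError("reference series has zero variance; regression undefined")
    fit = stats.linregress(ref, tst)
    return fit.rvalue**2, fit.slope, fit.intercept


def bland_altman(
    reference: Sequence[float],
    test: Sequence[float],
    loa_multiplier: float = 2.0,
    pe_limit: float = PE_ACCEPTABLE_LIMIT,
) -> AgreementReport:
    """Bland–Altman agreement of a test method against a reference.

    Differences are oriented reference − test, so a test method that reads
    high gives a negative bias.  The SD of differences uses the n−1
    denominator.  Raises on length mismatch, fewer than 2 pairs, or a zero
    reference mean (percentage error undefined).
    """
    ref = _as_finite_array(reference, "reference")
    tst = _as_finite_array(test, "test")
    if ref.shape != tst.shape:
        raise ValueError(f"length mismatch: {ref.size} reference vs {tst.size} test")
    if ref.size < 2:
        raise ValueError(f"need at least 2 pairs, got {ref.size}")
    mean_ref = float(np.mean(ref))
    if mean_ref == 0:
        raise ValueError("reference mean is zero: percentage error undefined")

    d = ref - tst
    bias = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    half_width = loa_multiplier * sd_diff
    pe = 100.0 * half_width / mean_ref

    r2 = slope = intercept = None
    if ref.size >= 3 and np.ptp(ref) > 0:
        r2, slope, intercept = regression_summary(ref, tst)

    return AgreementReport(
        n=int(ref.size),
        bias=bias,
        sd_diff=sd_diff,
        loa_lower=bias - half_width,
        loa_upper=bias + half_width,
        percentage_error=pe,
        loa_multiplier=loa_multiplier,
        acceptable=pe <= pe_limit,
        r_squared=r2,
        slope=slope,
        intercept=intercept,
    )


def format_report(report: AgreementReport) -> str:
    """Plain-text summary block of an agreement report."""
    lines = [
        f"n pairs             : {report.n}",
        f"bias (ref - test)   : {report.bias:.2f} ml",
        f"SD of differences   : {report.sd_diff:.2f} ml",
        f"limits of agreement : {report.loa_lower:.2f} to {report.loa_upper:.2f} ml"
        f" (bias ± {report.loa_multiplier:g}·SD)",
        f"percentage error    : {report.percentage_error:.1f} %",
        f"acceptable (PE<=30%): {'yes' if report.acceptable else 'no'}",
    ]
    if report.r_squared is not None:
        lines += [
            f"R^2                 : {report.r_squared:.3f}",
            f"slope               : {report.slope:.3f}",
            f"intercept           : {report.intercept:.2f} ml",
        ]
    return "\n".join(lines)


def plot_bland_altman(report: AgreementReport, reference, test, path):
    """Save a Bland–Altman scatter (mean vs difference) to ``path``.

    Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = np.asarray(reference, float)
    tst = np.asarray(test, float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((ref + tst) / 2, ref - tst, s=12, alpha=0.7)
    for y, style in ((report.bias, "-"), (report.loa_lower, "--"), (report.loa_upper, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=0.8)
    ax.set_xlabel("mean of methods (ml)")
    ax.set_ylabel("reference − test (ml)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
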