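"""Transcriptome-wide variability-change estimation.

For a pair of tumour groups, each gene contributes one summary statistic per
group (SD, CV, MAD or mean).  Regressing the test group's statistics on the
reference group's gives a slope beta whose departure from the equity model
(beta = 1, identical variability) measures the transcriptome-wide change:
``percent_change = (beta - 1) * 100``, positive when the test group is more
variable.  A low-order polynomial fit is reported as a linearity diagnostic.

Orientation is always recorded in the output: the test group (e.g. BRCA1 or
basal-like) is the response, the reference group (BRCAx or non-basal) the
predictor.  Estimation noise in the predictor attenuates the slope toward
zero (errors in variables); this is documented, not corrected, and shrinks
with per-group sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GlobalComparison",
    "fit_equity_regression",
    "percent_change_from_slope",
    "polynomial_diagnostic",
]


@dataclass(frozen=True)
class GlobalComparison:
    """One group pair x one statistic, compared against the equity model."""

    statistic_name: str
    test_group: str
    reference_group: str
    n_genes: int
    n_excluded: int
    beta: float
    beta_ci_low: float
    beta_ci_high: float
    intercept: float
    percent_change: float
    percent_ci_low: float
    percent_ci_high: float
    equity_p: float
    poly_coeffs: tuple = field(default=())


def percent_change_from_slope(beta: float) -> float:
    """Percent change in variability relative to the equity model.

    ``(beta - 1) * 100``: +22.8 means the test group's gene-wise statistics
    are on average 22.8% larger than the reference group's.
    """
    if not math.isfinite(beta):
        raise ValueError("slope must be finite")
    return (beta - 1.0) * 100.0


def fit_equity_regression(
    stats_test,
    stats_ref,
    include_intercept: bool = True,
    level: float = 0.95,
    statistic_name: str = "",
    test_group: str = "",
    reference_group: str = "",
    poly_degree: int = 2,
) -> GlobalComparison:
    """OLS of test-group gene statistics on reference-group gene statistics.

    Gene pairs where either statistic is undefined (NaN) are dropped and
    counted in ``n_excluded``.  The slope CI uses the normal quantile at
    ``level`` (gene counts are in the thousands) and ``equity_p`` is the
    two-sided Wald test of beta = 1.  Multiplying ``stats_test`` by c scales
    beta and its CI by c exactly.
    """
    x = np.asarray(stats_ref, dtype=float)
    y = np.asarray(stats_test, dtype=float)
    if x.shape != y.shape:
        raise ValueError("test and reference statistic lists differ in length")
    keep = np.isfinite(x) & np.isfinite(y)
    n_excluded = int((~keep).sum())
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 usable gene pairs, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("reference statistics are constant: slope undefined")

    if include_intercept:
        xm, ym = x.mean(), y.mean()
        sxx = ((x - xm) ** 2).sum()
        beta = ((x - xm) * (y - ym)).sum() / sxx
        intercept = ym - beta * xm
        resid = y - intercept - beta * x
        dof = n - 2
    else:
        sxx = (x**2).sum()
        beta = (x * y).sum() / sxx
        intercept = 0.0
        resid = y - beta * x
        dof = n - 1
    sigma2 = (resid**2).sum() / dof if dof > 0 else 0.0
    se = math.sqrt(sigma2 / sxx)
    zq = stats.norm.ppf(1 - (1 - level) / 2)
    lo, hi = beta - zq * se, beta + zq * se
    if se == 0:
        equity_p = 1.0 if beta == 1.0 else 0.0
    else:
        equity_p = float(2 * stats.norm.sf(abs(beta - 1.0) / se))
    poly = polynomial_diagnostic(y, x, degree=poly_degree) if n >= poly_degree + 2 else ()
    return GlobalComparison(
        statistic_name=statistic_name,
        test_group=test_group,
        reference_group=reference_group,
        n_genes=n,
        n_excluded=n_excluded,
        beta=float(beta),
        beta_ci_low=float(lo),
        beta_ci_high=float(hi),
        intercept=float(intercept),
        percent_change=percent_change_from_slope(beta),
        percent_ci_low=percent_change_from_slope(lo),
        percent_ci_high=percent_change_from_slope(hi),
        equity_p=equity_p,
        poly_coeffs=tuple(poly),
    )


def polynomial_diagnostic(stats_test, stats_ref, degree: int = 2) -> tuple:
    """Least-squares polynomial fit of test on reference statistics.

    Returns ``degree + 1`` coefficients, constant term first.  Diagnostic
    only: a near-zero high-order coefficient supports the linear model.
    """
    x = np.asarray(stats_ref, dtype=float)
    y = np.asarray(stats_test, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} usable pairs for degree {degree}, got {x.size}"
        )
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    return tuple(float(c) for c in coeffs)
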