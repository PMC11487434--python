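"""Agreement statistics between raters: mean differences, Bland–Altman
limits of agreement, and the two-way absolute-agreement intraclass
correlation coefficient.

The ICC is computed from the classical two-way ANOVA decomposition without
replication (rows = subjects, columns = raters):

* single-measures form (the default, the one that reproduces published
  two-rater tables for this pipeline)::

      ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

* average-measures form::

      ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

Confidence intervals follow the McGraw–Wong F-based construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import MeasurementMatrix

__all__ = [
    "AnovaDecomposition",
    "AgreementReport",
    "mean_difference",
    "bland_altman",
    "two_way_anova",
    "icc_absolute",
    "icc_confidence_interval",
    "agreement_report",
]


def _columns(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 paired measurements")
    return a, b


def _matrix(m) -> np.ndarray:
    values = m.values if isinstance(m, MeasurementMatrix) else np.asarray(m, dtype=float)
    if values.ndim != 2:
        raise ValueError("measurement matrix must be 2-D")
    if not np.isfinite(values).all():
        raise ValueError("measurement matrix has missing cells")
    s, r = values.shape
    if s < 2 or r < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    return values


@dataclass(frozen=True)
class AnovaDecomposition:
    """Mean squares of the two-way (subjects x raters) decomposition."""

    msr: float  # rows (subjects)
    msc: float  # columns (raters)
    mse: float  # residual
    n: int  # subjects
    k: int  # raters

    @property
    def total_ss(self) -> float:
        return (
            self.msr * (self.n - 1)
            + self.msc * (self.k - 1)
            + self.mse * (self.n - 1) * (self.k - 1)
        )


@dataclass
class AgreementReport:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_outside_loa: int
    means: np.ndarray = field(default=None, repr=False)
    diffs: np.ndarray = field(default=None, repr=False)
    icc_single: float | None = None
    icc_average: float | None = None
    icc_ci: tuple | None = None


def mean_difference(a, b) -> tuple[float, float]:
    """Mean and sample SD (n-1) of the paired differences a - b."""
    a, b = _columns(a, b)
    d = a - b
    return float(d.mean()), float(d.std(ddof=1))


def bland_altman(a, b, coverage: float = 1.96) -> AgreementReport:
    """Bland–Altman analysis: mean difference, limits of agreement
    (mean +/- coverage x SD), per-pair (mean, difference) coordinates, and
    the count of pairs outside the limits."""
    a, b = _columns(a, b)
    d = a - b
    md, sd = mean_difference(a, b)
    lo, hi = md - coverage * sd, md + coverage * sd
    outside = int(np.sum((d < lo) | (d > hi)))
    return AgreementReport(
        mean_diff=md,
        sd_diff=sd,
        loa_low=lo,
        loa_high=hi,
        n_outside_loa=outside,
        means=0.5 * (a + b),
        diffs=d,
    )


def two_way_anova(matrix) -> AnovaDecomposition:
    """Row/column/error mean squares of an S x R table (no replication)."""
    v = _matrix(matrix)
    n, k = v.shape
    grand = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sse = float(((v - row_means[:, None] - col_means[None, :] + grand) ** 2).sum())
    return AnovaDecomposition(
        msr=ssr / (n - 1), msc=ssc / (k - 1), mse=sse / ((n - 1) * (k - 1)), n=n, k=k
    )


def icc_absolute(matrix, form: str = "single") -> float:
    """Two-way absolute-agreement ICC of an S x R measurement table."""
    dec = two_way_anova(matrix)
    msr, msc, mse, n, k = dec.msr, dec.msc, dec.mse, dec.n, dec.k
    if msr == 0.0 and mse == 0.0:
        raise ValueError("degenerate table: no subject variance and no error variance")
    if form == "single":
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if form == "average":
        return (msr - mse) / (msr + (msc - mse) / n)
    raise ValueError("form must be 'single' or 'average'")


def icc_confidence_interval(matrix, form: str = "single", level: float = 0.95) -> tuple[float, float]:
    """McGraw–Wong F-based confidence interval for the absolute-agreement
    ICC; degenerate perfectly-agreeing tables clamp to [1, 1]."""
    dec = two_way_anova(matrix)
    msr, msc, mse, n, k = dec.msr, dec.msc, dec.mse, dec.n, dec.k
    point = icc_absolute(matrix, form=form)
    if mse == 0.0 and msc == 0.0:
        return (1.0, 1.0)
    alpha = 1.0 - level
    r = icc_absolute(matrix, form="single")
    a = k * r / (n * (1.0 - r))
    b = 1.0 + k * r * (n - 1.0) / (n * (1.0 - r))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    )
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    if form == "average":
        # Spearman-Brown step-up of the single-measures bounds
        lower = k * lower / (1.0 + (k - 1.0) * lower)
        upper = k * upper / (1.0 + (k - 1.0) * upper)
    lower = min(lower, point)
    upper = max(upper, point)
    return (float(lower), float(upper))


def agreement_report(a, b, form: str = "single", coverage: float = 1.96) -> AgreementReport:
    """Combined Bland–Altman + ICC report for one rater pair."""
    rep = bland_altman(a, b, coverage=coverage)
    a, b = _columns(a, b)
    table = np.column_stack([a, b])
    rep.icc_single = float(icc_absolute(table, form="single"))
    rep.icc_average = float(icc_absolute(table, form="average"))
    rep.icc_ci = icc_confidence_interval(table, form=form)
    return rep
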