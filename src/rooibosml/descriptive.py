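"""Summary statistics, pairwise correlations, and 95% confidence ellipses.

The correlation report mirrors the study's table layout: each pair of assays
within one solvent and one fermentation class gets a Pearson r, a signed
squared correlation sign(r)·r², a classical standard error of r, and a
two-sided p-value from the exact t reference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .data import ASSAYS, LABELS, SOLVENTS, AssayDataset


@dataclass(frozen=True)
class SummaryRow:
    label: str
    solvent: str
    assay: str
    min: float
    max: float
    median: float
    mean: float


@dataclass(frozen=True)
class CorrelationEstimate:
    """Pearson correlation with uncertainty for one assay pair.

    ``sigma`` is the classical large-sample standard error of r,
    sqrt((1−r²)/(n−2)); ``p_value`` is the two-sided test of ρ = 0 based on
    t = r·sqrt((n−2)/(1−r²)) with n−2 degrees of freedom.
    """

    var1: str
    var2: str
    label: str
    solvent: str
    r: float
    signed_r2: float
    sigma: float
    p_value: float
    n: int


@dataclass(frozen=True)
class ConfidenceEllipse:
    """Level set of a bivariate Gaussian's Mahalanobis quadratic form.

    Encloses the stated probability mass of N(center, covariance); the
    boundary is (x−c)ᵀ Σ⁻¹ (x−c) = chi2_quantile with the χ²₂ quantile at
    ``level``.
    """

    center: np.ndarray
    covariance: np.ndarray
    level: float = 0.95
    chi2_quantile: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "covariance", np.asarray(self.covariance, dtype=float))
        if self.center.shape != (2,):
            raise ValueError("center must be a 2-vector")
        cov = self.covariance
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be 2x2 symmetric")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("covariance must be positive-definite")
        if not 0 < self.level < 1:
            raise ValueError("level must be a probability in (0, 1)")
        if self.chi2_quantile is None:
            object.__setattr__(
                self, "chi2_quantile", float(stats.chi2.ppf(self.level, df=2))
            )


def summarize(dataset: AssayDataset) -> list[SummaryRow]:
    """12 rows: min/max/median/mean per (label × solvent × assay) group."""
    counts = dataset.label_counts()
    for label in LABELS:
        if counts.get(label, 0) == 0:
            raise ValueError(f"dataset contains no {label} samples")
    rows = []
    for label in LABELS:
        idx = [i for i, s in enumerate(dataset.samples) if s.label == label]
        group = dataset.subset(idx)
        for solvent in SOLVENTS:
            for assay in ASSAYS:
                v = group.column(assay, solvent)
                rows.append(
                    SummaryRow(
                        label=label,
                        solvent=solvent,
                        assay=assay,
                        min=float(v.min()),
                        max=float(v.max()),
                        median=float(np.median(v)),
                        mean=float(v.mean()),
                    )
                )
    return rows


def summary_frame(dataset: AssayDataset) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in summarize(dataset)])


def pairwise_correlation(
    x: np.ndarray,
    y: np.ndarray,
    *,
    var1: str = "x",
    var2: str = "y",
    label: str = "",
    solvent: str = "",
) -> CorrelationEstimate:
    """Pearson correlation between two vectors with SE and p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need n >= 4 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    sigma = float(np.sqrt(max(1.0 - r * r, 0.0) / (n - 2)))
    return CorrelationEstimate(
        var1=var1,
        var2=var2,
        label=label,
        solvent=solvent,
        r=r,
        signed_r2=float(np.sign(r) * r * r),
        sigma=sigma,
        p_value=float(res.pvalue),
        n=n,
    )


def correlation_table(dataset: AssayDataset) -> pd.DataFrame:
    """All 12 within-solvent assay-pair correlations, per class and solvent."""
    rows = []
    for label in LABELS:
        idx = [i for i, s in enumerate(dataset.samples) if s.label == label]
        group = dataset.subset(idx)
        for solvent in SOLVENTS:
            for a1, a2 in combinations(ASSAYS, 2):
                est = pairwise_correlation(
                    group.column(a1, solvent),
                    group.column(a2, solvent),
                    var1=a1,
                    var2=a2,
                    label=label,
                    solvent=solvent,
                )
                rows.append(vars(est))
    return pd.DataFrame(rows)


def confidence_ellipse(points: np.ndarray, level: float = 0.95) -> ConfidenceEllipse:
    """Ellipse from the sample mean and sample covariance (divisor n−1)."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an n x 2 matrix")
    if points.shape[0] < 3:
        raise ValueError("need at least 3 points")
    center = points.mean(axis=0)
    cov = np.cov(points, rowvar=False, ddof=1)
    if np.linalg.eigvalsh(cov).min() <= 1e-12 * max(1.0, np.trace(cov)):
        raise ValueError("degenerate (rank-deficient) scatter")
    return ConfidenceEllipse(center=center, covariance=cov, level=level)


def ellipse_contains(ellipse: ConfidenceEllipse, point: np.ndarray) -> bool:
    """True iff the point's quadratic form is within the χ²₂ threshold.

    Boundary points count as contained.
    """
    d = np.asarray(point, dtype=float) - ellipse.center
    q = float(d @ np.linalg.solve(ellipse.covariance, d))
    return q <= ellipse.chi2_quantile


def ellipse_contains_many(ellipse: ConfidenceEllipse, points: np.ndarray) -> np.ndarray:
    """Vectorized containment verdicts for an n×2 point array."""
    d = np.asarray(points, dtype=float) - ellipse.center
    q = np.einsum("ij,ij->i", d, np.linalg.solve(ellipse.covariance, d.T).T)
    return q <= ellipse.chi2_quantile
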