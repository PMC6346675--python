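"""Cohort-level comparisons: PCA summaries, t tests, and diversity regressions.

These are the closing analyses of the pipeline: a PCA of the genotype
(dosage) covariance matrix summarizing structure among individuals, a paired
t test contrasting expected and observed heterozygosity across hunt units, a
Welch t test contrasting diversity between remnant and reintroduced herds,
and a simple OLS of diversity on the number of translocation source units.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .formats import DosageMatrix

__all__ = ["TestResult", "PCASummary", "pca_summary", "paired_t", "welch_t",
           "ols_diversity"]


@dataclasses.dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    label: str


@dataclasses.dataclass
class PCASummary:
    scores: np.ndarray            # individuals x components
    percent_variance: np.ndarray  # per component
    degenerate: bool = False


def pca_summary(m: DosageMatrix | np.ndarray) -> PCASummary:
    """PCA of the individual-by-individual genotype covariance matrix.

    Columns (loci) are centered, no scaling (covariance, not correlation);
    missing entries are replaced by the locus mean before centering.  Scores
    are the eigenvector coordinates scaled by the singular values; percent
    variance is each eigenvalue's share of the trace.
    """
    dosage = m.dosage if isinstance(m, DosageMatrix) else np.asarray(m, float)
    n = dosage.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 individuals")
    col_mean = np.nanmean(dosage, axis=0)
    filled = np.where(np.isfinite(dosage), dosage, col_mean)
    x = filled - col_mean
    cov = x @ x.T / max(x.shape[1] - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    total = vals.sum()
    if total <= 0:
        return PCASummary(np.zeros((n, n)), np.zeros(n), degenerate=True)
    scores = vecs * np.sqrt(vals)
    return PCASummary(scores, 100.0 * vals / total)


def paired_t(x, y, alternative: str = "two-sided") -> TestResult:
    """Paired t test of x against y (df = n - 1)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired vectors must have equal length >= 2")
    if np.var(x - y, ddof=1) == 0:
        raise ValueError("zero variance of paired differences — t undefined")
    res = stats.ttest_rel(x, y, alternative=alternative)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue),
                      f"paired t ({alternative})")


def welch_t(group_a, group_b, alternative: str = "two-sided") -> TestResult:
    """Welch's unequal-variance t test with Welch–Satterthwaite df."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue),
                      f"Welch t ({alternative})")


def ols_diversity(table: pd.DataFrame, response: str = "h_e",
                  predictor: str = "n_sources") -> dict:
    """Simple OLS of a diversity column on a herd covariate.

    Returns slope, intercept, R², F (with 1 and n-2 df), and the two-tailed
    p-value.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 units for the regression")
    x = table[predictor].to_numpy(float)
    y = table[response].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {predictor!r} is constant")
    lr = stats.linregress(x, y)
    n = x.size
    r2 = lr.rvalue ** 2
    f = np.inf if r2 >= 1.0 else r2 / (1.0 - r2) * (n - 2)
    return {
        "slope": float(lr.slope),
        "intercept": float(lr.intercept),
        "r_squared": float(r2),
        "f": float(f),
        "df": (1, n - 2),
        "p_value": float(lr.pvalue),
        "response": response,
        "predictor": predictor,
    }
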