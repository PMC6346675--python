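"""Diversity and differentiation statistics from posterior dosages.

All statistics work directly on the 0–2 dosage scale.  Allele frequencies
are half the mean dosage over non-missing individuals; expected
heterozygosity uses the Hardy–Weinberg expectation 2p(1-p); observed
heterozygosity scores an (individual, locus) entry as heterozygous when its
dosage lies in a window around 1 (a perfectly known heterozygote has dosage
exactly 1); heterozygote deficiency is F_IS = 1 - H_O/H_E.  Differentiation
uses Hudson's F_ST with the finite-sample correction, combined across loci
as a ratio of sums.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .formats import DosageMatrix

__all__ = [
    "DiversityRecord",
    "PairwiseMatrix",
    "MIN_INDIVIDUALS",
    "HET_WINDOW",
    "unit_allele_freqs",
    "expected_het",
    "observed_het",
    "fis",
    "hudson_fst",
    "fst_matrix",
    "fst_summary",
    "diversity_table",
    "diversity_frame",
]

#: Reporting threshold: statistics are computed only for units with at least
#: this many genotyped individuals.
MIN_INDIVIDUALS = 5

#: Dosage window scored as heterozygous (inclusive endpoints).
HET_WINDOW = (0.9, 1.1)


@dataclasses.dataclass
class DiversityRecord:
    unit: str
    n: int
    h_e: float
    h_o: float
    f_is: float


@dataclasses.dataclass
class PairwiseMatrix:
    """Symmetric unit-by-unit matrix (F_ST or kilometres)."""

    units: list
    values: np.ndarray
    kind: str = "fst"

    def __post_init__(self):
        self.units = list(self.units)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.units)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match unit list")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(len(self.units), k=-1)
        return self.values[i, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.units, columns=self.units)

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.units.index(a), self.units.index(b)])


def _unit_rows(m: DosageMatrix, unit: str) -> np.ndarray:
    rows = np.flatnonzero(m.units == unit)
    if rows.size == 0:
        raise ValueError(f"unit {unit!r} has no individuals in the matrix")
    return rows


def unit_allele_freqs(m: DosageMatrix, units=None) -> pd.DataFrame:
    """Per-unit, per-locus alternate-allele frequencies (mean dosage / 2)."""
    if units is None:
        units = sorted(set(m.units))
    out = {}
    for u in units:
        rows = _unit_rows(m, u)
        with np.errstate(invalid="ignore"):
            out[u] = np.nanmean(m.dosage[rows], axis=0) / 2.0
    return pd.DataFrame(out, index=m.locus_ids).T


def _freqs_and_counts(m: DosageMatrix, unit: str):
    rows = _unit_rows(m, unit)
    d = m.dosage[rows]
    n_ind = np.isfinite(d).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=0) / 2.0
    return p, 2 * n_ind  # allele copies


def expected_het(m: DosageMatrix, unit: str, min_n: int = MIN_INDIVIDUALS,
                 sample_size_correction: bool = False) -> float:
    """Mean Hardy–Weinberg expected heterozygosity, 2p(1-p) averaged over loci.

    With ``sample_size_correction`` the per-locus value is scaled by
    n/(n-1) (unbiased small-sample form); the default is the uncorrected
    expectation.
    """
    rows = _unit_rows(m, unit)
    if rows.size < min_n:
        raise ValueError(
            f"unit {unit!r} has {rows.size} genotyped individuals; need >= {min_n}"
        )
    p, copies = _freqs_and_counts(m, unit)
    ok = np.isfinite(p) & (copies > (2 if sample_size_correction else 0))
    h = 2.0 * p[ok] * (1.0 - p[ok])
    if sample_size_correction:
        n = copies[ok]
        h = h * n / (n - 1)
    return float(h.mean())


def observed_het(m: DosageMatrix, unit: str, min_n: int = MIN_INDIVIDUALS,
                 window: tuple = HET_WINDOW) -> float:
    """Fraction of non-missing entries with dosage in the heterozygote window,
    averaged over loci."""
    rows = _unit_rows(m, unit)
    if rows.size < min_n:
        raise ValueError(
            f"unit {unit!r} has {rows.size} genotyped individuals; need >= {min_n}"
        )
    d = m.dosage[rows]
    ok = np.isfinite(d)
    het = ok & (d >= window[0]) & (d <= window[1])
    n_ok = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        per_locus = np.where(n_ok > 0, het.sum(axis=0) / np.maximum(n_ok, 1), np.nan)
    return float(np.nanmean(per_locus))


def fis(h_e: float, h_o: float) -> float:
    """Heterozygote deficiency F_IS = 1 - H_O / H_E (nan when H_E = 0)."""
    if h_e == 0:
        return float("nan")
    return 1.0 - h_o / h_e


def hudson_fst(m: DosageMatrix, unit_a: str, unit_b: str,
               min_n: int = MIN_INDIVIDUALS, ratio_of_sums: bool = True) -> float:
    """Hudson's F_ST between two units, combined across loci.

    Per locus, with sample frequencies p1, p2 and allele-copy counts n1, n2:

        numerator   = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        denominator = p1(1-p2) + p2(1-p1)

    The default multi-locus combination is the ratio of sums (sum of
    numerators over sum of denominators); ``ratio_of_sums=False`` averages
    the per-locus ratios instead.  Loci with a zero denominator (monomorphic
    for the same allele in both units) are skipped.  Negative per-locus
    numerators are retained so the estimator stays unbiased.
    """
    for u in (unit_a, unit_b):
        rows = _unit_rows(m, u)
        if rows.size < min_n:
            raise ValueError(
                f"unit {u!r} has {rows.size} genotyped individuals; need >= {min_n}"
            )
    p1, n1 = _freqs_and_counts(m, unit_a)
    p2, n2 = _freqs_and_counts(m, unit_b)
    ok = np.isfinite(p1) & np.isfinite(p2) & (n1 > 1) & (n2 > 1)
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    if not np.any(keep):
        return float("nan")
    if ratio_of_sums:
        return float(num[keep].sum() / den[keep].sum())
    return float(np.mean(num[keep] / den[keep]))


def fst_matrix(m: DosageMatrix, units=None, min_n: int = MIN_INDIVIDUALS) -> PairwiseMatrix:
    """All pairwise Hudson F_ST values among the requested units."""
    if units is None:
        labels, counts = np.unique(m.units, return_counts=True)
        units = [u for u, c in zip(labels, counts) if c >= min_n]
    units = list(units)
    n = len(units)
    vals = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        f = hudson_fst(m, units[i], units[j], min_n=min_n)
        vals[i, j] = vals[j, i] = f
    return PairwiseMatrix(units, vals, kind="fst")


def fst_summary(pm: PairwiseMatrix) -> dict:
    """Mean / sd / extremes of the off-diagonal F_ST distribution."""
    tri = pm.lower_triangle()
    i, j = np.tril_indices(len(pm.units), k=-1)
    lo, hi = np.nanargmin(tri), np.nanargmax(tri)
    return {
        "n_pairs": tri.size,
        "mean": float(np.nanmean(tri)),
        "sd": float(np.nanstd(tri, ddof=1)),
        "min": float(tri[lo]),
        "min_pair": (pm.units[i[lo]], pm.units[j[lo]]),
        "max": float(tri[hi]),
        "max_pair": (pm.units[i[hi]], pm.units[j[hi]]),
    }


def diversity_table(m: DosageMatrix, units=None, min_n: int = MIN_INDIVIDUALS,
                    **kwargs) -> list:
    """Per-unit diversity records (N, H_E, H_O, F_IS) for qualifying units."""
    if units is None:
        labels, counts = np.unique(m.units, return_counts=True)
        units = [u for u, c in zip(labels, counts) if c >= min_n]
    records = []
    for u in units:
        n = int((m.units == u).sum())
        he = expected_het(m, u, min_n=min_n, **kwargs)
        ho = observed_het(m, u, min_n=min_n)
        records.append(DiversityRecord(u, n, he, ho, fis(he, ho)))
    return records


def diversity_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [{"unit": r.unit, "n": r.n, "h_e": r.h_e, "h_o": r.h_o, "f_is": r.f_is}
         for r in records]
    )
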