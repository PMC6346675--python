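"""Post-calling quality filters for GBS cohorts.

The filter chain mirrors the standard reduced-representation workflow:
one variant per contig, biallelic sites only, a strict minor-allele-frequency
floor, a site presence rule, then a final round removing high-missingness
individuals and high-coverage loci (putative paralog collapses).  Every
removal is recorded, in application order, in a :class:`FilterReport`.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .formats import CohortGL

__all__ = ["FilterConfig", "FilterReport", "apply_filters", "summarize_reads"]


@dataclasses.dataclass
class FilterConfig:
    """Thresholds for the filter chain.

    ``maf_min`` is exclusive (a site is kept only if maf > maf_min);
    ``presence_min`` is inclusive (kept if the fraction of individuals with
    at least one read is >= presence_min); ``indiv_missing_max`` is exclusive
    (an individual is removed only if its missing fraction is strictly
    greater); ``mean_cov_max`` is exclusive (a locus is removed only if its
    mean coverage is strictly greater).
    """

    maf_min: float = 0.05
    presence_min: float = 0.60
    indiv_missing_max: float = 0.50
    mean_cov_max: float = 10.0
    one_per_contig: bool = True
    biallelic_only: bool = True

    def __post_init__(self):
        for name in ("maf_min", "presence_min", "indiv_missing_max"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.maf_min >= 0.5:
            raise ValueError("maf_min must be < 0.5")
        if self.mean_cov_max < 0:
            raise ValueError("mean_cov_max must be non-negative")


@dataclasses.dataclass
class FilterReport:
    """Per-rule removal accounting, in application order."""

    n_individuals_in: int
    n_loci_in: int
    steps: list = dataclasses.field(default_factory=list)
    n_individuals_out: int = 0
    n_loci_out: int = 0

    def record(self, rule: str, axis: str, removed_ids) -> None:
        self.steps.append(
            {"rule": rule, "axis": axis, "n_removed": len(removed_ids),
             "removed_ids": list(removed_ids)}
        )

    def removed(self, axis: str) -> int:
        return sum(s["n_removed"] for s in self.steps if s["axis"] == axis)

    def conserved(self) -> bool:
        """removed + retained == input, on both axes."""
        return (
            self.n_loci_in == self.removed("locus") + self.n_loci_out
            and self.n_individuals_in
            == self.removed("individual") + self.n_individuals_out
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"rule": s["rule"], "axis": s["axis"], "n_removed": s["n_removed"]}
             for s in self.steps]
        )


def _alt_allele_counts(cohort: CohortGL):
    """Alt-allele and called-copy counts per locus from best-guess genotypes."""
    g = cohort.best_genotypes().astype(float)
    has_data = g >= 0
    alt = np.where(has_data, g, 0.0).sum(axis=0)
    copies = 2.0 * has_data.sum(axis=0)
    return alt, copies


def _maf(cohort: CohortGL) -> np.ndarray:
    alt, copies = _alt_allele_counts(cohort)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(copies > 0, alt / np.where(copies > 0, copies, 1), 0.0)
    return np.minimum(f, 1.0 - f)


def apply_filters(cohort: CohortGL, config: FilterConfig | None = None):
    """Apply the full filter chain, returning (filtered cohort, report).

    Order: (1) one variant per contig, (2) biallelic only (structurally
    guaranteed for likelihood-triple input, recorded as zero removals),
    (3) minor allele frequency, (4) site presence; then the final round:
    (5) individual missingness, (6) locus mean-coverage cap (recomputed on
    the retained individuals).

    Raises
    ------
    ValueError
        If every locus (or every individual) is removed.
    """
    if config is None:
        config = FilterConfig()
    if cohort.n_individuals == 0 or cohort.n_loci == 0:
        raise ValueError("cannot filter an empty cohort")
    report = FilterReport(cohort.n_individuals, cohort.n_loci)
    cur = cohort

    # (1) one variant per contig: keep the highest minor-allele-count site,
    # ties broken by lowest position
    if config.one_per_contig:
        alt, copies = _alt_allele_counts(cur)
        mac = np.minimum(alt, copies - alt)
        pos = np.array([int(l.rsplit(":", 1)[1]) for l in cur.locus_ids])
        keep = np.zeros(cur.n_loci, dtype=bool)
        contigs = cur.contigs
        order = np.lexsort((pos, -mac, contigs))  # by contig, mac desc, pos asc
        seen = set()
        for j in order:
            if contigs[j] not in seen:
                seen.add(contigs[j])
                keep[j] = True
        removed = [cur.locus_ids[j] for j in np.flatnonzero(~keep)]
        report.record("one_per_contig", "locus", removed)
        cur = cur.subset(loci=keep)

    # (2) biallelic only — likelihood triples encode exactly two alleles, so
    # nothing can be removed here; the step is recorded for auditability
    if config.biallelic_only:
        report.record("biallelic_only", "locus", [])

    # (3) minor allele frequency (strict: keep only maf > maf_min)
    maf = _maf(cur)
    keep = maf > config.maf_min
    report.record("maf", "locus", [cur.locus_ids[j] for j in np.flatnonzero(~keep)])
    cur = cur.subset(loci=keep)

    # (4) site presence: fraction of individuals with >= 1 read
    presence = (cur.depth > 0).mean(axis=0)
    keep = presence >= config.presence_min
    report.record("presence", "locus", [cur.locus_ids[j] for j in np.flatnonzero(~keep)])
    cur = cur.subset(loci=keep)
    if cur.n_loci == 0:
        raise ValueError("all loci removed by site filters — empty result")

    # (5) individual missingness (strict: removed only if > indiv_missing_max)
    missing = (cur.depth == 0).mean(axis=1)
    keep_ind = missing <= config.indiv_missing_max
    report.record(
        "individual_missingness", "individual",
        [cur.individual_ids[i] for i in np.flatnonzero(~keep_ind)],
    )
    cur = cur.subset(individuals=keep_ind)
    if cur.n_individuals == 0:
        raise ValueError("all individuals removed — empty result")

    # (6) mean-coverage cap, recomputed on the retained individuals
    mean_cov = cur.depth.mean(axis=0)
    keep = mean_cov <= config.mean_cov_max
    report.record("mean_coverage", "locus", [cur.locus_ids[j] for j in np.flatnonzero(~keep)])
    cur = cur.subset(loci=keep)
    if cur.n_loci == 0:
        raise ValueError("all loci removed by coverage cap — empty result")

    report.n_individuals_out = cur.n_individuals
    report.n_loci_out = cur.n_loci
    return cur, report


def summarize_reads(cohort: CohortGL):
    """Depth summaries per individual and per locus.

    Returns
    -------
    (per_individual, per_locus) : pair of DataFrames
        Columns: ``mean_depth, sd_depth, missing_fraction``.
    """
    d = cohort.depth.astype(float)
    per_ind = pd.DataFrame(
        {
            "mean_depth": d.mean(axis=1),
            "sd_depth": d.std(axis=1),
            "missing_fraction": (d == 0).mean(axis=1),
        },
        index=pd.Index(cohort.individual_ids, name="individual"),
    )
    per_locus = pd.DataFrame(
        {
            "mean_depth": d.mean(axis=0),
            "sd_depth": d.std(axis=0),
            "missing_fraction": (d == 0).mean(axis=0),
        },
        index=pd.Index(cohort.locus_ids, name="locus"),
    )
    return per_ind, per_locus
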