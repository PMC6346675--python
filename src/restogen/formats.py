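"""Shared data model and file formats for the translocation-genomics pipeline.

The pipeline's in-memory objects are deliberately simple: genotype
likelihoods and read depths live in a :class:`CohortGL`, posterior mean
genotypes ("dosages", on a 0–2 scale) in a :class:`DosageMatrix`, and herd
metadata / translocation records in validated :class:`pandas.DataFrame`
tables.  Everything on disk is plain delimited text except the genotype
likelihoods, which can additionally be read from a VCF carrying PL or GL
annotations.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortGL",
    "DosageMatrix",
    "HERD_TABLE_COLUMNS",
    "LEDGER_COLUMNS",
    "VALID_STATUS",
    "canonical_unit",
    "read_cohort_vcf",
    "write_cohort_vcf",
    "read_unit_map",
    "read_dosage_matrix",
    "write_dosage_matrix",
    "read_herd_table",
    "write_herd_table",
    "read_ledger",
    "write_ledger",
]

#: Hunt units whose herds move freely between contiguous ranges are merged
#: under a single label (the Black and Muddy Mountains share one population).
UNIT_MERGES = {"267": "268"}

VALID_STATUS = ("remnant", "reintroduced", "pioneering")

HERD_TABLE_COLUMNS = ("unit", "desert", "status", "n_sources", "lat", "lon")
LEDGER_COLUMNS = ("source", "destination", "year", "count")

#: Written dosage matrices carry this many decimals; round-trips are exact
#: at this precision.
DOSAGE_DECIMALS = 6


def canonical_unit(label: str) -> str:
    """Normalize a hunt-unit label, applying population merges."""
    label = str(label).strip()
    return UNIT_MERGES.get(label, label)


@dataclasses.dataclass
class CohortGL:
    """Genotype likelihoods for a cohort of individuals at biallelic loci.

    Parameters
    ----------
    individual_ids : list of str
        Sample labels, one per row of ``gl``.
    locus_ids : list of str
        ``contig:position`` labels (1-based positions), one per column.
    unit_of : dict
        Maps each individual to its hunt-unit label.
    gl : ndarray, shape (n_individuals, n_loci, 3)
        Likelihoods of the read data under genotypes 0, 1, 2 (count of the
        non-reference allele), on the probability scale.  Triples may be
        unnormalized; they are non-negative, and a missing observation
        (depth 0) carries a flat (uninformative) triple.
    depth : ndarray, shape (n_individuals, n_loci)
        Read count per individual per locus; 0 encodes missing.
    """

    individual_ids: list
    locus_ids: list
    unit_of: dict
    gl: np.ndarray
    depth: np.ndarray

    def __post_init__(self):
        self.individual_ids = list(self.individual_ids)
        self.locus_ids = list(self.locus_ids)
        self.gl = np.asarray(self.gl, dtype=float)
        self.depth = np.asarray(self.depth)
        n, l = len(self.individual_ids), len(self.locus_ids)
        if self.gl.shape != (n, l, 3):
            raise ValueError(
                f"gl shape {self.gl.shape} does not match ({n}, {l}, 3)"
            )
        if self.depth.shape != (n, l):
            raise ValueError(
                f"depth shape {self.depth.shape} does not match ({n}, {l})"
            )
        if np.any(self.gl < 0):
            raise ValueError("genotype likelihoods must be non-negative")
        if np.any(self.depth < 0):
            raise ValueError("read depths must be non-negative")
        missing = [s for s in self.individual_ids if s not in self.unit_of]
        if missing:
            raise ValueError(
                "individuals missing from unit assignment: " + ", ".join(map(str, missing))
            )

    # -- basic geometry ------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def units(self) -> np.ndarray:
        """Per-individual hunt-unit labels, aligned with ``individual_ids``."""
        return np.array([self.unit_of[s] for s in self.individual_ids])

    def contig_of(self, locus_id: str) -> str:
        return locus_id.rsplit(":", 1)[0]

    @property
    def contigs(self) -> np.ndarray:
        return np.array([self.contig_of(l) for l in self.locus_ids])

    def subset(self, individuals=None, loci=None) -> "CohortGL":
        """Return a new cohort restricted to boolean/integer index arrays."""
        ii = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        if ii.dtype == bool:
            ii = np.flatnonzero(ii)
        ll = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        if ll.dtype == bool:
            ll = np.flatnonzero(ll)
        ids = [self.individual_ids[i] for i in ii]
        return CohortGL(
            individual_ids=ids,
            locus_ids=[self.locus_ids[j] for j in ll],
            unit_of={s: self.unit_of[s] for s in ids},
            gl=self.gl[np.ix_(ii, ll)],
            depth=self.depth[np.ix_(ii, ll)],
        )

    # -- point summaries -----------------------------------------------

    def normalized_gl(self) -> np.ndarray:
        """Likelihood triples rescaled to sum to one per (individual, locus)."""
        tot = self.gl.sum(axis=2, keepdims=True)
        out = np.where(tot > 0, self.gl / np.where(tot > 0, tot, 1.0), 1.0 / 3.0)
        return out

    def point_dosage(self) -> np.ndarray:
        """Likelihood-weighted mean genotype (flat genotype prior), in [0, 2]."""
        p = self.normalized_gl()
        return p[:, :, 1] + 2.0 * p[:, :, 2]

    def best_genotypes(self) -> np.ndarray:
        """Most-supported genotype per entry; ties resolved toward the
        heterozygote; -1 where depth is 0 (no data)."""
        p = self.normalized_gl()
        # bias the heterozygote by the smallest representable margin so that
        # exact ties go to genotype 1
        tie = np.zeros(3)
        tie[1] = 1e-12
        g = np.argmax(p + tie, axis=2).astype(np.int8)
        g[self.depth == 0] = -1
        return g


@dataclasses.dataclass
class DosageMatrix:
    """Posterior mean genotypes (0–2 scale) per individual per locus.

    A perfectly known heterozygote has dosage exactly 1.  Missing entries are
    ``nan`` and are never imputed.
    """

    individual_ids: list
    locus_ids: list
    unit_of: dict
    dosage: np.ndarray

    def __post_init__(self):
        self.individual_ids = list(self.individual_ids)
        self.locus_ids = list(self.locus_ids)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, l = len(self.individual_ids), len(self.locus_ids)
        if self.dosage.shape != (n, l):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match ({n}, {l})"
            )
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            bad = np.argwhere(
                np.isfinite(self.dosage) & ((self.dosage < 0) | (self.dosage > 2))
            )[0]
            raise ValueError(
                f"dosage out of [0, 2] at individual {self.individual_ids[bad[0]]}, "
                f"locus {self.locus_ids[bad[1]]}"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def units(self) -> np.ndarray:
        return np.array([self.unit_of.get(s, "?") for s in self.individual_ids])

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.dosage)

    def subset_units(self, units: Sequence[str]) -> "DosageMatrix":
        keep = np.isin(self.units, list(units))
        ids = [s for s, k in zip(self.individual_ids, keep) if k]
        return DosageMatrix(
            individual_ids=ids,
            locus_ids=self.locus_ids,
            unit_of={s: self.unit_of.get(s, "?") for s in ids},
            dosage=self.dosage[keep],
        )

    @staticmethod
    def from_posterior(post: np.ndarray, individual_ids, locus_ids, unit_of) -> "DosageMatrix":
        """Collapse a 3-vector genotype posterior (N, L, 3) to mean dosage."""
        post = np.asarray(post, dtype=float)
        tot = post.sum(axis=2)
        dos = (post[:, :, 1] + 2.0 * post[:, :, 2]) / np.where(tot > 0, tot, np.nan)
        return DosageMatrix(individual_ids, locus_ids, unit_of, dos)


# ----------------------------------------------------------------------
# VCF input
# ----------------------------------------------------------------------

def read_cohort_vcf(path, unit_map: Mapping[str, str]) -> CohortGL:
    """Read genotype likelihoods from a VCF with per-sample PL or GL fields.

    PL values are phred-scaled likelihoods and convert as ``10**(-PL/10)``;
    GL values are log10 likelihoods and convert as ``10**GL``.  Per-sample
    depth is taken from the DP format field; entries with depth 0 (or with
    missing likelihoods) carry a flat triple.

    Raises
    ------
    ValueError
        If a record is not biallelic, if no likelihood annotation is
        present, or if a sample is absent from ``unit_map``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in unit_map]
    if unknown:
        raise ValueError(
            "samples absent from unit map: " + ", ".join(unknown)
        )

    gl_rows, depth_rows, locus_ids = [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} — split before loading"
            )
        locus_ids.append(f"{rec.CHROM}:{rec.POS}")

        def _fmt(tag):
            try:
                return rec.format(tag)
            except KeyError:
                return None

        pl = _fmt("PL")
        if pl is not None:
            pl = np.asarray(pl, dtype=float)
            probs = np.power(10.0, -np.clip(pl, 0, 760) / 10.0)
        else:
            gl10 = _fmt("GL")
            if gl10 is None:
                raise ValueError(
                    f"record {rec.CHROM}:{rec.POS} has neither PL nor GL"
                )
            gl10 = np.asarray(gl10, dtype=float)
            probs = np.power(10.0, np.clip(gl10, -760, 0))
        probs = np.where(np.isfinite(probs), probs, 0.0)
        dp = _fmt("DP")
        if dp is None:
            dp = np.where(probs.sum(axis=1) > 0, 1, 0)
        else:
            dp = np.clip(np.asarray(dp, dtype=float).reshape(-1), 0, None)
            dp = np.where(np.isfinite(dp), dp, 0).astype(int)
        flat = dp == 0
        probs[flat] = 1.0
        gl_rows.append(probs)
        depth_rows.append(dp)

    gl = np.stack(gl_rows, axis=1) if gl_rows else np.empty((len(samples), 0, 3))
    depth = np.stack(depth_rows, axis=1) if depth_rows else np.empty((len(samples), 0), int)
    units = {s: canonical_unit(unit_map[s]) for s in samples}
    return CohortGL(samples, locus_ids, units, gl, depth)


def write_cohort_vcf(cohort: CohortGL, path) -> None:
    """Write a cohort as an uncompressed VCF with GL (log10) and DP fields.

    Alleles are written as placeholder A/G (the pipeline is agnostic to the
    actual bases); likelihood triples are normalized and stored as log10
    values, so ``read_cohort_vcf(write_cohort_vcf(c))`` preserves the
    normalized triples to the printed precision.
    """
    gl_norm = cohort.normalized_gl()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GL,Number=G,Type=Float,Description='
                 '"Log10 genotype likelihoods">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, cohort.individual_ids)) + "\n")
        logs = np.log10(np.clip(gl_norm, 1e-300, None))
        for j, locus in enumerate(cohort.locus_ids):
            contig, pos = locus.rsplit(":", 1)
            cells = [
                f"{logs[i, j, 0]:.4f},{logs[i, j, 1]:.4f},{logs[i, j, 2]:.4f}"
                f":{int(cohort.depth[i, j])}"
                for i in range(cohort.n_individuals)
            ]
            fh.write(f"{contig}\t{pos}\t.\tA\tG\t.\tPASS\t.\tGL:DP\t"
                     + "\t".join(cells) + "\n")


def read_unit_map(path, sep: str = "\t") -> dict:
    """Read an individual → hunt-unit assignment table (columns:
    ``individual, unit``)."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("individual", "unit"):
        if col not in df.columns:
            raise ValueError(f"unit map missing column {col!r}")
    return {r.individual: canonical_unit(r.unit) for r in df.itertuples()}


def write_unit_map(unit_of: Mapping[str, str], path, sep: str = "\t") -> None:
    pd.DataFrame(
        {"individual": list(unit_of), "unit": [unit_of[s] for s in unit_of]}
    ).to_csv(path, sep=sep, index=False)


# ----------------------------------------------------------------------
# Dosage matrix (delimited text, individuals x loci)
# ----------------------------------------------------------------------

def write_dosage_matrix(m: DosageMatrix, path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        np.round(m.dosage, DOSAGE_DECIMALS),
        index=pd.Index(m.individual_ids, name="individual"),
        columns=m.locus_ids,
    )
    df.to_csv(path, sep=sep, float_format=f"%.{DOSAGE_DECIMALS}f", na_rep="NA")


def read_dosage_matrix(path, unit_of: Mapping[str, str] | None = None, sep: str | None = None) -> DosageMatrix:
    """Read a delimited individuals × loci dosage matrix.

    The header row holds locus ids; the first column holds individual ids.
    Values must lie in [0, 2]; ``NA``/empty encodes missing.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        with open(path) as fh:
            first = fh.readline()
        if "\t" in first:
            sep = "\t"
        elif "," in first:
            sep = ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    dosage = df.to_numpy(dtype=float)
    bad = np.argwhere(np.isfinite(dosage) & ((dosage < 0) | (dosage > 2)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"dosage {dosage[i, j]} out of [0, 2] at row {df.index[i]}, column {df.columns[j]}"
        )
    ids = [str(s) for s in df.index]
    units = {s: canonical_unit(unit_of[s]) for s in ids} if unit_of else {s: "?" for s in ids}
    return DosageMatrix(ids, [str(c) for c in df.columns], units, dosage)


# ----------------------------------------------------------------------
# Herd metadata table and translocation ledger
# ----------------------------------------------------------------------

def _validate_herd_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in HERD_TABLE_COLUMNS if c not in df.columns and c not in ("lat", "lon")]
    if missing:
        raise ValueError(f"herd table missing columns: {missing}")
    df = df.copy()
    df["unit"] = df["unit"].map(canonical_unit)
    status = df["status"].astype(str).str.strip().str.lower()
    bad = sorted(set(status) - set(VALID_STATUS))
    if bad:
        raise ValueError(f"unknown herd status labels: {bad}")
    df["status"] = status
    df["n_sources"] = df["n_sources"].astype(int)
    if (df["n_sources"] < 0).any():
        raise ValueError("n_sources must be non-negative")
    for col, lo, hi in (("lat", -90.0, 90.0), ("lon", -180.0, 180.0)):
        if col in df.columns:
            v = pd.to_numeric(df[col], errors="coerce")
            out = df.loc[v.notna() & ((v < lo) | (v > hi)), "unit"]
            if len(out):
                raise ValueError(
                    f"{col} out of [{lo}, {hi}] for unit(s): {', '.join(map(str, out))}"
                )
            df[col] = v
    return df.reset_index(drop=True)


def read_herd_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read and validate a herd metadata table.

    Required columns: ``unit, desert, status, n_sources``; optional:
    ``lat, lon, n_genotyped, h_e, h_o, f_is``.  Status labels are
    normalized case-insensitively to remnant / reintroduced / pioneering.
    """
    return _validate_herd_table(pd.read_csv(path, sep=sep, dtype={"unit": str}))


def write_herd_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    _validate_herd_table(df).to_csv(path, sep=sep, index=False)


def read_ledger(path, sep: str = "\t") -> pd.DataFrame:
    """Read a translocation ledger (source, destination, year, count).

    An empty file (header only, or zero bytes) yields an empty ledger.
    """
    try:
        df = pd.read_csv(path, sep=sep, dtype={"source": str, "destination": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=list(LEDGER_COLUMNS))
    missing = [c for c in LEDGER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ledger missing columns: {missing}")
    if len(df):
        df["source"] = df["source"].map(canonical_unit)
        df["destination"] = df["destination"].map(canonical_unit)
        df["count"] = df["count"].astype(int)
        if (df["count"] < 1).any():
            raise ValueError("ledger counts must be >= 1")
        if (df["source"] == df["destination"]).any():
            raise ValueError("ledger source and destination must differ")
    return df.reset_index(drop=True)


def write_ledger(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False, columns=list(LEDGER_COLUMNS))
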