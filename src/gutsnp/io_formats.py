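"""Readers, writers and domain types for the external formats the pipeline touches.

All coordinates are 1-based and inclusive on the catalog gene sequence; catalog
genes are ORF sequences, so position 1 is codon 1 base 1 unless an annotation's
``cds_offset`` says otherwise.  Tables are tab-delimited UTF-8 with a header row
and ``.`` for missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

BASES: tuple[str, ...] = ("A", "C", "G", "T")
MISSING = "."

COHORT_DAYS = {"PWS": frozenset({0, 30, 60, 90}), "SO": frozenset({0, 30})}


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A file parses but violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleMeta:
    """One metagenome sample: subject, cohort, intervention day and depth.

    ``read_pairs_million`` is T_S, the sample's sequencing amount in millions
    of paired-end read pairs; SNP densities are normalised by it.
    """

    sample_id: str
    subject_id: str
    cohort: str
    day: int
    read_pairs_million: float

    def __post_init__(self) -> None:
        if self.cohort not in COHORT_DAYS:
            raise ValidationError(
                f"sample {self.sample_id}: unknown cohort {self.cohort!r}"
            )
        if self.read_pairs_million <= 0:
            raise ValidationError(
                f"sample {self.sample_id}: read_pairs_million must be > 0"
            )


@dataclass
class SnpSite:
    """A variant position on a catalog gene with per-sample allele read counts.

    ``counts`` maps sample_id -> {base -> read count}; bases absent from the
    map carry zero reads.
    """

    gene_id: str
    pos: int
    ref: str
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref not in BASES:
            raise ValidationError(f"{self.key}: ref base {self.ref!r} not in ACGT")
        if self.pos < 1:
            raise ValidationError(f"{self.key}: position must be 1-based positive")
        for sample, bc in self.counts.items():
            for base, n in bc.items():
                if n < 0:
                    raise ValidationError(
                        f"{self.key} sample {sample}: negative count for {base}"
                    )

    @property
    def key(self) -> tuple[str, int]:
        return (self.gene_id, self.pos)

    def total_depth(self, sample_id: str) -> int:
        return sum(self.counts.get(sample_id, {}).values())

    def variant_depth(self, sample_id: str) -> int:
        """Read support for any non-reference allele in this sample."""
        bc = self.counts.get(sample_id, {})
        return sum(n for base, n in bc.items() if base != self.ref)

    def observed(self, sample_id: str, min_depth: int = 5) -> bool:
        """Whether the site is covered in the sample (total depth gate)."""
        return self.total_depth(sample_id) >= min_depth

    def carries_variant(self, sample_id: str, min_reads: int = 5) -> bool:
        """Whether the sample supports a non-reference allele with >= min_reads."""
        return self.variant_depth(sample_id) >= min_reads


@dataclass(frozen=True)
class GeneAnnotation:
    """Catalog gene metadata: length, taxonomy, functional memberships, frame."""

    gene_id: str
    length_bp: int
    species: str
    genus: str
    kos: frozenset[str] = frozenset()
    pathways: frozenset[str] = frozenset()
    cds_offset: int = 0

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValidationError(f"gene {self.gene_id}: length_bp must be positive")

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


@dataclass
class GenomeSiteMap:
    """Nucleotide states of one reference strain genome at catalog SNP sites.

    ``entries`` maps (gene_id, pos) -> base, or MISSING when the site could not
    be located in that genome.
    """

    strain_id: str
    entries: dict[tuple[str, int], str] = field(default_factory=dict)

    def coverage(self, site_keys: Iterable[tuple[str, int]]) -> float:
        keys = list(site_keys)
        if not keys:
            return 0.0
        hit = sum(1 for k in keys if self.entries.get(k, MISSING) != MISSING)
        return hit / len(keys)


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

_META_COLS = ["sample_id", "subject_id", "cohort", "day", "read_pairs_million"]


def read_metadata(path: str | Path, enforce_design: bool = True) -> list[SampleMeta]:
    """Read the sample metadata table.

    With ``enforce_design`` the intervention days are validated against the
    study layout (PWS sampled on days 0/30/60/90, SO on days 0/30).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata is missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ValidationError(f"{path}: duplicate sample_id values {dups}")
    out = []
    for row in df.itertuples(index=False):
        meta = SampleMeta(
            sample_id=row.sample_id,
            subject_id=row.subject_id,
            cohort=row.cohort,
            day=int(row.day),
            read_pairs_million=float(row.read_pairs_million),
        )
        if enforce_design and meta.day not in COHORT_DAYS[meta.cohort]:
            raise ValidationError(
                f"sample {meta.sample_id}: day {meta.day} invalid for cohort "
                f"{meta.cohort} (allowed {sorted(COHORT_DAYS[meta.cohort])})"
            )
        out.append(meta)
    return out


def write_metadata(metadata: Iterable[SampleMeta], path: str | Path) -> None:
    rows = [
        (m.sample_id, m.subject_id, m.cohort, m.day, f"{m.read_pairs_million:g}")
        for m in metadata
    ]
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# allele count table
# ---------------------------------------------------------------------------

_COUNT_COLS = ["gene_id", "pos", "ref", "sample_id", "A", "C", "G", "T"]


def read_allele_count_table(path: str | Path) -> list[SnpSite]:
    """Read a pileup-style allele count table into SnpSites.

    One row per (site, sample); rows are grouped by (gene_id, pos, ref).
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str})
    missing = [c for c in _COUNT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: allele count table missing columns {missing}")
    for b in BASES:
        if (df[b] < 0).any():
            raise ValidationError(f"{path}: negative {b} count")
    dup = df.duplicated(subset=["gene_id", "pos", "sample_id"])
    if dup.any():
        rows = df.loc[dup, ["gene_id", "pos", "sample_id"]].values.tolist()
        raise ValidationError(f"{path}: duplicate (gene,pos,sample) rows {rows[:5]}")
    refs = df.groupby(["gene_id", "pos"])["ref"].nunique()
    if (refs > 1).any():
        bad = refs[refs > 1].index.tolist()
        raise ValidationError(f"{path}: conflicting ref bases at sites {bad[:5]}")

    sites: list[SnpSite] = []
    for (gene, pos), grp in df.groupby(["gene_id", "pos"], sort=True):
        ref = grp["ref"].iloc[0]
        counts = {
            row.sample_id: {b: int(getattr(row, b)) for b in BASES}
            for row in grp.itertuples(index=False)
        }
        sites.append(SnpSite(gene_id=gene, pos=int(pos), ref=ref, counts=counts))
    return sites


def write_allele_count_table(sites: Iterable[SnpSite], path: str | Path) -> None:
    """Write sites in canonical order (gene, pos, sample); round-trip stable."""
    rows = []
    for site in sorted(sites, key=lambda s: s.key):
        for sample in sorted(site.counts):
            bc = site.counts[sample]
            rows.append(
                [site.gene_id, site.pos, site.ref, sample]
                + [int(bc.get(b, 0)) for b in BASES]
            )
    pd.DataFrame(rows, columns=_COUNT_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf_callset(path: str | Path, metadata: Iterable[SampleMeta]) -> list[SnpSite]:
    """Read a multi-sample VCF (CHROM = gene id, POS = gene coordinate).

    Per-sample allele depths (FORMAT/AD) are mapped to base counts.
    Multiallelic records become a single SnpSite carrying every allele's
    counts.  Records with a non-ACGT allele (indels, symbolic alleles) are
    skipped with a warning.
    """
    import pysam

    known = {m.sample_id for m in metadata}
    with pysam.VariantFile(str(path)) as vf:
        if "AD" not in vf.header.formats:
            raise FormatError(f"{path}: FORMAT/AD allele depths are required")
        unknown = [s for s in vf.header.samples if s not in known]
        if unknown:
            raise ValidationError(f"{path}: samples not in metadata: {unknown}")
        sites: list[SnpSite] = []
        for rec in vf:
            alleles = tuple(rec.alleles or ())
            if any(len(a) != 1 or a not in BASES for a in alleles):
                log.warning(
                    "skipping %s:%s: non-ACGT allele in %s", rec.chrom, rec.pos, alleles
                )
                continue
            counts: dict[str, dict[str, int]] = {}
            for sample, call in rec.samples.items():
                ad = call.get("AD")
                bc = {b: 0 for b in BASES}
                if ad is not None:
                    for allele, depth in zip(alleles, ad):
                        if depth is not None:
                            bc[allele] += int(depth)
                counts[sample] = bc
            sites.append(
                SnpSite(gene_id=rec.chrom, pos=rec.pos, ref=rec.ref, counts=counts)
            )
    return sites


# ---------------------------------------------------------------------------
# gene catalog + annotations
# ---------------------------------------------------------------------------

_ANNOT_COLS = ["gene_id", "length_bp", "species", "genus", "kos", "pathways", "cds_offset"]


def _split_set(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text or text == MISSING:
        return frozenset()
    return frozenset(p for p in text.split(",") if p)


def read_catalog_and_annotations(
    fasta: str | Path, tsv: str | Path
) -> tuple[dict[str, GeneAnnotation], dict[str, str]]:
    """Read the gene catalog FASTA and its annotation table together.

    Returns (annotations by gene_id, uppercase sequences by gene_id).  FASTA
    ids and TSV gene_ids must agree, and any length_bp given in the TSV must
    equal the sequence length.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    df = pd.read_csv(tsv, sep="\t", dtype=str)
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{tsv}: annotation table missing columns {missing}")
    tsv_ids = set(df["gene_id"])
    only_tsv = sorted(tsv_ids - set(seqs))
    only_fasta = sorted(set(seqs) - tsv_ids)
    if only_tsv or only_fasta:
        raise ValidationError(
            f"catalog/annotation id mismatch: TSV-only {only_tsv[:5]}, "
            f"FASTA-only {only_fasta[:5]}"
        )
    annots: dict[str, GeneAnnotation] = {}
    for row in df.itertuples(index=False):
        seq_len = len(seqs[row.gene_id])
        length = int(row.length_bp)
        if length != seq_len:
            raise ValidationError(
                f"gene {row.gene_id}: length_bp {length} != sequence length {seq_len}"
            )
        annots[row.gene_id] = GeneAnnotation(
            gene_id=row.gene_id,
            length_bp=length,
            species=row.species,
            genus=row.genus,
            kos=_split_set(row.kos),
            pathways=_split_set(row.pathways),
            cds_offset=int(row.cds_offset),
        )
    return annots, seqs


def write_annotations(annots: Iterable[GeneAnnotation], path: str | Path) -> None:
    rows = [
        (
            a.gene_id,
            a.length_bp,
            a.species,
            a.genus,
            ",".join(sorted(a.kos)) or MISSING,
            ",".join(sorted(a.pathways)) or MISSING,
            a.cds_offset,
        )
        for a in annots
    ]
    pd.DataFrame(rows, columns=_ANNOT_COLS).to_csv(path, sep="\t", index=False)


def write_catalog(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_id in seqs:
            fh.write(f">{gene_id}\n{seqs[gene_id]}\n")


# ---------------------------------------------------------------------------
# genome site maps
# ---------------------------------------------------------------------------

_MAP_COLS = ["strain_id", "gene_id", "pos", "base"]


def read_genome_site_maps(path: str | Path) -> list[GenomeSiteMap]:
    """Read strain genome states at catalog sites (strain, gene, pos, base)."""
    df = pd.read_csv(path, sep="\t", dtype={"strain_id": str, "gene_id": str, "base": str})
    missing = [c for c in _MAP_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: genome site map missing columns {missing}")
    bad = df.loc[~df["base"].isin(list(BASES) + [MISSING]), "base"].unique()
    if len(bad):
        raise ValidationError(f"{path}: invalid bases {bad.tolist()}")
    maps: list[GenomeSiteMap] = []
    for strain, grp in df.groupby("strain_id", sort=True):
        entries = {
            (row.gene_id, int(row.pos)): row.base
            for row in grp.itertuples(index=False)
        }
        maps.append(GenomeSiteMap(strain_id=strain, entries=entries))
    return maps


def write_genome_site_maps(maps: Iterable[GenomeSiteMap], path: str | Path) -> None:
    rows = []
    for m in sorted(maps, key=lambda m: m.strain_id):
        for (gene, pos) in sorted(m.entries):
            rows.append([m.strain_id, gene, pos, m.entries[(gene, pos)]])
    pd.DataFrame(rows, columns=_MAP_COLS).to_csv(path, sep="\t", index=False)
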