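"""Synonymous/nonsynonymous classification, taxon attribution and enrichment.

Substitutions are classified against the catalog ORF under NCBI translation
table 11 (bacteria/archaea); pathway over-representation uses the upper-tail
hypergeometric test with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable
from scipy.stats import hypergeom
from .io_formats import GeneAnnotation, ValidationError
from .snp_core import bh_adjust

log = logging.getLogger(__name__)

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_STOPS = frozenset(_TABLE11.stop_codons)
STOP = "*"


def translate_codon(codon: str) -> str:
    """Amino acid (one-letter) for a codon under table 11; '*' for stop."""
    codon = codon.upper()
    if codon in _STOPS:
        return STOP
    return _TABLE11.forward_table[codon]


@dataclass(frozen=True)
class SubstitutionCall:
    """Effect of a single-base substitution on the encoded protein."""

    gene_id: str
    pos: int
    ref: str
    alt: str
    codon_index: int
    codon_pos: int
    ref_aa: str | None
    alt_aa: str | None
    effect: str  # synonymous | nonsynonymous | stop_gain | stop_loss | out_of_frame

    @property
    def changes_protein(self) -> bool:
        """Nonsynonymous in the broad sense (includes stop gain/loss)."""
        return self.effect in ("nonsynonymous", "stop_gain", "stop_loss")


def classify_substitution(
    cds_sequence: str,
    cds_offset: int,
    pos: int,
    ref: str,
    alt: str,
    gene_id: str = "",
) -> SubstitutionCall:
    """Classify a substitution at 1-based ``pos`` of an in-frame ORF sequence.

    The codon containing the site is located from ``cds_offset`` (number of
    bases before the first codon).  Sites upstream of the frame or beyond the
    last complete codon are flagged ``out_of_frame`` and excluded from effect
    tallies.  The reference base must match the sequence.
    """
    seq = cds_sequence.upper()
    if not 1 <= pos <= len(seq):
        raise ValidationError(f"{gene_id}: pos {pos} outside sequence (len {len(seq)})")
    if seq[pos - 1] != ref:
        raise ValidationError(
            f"{gene_id}: ref {ref} does not match catalog base {seq[pos - 1]} at {pos}"
        )
    if alt == ref:
        raise ValidationError(f"{gene_id}: alt equals ref at {pos}")

    rel = pos - 1 - cds_offset
    codon_index = rel // 3 + 1 if rel >= 0 else 0
    codon_pos = rel % 3 + 1
    if rel < 0:
        log.warning("%s:%s upstream of CDS frame; out_of_frame", gene_id, pos)
        return SubstitutionCall(gene_id, pos, ref, alt, 0, codon_pos, None, None,
                                "out_of_frame")
    start = cds_offset + (codon_index - 1) * 3
    codon = seq[start : start + 3]
    if len(codon) < 3:
        log.warning("%s:%s beyond last complete codon; out_of_frame", gene_id, pos)
        return SubstitutionCall(gene_id, pos, ref, alt, codon_index, codon_pos,
                                None, None, "out_of_frame")
    alt_codon = codon[: codon_pos - 1] + alt + codon[codon_pos:]
    ref_aa, alt_aa = translate_codon(codon), translate_codon(alt_codon)
    if ref_aa == alt_aa:
        effect = "synonymous"
    elif ref_aa == STOP:
        effect = "stop_loss"
    elif alt_aa == STOP:
        effect = "stop_gain"
    else:
        effect = "nonsynonymous"
    return SubstitutionCall(gene_id, pos, ref, alt, codon_index, codon_pos,
                            ref_aa, alt_aa, effect)


def classify_bias_records(
    records: Iterable,
    sequences: Mapping[str, str],
    annotations: Mapping[str, GeneAnnotation],
    pre_is_ref: bool = False,
) -> list[SubstitutionCall]:
    """Classify each BiasSNP as a substitution from its group-A to group-B allele.

    When the group-A allele equals the catalog base the call is simply A->B;
    otherwise the substitution is taken between the two dominant alleles
    directly (the catalog base only anchors the codon context).
    """
    calls = []
    for rec in records:
        seq = sequences[rec.gene_id]
        offset = annotations[rec.gene_id].cds_offset
        # replace the catalog base with the group-A (pre) allele as context
        seq_pre = seq[: rec.pos - 1] + rec.group_a_allele + seq[rec.pos :]
        calls.append(
            classify_substitution(
                seq_pre, offset, rec.pos, rec.group_a_allele, rec.group_b_allele,
                gene_id=rec.gene_id,
            )
        )
    return calls


def effect_summary(calls: Sequence[SubstitutionCall]) -> dict[str, int]:
    """Tally effects; stop gain/loss count as nonsynonymous in the binary split."""
    in_frame = [c for c in calls if c.effect != "out_of_frame"]
    return {
        "n": len(in_frame),
        "synonymous": sum(c.effect == "synonymous" for c in in_frame),
        "nonsynonymous": sum(c.changes_protein for c in in_frame),
        "stop_gain": sum(c.effect == "stop_gain" for c in in_frame),
        "stop_loss": sum(c.effect == "stop_loss" for c in in_frame),
        "out_of_frame": len(calls) - len(in_frame),
    }


# ---------------------------------------------------------------------------
# taxon attribution
# ---------------------------------------------------------------------------


def taxon_composition(
    records: Iterable,
    annotations: Mapping[str, GeneAnnotation],
    level: str = "genus",
) -> pd.Series:
    """Proportion of records (SNPs or genes) attributed to each taxon.

    ``records`` may be anything with a ``gene_id`` attribute, or raw gene ids.
    Unannotated genes fall into an ``Unclassified`` bucket.  Proportions sum
    to 1; the result is sorted descending.
    """
    if level not in ("genus", "species"):
        raise ValidationError("level must be 'genus' or 'species'")
    counts: dict[str, int] = {}
    total = 0
    for rec in records:
        gene_id = rec if isinstance(rec, str) else rec.gene_id
        ann = annotations.get(gene_id)
        taxon = getattr(ann, level) if ann is not None else "Unclassified"
        counts[taxon] = counts.get(taxon, 0) + 1
        total += 1
    if total == 0:
        return pd.Series(dtype=float, name=level)
    s = pd.Series(counts, name=level) / total
    return s.sort_values(ascending=False)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric P(X >= k) for k hits of K in a draw of n from N."""
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrichment(
    gene_set: Iterable[str],
    background: Iterable[str],
    pathway_map: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pathway over-representation of ``gene_set`` within ``background``.

    For each pathway with K background members, the upper-tail hypergeometric
    p-value of observing k set members among n drawn from N background genes
    is computed, then BH-adjusted across pathways.
    """
    genes = set(gene_set)
    bg = set(background)
    if not genes <= bg:
        raise ValidationError(
            f"gene_set not a subset of background: {sorted(genes - bg)[:5]}"
        )
    by_pathway: dict[str, set[str]] = {}
    for gene in bg:
        for pw in pathway_map.get(gene, ()):
            by_pathway.setdefault(pw, set()).add(gene)
    N, n = len(bg), len(genes)
    rows = []
    for pw in sorted(by_pathway):
        members = by_pathway[pw]
        K = len(members)
        k = len(members & genes)
        rows.append({"pathway": pw, "k": k, "K": K, "n": n, "N": N,
                     "p_value": hypergeom_pvalue(k, K, n, N)})
    table = pd.DataFrame(rows, columns=["pathway", "k", "K", "n", "N", "p_value"])
    if len(table):
        table["adjusted_p"] = bh_adjust(table["p_value"])
        table = table.sort_values(
            ["adjusted_p", "p_value", "pathway"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        table["adjusted_p"] = pd.Series(dtype=float)
    table["significant"] = table["adjusted_p"] < alpha
    return table
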