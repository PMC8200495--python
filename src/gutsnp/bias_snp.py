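"""Detection of BiasSNPs: sites whose dominant nucleotide differs between groups.

A site is a BiasSNP between groups A and B when there are two distinct bases
X != Y such that strictly more than ``prevalence_threshold`` (default 60%) of
A's evaluable individuals carry X as their within-sample dominant allele and
strictly more than the threshold of B's carry Y.  Dominance within a sample
is the majority read allele, gated on a minimum total depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import BASES, SnpSite, ValidationError


@dataclass(frozen=True)
class BiasSnpRecord:
    """One detected BiasSNP with each group's dominant allele and prevalence."""

    gene_id: str
    pos: int
    ref: str
    group_a_allele: str
    group_a_prevalence: float
    group_b_allele: str
    group_b_prevalence: float

    @property
    def key(self) -> tuple[str, int]:
        return (self.gene_id, self.pos)

    @property
    def allele_pair(self) -> tuple[str, str]:
        return (self.group_a_allele, self.group_b_allele)


@dataclass
class BiasSnpSetComparison:
    """Common and cohort-specific BiasSNPs between two detection runs."""

    set_a: list[BiasSnpRecord]
    set_b: list[BiasSnpRecord]
    common: list[BiasSnpRecord]
    a_specific: list[BiasSnpRecord]
    b_specific: list[BiasSnpRecord]


def dominant_allele(
    counts: Mapping[str, int], min_depth: int = 5
) -> str | None:
    """Majority allele of a sample's read counts, or None below the depth gate.

    Ties are broken by fixed base order A < C < G < T.
    """
    total = sum(counts.values())
    if total < min_depth:
        return None
    return max(BASES, key=lambda b: (counts.get(b, 0), -BASES.index(b)))


def detect_bias_snps(
    sites: Sequence[SnpSite],
    group_a: Sequence[str],
    group_b: Sequence[str],
    prevalence_threshold: float = 0.6,
    min_depth: int = 5,
) -> list[BiasSnpRecord]:
    """Screen sites for group-differential dominant alleles.

    Prevalences are computed over each group's non-missing individuals (those
    passing the depth gate); a site needs at least 2 such individuals per
    group to be evaluable.  Output is sorted by (gene_id, pos).
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValidationError(f"groups overlap: {sorted(set_a & set_b)[:5]}")

    records: list[BiasSnpRecord] = []
    for site in sites:
        dom_a = [dominant_allele(site.counts.get(s, {}), min_depth) for s in group_a]
        dom_b = [dominant_allele(site.counts.get(s, {}), min_depth) for s in group_b]
        dom_a = [d for d in dom_a if d is not None]
        dom_b = [d for d in dom_b if d is not None]
        if len(dom_a) < 2 or len(dom_b) < 2:
            continue
        best = None
        for x in BASES:
            prev_a = dom_a.count(x) / len(dom_a)
            if prev_a <= prevalence_threshold:
                continue
            for y in BASES:
                if y == x:
                    continue
                prev_b = dom_b.count(y) / len(dom_b)
                if prev_b <= prevalence_threshold:
                    continue
                cand = (prev_a, prev_b, x, y)
                if best is None or cand[:2] > best[:2]:
                    best = cand
        if best is not None:
            prev_a, prev_b, x, y = best
            records.append(
                BiasSnpRecord(
                    gene_id=site.gene_id,
                    pos=site.pos,
                    ref=site.ref,
                    group_a_allele=x,
                    group_a_prevalence=prev_a,
                    group_b_allele=y,
                    group_b_prevalence=prev_b,
                )
            )
    records.sort(key=lambda r: r.key)
    return records


def compare_bias_sets(
    set_a: Sequence[BiasSnpRecord], set_b: Sequence[BiasSnpRecord]
) -> BiasSnpSetComparison:
    """Split two BiasSNP sets into common and set-specific records.

    A record is common when the other set has the same (gene_id, pos) with an
    identical ordered allele pair (group-A allele, group-B allele), i.e. the
    same directional change in both cohorts.
    """
    index_b = {(r.key, r.allele_pair) for r in set_b}
    common = [r for r in set_a if (r.key, r.allele_pair) in index_b]
    common_keys = {(r.key, r.allele_pair) for r in common}
    a_specific = [r for r in set_a if (r.key, r.allele_pair) not in common_keys]
    b_specific = [r for r in set_b if (r.key, r.allele_pair) not in common_keys]
    return BiasSnpSetComparison(
        set_a=list(set_a),
        set_b=list(set_b),
        common=common,
        a_specific=a_specific,
        b_specific=b_specific,
    )
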