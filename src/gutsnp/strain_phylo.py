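"""Strain attribution of BiasSNPs: site projection, consensus, distances, NJ.

Reference strain genomes are reduced to their nucleotide states at the
BiasSNP sites; strains covering more than 70% of the sites are kept and
compared (p-distance with pairwise deletion) against group-consensus
pseudo-sequences built from the per-sample dominant alleles.  An internal
neighbor-joining tree provides a deterministic topology; the site alignment
can be exported for external maximum-likelihood tree building.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bias_snp import BiasSnpRecord, dominant_allele
from .io_formats import BASES, MISSING, GenomeSiteMap, SnpSite, ValidationError

log = logging.getLogger(__name__)


def site_key(gene_id: str, pos: int) -> str:
    return f"{gene_id}:{pos}"


def project_sites(
    bias_set: Sequence[BiasSnpRecord],
    genome_maps: Iterable[GenomeSiteMap],
    min_cov: float = 0.7,
) -> pd.DataFrame:
    """Strain x site matrix of nucleotide states at the BiasSNP sites.

    Strains with strictly more than ``min_cov`` of the sites non-missing are
    retained; the rest are dropped (and logged).  Column order follows the
    bias set.
    """
    if not bias_set:
        raise ValidationError("bias_set is empty")
    keys = [r.key for r in bias_set]
    cols = [site_key(*k) for k in keys]
    rows, dropped = {}, []
    for gmap in genome_maps:
        cov = gmap.coverage(keys)
        if cov > min_cov:
            rows[gmap.strain_id] = [gmap.entries.get(k, MISSING) for k in keys]
        else:
            dropped.append((gmap.strain_id, cov))
    if dropped:
        log.info("dropped %d strains below %.0f%% site coverage: %s",
                 len(dropped), 100 * min_cov, [s for s, _ in dropped])
    if not rows:
        raise ValidationError("no strain reaches the site-coverage threshold")
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def group_consensus(
    sites: Sequence[SnpSite],
    bias_set: Sequence[BiasSnpRecord],
    samples: Sequence[str],
    min_depth: int = 5,
) -> pd.Series:
    """Per-site majority of per-sample dominant alleles across a sample group.

    Ties break by base order A < C < G < T; sites with no evaluable sample are
    MISSING.  When the bias set was detected with prevalence > 0.5 the
    consensus of the detection group equals the detected group allele.
    """
    if not samples:
        raise ValidationError("samples must be non-empty")
    by_key = {s.key: s for s in sites}
    values = {}
    for rec in bias_set:
        site = by_key.get(rec.key)
        if site is None:
            values[site_key(*rec.key)] = MISSING
            continue
        doms = [dominant_allele(site.counts.get(s, {}), min_depth) for s in samples]
        doms = [d for d in doms if d is not None]
        if not doms:
            values[site_key(*rec.key)] = MISSING
        else:
            values[site_key(*rec.key)] = max(
                BASES, key=lambda b: (doms.count(b), -BASES.index(b))
            )
    return pd.Series(values, name="consensus")


def p_distance(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise mismatch fraction over jointly non-missing sites.

    Returns (distance matrix, matrix of shared-site counts).  A pair with no
    jointly observed site is an error.
    """
    if len(matrix) < 2:
        raise ValidationError("need at least 2 rows")
    names = list(matrix.index)
    x = matrix.to_numpy(dtype=object)
    n = len(names)
    dist = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    for i in range(n):
        shared[i, i] = int(np.sum(x[i] != MISSING))
        for j in range(i + 1, n):
            mask = (x[i] != MISSING) & (x[j] != MISSING)
            m = int(mask.sum())
            if m == 0:
                raise ValidationError(
                    f"rows {names[i]!r} and {names[j]!r} share no observed site"
                )
            mism = int(np.sum(x[i][mask] != x[j][mask]))
            dist[i, j] = dist[j, i] = mism / m
            shared[i, j] = shared[j, i] = m
    return (
        pd.DataFrame(dist, index=names, columns=names),
        pd.DataFrame(shared, index=names, columns=names),
    )


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dist: pd.DataFrame) -> str:
    """Neighbor-joining tree (Newick) from a distance matrix.

    Deterministic: the pair minimising the Q criterion is chosen with ties
    broken by row-major order.  Negative branch lengths are clamped to zero
    with a warning.  The final join places the root midway between the last
    two clusters, preserving all leaf-to-leaf path lengths.
    """
    d = np.asarray(dist, dtype=float)
    names = [str(x) for x in dist.index]
    n = len(names)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValidationError("distance matrix must be square and symmetric")

    active = list(range(n))
    newick = {i: names[i] for i in range(n)}
    dm = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}
    next_id = n

    def get(i: int, j: int) -> float:
        return dm[(i, j) if i < j else (j, i)]

    def branch(length: float) -> float:
        if length < -1e-12:
            warnings.warn(f"negative NJ branch length {length:.3g} clamped to 0")
            return 0.0
        return max(length, 0.0)

    while len(active) > 2:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best, best_q = None, np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        dij = get(i, j)
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = branch(li), branch(lj)
        u = next_id
        next_id += 1
        newick[u] = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})"
        for k in active:
            if k not in (i, j):
                dm[(min(u, k), max(u, k))] = (get(i, k) + get(j, k) - dij) / 2
        active = [k for k in active if k not in (i, j)] + [u]

    a, b = active
    half = branch(get(a, b) / 2)
    return f"({newick[a]}:{half:.10g},{newick[b]}:{half:.10g});"


def closest_strains(
    dist: pd.DataFrame,
    query: str,
    candidates: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Strains ranked by ascending distance to ``query``; ties share a rank."""
    if query not in dist.index:
        raise ValidationError(f"query row {query!r} not in distance matrix")
    cands = [c for c in (candidates or dist.index) if c != query]
    table = pd.DataFrame(
        {"strain": cands, "distance": [dist.at[query, c] for c in cands]}
    ).sort_values(["distance", "strain"], kind="mergesort").reset_index(drop=True)
    table["rank"] = table["distance"].rank(method="min").astype(int)
    table["tie"] = table.duplicated("distance", keep=False)
    return table


# ---------------------------------------------------------------------------
# alignment export / import
# ---------------------------------------------------------------------------


def export_alignment(matrix: pd.DataFrame, path, fmt: str = "fasta") -> None:
    """Write the allele matrix as a site alignment (MISSING -> 'N').

    Formats: ``fasta`` or relaxed ``phylip`` (full names, two-space separator),
    both ready for external ML tree builders.
    """
    if matrix.index.duplicated().any():
        raise ValidationError("duplicate row names in alignment")
    seqs = {
        str(name): "".join("N" if c == MISSING else c for c in row)
        for name, row in zip(matrix.index, matrix.to_numpy(dtype=object))
    }
    with open(path, "w") as fh:
        if fmt == "fasta":
            for name, seq in seqs.items():
                fh.write(f">{name}\n{seq}\n")
        elif fmt == "phylip":
            fh.write(f" {len(seqs)} {matrix.shape[1]}\n")
            for name, seq in seqs.items():
                fh.write(f"{name}  {seq}\n")
        else:
            raise ValidationError(f"unknown alignment format {fmt!r}")


def read_alignment_fasta(path, columns: Sequence[str]) -> pd.DataFrame:
    """Re-read an exported FASTA alignment ('N' -> MISSING)."""
    from Bio import SeqIO

    rows = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rows[rec.id] = [MISSING if c == "N" else c for c in str(rec.seq).upper()]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(columns))


# ---------------------------------------------------------------------------
# flank-search site mapping
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _find_all(haystack: str, needle: str) -> list[int]:
    out, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def map_sites_by_flank(
    gene_sequences: Mapping[str, str],
    site_keys: Sequence[tuple[str, int]],
    genome_sequence: str,
    strain_id: str,
    flank: int = 15,
) -> GenomeSiteMap:
    """Locate catalog SNP sites in a genome by exact flank search.

    For each site the catalog subsequence of +/- ``flank`` bp around the site
    is searched on both strands of the genome; a unique hit yields the genome
    base at the site position, anything else is MISSING.
    """
    genome = genome_sequence.upper()
    entries: dict[tuple[str, int], str] = {}
    for gene_id, pos in site_keys:
        seq = gene_sequences[gene_id].upper()
        lo = max(0, pos - 1 - flank)
        hi = min(len(seq), pos + flank)
        pattern = seq[lo:hi]
        center = pos - 1 - lo
        fwd = _find_all(genome, pattern)
        rc_pattern = _revcomp(pattern)
        rev = _find_all(genome, rc_pattern)
        if len(fwd) + len(rev) == 1:
            if fwd:
                entries[(gene_id, pos)] = genome[fwd[0] + center]
            else:
                i = rev[0] + (len(pattern) - 1 - center)
                entries[(gene_id, pos)] = genome[i].translate(_COMP)
        else:
            entries[(gene_id, pos)] = MISSING
    return GenomeSiteMap(strain_id=strain_id, entries=entries)
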