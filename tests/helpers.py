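"""Independent brute-force oracles shared by the unit and acceptance tests.

Everything here re-derives the scientific rules from first principles (plain
loops, exhaustive enumeration, hard-coded genetic code) without calling the
package's implementation, so agreement between the two routes is meaningful.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

BASES = ("A", "C", "G", "T")

# NCBI genetic code 11, written down independently: amino acids for codons
# enumerated in TCAG order on all three positions.
_NCBI11_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_TCAG = "TCAG"
CODE11 = {
    a + b + c: _NCBI11_AAS[16 * i + 4 * j + k]
    for i, a in enumerate(_TCAG)
    for j, b in enumerate(_TCAG)
    for k, c in enumerate(_TCAG)
}


def oracle_effect(codon: str, codon_pos: int, alt: str) -> str:
    """Effect of substituting ``alt`` at 1-based ``codon_pos`` of ``codon``."""
    alt_codon = codon[: codon_pos - 1] + alt + codon[codon_pos:]
    ref_aa, alt_aa = CODE11[codon], CODE11[alt_codon]
    if ref_aa == alt_aa:
        return "synonymous"
    if ref_aa == "*":
        return "stop_loss"
    if alt_aa == "*":
        return "stop_gain"
    return "nonsynonymous"


def oracle_min_support(sites, min_reads):
    """Sites where some sample's non-reference read support reaches min_reads."""
    kept = []
    for s in sites:
        ok = False
        for sample, bc in s.counts.items():
            support = sum(n for b, n in bc.items() if b != s.ref)
            if support >= min_reads:
                ok = True
        if ok:
            kept.append(s.key)
    return set(kept)


def oracle_group_coverage(sites, groups, min_frac, min_reads):
    """Sites observed (total depth >= min_reads) in >= min_frac of some group."""
    members = {}
    for sample, g in groups.items():
        members.setdefault(g, []).append(sample)
    kept = set()
    for s in sites:
        for samp in members.values():
            n_obs = 0
            for sample in samp:
                if sum(s.counts.get(sample, {}).values()) >= min_reads:
                    n_obs += 1
            if n_obs / len(samp) >= min_frac:
                kept.add(s.key)
                break
    return kept


def oracle_dominant(counts, min_depth):
    total = sum(counts.values())
    if total < min_depth:
        return None
    best, best_n = None, -1
    for b in BASES:  # first in A<C<G<T order wins ties
        if counts.get(b, 0) > best_n:
            best, best_n = b, counts.get(b, 0)
    return best


def oracle_bias_sites(sites, group_a, group_b, threshold, min_depth):
    """Exhaustive check of the group-differential dominance definition."""
    found = {}
    for s in sites:
        dom_a = [oracle_dominant(s.counts.get(x, {}), min_depth) for x in group_a]
        dom_b = [oracle_dominant(s.counts.get(x, {}), min_depth) for x in group_b]
        dom_a = [d for d in dom_a if d is not None]
        dom_b = [d for d in dom_b if d is not None]
        if len(dom_a) < 2 or len(dom_b) < 2:
            continue
        hits = []
        for x in BASES:
            for y in BASES:
                if x == y:
                    continue
                pa = dom_a.count(x) / len(dom_a)
                pb = dom_b.count(y) / len(dom_b)
                if pa > threshold and pb > threshold:
                    hits.append((pa, pb, x, y))
        if hits:
            found[s.key] = max(hits)
    return found


def oracle_hypergeom_upper(k, K, n, N) -> Fraction:
    """Exact upper-tail P(X >= k) by combinatorial enumeration."""
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), math.comb(N, n))
    return total


def oracle_bh(pvals):
    """Benjamini-Hochberg step-up adjusted p-values, closed form."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


def oracle_pseudo_f(dist, labels):
    """Anderson's pseudo-F from scratch: plain double loops over pairs."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += dist[i][j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        acc = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                acc += dist[idx[a]][idx[b]] ** 2
        ss_within += acc / len(idx)
    ss_among = ss_total - ss_within
    return (ss_among / (len(groups) - 1)) / (ss_within / (n - len(groups)))


def oracle_permanova_exact(dist, labels):
    """Exact permutation p-value by enumerating distinct label arrangements."""
    f_obs = oracle_pseudo_f(dist, labels)
    arrangements = sorted(set(itertools.permutations(labels)))
    count = sum(
        1 for arr in arrangements if oracle_pseudo_f(dist, list(arr)) >= f_obs - 1e-12
    )
    return count / len(arrangements)


def random_additive_tree(rng, n_taxa):
    """Random binary tree with U(0.1, 1) branch lengths.

    Returns (newick, leaf-to-leaf patristic distance matrix, names); the
    distances are read back from the newick with dendropy, independently of
    any neighbor-joining logic.
    """
    import dendropy

    names = [f"t{i}" for i in range(n_taxa)]
    clusters = list(names)
    while len(clusters) > 2:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        bi, bj = rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0)
        merged = f"({clusters[i]}:{bi:.10f},{clusters[j]}:{bj:.10f})"
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    bridge = rng.uniform(0.2, 1.0)
    newick = f"({clusters[0]}:{bridge / 2:.10f},{clusters[1]}:{bridge / 2:.10f});"

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    dist = np.zeros((n_taxa, n_taxa))
    for a, la in enumerate(names):
        for b in range(a + 1, n_taxa):
            ta = tree.taxon_namespace.get_taxon(la)
            tb = tree.taxon_namespace.get_taxon(names[b])
            dist[a, b] = dist[b, a] = pdm.distance(ta, tb)
    return newick, dist, names
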