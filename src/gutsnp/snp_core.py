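"""SNP filtering, per-gene SNP density and density-based statistical screens.

The density statistic D_i = n_i / (T_S * L_i) counts SNP sites on gene i
observed in sample S per kilobase of gene per million sequenced read pairs.
Two filters precede it: a read-support gate (a variant allele must be backed
by at least ``min_reads`` reads in at least one sample) and a group-coverage
gate (a site must be covered, at total depth >= ``min_reads``, in at least
60% of the samples of at least one group).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import SnpSite, GeneAnnotation, SampleMeta, ValidationError

log = logging.getLogger(__name__)


@dataclass
class FilteredCallset:
    """Sites surviving the filters, with a record of the thresholds applied."""

    sites: list[SnpSite]
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_min_support(
    sites: Sequence[SnpSite], min_reads: int = 5
) -> FilteredCallset:
    """Keep sites whose variant allele has >= min_reads support in some sample.

    A site is retained *for a sample* when that sample's non-reference read
    support reaches ``min_reads``; a site with no such sample is dropped.
    """
    if min_reads < 1:
        raise ValidationError("min_reads must be >= 1")
    kept = [
        s
        for s in sites
        if any(s.carries_variant(sample, min_reads) for sample in s.counts)
    ]
    return FilteredCallset(
        sites=kept, provenance={"min_support_reads": min_reads}
    )


def filter_group_coverage(
    callset: FilteredCallset | Sequence[SnpSite],
    groups: Mapping[str, str],
    min_frac: float = 0.6,
    min_reads: int = 5,
) -> FilteredCallset:
    """Drop sites covered in fewer than ``min_frac`` of every group's samples.

    Coverage of a site in a sample means total read depth >= ``min_reads``.
    A site survives when at least one group reaches the fraction (inclusive:
    sites with *less than* 60% coverage in every group are removed).
    """
    if not 0 < min_frac <= 1:
        raise ValidationError("min_frac must be in (0, 1]")
    sites = callset.sites if isinstance(callset, FilteredCallset) else list(callset)
    prov = dict(callset.provenance) if isinstance(callset, FilteredCallset) else {}

    members: dict[str, list[str]] = {}
    for sample, group in groups.items():
        members.setdefault(group, []).append(sample)
    if not members:
        raise ValidationError("grouping assigns no samples to any group")

    kept = []
    for site in sites:
        for samp in members.values():
            frac = sum(site.observed(s, min_reads) for s in samp) / len(samp)
            if frac >= min_frac:
                kept.append(site)
                break
    prov.update({"min_group_coverage": min_frac, "coverage_min_depth": min_reads,
                 "grouping": sorted(members)})
    return FilteredCallset(sites=kept, provenance=prov)


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def snp_density(n_snps: int, t_million_pairs: float, length_kb: float) -> float:
    """SNPs per kilobase of gene per million read pairs: n / (T * L)."""
    if t_million_pairs <= 0:
        raise ValidationError("t_million_pairs must be > 0")
    if length_kb <= 0:
        raise ValidationError("length_kb must be > 0")
    if n_snps < 0:
        raise ValidationError("n_snps must be >= 0")
    return n_snps / (t_million_pairs * length_kb)


def density_matrix(
    callset: FilteredCallset | Sequence[SnpSite],
    annotations: Mapping[str, GeneAnnotation],
    metadata: Sequence[SampleMeta],
    min_reads: int = 5,
) -> pd.DataFrame:
    """Genes x samples matrix of SNP densities.

    Cell (i, S) counts the retained sites of gene i present in sample S (the
    sample's variant support >= ``min_reads``), divided by T_S * L_i.
    """
    sites = callset.sites if isinstance(callset, FilteredCallset) else list(callset)
    genes = sorted({s.gene_id for s in sites})
    unknown = [g for g in genes if g not in annotations]
    if unknown:
        raise ValidationError(f"genes without annotation: {unknown[:5]}")
    samples = [m.sample_id for m in metadata]
    t_s = {m.sample_id: m.read_pairs_million for m in metadata}

    counts = pd.DataFrame(0, index=genes, columns=samples, dtype=float)
    for site in sites:
        for sample in samples:
            if site.carries_variant(sample, min_reads):
                counts.at[site.gene_id, sample] += 1
    for gene in genes:
        counts.loc[gene] /= annotations[gene].length_kb
    for sample in samples:
        counts[sample] /= t_s[sample]
    return counts


# ---------------------------------------------------------------------------
# differential density
# ---------------------------------------------------------------------------


def differential_density(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    paired: bool = True,
    alpha: float = 0.05,
    fc_threshold: float = 8.0,
) -> pd.DataFrame:
    """Per-gene Wilcoxon screen of SNP density between two sample groups.

    Paired design compares ``group_a[i]`` with ``group_b[i]`` (same subject,
    two time points) by signed-rank test; unpaired uses the rank-sum test.
    P-values are Benjamini-Hochberg adjusted.  Fold change is the ratio of
    group mean densities after adding a pseudocount of half the smallest
    nonzero density in the matrix; ``direction`` records which group's mean
    was higher.  Genes that are all-zero in both groups are excluded.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least 2 samples")
    if paired and len(group_a) != len(group_b):
        raise ValidationError("paired design requires equal-length groups")

    a = matrix[list(group_a)].to_numpy(float)
    b = matrix[list(group_b)].to_numpy(float)
    nonzero = matrix.to_numpy(float)
    nonzero = nonzero[nonzero > 0]
    eps = nonzero.min() / 2.0 if nonzero.size else 0.0

    rows = []
    for gi, gene in enumerate(matrix.index):
        xa, xb = a[gi], b[gi]
        if not xa.any() and not xb.any():
            log.info("gene %s: all-zero densities in both groups; excluded", gene)
            continue
        if paired:
            diff = xa - xb
            if np.all(diff == 0):
                p = 1.0
            else:
                p = stats.wilcoxon(
                    xa, xb, zero_method="wilcox", alternative="two-sided",
                    method="auto",
                ).pvalue
        else:
            p = stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
        mean_a, mean_b = float(xa.mean()), float(xb.mean())
        hi, lo = max(mean_a, mean_b) + eps, min(mean_a, mean_b) + eps
        fc = hi / lo if lo > 0 else np.inf
        rows.append(
            {
                "gene_id": gene,
                "p_value": float(p),
                "mean_a": mean_a,
                "mean_b": mean_b,
                "fold_change": float(fc),
                "direction": "higher-pre" if mean_a >= mean_b else "higher-post",
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene_id", "p_value", "mean_a", "mean_b", "fold_change", "direction"]
    ).set_index("gene_id")
    if len(table):
        table["adjusted_p"] = bh_adjust(table["p_value"])
    else:
        table["adjusted_p"] = pd.Series(dtype=float)
    table["significant"] = table["adjusted_p"] < alpha
    table["significant_fc"] = table["significant"] & (table["fold_change"] > fc_threshold)
    return table


# ---------------------------------------------------------------------------
# ordination & PERMANOVA
# ---------------------------------------------------------------------------


def pca_scores(
    matrix: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores of samples in gene-density space.

    Columns (samples) become observations; gene densities are centred before
    decomposition.  Returns (scores, explained variance fractions).
    """
    from sklearn.decomposition import PCA

    if matrix.shape[1] < 2:
        raise ValidationError("PCA requires at least 2 samples")
    x = matrix.to_numpy(float).T
    k = min(n_components, x.shape[0], x.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=matrix.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample Bray-Curtis dissimilarity on the density matrix."""
    from scipy.spatial.distance import pdist, squareform

    x = matrix.to_numpy(float).T
    d = squareform(pdist(x, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)  # identical all-zero samples
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


def euclidean(matrix: pd.DataFrame) -> pd.DataFrame:
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(matrix.to_numpy(float).T, metric="euclidean"))
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


def _pseudo_f(sq: np.ndarray, label_codes: np.ndarray, n_groups: int) -> float:
    """Anderson's pseudo-F from squared distances and integer group codes."""
    n = sq.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = sq[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(label_codes == g)
        if idx.size > 1:
            sub = sq[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_among = ss_total - ss_within
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    dist: pd.DataFrame | np.ndarray,
    labels: Sequence[str],
    n_perm: int | str = 999,
    seed: int | None = None,
) -> dict:
    """Permutational multivariate ANOVA (one-way) on a distance matrix.

    The observed pseudo-F is compared against label permutations; the p-value
    is (1 + #{F_perm >= F_obs}) / (1 + n_perm).  With ``n_perm="all"`` every
    distinct label arrangement is enumerated and the p-value becomes the exact
    fraction #{F >= F_obs} / #arrangements (the identity arrangement counts).
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValidationError("dist must be a symmetric matrix with zero diagonal")
    if len(labels) != n:
        raise ValidationError("labels length must match the distance matrix")
    uniq = sorted(set(labels))
    codes = np.array([uniq.index(l) for l in labels])
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValidationError("every group needs at least 2 samples")
    sq = d**2
    f_obs = _pseudo_f(sq, codes, len(uniq))

    if n_perm == "all":
        arrangements = sorted(set(itertools.permutations(codes.tolist())))
        f_perm = np.array(
            [_pseudo_f(sq, np.array(arr), len(uniq)) for arr in arrangements]
        )
        count = int(np.sum(f_perm >= f_obs - 1e-12))
        p = count / len(arrangements)
        n_done = len(arrangements)
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(int(n_perm)):
            perm = rng.permutation(codes)
            if _pseudo_f(sq, perm, len(uniq)) >= f_obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + int(n_perm))
        n_done = int(n_perm)
    return {"pseudo_F": float(f_obs), "p_value": float(p), "n_perm": n_done}
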