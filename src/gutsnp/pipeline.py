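"""End-to-end orchestration: filter -> density -> screens -> BiasSNP -> strains.

``run_pipeline`` chains every stage on a run directory (as produced by the
synthetic generator, or assembled from real calls), writing each stage's TSV,
a summary and a content-hash manifest, deterministically for a given seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import bias_snp as bs
from . import functional_annotation as fa
from . import io_formats as iof
from . import snp_core as sc
from . import strain_phylo as sp
from .io_formats import ValidationError

log = logging.getLogger(__name__)

_BIAS_COLS = ["gene_id", "pos", "ref", "allele_a", "prev_a", "allele_b", "prev_b"]


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run.

    Threshold defaults are the study's stated values: >=5 supporting reads,
    >=60% group coverage, >60% dominance prevalence, >70% strain site
    coverage, adjusted P < 0.05, fold change > 8.
    """

    run_dir: str | Path
    out_dir: str | Path
    min_reads: int = 5
    min_frac: float = 0.6
    prevalence_threshold: float = 0.6
    min_cov: float = 0.7
    alpha: float = 0.05
    fc_threshold: float = 8.0
    n_perm: int = 999
    distance: str = "braycurtis"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValidationError("min_reads must be >= 1")
        for name in ("min_frac", "prevalence_threshold", "min_cov", "alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1]")
        if self.distance not in ("braycurtis", "euclidean"):
            raise ValidationError("distance must be 'braycurtis' or 'euclidean'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input missing: {path}")
    return path


def bias_records_to_frame(records) -> pd.DataFrame:
    rows = [
        (r.gene_id, r.pos, r.ref, r.group_a_allele, r.group_a_prevalence,
         r.group_b_allele, r.group_b_prevalence)
        for r in records
    ]
    return pd.DataFrame(rows, columns=_BIAS_COLS)


def frame_to_bias_records(df: pd.DataFrame) -> list[bs.BiasSnpRecord]:
    return [
        bs.BiasSnpRecord(
            gene_id=row.gene_id, pos=int(row.pos), ref=row.ref,
            group_a_allele=row.allele_a, group_a_prevalence=float(row.prev_a),
            group_b_allele=row.allele_b, group_b_prevalence=float(row.prev_b),
        )
        for row in df.itertuples(index=False)
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the summary dictionary."""
    run_dir, out_dir = Path(config.run_dir), Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # ---- inputs -----------------------------------------------------------
    metadata = iof.read_metadata(_require(run_dir / "metadata.tsv"))
    annots, seqs = iof.read_catalog_and_annotations(
        _require(run_dir / "catalog.fasta"), _require(run_dir / "annotations.tsv")
    )
    counts_path = run_dir / "allele_counts.tsv"
    if counts_path.exists():
        sites = iof.read_allele_count_table(counts_path)
    else:
        sites = iof.read_vcf_callset(_require(run_dir / "calls.vcf"), metadata)
    by_cohort_day: dict[tuple[str, int], list[str]] = {}
    for m in metadata:
        by_cohort_day.setdefault((m.cohort, m.day), []).append(m.sample_id)
    subj: dict[str, str] = {m.sample_id: m.subject_id for m in metadata}

    # ---- filters ----------------------------------------------------------
    callset = sc.filter_min_support(sites, config.min_reads)
    groups = {
        m.sample_id: f"{m.cohort}_d{m.day:02d}" for m in metadata
    }
    callset = sc.filter_group_coverage(
        callset, groups, config.min_frac, config.min_reads
    )
    log.info("retained %d/%d sites after filters", len(callset.sites), len(sites))

    # ---- density, ordination, PERMANOVA -----------------------------------
    dens = sc.density_matrix(callset, annots, metadata, config.min_reads)
    dens.to_csv(out_dir / "density_matrix.tsv", sep="\t")
    scores, evr = sc.pca_scores(dens)
    scores.to_csv(out_dir / "pca_scores.tsv", sep="\t")
    dist = (sc.bray_curtis if config.distance == "braycurtis" else sc.euclidean)(dens)
    labels = [groups[s] for s in dens.columns]
    perma = sc.permanova(dist, labels, n_perm=config.n_perm, seed=config.seed)
    pd.DataFrame([perma]).to_csv(out_dir / "permanova.tsv", sep="\t", index=False)

    # ---- differential density (paired, day 0 vs day 30 per cohort) --------
    differential = {}
    for cohort in ("PWS", "SO"):
        pre = sorted(by_cohort_day.get((cohort, 0), []), key=lambda s: subj[s])
        post = sorted(by_cohort_day.get((cohort, 30), []), key=lambda s: subj[s])
        if len(pre) < 2 or len(post) < 2:
            continue
        table = sc.differential_density(
            dens, pre, post, paired=True,
            alpha=config.alpha, fc_threshold=config.fc_threshold,
        )
        table.to_csv(out_dir / f"differential_{cohort}.tsv", sep="\t")
        differential[cohort] = table

    # ---- BiasSNP detection -------------------------------------------------
    bias = {}
    for cohort in ("PWS", "SO"):
        pre = by_cohort_day.get((cohort, 0), [])
        post = by_cohort_day.get((cohort, 30), [])
        recs = bs.detect_bias_snps(
            callset.sites, pre, post,
            prevalence_threshold=config.prevalence_threshold,
            min_depth=config.min_reads,
        )
        bias[cohort] = recs
        bias_records_to_frame(recs).to_csv(
            out_dir / f"bias_{cohort}.tsv", sep="\t", index=False
        )
    comparison = bs.compare_bias_sets(bias["PWS"], bias["SO"])
    bias_records_to_frame(comparison.common).to_csv(
        out_dir / "bias_common.tsv", sep="\t", index=False
    )

    # ---- effects, composition, enrichment ----------------------------------
    union = {r.key: r for c in ("PWS", "SO") for r in bias[c]}
    union_records = [union[k] for k in sorted(union)]
    calls = fa.classify_bias_records(union_records, seqs, annots)
    pd.DataFrame(
        [dataclasses.asdict(c) for c in calls]
    ).to_csv(out_dir / "effects.tsv", sep="\t", index=False)
    summary_effects = fa.effect_summary(calls)

    fa.taxon_composition(callset.sites, annots, "genus").to_csv(
        out_dir / "composition_snps_genus.tsv", sep="\t", header=["proportion"]
    )
    fa.taxon_composition(
        comparison.common or union_records, annots, "species"
    ).to_csv(out_dir / "composition_bias_species.tsv", sep="\t", header=["proportion"])

    background = sorted({s.gene_id for s in callset.sites})
    nonsyn_genes = sorted({c.gene_id for c in calls if c.changes_protein})
    pathway_map = {g: sorted(annots[g].pathways) for g in background}
    enrichment = fa.hypergeom_enrichment(
        nonsyn_genes, background, pathway_map, alpha=config.alpha
    )
    enrichment.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)

    # ---- strain phylogeny ---------------------------------------------------
    phylo_summary = {}
    phylo_set = comparison.common or union_records
    maps_path = run_dir / "genome_sites.tsv"
    if phylo_set and maps_path.exists():
        maps = iof.read_genome_site_maps(maps_path)
        matrix = sp.project_sites(phylo_set, maps, config.min_cov)
        pre_all = [m.sample_id for m in metadata if m.day == 0]
        post_all = [m.sample_id for m in metadata if m.day == 30]
        matrix.loc["group_pre"] = sp.group_consensus(
            callset.sites, phylo_set, pre_all, config.min_reads
        ).values
        matrix.loc["group_post"] = sp.group_consensus(
            callset.sites, phylo_set, post_all, config.min_reads
        ).values
        dist_m, shared = sp.p_distance(matrix)
        dist_m.to_csv(out_dir / "strain_distances.tsv", sep="\t")
        sp.export_alignment(matrix, out_dir / "bias_alignment.fasta", "fasta")
        if len(matrix) >= 3:
            (out_dir / "nj_tree.nwk").write_text(sp.nj_tree(dist_m) + "\n")
        strains = [s for s in matrix.index if s not in ("group_pre", "group_post")]
        for grp in ("group_pre", "group_post"):
            ranking = sp.closest_strains(dist_m, grp, strains)
            ranking.to_csv(out_dir / f"closest_{grp}.tsv", sep="\t", index=False)
            phylo_summary[f"closest_to_{grp}"] = ranking["strain"].iloc[0]
        phylo_summary["n_strains_retained"] = len(strains)

    # ---- summary + manifest --------------------------------------------------
    summary = {
        "n_sites_input": len(sites),
        "n_sites_retained": len(callset.sites),
        "n_genes_with_snps": len(background),
        "permanova_pseudo_F": perma["pseudo_F"],
        "permanova_p": perma["p_value"],
        "pca_var_pc1": float(evr[0]),
        "bias_snps_PWS": len(bias["PWS"]),
        "bias_snps_SO": len(bias["SO"]),
        "bias_snps_common": len(comparison.common),
        "effects": summary_effects,
        **{
            f"differential_genes_{c}": int(t["significant"].sum())
            for c, t in differential.items()
        },
        **phylo_summary,
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("run_dir", "out_dir")
        },
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    _write_manifest(out_dir)
    return summary


def _write_manifest(out_dir: Path) -> None:
    rows = []
    for f in sorted(out_dir.iterdir()):
        if f.name == "manifest.tsv" or not f.is_file():
            continue
        rows.append(f"{f.name}\t{hashlib.sha256(f.read_bytes()).hexdigest()}")
    (out_dir / "manifest.tsv").write_text("file\tsha256\n" + "\n".join(rows) + "\n")


def evaluate_run(run_dir: str | Path, out_dir: str | Path) -> dict:
    """Compare a pipeline output directory against the run's planted truth."""
    from .synthetic_data import TruthTable, evaluate_against_truth

    run_dir, out_dir = Path(run_dir), Path(out_dir)
    truth = TruthTable.from_json(_require(run_dir / "truth.json"))
    detected: set[tuple[str, int]] = set()
    for cohort in ("PWS", "SO"):
        df = pd.read_csv(out_dir / f"bias_{cohort}.tsv", sep="\t")
        detected |= {(r.gene_id, int(r.pos)) for r in df.itertuples(index=False)}
    eff = pd.read_csv(out_dir / "effects.tsv", sep="\t")
    calls = [
        fa.SubstitutionCall(
            gene_id=r.gene_id, pos=int(r.pos), ref=r.ref, alt=r.alt,
            codon_index=int(r.codon_index), codon_pos=int(r.codon_pos),
            ref_aa=r.ref_aa, alt_aa=r.alt_aa, effect=r.effect,
        )
        for r in eff.itertuples(index=False)
    ]
    ranking_path = out_dir / "closest_group_post.tsv"
    ranking = (
        pd.read_csv(ranking_path, sep="\t") if ranking_path.exists() else None
    )
    metrics = evaluate_against_truth(
        sorted(detected), truth, effect_calls=calls, strain_ranking=ranking
    )
    metrics["enriched_pathway"] = truth.enriched_pathway
    enr = pd.read_csv(out_dir / "enrichment.tsv", sep="\t")
    if len(enr):
        pos = enr.index[enr["pathway"] == truth.enriched_pathway]
        metrics["enriched_pathway_rank"] = int(pos[0]) + 1 if len(pos) else None
    (out_dir / "evaluation.json").write_text(
        json.dumps(metrics, indent=1, sort_keys=True) + "\n"
    )
    return metrics
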