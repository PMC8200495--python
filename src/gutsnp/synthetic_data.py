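"""Seeded synthetic study generator with planted ground truth.

Emulates the two-cohort dietary-intervention design: a PWS cohort sampled on
intervention days 0/30/60/90 and an SO cohort on days 0/30, variant calls
against a small in-frame ORF catalog, planted group-differential (Bias) SNP
sites whose dominant allele switches between day 0 and the later time points
at controlled prevalences, a pathway map with one planted enriched pathway,
and reference-strain genome site maps including a strain carrying the
post-intervention alleles.  Everything flows from a single seeded generator,
so identical configs yield byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io_formats as iof
from .functional_annotation import classify_substitution
from .io_formats import BASES, GeneAnnotation, GenomeSiteMap, SampleMeta, SnpSite

_GENERA = [
    "Faecalibacterium", "Bacteroides", "Bifidobacterium", "Ruminococcus",
    "Blautia", "Escherichia", "Collinsella", "Clostridium",
]
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohorts.

    Defaults mirror the intervention design (17 PWS children over days
    0/30/60/90, 19 SO children over days 0/30) and a per-sample sequencing
    amount spread around the mid-80s of millions of read pairs, at a desk
    scale of 60 catalog genes.
    """

    seed: int = 0
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (300, 900)
    n_species: int = 8
    n_pws: int = 17
    n_so: int = 19
    pws_days: tuple[int, ...] = (0, 30, 60, 90)
    so_days: tuple[int, ...] = (0, 30)
    depth_per_site_mean: float = 20.0
    read_pairs_million_range: tuple[float, float] = (55.0, 115.0)
    baseline_snp_rate: float = 2.0  # SNP sites per kb of gene
    bias_fraction: float = 0.1
    planted_prevalence_pre: float = 0.9
    planted_prevalence_post: float = 0.9
    dominant_read_fraction: float = 0.9
    nonsyn_fraction: float = 0.5
    n_pathways: int = 10
    n_reference_strains: int = 8

    def __post_init__(self) -> None:
        for name in ("bias_fraction", "nonsyn_fraction", "dominant_read_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("planted_prevalence_pre", "planted_prevalence_post"):
            v = getattr(self, name)
            if not 0.5 < v <= 1:
                raise ValueError(f"{name} must be in (0.5, 1]")
        if self.n_pws < 2 or self.n_so < 2:
            raise ValueError("cohort sizes must be >= 2")
        lo, hi = self.gene_length_range
        if lo < 9 or hi < lo:
            raise ValueError("invalid gene_length_range")


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted group-differential site."""

    gene_id: str
    pos: int
    ref: str
    pre_allele: str
    post_allele: str
    effect: str  # synonymous | nonsynonymous | stop_gain | stop_loss

    @property
    def key(self) -> tuple[str, int]:
        return (self.gene_id, self.pos)

    @property
    def changes_protein(self) -> bool:
        return self.effect != "synonymous"


@dataclass
class TruthTable:
    """Everything the generator planted, for downstream evaluation."""

    planted: list[PlantedSite]
    enriched_pathway: str
    donor_post_strain: str
    donor_pre_strain: str
    n_sites_total: int
    n_planted: int
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted": [asdict(p) for p in self.planted],
            "enriched_pathway": self.enriched_pathway,
            "donor_post_strain": self.donor_post_strain,
            "donor_pre_strain": self.donor_pre_strain,
            "n_sites_total": self.n_sites_total,
            "n_planted": self.n_planted,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        planted = [PlantedSite(**p) for p in payload.pop("planted")]
        return cls(planted=planted, **payload)


def _random_orf(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    lo, hi = length_range
    n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
    body = rng.choice(_NONSTOP_CODONS, size=n_codons - 2)
    stop = rng.choice(["TAA", "TAG", "TGA"])
    return "ATG" + "".join(body) + stop


def _pick_alt(
    rng: np.random.Generator, seq: str, pos: int, want_nonsyn: bool
) -> tuple[str, str] | None:
    """Alt base at pos realising the wanted effect class, or None."""
    ref = seq[pos - 1]
    options = []
    for alt in BASES:
        if alt == ref:
            continue
        call = classify_substitution(seq, 0, pos, ref, alt)
        if call.effect == "out_of_frame":
            continue
        if call.changes_protein == want_nonsyn:
            options.append((alt, call.effect))
    if not options:
        return None
    return options[int(rng.integers(len(options)))]


def generate(config: SimConfig, outdir: str | Path) -> TruthTable:
    """Write a complete synthetic run directory and return its truth table.

    Files: catalog.fasta, annotations.tsv, metadata.tsv, allele_counts.tsv,
    genome_sites.tsv, truth.json, config.json, manifest.tsv.
    """
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- taxonomy, catalog, annotations -----------------------------------
    species = []
    for i in range(config.n_species):
        genus = _GENERA[i % len(_GENERA)]
        species.append((f"{genus} sp{i + 1:02d}", genus))
    gene_ids = [f"gene_{i:04d}" for i in range(config.n_genes)]
    seqs = {g: _random_orf(rng, config.gene_length_range) for g in gene_ids}
    pathway_ids = [f"pw{i + 1:02d}" for i in range(config.n_pathways)]
    enriched_pathway = pathway_ids[int(rng.integers(config.n_pathways))]

    gene_species = {g: species[int(rng.integers(len(species)))] for g in gene_ids}
    gene_pathways = {
        g: set(rng.choice(pathway_ids, size=int(rng.integers(1, 3)), replace=False))
        for g in gene_ids
    }
    gene_kos = {
        g: {f"K{int(rng.integers(0, 20000)):05d}"} for g in gene_ids
    }

    # --- site layout -------------------------------------------------------
    site_positions: dict[str, list[int]] = {}
    for g in gene_ids:
        n_sites = _round_half_up(config.baseline_snp_rate * len(seqs[g]) / 1000)
        interior = np.arange(4, len(seqs[g]) - 3 + 1)
        n_sites = min(n_sites, interior.size)
        pos = sorted(rng.choice(interior, size=n_sites, replace=False).tolist())
        site_positions[g] = [int(p) for p in pos]
    all_sites = [(g, p) for g in gene_ids for p in site_positions[g]]
    n_total = len(all_sites)
    n_planted = min(_round_half_up(config.bias_fraction * n_total), n_total)
    planted_idx = set(
        rng.choice(n_total, size=n_planted, replace=False).tolist()
    )
    n_nonsyn = _round_half_up(config.nonsyn_fraction * n_planted)
    planted_order = sorted(planted_idx)
    want_nonsyn = {
        planted_order[i]: i in set(
            rng.choice(n_planted, size=n_nonsyn, replace=False).tolist()
        )
        for i in range(n_planted)
    }

    # --- allele plan per site ----------------------------------------------
    planted: list[PlantedSite] = []
    site_plan: dict[tuple[str, int], dict] = {}
    for idx, (g, pos) in enumerate(all_sites):
        seq = seqs[g]
        ref = seq[pos - 1]
        if idx in planted_idx:
            want = want_nonsyn[idx]
            picked = _pick_alt(rng, seq, pos, want)
            attempts = 0
            # move the site within its gene if the wanted class is not
            # realisable at the drawn position (rare for nonsynonymous)
            while picked is None and attempts < 50:
                cand = int(rng.integers(4, len(seq) - 3 + 1))
                if cand not in site_positions[g]:
                    pos = cand
                    ref = seq[pos - 1]
                    picked = _pick_alt(rng, seq, pos, want)
                    if picked is not None:
                        site_positions[g].append(pos)
                attempts += 1
            if picked is None:  # fall back to any effect, record the actual class
                alt = [b for b in BASES if b != ref][int(rng.integers(3))]
                effect = classify_substitution(seq, 0, pos, ref, alt).effect
            else:
                alt, effect = picked
            planted.append(PlantedSite(g, pos, ref, ref, alt, effect))
            site_plan[(g, pos)] = {"planted": True, "pre": ref, "post": alt}
        else:
            alt = [b for b in BASES if b != ref][int(rng.integers(3))]
            site_plan[(g, pos)] = {"planted": False, "dom": alt, "minor": ref}
    # positions may have moved during planting; rebuild the ordered site list
    all_keys = sorted(site_plan)

    # planted enriched pathway contains every planted-nonsynonymous gene
    for p in planted:
        if p.changes_protein:
            gene_pathways[p.gene_id].add(enriched_pathway)

    # --- samples ------------------------------------------------------------
    metadata: list[SampleMeta] = []
    lo, hi = config.read_pairs_million_range
    for i in range(config.n_pws):
        subj = f"P{i + 1:02d}"
        for day in config.pws_days:
            metadata.append(SampleMeta(
                sample_id=f"{subj}_d{day:02d}", subject_id=subj, cohort="PWS",
                day=day, read_pairs_million=round(float(rng.uniform(lo, hi)), 1),
            ))
    for i in range(config.n_so):
        subj = f"S{i + 1:02d}"
        for day in config.so_days:
            metadata.append(SampleMeta(
                sample_id=f"{subj}_d{day:02d}", subject_id=subj, cohort="SO",
                day=day, read_pairs_million=round(float(rng.uniform(lo, hi)), 1),
            ))

    # --- read counts --------------------------------------------------------
    sites: list[SnpSite] = []
    for (g, pos) in all_keys:
        plan = site_plan[(g, pos)]
        ref = seqs[g][pos - 1]
        counts: dict[str, dict[str, int]] = {}
        for m in metadata:
            if plan["planted"]:
                if m.day == 0:
                    p_dom = config.planted_prevalence_pre
                    dom, other = plan["pre"], plan["post"]
                else:
                    p_dom = config.planted_prevalence_post
                    dom, other = plan["post"], plan["pre"]
                if rng.random() >= p_dom:
                    dom, other = other, dom
            else:
                dom, other = plan["dom"], plan["minor"]
            depth = int(rng.poisson(config.depth_per_site_mean))
            bc = {b: 0 for b in BASES}
            if depth > 0:
                f = config.dominant_read_fraction
                n_dom, n_other = rng.multinomial(depth, [f, 1 - f])
                bc[dom], bc[other] = int(n_dom), int(bc[other] + n_other)
            counts[m.sample_id] = bc
        sites.append(SnpSite(gene_id=g, pos=pos, ref=ref, counts=counts))

    # --- reference strain genome maps ---------------------------------------
    strain_ids = [f"ref_strain_{i + 1:02d}" for i in range(config.n_reference_strains)]
    donor_post = strain_ids[0]
    donor_pre = strain_ids[1] if len(strain_ids) > 1 else strain_ids[0]
    maps: list[GenomeSiteMap] = []
    for sid in strain_ids:
        entries: dict[tuple[str, int], str] = {}
        if sid == donor_post or sid == donor_pre:
            for (g, pos) in all_keys:
                plan = site_plan[(g, pos)]
                if plan["planted"]:
                    entries[(g, pos)] = plan["post" if sid == donor_post else "pre"]
                else:
                    entries[(g, pos)] = plan["dom"]
        else:
            cov = float(rng.uniform(0.5, 0.95))
            for (g, pos) in all_keys:
                if rng.random() < cov:
                    entries[(g, pos)] = BASES[int(rng.integers(4))]
                else:
                    entries[(g, pos)] = iof.MISSING
        maps.append(GenomeSiteMap(strain_id=sid, entries=entries))

    # --- emit files ----------------------------------------------------------
    annots = [
        GeneAnnotation(
            gene_id=g,
            length_bp=len(seqs[g]),
            species=gene_species[g][0],
            genus=gene_species[g][1],
            kos=frozenset(gene_kos[g]),
            pathways=frozenset(gene_pathways[g]),
            cds_offset=0,
        )
        for g in gene_ids
    ]
    iof.write_catalog(seqs, outdir / "catalog.fasta")
    iof.write_annotations(annots, outdir / "annotations.tsv")
    iof.write_metadata(metadata, outdir / "metadata.tsv")
    iof.write_allele_count_table(sites, outdir / "allele_counts.tsv")
    iof.write_genome_site_maps(maps, outdir / "genome_sites.tsv")

    truth = TruthTable(
        planted=sorted(planted, key=lambda p: p.key),
        enriched_pathway=enriched_pathway,
        donor_post_strain=donor_post,
        donor_pre_strain=donor_pre,
        n_sites_total=len(all_keys),
        n_planted=len(planted),
        seed=config.seed,
    )
    truth.to_json(outdir / "truth.json")
    (outdir / "config.json").write_text(
        json.dumps(asdict(config), indent=1) + "\n"
    )
    _write_manifest(outdir)
    return truth


def _write_manifest(outdir: Path) -> None:
    rows = []
    for f in sorted(outdir.iterdir()):
        if f.name == "manifest.tsv" or not f.is_file():
            continue
        digest = hashlib.sha256(f.read_bytes()).hexdigest()
        rows.append(f"{f.name}\t{digest}")
    (outdir / "manifest.tsv").write_text(
        "file\tsha256\n" + "\n".join(rows) + "\n"
    )


# ---------------------------------------------------------------------------
# evaluation against the planted truth
# ---------------------------------------------------------------------------


def evaluate_against_truth(
    detected: Sequence,
    truth: TruthTable,
    effect_calls: Sequence | None = None,
    strain_ranking=None,
) -> dict:
    """Confusion metrics of BiasSNP recovery plus optional effect/strain checks.

    ``detected`` holds records (or (gene, pos) keys) from detect_bias_snps;
    ``effect_calls`` optionally holds SubstitutionCalls for the detected
    sites; ``strain_ranking`` optionally holds the closest_strains table for
    the post-group consensus.
    """
    det_keys = {d if isinstance(d, tuple) else d.key for d in detected}
    true_keys = {p.key for p in truth.planted}
    tp = len(det_keys & true_keys)
    fp = len(det_keys - true_keys)
    out = {
        "n_detected": len(det_keys),
        "n_planted": len(true_keys),
        "sensitivity": tp / len(true_keys) if true_keys else float("nan"),
        "false_discovery_proportion": fp / len(det_keys) if det_keys else 0.0,
    }
    if effect_calls is not None:
        truth_by_key = {p.key: p for p in truth.planted}
        matched = [
            c for c in effect_calls
            if (c.gene_id, c.pos) in truth_by_key and c.effect != "out_of_frame"
        ]
        if matched:
            ok = sum(
                c.changes_protein == truth_by_key[(c.gene_id, c.pos)].changes_protein
                for c in matched
            )
            out["effect_accuracy"] = ok / len(matched)
        else:
            out["effect_accuracy"] = float("nan")
    if strain_ranking is not None:
        hits = strain_ranking.loc[
            strain_ranking["strain"] == truth.donor_post_strain, "rank"
        ]
        out["donor_strain_rank"] = int(hits.iloc[0]) if len(hits) else None
    return out
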