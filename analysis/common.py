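"""Shared paths and lazy inputs for the numbered analysis drivers."""

from pathlib import Path

from gutsnp import io_formats as iof
from gutsnp.synthetic_data import SimConfig, TruthTable, generate

ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = ROOT / "results" / "analysis" / "run"
OUT_DIR = ROOT / "results" / "analysis"
SEED = 1


def ensure_run() -> TruthTable:
    """Simulate the study (seed 1) unless the run directory already exists."""
    if not (RUN_DIR / "truth.json").exists():
        generate(SimConfig(seed=SEED), RUN_DIR)
    return TruthTable.from_json(RUN_DIR / "truth.json")


def load_inputs():
    ensure_run()
    metadata = iof.read_metadata(RUN_DIR / "metadata.tsv")
    annots, seqs = iof.read_catalog_and_annotations(
        RUN_DIR / "catalog.fasta", RUN_DIR / "annotations.tsv"
    )
    sites = iof.read_allele_count_table(RUN_DIR / "allele_counts.tsv")
    return metadata, annots, seqs, sites
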