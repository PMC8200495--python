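"""Shared fixtures: site builders and a small synthetic run directory."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from gutsnp.io_formats import BASES, SnpSite
from gutsnp.synthetic_data import SimConfig, generate


def make_site(gene="g1", pos=10, ref="A", **sample_counts) -> SnpSite:
    """Site builder; sample counts given as s1={'A': 3, 'G': 7} kwargs."""
    counts = {
        sample: {b: int(bc.get(b, 0)) for b in BASES}
        for sample, bc in sample_counts.items()
    }
    return SnpSite(gene_id=gene, pos=pos, ref=ref, counts=counts)


def random_sites(rng, n_sites, samples, max_depth=30):
    """Random callset for oracle-equivalence checks."""
    sites = []
    for i in range(n_sites):
        ref = BASES[int(rng.integers(4))]
        counts = {}
        for s in samples:
            depth = int(rng.integers(0, max_depth))
            if depth:
                probs = rng.dirichlet([0.6] * 4)
                alloc = rng.multinomial(depth, probs)
                counts[s] = {b: int(c) for b, c in zip(BASES, alloc)}
            else:
                counts[s] = {b: 0 for b in BASES}
        sites.append(SnpSite(gene_id=f"g{i // 10}", pos=(i % 10) + 1, ref=ref,
                             counts=counts))
    return sites


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A compact synthetic study (seed 7) shared by read-only tests."""
    outdir = tmp_path_factory.mktemp("run") / "seed7"
    cfg = SimConfig(seed=7, n_genes=25, n_pws=6, n_so=6)
    truth = generate(cfg, outdir)
    return outdir, cfg, truth
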