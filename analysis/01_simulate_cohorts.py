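#!/usr/bin/env python
"""Simulate the two-cohort high-fiber-intervention study with planted truth.

Generates 17 PWS subjects (days 0/30/60/90) and 19 SO subjects (days 0/30),
a 60-gene in-frame ORF catalog with ~2 SNP sites/kb, and plants a fraction of
group-differential sites whose dominant allele flips between day 0 and the
later time points at 90%/90% prevalence.
"""

from common import RUN_DIR, SEED, ensure_run

truth = ensure_run()
print(f"run directory: {RUN_DIR} (seed {SEED})")
print(f"total SNP sites: {truth.n_sites_total}")
print(f"planted bias sites: {truth.n_planted}")
nonsyn = sum(p.changes_protein for p in truth.planted)
print(f"  of which protein-changing: {nonsyn}")
print(f"planted enriched pathway: {truth.enriched_pathway}")
print(f"post-allele donor strain: {truth.donor_post_strain}; "
      f"pre-allele donor: {truth.donor_pre_strain}")
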