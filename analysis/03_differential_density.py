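#!/usr/bin/env python
"""Screen genes whose SNP density changed over the intervention (per cohort).

Paired Wilcoxon signed-rank test per gene between each subject's day-0 and
day-30 samples, Benjamini-Hochberg adjusted, with mean-density fold changes
(pseudocount = half the smallest nonzero density).
"""

from common import OUT_DIR, load_inputs
from gutsnp import snp_core as sc

metadata, annots, _, sites = load_inputs()
callset = sc.filter_min_support(sites, 5)
groups = {m.sample_id: f"{m.cohort}_d{m.day:02d}" for m in metadata}
callset = sc.filter_group_coverage(callset, groups, 0.6, 5)
dens = sc.density_matrix(callset, annots, metadata)

subject = {m.sample_id: m.subject_id for m in metadata}
for cohort in ("PWS", "SO"):
    pre = sorted((m.sample_id for m in metadata if m.cohort == cohort and m.day == 0),
                 key=subject.get)
    post = sorted((m.sample_id for m in metadata if m.cohort == cohort and m.day == 30),
                  key=subject.get)
    table = sc.differential_density(dens, pre, post, paired=True)
    table.to_csv(OUT_DIR / f"differential_{cohort}.tsv", sep="\t")
    sig = table[table["significant"]]
    strong = table[table["significant_fc"]]
    higher_pre = (sig["direction"] == "higher-pre").sum()
    print(f"{cohort}: {len(sig)}/{len(table)} genes changed in SNP density "
          f"(adjusted P < 0.05); {len(strong)} also with fold change > 8; "
          f"{higher_pre} higher before the intervention, "
          f"{len(sig) - higher_pre} higher after")
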