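# Methods

## The analysis

`gutsnp` re-implements a strain-resolution analysis of gut-metagenome
single-nucleotide polymorphisms (SNPs) in a two-cohort dietary-intervention
design: children with Prader–Willi syndrome (PWS) sampled on intervention
days 0/30/60/90 and simple-obese (SO) children sampled on days 0/30.  Variant
calls are referenced to a gene catalog of predicted microbial ORFs, so every
position carries a codon context and a taxonomic/functional annotation.  The
pipeline runs five stages:

1. **Filtering.**  A site is kept only if some sample supports a
   non-reference allele with ≥ `min_reads` (default 5) reads, and only if, in
   at least one cohort/time-point group, the site is covered (total depth ≥
   `min_reads`) in at least `min_frac` (default 60%) of the group's samples.
   The coverage gate is inclusive (exactly 60% passes); it removes sites that
   are unrepresentative of every group.
2. **SNP density.**  For gene *i* and sample *S*,
   `D_i = n_i / (T_S · L_i)` — SNP sites of the gene present in the sample,
   per kilobase of gene (`L_i`) per million sequenced read pairs (`T_S`).
   "Present in the sample" uses the same variant-support rule as the first
   filter (≥ `min_reads` non-reference reads in that sample); the coverage
   filter's "observed" uses total depth.  The two readings are deliberately
   distinct: coverage asks whether the site was sequenced, presence asks
   whether the sample carries the variant.
   Densities feed a paired Wilcoxon signed-rank screen (day 0 vs day 30 per
   subject), BH adjustment, fold changes on group means with a pseudocount of
   half the smallest nonzero density (the densities can be exactly zero, and
   the screen needs a finite ratio), PCA of samples, and a one-way PERMANOVA.
3. **BiasSNP detection.**  Within a sample, the *dominant allele* is the
   majority read allele, gated on total depth ≥ `min_reads` (ties broken
   A<C<G<T).  A site is a BiasSNP between groups A and B when bases X ≠ Y
   exist with strictly more than `prevalence_threshold` (60%) of A's
   evaluable individuals dominant for X and strictly more than the threshold
   of B's dominant for Y.  Prevalence denominators count only evaluable
   (depth-passing) individuals, so missingness is not conflated with allele
   state.  Cross-cohort "common" BiasSNPs must match on site *and* on the
   ordered pre→post allele pair — a shared directional change.
4. **Effect classification and enrichment.**  Each BiasSNP is read as a
   substitution from the pre-group to the post-group dominant allele in its
   codon (NCBI translation table 11; catalog genes are in frame from
   `cds_offset`).  Stop gain/loss are reported separately but counted as
   nonsynonymous in binary tallies.  Genes with protein-changing BiasSNPs are
   tested for pathway over-representation with the upper-tail hypergeometric
   test against the background of all SNP-carrying genes (using the whole
   catalog as background would inflate significance), BH-adjusted.
5. **Strain attribution.**  Reference strain genomes, reduced to their bases
   at the BiasSNP sites (a precomputed site map, or the exact ±15 bp
   flank-search utility), are kept when strictly more than `min_cov` (70%) of
   sites are resolved.  Pre-/post-intervention consensus pseudo-sequences are
   the per-site majority of per-sample dominant alleles.  Distances are
   p-distances with pairwise deletion; the internal tree is neighbor-joining
   (deterministic tie-breaks, negative branches clamped to 0), and the site
   alignment is exported as FASTA/relaxed PHYLIP for external
   maximum-likelihood tree building, which is out of scope here.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `min_reads` | 5 | variant-support and depth gate (reads) |
| `min_frac` | 0.60 | group coverage fraction, inclusive |
| `prevalence_threshold` | 0.60 | dominance prevalence, strict (>) |
| `min_cov` | 0.70 | strain site coverage, strict (>) |
| `alpha` | 0.05 | adjusted-P cut-off |
| `fc_threshold` | 8 | fold-change cut-off, strict (>) |
| `n_perm` | 999 | PERMANOVA permutations (seeded) |
| `distance` | Bray–Curtis | PERMANOVA metric (Euclidean available) |

The inclusive/strict boundary conventions follow the phrasing of the rules
they implement ("less than 60% … removed" vs "more than 60%"/"more than
70%").  `T_S` is carried in the metadata in millions of *read pairs* and is
never recomputed from files.

## Statistical choices

- **Wilcoxon**: SciPy's signed-rank (paired) / rank-sum (unpaired) with the
  exact null when sample sizes permit and no ties, normal approximation
  otherwise.  All-zero paired differences yield p = 1 rather than an error.
- **Multiple testing**: Benjamini–Hochberg throughout, via a single shared
  helper.
- **PERMANOVA**: Anderson's pseudo-F computed from within-group sums of
  squared distances; p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm) with a
  seeded generator, or exact enumeration of all distinct label arrangements
  when `n_perm="all"`.  Implemented in-package because the contract requires
  this seeded scheme and the enumeration mode; scikit-bio's implementation is
  used as an independent cross-check in the tests.
- **Neighbor joining**: likewise implemented in-package for deterministic
  tie-breaks (row-major minimum of the Q criterion) and explicit clamping of
  negative branch lengths; on additive matrices it reproduces the generating
  tree's topology and path lengths to 1e-9.  The final join places the root
  midway between the last two clusters so leaf-to-leaf path lengths are
  preserved.
- **Ties** in per-sample dominance and in consensus building always break in
  fixed base order A<C<G<T, keeping every stage reproducible.

## The synthetic study

The generator (`synthetic_data`) emulates the study conditions rather than
real metagenomes: 17 PWS × 4 days + 19 SO × 2 days = 106 samples; per-sample
sequencing amounts uniform on 55–115 million read pairs (bracketing a mid-80s
mean with substantial spread); a catalog of 60 random in-frame ORFs of
300–900 bp across 8 genera; ~2 SNP sites per kb.  Per sample and site, total
depth is Poisson(20) and read counts are multinomial with the sample's true
dominant allele at 90%.  A `bias_fraction` (10%) of sites is planted as
group-differential: each day-0 sample is dominant for the pre-allele with
probability 0.9, each later sample for the post-allele with probability 0.9
(the strong-effect condition used for recovery benchmarks).  Half the
planted sites are constructed to be protein-changing, with the effect class
verified against the translation table at generation time so truth labels
are exact.  One planted pathway contains every gene carrying a planted
nonsynonymous site (the over-representation made deterministic, so the
enrichment benchmark has an unambiguous target); two reference strains copy
the post- and pre-intervention alleles respectively, the rest draw random
bases at 50–95% site coverage.  All randomness flows from one seeded
generator; identical configs give byte-identical files.

What the simulator does *not* model — strain mixtures within a sample,
alignment and mapping artefacts, depth correlation along genes, compositional
abundance shifts — means passing recovery benchmarks demonstrates the
correctness of the decision rules and statistics, not performance on real
metagenomes.

## Problem sizes and determinism

The bundled analyses and benchmarks run at desk scale (60 genes, ~78 sites,
106 samples; 5–10 seeds for pooled recovery metrics), chosen so the whole
workflow re-runs from scratch in seconds while every group-size-dependent
rule (60% of 17/19 subjects, 70% of sites, paired day-0/day-30 designs) is
exercised at the study's real cohort sizes.  Every stage is deterministic
given its seed: re-running the pipeline with the same inputs and seed yields
byte-identical outputs (checked via the content-hash manifest).

## Known limitations

- The per-individual dominance rule (majority allele) and the group-consensus
  construction are documented choices; the original study's exact
  supplementary definitions are not public, so other readings (e.g.
  depth-weighted dominance) are possible.
- The enrichment background (SNP-carrying genes) and test (hypergeometric)
  are standard defaults, not a verified match to any particular tool.
- Mapping catalog sites onto strain genomes is consumed as an explicit input
  (or the exact flank-search helper); no aligner is embedded, so divergent
  genomes with no exact 31-mer match around a site come out MISSING.
- The internal NJ tree carries no bootstrap support; ML tree building is
  delegated to external tools via the exported alignment.
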