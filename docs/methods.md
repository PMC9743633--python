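# Methods

## Units of analysis

Everything is gene-scoped. A gene model is the union of its isoform
transcription spans, keyed by (symbol, chromosome) so duplicated symbols on
different chromosomes stay distinct. Coordinates are 0-based half-open
internally; VCF input/output uses the native 1-based convention and BED the
half-open one. Only biallelic SNPs are analysed: non-SNP or multi-allelic
records, and sites on sex chromosomes (configurable), are dropped with a
logged count. Somatic records are restricted to SNVs; indels are logged and
skipped, since the site model has no representation for them.

The elementary unit is the phased haplotype copy at a gene. A copy is
Neanderthal-introgressed iff it carries the archaic allele at ≥ 1 tag SNP
inside the gene span; with ≥ 1 tag genotype observed and no archaic allele
it is modern; with no observed tag genotype the sample is excluded at that
gene (absence of evidence is not evidence of a modern haplotype). Genes
with no tag SNP in the data are flagged unclassifiable and never enter any
test family.

## Tag SNPs

A tag SNP carries an archaic and a modern allele, a record of which archaic
reference genomes the allele matches, and the archaic-allele frequency in
an outgroup panel. Curation keeps alleles that match the requested archaic
reference (Neanderthal by default) and have outgroup frequency ≤ 0.01. The
0.01 default is a conventional reading of "nearly absent" — the exact
upstream cutoff for such panels is generally not recoverable — and it is an
explicit parameter everywhere it is used. When a genotype panel VCF is
supplied instead of precomputed frequencies, the frequency is the
archaic-allele count over called alleles, and absence from the panel counts
as frequency 0. Specificity of an allele (e.g. Neanderthal-specific vs
shared archaic) is reported as specific/shared/unknown depending on whether
a second archaic reference was queried.

## Somatic provenance

Somatic mutations can enter two ways: already merged into the phased VCF
(site-level `SOMATIC` INFO flag, or a per-sample `SM` FORMAT field phased
like GT — the only representation that survives a write/read round trip
bit-exactly when a somatic site coincides with a germline polymorphism), or
as per-patient somatic VCFs matched on (chrom, pos, ref, alt). In the
latter case a mutation is attached to the single haplotype copy of its
patient carrying the alternate allele; records whose patient carries zero
or two alternate copies cannot be placed on one haplotype and are skipped
with a log entry.

## Test families and their conventions

- **Per-gene somatic enrichment.** The contingency unit is the haplotype
  copy with a *binary* has-somatic indicator (a copy with three mutations
  contributes one); the mutation *ratio* below uses raw counts. Genes need
  ≥ 5 Neanderthal copies to be tested. Fisher's exact test is two-sided
  (the hypothesis is "different", not "higher"); the direction of the
  difference is reported separately. The two-sided p follows the
  probability-mass rule (sum of same-margin tables with probability ≤ the
  observed table's), and the reported odds ratio is the sample odds ratio
  ad/bc.
- **Somatic mutation ratio.** Per individual, over the genes with ≥ 1
  introgressed copy anywhere in the cohort:
  (m_N/L_N)/(m_M/L_M). Haplotype "length" is the gene-span length summed
  over the copies so labelled — classification is gene-scoped here and true
  introgressed-segment lengths are not observable from exome-scale input —
  so the ratio is exact when mutation rates are uniform within genes, which
  is how the simulator generates data; on real data it inherits the usual
  gene-span approximation. Samples with no Neanderthal length, no modern
  length or zero modern mutations have an undefined ratio and are excluded
  from summaries (zero ratios are likewise excluded from the log-scale
  summary and remain visible in the per-sample table). Rates are reported
  in mutations/Mb and compared Neanderthal-vs-modern with a one-sided
  unpaired Wilcoxon rank-sum test, treating the two per-sample rate vectors
  as independent samples; a paired signed-rank alternative is one flag away
  for users who prefer matched comparisons.
- **Consequence severity.** Disruptive = VEP IMPACT HIGH; everything else
  (MODERATE/LOW/MODIFIER) is non-disruptive. The unit is the somatic
  mutation. Duplicate (variant, gene) annotation rows collapse to the most
  severe impact; mutations with no annotation for their gene count as
  MODIFIER, matching the annotator's default for unclassified records. By
  default the tested universe is the genes that showed nominally
  significant Neanderthal-direction somatic enrichment.
- **ASE.** Site fractions are archaic reads over total; per (sample, gene,
  tissue) the *unweighted* mean over that sample's heterozygous tag sites
  is used (weighting by depth would let one deep site dominate the gene
  summary, and the per-site minimum depth already bounds the noise).
  Filters: total depth ≥ 10 per site; genes need ≥ 5 heterozygous
  (sample, site) observations summed across samples. Heterozygosity is
  taken from the germline phased VCF when one is supplied, never inferred
  from the read counts. Any mapping-bias correction (e.g. read re-mapping)
  is an upstream property of the count tables. Tumor-vs-normal tests are
  per-gene two-sided rank-sum on per-sample fractions, restricted to genes
  present in both cohorts, with ≥ 3 samples per side.
- **Expression.** Counts-per-million without compositional normalisation
  (entry / library size × 10⁶) — the minimal scaling appropriate for
  within-gene group comparisons; log2(CPM+1) is available for plotting.
  Carrier groups (≥ 1 archaic allele at the gene) are compared with a
  two-sided rank-sum test when both groups have ≥ 2 samples, otherwise
  reported descriptively; significance bands ns/*/**/*** at
  0.05/0.01/0.001.
- **Cohort comparison.** Carrier calls are phase-free. Only tag sites
  genotyped in both cohorts are used. The 2×2 χ² is computed with and
  without the Yates continuity correction (the correction is the single
  point of divergence between common statistical environments); the
  corrected variant is the headline column by default. Genes where carrier
  status is fixed across both cohorts are reported untested and stay out of
  the Bonferroni family.
- **Multiple testing.** Bonferroni only, with the divisor equal to the
  number of tests actually performed in the family.

## Statistical kernels

Fisher's exact test and the rank-sum test delegate to scipy
(`fisher_exact`, `mannwhitneyu`); the rank-sum switches from exact null
enumeration to the normal approximation with midranks, tie correction and
continuity correction when the pooled sample exceeds 20 observations or
contains ties. The 2×2 χ² is computed in closed form
N(|ad−bc|−c₀)²/(r₁r₂c₁c₂) with c₀ = min(N/2, |ad−bc|) under the Yates
option, so degenerate margins are reported as untested rather than raising.
The test suite checks all three against independent oracles: exact
rational hypergeometric enumeration, exhaustive rank assignments, and
Monte-Carlo permutation for tied data.

## The simulator

`SimulationConfig` defaults describe a liver-cancer-like desk-scale study:
100 cases, 100 controls, 50 unaffected expression samples; 200 genes of
50 kb with 4 tag SNPs each; per-haplotype introgression frequency 0.15;
modern somatic rate 10⁻⁶ per bp per copy (≈ 1 mutation/Mb, the scale
reported for hepatocellular tumors); ASE depth 30; negative-binomial
expression with size 10 and lognormal library factors (σ = 0.2). Effects
are planted per gene: a somatic-rate multiplier ρ on introgressed copies,
an ASE shift δ of the archaic-read probability away from 0.5 in tumor, a
multiplicative carrier expression effect, and a case-minus-control carrier
frequency difference. All tag sites of a gene flip together on an
introgressed copy — introgression is simulated at the unit the pipeline
analyses — so there is no linkage between genes, no recombination, no
demography, and no read-level error model. Consequently the tests
demonstrate correctness of the statistical machinery and calibration under
the assumed generative structure, not robustness to phasing errors,
incomplete tagging, mapping bias or population structure, none of which the
generator produces. Everything derives from one `numpy` generator seeded by
`seed`; equal seeds give byte-identical output files (writers emit no
timestamps).

## Calibration and recovery experiments

The acceptance suite and `scripts/acceptance.py` use explicit study
designs, chosen for adequate expected counts rather than strict realism:

- *Null calibration*: 200 genes, 100 cases/100 controls/50 unaffected,
  introgression frequency 0.3 and somatic rate 7×10⁻⁶/bp, making the
  per-copy somatic probability ≈ 0.3 so every Fisher margin is well
  populated — at ≈ 1 mutation/Mb the exact test's discreteness would make
  its realized size uninformative. Each family's fraction of raw p < 0.05
  is checked against the binomial 99% envelope around 0.05; for the χ²
  family the envelope applies to the uncorrected Pearson variant, the
  nominally calibrated one, while the Yates variant is only bounded above
  (it is conservative by construction). The per-sample log₁₀ somatic ratio
  must have its sign-test 99% confidence interval for the median covering
  0.
- *Somatic recovery*: ρ = 5 at the same design (≈ 60 introgressed copies
  per gene, ≥ 10⁴ somatic mutations in aggregate); ≥ 80% of genes must
  reach raw p < 0.05 and the median per-sample ratio must land within 20%
  of ρ.
- *ASE recovery*: 20 replicates of 200 genes (50 tumor / 25 normal
  samples), δ = 0.2 planted in 4 genes; the planted genes must occupy the
  top four p-values in ≥ 90% of replicates.
- *Determinism*: two full simulate-plus-pipeline runs from one seed must
  produce byte-identical TSVs.

## Known limitations

Gene-span lengths stand in for introgressed-segment lengths in the
mutation ratio; tag-SNP discovery itself (S*/Sprime-style inference) is out
of scope — tag sets are consumed, not inferred; no FDR-style correction is
offered (Bonferroni only); the CLI's `run-all` expects the simulator's file
layout, while arbitrary file layouts go through the per-stage subcommands
or the Python API.
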