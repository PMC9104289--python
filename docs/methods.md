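# Methods

This note documents the models and procedures implemented in `cohortvar`,
the defaults chosen where the underlying conventions are genuinely open,
and what the synthetic-data experiments do and do not demonstrate.

## Allele counting and site filters

For a genotype cohort, a site's alternate allele count is the sum of
dosages over called genotypes, the allele number is twice the number of
called samples, and carriers are individuals with at least one alternate
allele. Two filters mirror standard joint-genotyping practice: sites with
a genotyping rate below 90% (configurable) and sites invariant in the
cohort are dropped at read time. Frequency-only cohorts (AC/AN INFO
without genotype columns, the gnomAD release style) are accepted;
carrier-based operations raise on them rather than guessing.

Internal coordinates are 1-based inclusive everywhere (the VCF
convention); BED inputs are converted at the boundary and the conversion
is exact and round-trips. Multiallelic records are rejected with advice
to decompose upstream — normalisation is a solved upstream problem and
re-implementing it would only invite disagreement with `bcftools norm`.

## Frequency tiers and singletons

Tier boundaries are closed on the inner tier so every frequency maps to
exactly one tier: af > 0.5% / 0.1% ≤ af ≤ 0.5% / af < 0.1%. "Common"
(MAF ≥ 1%) for spectrum reporting and "MAF > 1%" for F_ST pruning are
deliberately distinct thresholds with distinct config keys — one is
closed, one strict. A singleton is defined by one carrier *individual*,
not AC = 1, so a homozygous-alternate private variant still counts as one
singleton. Reported percentages round half away from zero at the printed
precision (two decimals for MAF-like values, one for cohort fractions).

## Rare pathogenic selection

A variant is pathogenic when its clinical-significance label contains
`Pathogenic` or `Likely_pathogenic` and no conflicting interpretation.
Confidence follows the standard ClinVar star scheme: 0–1 stars → tier 1,
two stars (criteria provided, multiple submitters, no conflicts) →
tier 2, expert panel → tier 3, practice guideline → tier 4; unknown
review statuses fall to tier 1 with a warning. Variants absent from the
comparator database are treated as rare and retained (absence from a
30k-genome panel is itself evidence of rarity) but flagged, so a stricter
analysis can drop them.

## Gene and panel burden

The tested unit is the gene region: CDS bounds ± 5 kb, strand-independent,
clipped at position 1. Variants in scope are HIGH/MODERATE/MODIFIER
impact (LOW excluded — synonymous-class variation is not a plausible
recessive-disease allele but regulatory MODIFIER variants are in scope)
and pathogenic per the rule above. Cumulative counts per gene use
AN = 2 × cohort size for genotype cohorts. For frequency-only
comparators the per-variant allele numbers differ site to site; we use
the median AN over the gene's selected sites (falling back to 2 × the
declared cohort size when the gene has no sites in that cohort). No
published convention exists for this harmonisation; the median is robust
to single low-call-rate sites and keeps the 2×2 margins integral.

Each gene with pathogenic variation in at least one cohort gets a
two-sided Fisher exact test; BH runs once across all tested genes. A
site overlapping two gene regions contributes fully to both — gene tests
are therefore not independent, which is documented rather than corrected,
matching the per-gene FDR convention. Genes with more than 10% of the
canonical transcript below 20× depth are excluded (strict inequality;
coverage 0.10 exactly is retained).

Panels sum member-gene allele counts with site-level de-duplication (a
variant inside two member genes counts once). The per-panel correction
for gene count is implemented as a Bonferroni-style multiplication of the
panel's Fisher p by its number of genes, capped at 1, before BH across
panels. Alternatives (e.g. correcting within-panel minimum p) exist; the
multiplication is the most conservative reading and keeps panel q-values
comparable across panel sizes.

Fisher's exact test and BH are delegated to `scipy` and `statsmodels`;
the test suite holds both to independent oracles (exhaustive
hypergeometric enumeration for every 2×2 table up to N = 30 plus sampled
tables to N = 200; hand step-up vectors for BH).

## SV quality and loss-of-function rules

Quality gates follow the Smoove author recommendations: heterozygous
calls need mean split-read het quality ≥ 3; deletions must show a depth
drop (DHFFC < 0.7) and duplications a depth gain (DHFFC > 1.25); at
least one split read per allele is required; break-end records are
excluded as biologically uncertain. The filter is idempotent and
order-independent.

LoF rules: a deletion is LoF on any exon overlap; a duplication
additionally requires both breakpoints inside the gene; an inversion
requires exon overlap and at least one breakpoint inside the gene. "Inside
the gene" means the CDS interval, inclusive at both bounds — the LoF
criteria concern gene bodies, not the ± 5 kb burden flank. Exon overlap is
also required for single-breakpoint inversions, the consistent reading of
the rule set.

Per-gene cumulative LoF SV frequency sums allele frequencies of LoF SVs
below the 1% cap, applied per cohort independently (an SV common in one
cohort can still count in the other, where it is rare). No significance
test is attached: SV callers and genotypers differ too much between
datasets for a calibrated test, so the output is the descriptive
frequency difference plus a complex-artifact flag raised when a gene's
cumulative frequency exceeds 10% — many overlapping rare heterozygous
calls piling far above any individual SV's frequency are characteristic
of one mis-genotyped complex event.

## Weir–Cockerham F_ST

Per biallelic site the two-level variance components are

    a — among populations, b — among individuals within populations,
    c — within individuals (half the average heterozygosity),

computed from per-population sample sizes, alternate-allele frequencies
and observed heterozygote proportions (HWE-expected heterozygosity is
substituted, with a warning, for frequency-only cohorts). The multi-site
estimate is the ratio of sums Σa / Σ(a+b+c) — the standard
variance-component convention, preferred to a mean of per-site ratios
because per-site denominators can be tiny or zero. Monomorphic-overall
sites are undefined and excluded; negative estimates are reported as
computed, never truncated. "1000-SNP sliding windows" default to
non-overlapping 1000-site blocks (step = window); a step flag enables
true sliding. The correctness anchor is an independent nested-ANOVA
derivation of the same estimator (mean squares over the explicit allele
table), which the closed-form components match exactly in tests.

## Synthetic data: what it emulates, what it does not

The generator draws unrelated diploids with per-site HWE binomial
dosages (`dosage ~ Binomial(2, f)`) — no linkage disequilibrium, no
relatedness, no sequencing error. Defaults define the study scale: a
1076-diploid genotype cohort against a 16,000-diploid frequency-only
comparator; 50 autosomal-recessive genes of 20 kb CDS with five exons;
three pathogenic sites per gene splitting the gene's cumulative
frequency 0.6/0.3/0.1 (a dominant founder-style allele plus minor ones);
a null cumulative pathogenic frequency of 0.2% per gene, typical of
recessive-disease gene carrier burden; review-status and impact mixes
matching observed ClinVar proportions (predominantly one- and two-star
assertions). SV lengths are log-normal with modes near 300 bp (DEL),
200 bp (DUP) and 1.5 kb (INV), matching reported SV length peaks; quality
fields are drawn so a configured fraction fails each gate, recorded in
the truth table. F_ST scenarios use the Balding–Nichols model — each
population's frequency Beta-distributed about a uniform ancestral
frequency with variance θ·p(1−p) — because it is the simplest model with
a closed-form target θ.

Passing tests on these data show the *statistical machinery* is
correct and calibrated at the study's sample sizes. They do not show
robustness to real-data pathologies: LD between sites (which inflates
the effective number of tests), annotation errors, population
stratification within a cohort, caller-specific SV breakpoint noise, or
reference-bias differences between cohorts.

## Numerical and scale choices

Simulation-based checks run at sizes chosen to make Monte-Carlo error
small relative to the tolerances: burden power and null FDR use 100
replicates of the full two-cohort draw (binomial SE ≈ 3% on a 90% power
bound); F_ST recovery uses 10⁵ sites at 500/500 diploids (window-level
SE well under the ±0.01 tolerance). Fisher oracle equivalence is
exhaustive for all tables with N ≤ 30 and sampled up to N = 200 —
beyond that, exhaustive enumeration over all tables grows combinatorially
while adding no new code paths. Ties in burden tables are broken by a
stable sort on (p, unit id) so reruns are bitwise identical.

## Known limitations

* No compound-heterozygote or phase-aware logic: burden counts alleles,
  not genotypic configurations, so it measures carrier-allele burden
  rather than expected affected-individual rates.
* The AN harmonisation for frequency-only comparators (median over gene
  sites) is a documented stand-in for unknown upstream conventions.
* Per-individual SV affected length adds overlapping SVs without
  merging; nested calls double-count affected bases.
* The panel gene-count correction is one defensible reading of an
  under-specified procedure; sensitivity to the alternative (no
  multiplication, BH only) can be assessed by comparing `p` and
  `p_gene_corrected` columns in the output.
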