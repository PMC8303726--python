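# Methods

This note documents the statistical model behind each stage, the defaults
and why they are what they are, what the synthetic-data generator does and
does not emulate, and the numerical choices a maintainer would otherwise
have to reverse-engineer.

## Allelic-asymmetry model

At a heterozygous site with `ref` and `alt` read counts, the null model is
`ref ~ Binomial(ref + alt, 1/2)`: with no allele-specific effect and no
mapping bias, reads sample the two alleles equally. The two-sided p-value
doubles the smaller exact tail and caps at 1; for this symmetric null the
rule coincides with the minimum-likelihood convention, and the
implementation is checked against direct integer tail summation for every
total up to 200 (1e−12) and against `scipy.stats.binomtest`.

A site qualifies as heterozygous when the minor allele has ≥ 10 reads
(`min_minor_reads`), applied after summing counts across samples per site
and assay. Pooling is a deliberate choice: the combination rule across
donors is otherwise unconstrained, and a pooled binomial maximises power
when effects are shared; a `per-sample` mode is available when donors
should be kept separate.

Event classes use the ref/alt odds ratio at padj ≤ 0.1 (BH): enrichment
when OR ≥ 1.5, depletion when the *reciprocal* ratio is ≥ 1.5. The
literal rule "depletion when OR < 1.5" would label a significant site
with OR = 1.01 as depleted; we treat that as a wording slip and keep the
literal behaviour behind `literal_depletion=True`. Zero counts on either side
get a 0.5 pseudocount on both counts for the ratio only (flagged per
row); the p-value never uses pseudocounts.

Two thresholds coexist by design: the ASB/ASE *join* uses raw binomial
p < 0.1 in both assays (a deliberately permissive gate, since the
predicted-probability filter follows), while *event classification* uses
adjusted padj ≤ 0.1. Both are independent config knobs.

## Evidence combination and scoring

The weighted Stouffer statistic transforms each two-sided p one-sidedly,
`z_i = Φ⁻¹(1 − p_i)`, ignoring effect direction; ASB/ASE direction
concordance is reported (`direction_concordant`) but not enforced, since
a binding change can plausibly suppress or enhance expression. Weights
default to `√coverage` of each test — the standard
information-proportional choice — with an equal-weights mode; the
combination is invariant to rescaling both weights, and equal weights
reproduce the unweighted closed form to 1e−12.

The scoring model is a plain maximum-likelihood logistic regression of
binary eQTL-catalog membership on three features: |log₂FC1| (ChIP),
|log₂FC2| (RNA) and |log₂FC1/FC2| = |log₂FC1 − log₂FC2| (the algebraic
identity on signed log fold changes). It requires ≥ 50 candidates and
both classes; perfect separation raises with advice to refit regularized
rather than silently changing the estimator. Nested fits are compared by
the likelihood-ratio test (χ² = 2Δllf); its null distribution is verified
to be χ²(1) by a 500-seed KS check.

The final panel keeps predicted probability strictly above the cutoff.
The default cutoff 0.1929408 is the published value; `derive_pp_cutoff`
reproduces its construction (minimum score within the top 50 of 100
score-ordered ranks). Rank bins are stable-sorted by (score, site id) and
sized ⌈n/k⌉ for the first n mod k bins, ⌊n/k⌋ after, so bin sizes differ
by at most one. Multiple (site, gene) candidates per site are scored
independently; catalog-overlap counts deduplicate to unique sites.

## Linkage and conditional probability

NHD is computed on rare-allele count vectors, the rare allele being the
matrix-wide minor allele fixed at ingest. Marker discovery checks both
allele orientations (flipping the marker vector to 2 − g) and records
which marker allele predicts the rSNP rare allele; anti-associated pairs
are thereby usable rather than discarded. Two context-specific thresholds
are exposed for the same statistic: 0.001 for pairing panel SNPs with
trait-associated markers, 0.1 for coding-marker discovery.

Carrier conditional probability is read off the 3×3 genotype contingency:
P(target carrier | marker carrier) = Σ cells with both counts ≥ 1 / Σ
cells with marker count ≥ 1. `GenotypeMatrix.from_contingency` expands a
printed table into synthetic individuals so published contingency tables
can be re-ingested and checked through the same code path as simulated
matrices.

## Cohort genotyping and differential expression

Marker reads are routed onto rSNP alleles through each marker's allele
map and added to the direct coverage, at most ten markers in NHD order.
Calls use the minor-fraction rule: heterozygous iff the less-covered
allele holds ≥ 10% of combined reads, homozygous for the more covered
allele otherwise, unknown at zero coverage. Group admission requires ≥ 6
genotyped individuals and ≥ 3 minor-allele carriers (heterozygotes or
rare-allele homozygotes).

Differential expression is a plugin interface keyed by method id. The
built-in `builtin-welch` stand-in normalizes to CPM, takes log₂(CPM+1)
and applies Welch's t per gene with Bonferroni correction at padj < 0.1 —
deliberately simple, calibration-tested (familywise error near nominal
under the null, ≥ 95% detection of a planted 4-fold gene at n = 20/20),
and clearly not a negative-binomial shrinkage estimator; a dedicated DE
package can be registered under its own id without touching callers. When
a per-sample structure label is supplied (e.g. brain regions), structures
are analyzed separately and concatenated.

## Synthetic-data generator

The generator emulates the statistical regimes the pipeline assumes, not
any real dataset's content:

- **Genotypes**: sites in consecutive blocks copy a shared pair of
  haplotype indicators (block MAF uniform in `maf_range`, default
  0.05–0.5) with per-site flip probability `block_mutation_rate`
  (default 0, i.e. perfect within-block proxies). This is the simplest
  structure producing both NHD regimes — near 0 within blocks, near the
  independence expectation across them. It is *not* a coalescent model:
  no recombination gradients, no population structure, no allele-age/
  frequency correlation.
- **Assay counts**: per-sample coverage is negative binomial
  (mean 60, size 10 — overdispersed sequencing coverage); reference reads
  are binomial with p = 0.5 + `reference_bias` at null sites (bias
  default 0, exposed to test robustness since bias mitigation by
  realignment happens upstream) and p = 0.8 at planted rSNPs in both
  assays. Defaults are the end-to-end study conditions: 2,504
  individuals, 19 assay donors, 10,000 sites, 200 planted rSNPs.
- **Catalogs**: eQTL membership 0.5 for planted sites vs 0.1 for null
  sites (GWAS 0.10/0.02) — chosen once to emulate the several-fold
  staged enrichment seen in real catalog overlaps without reproducing
  any download-dependent count.
- **Cohort**: each planted rSNP shifts its own gene's negative-binomial
  expression mean by `eqtl_log2fc` (default 2) per rare-allele copy in a
  40-sample cohort drawn from the opposite end of the panel from the
  assay donors; allele coverage at rSNP sites is sparse (mean 2) and at
  coding markers substantial (mean 30), mimicking non-transcribed
  regulatory sites proxied by expressed markers.

Because planted effects are large and clean, passing recovery tests shows
the machinery is correct, not that real-data power matches: real ASB/ASE
effects are smaller, reference bias is position-dependent, LD is messier,
and catalogs carry their own ascertainment. The geometry (one single-exon
gene per site, SNP in the promoter/5′UTR overlap) exercises every mapping
path but is far simpler than real gene annotation.

## Numerical and scale choices

- Positions are 1-based, intervals 0-based half-open; all conversions go
  through `rsnpscan._coords` and are tested, including minus-strand
  promoter windows.
- Sex chromosomes and mitochondrial DNA are dropped on ingest; an
  optional position mask handles indel-proximity exclusions, since indel
  calls originate upstream of this package.
- p-values of exactly 0/1 entering the z-combination are clamped to
  [1e−300, 1 − 1e−16] with a warning.
- Equal seeds give byte-identical outputs everywhere; the chip and rna
  streams are seeded independently so the two assays are conditionally
  independent given the genotypes.
- Test and acceptance problem sizes (10,000–12,000 sites, 20,000
  observations for parameter recovery, 300–500 seeds for null-
  distribution checks) were chosen as the smallest scales at which the
  Monte-Carlo error is comfortably below the asserted tolerances.

## Known limitations

No beta-binomial overdispersion (a single pooled binomial can be
anti-conservative if donors truly differ), no haplotype phasing or
r²/D′-style LD, no read-level simulation (FASTQ/alignment artifacts,
indels), no sex chromosomes, and the built-in DE stand-in is not a
substitute model for count-based DE inference — it is the interface's
reference implementation.
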