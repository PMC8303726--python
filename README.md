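# rsnpscan

Discovery of **regulatory SNPs (rSNPs)** from paired allele-specific
evidence: ChIP-seq reads that cover the two alleles of a heterozygous site
unequally (allele-specific binding, ASB) and RNA-seq reads that do the same
inside a target gene (allele-specific expression, ASE). A variant showing
both effects on the same gene is a strong candidate for a causal regulatory
polymorphism — the kind of variant GWAS tags but cannot pinpoint.

The package is aimed at computational genomicists who already have per-site
allele-count tables (the output of an alignment + variant-calling workflow)
and want a tested, reproducible implementation of the downstream inference.

## What it computes

Per heterozygous site (minor-allele coverage ≥ 10), an exact two-sided
binomial test of H₀: both alleles equally covered, with BH adjustment and
event classes from the odds ratio (enrichment if ref/alt ≥ 1.5, depletion
for the reciprocal, at padj ≤ 0.1). The degree of asymmetry is |log₂FC|,
FC the ref/alt fold change.

ASB sites are mapped to target genes through strand-aware promoter windows
(TSS −1000/+500 by default) and through enhancer intervals with annotated
target genes; candidates with binomial p < 0.1 in both assays are joined
into (SNP, gene) pairs. Evidence is combined with a weighted Stouffer
z-score,

  z = (w₁z₁ + w₂z₂) / √(w₁² + w₂²),  zᵢ = Φ⁻¹(1 − pᵢ),  wᵢ = √coverageᵢ,

and each candidate is scored by the **predicted probability** of being an
eQTL: a logistic regression of catalog membership on |log₂FC1|, |log₂FC2|
and |log₂FC1/FC2|, exposed as a statsmodels-style Model/Results pair. The
final panel keeps candidates with predicted probability strictly above the
cutoff (default 0.1929408, derivable from the top-50-rank enrichment
trend).

Linkage uses the normalized Hamming distance over rare-allele counts
R ∈ {0,1,2} across individuals,

  NHD(a, b) = Σᵢ |Rᵢₐ − Rᵢᵦ| / Σᵢ (Rᵢₐ + Rᵢᵦ),

with carrier conditional probabilities P(rSNP allele | marker allele) from
3×3 genotype contingency tables. Tightly linked expressed coding markers
(NHD ≤ 0.1, conditional probability ≥ 0.9, top ten by NHD) let an
independent RNA-seq cohort be genotyped *in silico* at non-transcribed
rSNP positions (heterozygous iff the minor allele carries ≥ 10% of
combined coverage), split into genotype groups (≥ 6 individuals, ≥ 3 minor
carriers) and tested for differential expression (pluggable; built-in
Welch-on-log₂CPM stand-in with Bonferroni padj < 0.1).

A synthetic-data module generates every input with the statistical
structure the analysis assumes — haplotype-block LD, binomial allele
counts with optional reference bias, planted ASB/ASE effects and
genotype-driven expression shifts — plus ground-truth labels, so every
stage is testable end to end.

## Worked example

```python
from rsnpscan.simulate import SimulationConfig, generate_study
from rsnpscan.pipeline import run_in_memory

study = generate_study(SimulationConfig(n_individuals=300, n_sites=2000,
                                        n_true_rsnps=60, seed=7))
stages = run_in_memory(study)
print(stages["model_results"].summary().to_string(index=False))
panel = stages["panel"]
```

prints the fitted scoring model in the conventional layout

```
    Parameter  Regression Coefficient  Std. Error  p-Value Sign
    intercept               -5.482148    2.222420 0.013635    *
    |log2FC1|                0.850439    1.183610 0.472441
    |log2FC2|                2.106747    1.293498 0.103372
|log2FC1/FC2|               -0.131435    1.654336 0.936676
```

and the panel table (81 candidates in, 60 kept):

```
     site_id gene_id region_type        asb_p        ase_p    p_combined  predicted_probability
chr1:1105000  G00220    promoter 8.307794e-43 5.675162e-46  1.179550e-86               0.693804
chr1:1280000  G00255    promoter 1.141656e-54 3.026174e-65 1.329565e-117               0.807357
```

Against this simulation's ground truth the panel has precision 1.000 and
recall 1.000 (60/60 planted rSNPs recovered, no false positives): with a
planted allelic fraction of 0.8 at coverage ~60 per sample the binomial
evidence is overwhelming, so the filters are the binding constraint, not
power. The same flow is available from the shell:

```sh
rsnpscan simulate --outdir study/ --seed 7 --n-sites 2000 \
    --n-individuals 300 --n-true-rsnps 60
rsnpscan run-all --config pipeline.yaml --outdir run/
```

Stage subcommands (`asb`, `ase`, `join`, `score`, `link`, `genotype`,
`de`, `annotate`) operate on the intermediate TSVs individually.

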