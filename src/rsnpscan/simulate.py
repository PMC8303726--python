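"""Synthetic-data generator for the full rSNP pipeline.

Emulates the statistical structure of the study designs the pipeline is
built for — a population genotype panel with haplotype-block LD (1000
Genomes scale), paired ChIP-seq/RNA-seq allele-count tables for a small
donor series with planted allele-specific effects, annotation catalogs
enriched for the planted sites, and a genotype-driven expression cohort —
together with ground-truth labels for recovery tests.

Everything is driven by a single :class:`SimulationConfig` and a seed;
equal seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._coords import site_id
from .io import (
    AnnotationCatalog,
    EnhancerRecord,
    GeneModel,
    GenotypeMatrix,
)

ASSAY_EFFECT_FIELD = {"chip": "asb_effect", "rna": "ase_effect"}

#: distance between consecutive SNP sites on the synthetic chromosome;
#: large enough that neighbouring synthetic genes never overlap
SITE_SPACING = 5000

_TISSUES = ("artery", "brain_cortex", "lung", "whole_blood", "liver")


@dataclass
class SimulationConfig:
    """All knobs of the generator, with the study-scale defaults.

    Defaults mirror the data regimes the pipeline targets: a 2504-individual
    genotype panel, 19 paired ChIP/RNA donors, 10,000 candidate sites with
    200 planted regulatory SNPs at allelic fraction 0.8 and mean coverage
    60, and a 40-sample expression cohort with a 2 log2-unit eQTL effect
    per minor-allele copy.
    """

    n_individuals: int = 2504
    n_sites: int = 10_000
    block_size: int = 5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_true_rsnps: int = 200
    asb_effect: float = 0.8
    ase_effect: float = 0.8
    reference_bias: float = 0.0
    coverage_mean: float = 60.0
    coverage_dispersion: float = 10.0
    eqtl_log2fc: float = 2.0
    nb_dispersion: float = 20.0
    seed: int = 0
    # secondary knobs (kept out of the positional core above)
    n_assay_samples: int = 19
    block_mutation_rate: float = 0.0
    eqtl_rate_true: float = 0.5
    eqtl_rate_null: float = 0.1
    gwas_rate_true: float = 0.10
    gwas_rate_null: float = 0.02
    expression_mean: float = 200.0
    n_cohort_samples: int = 40
    rsnp_direct_coverage_mean: float = 2.0
    marker_coverage_mean: float = 30.0

    def __post_init__(self) -> None:
        checks = {
            "n_individuals": self.n_individuals >= 2,
            "n_sites": self.n_sites >= 1,
            "block_size": self.block_size >= 1,
            "maf_range": 0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5,
            "n_true_rsnps": 0 <= self.n_true_rsnps <= self.n_sites,
            "asb_effect": 0.5 < self.asb_effect < 1.0,
            "ase_effect": 0.5 < self.ase_effect < 1.0,
            "reference_bias": 0.0 <= 0.5 + self.reference_bias < 1.0,
            "coverage_mean": self.coverage_mean > 0,
            "coverage_dispersion": self.coverage_dispersion > 0,
            "nb_dispersion": self.nb_dispersion > 0,
            "block_mutation_rate": 0.0 <= self.block_mutation_rate < 0.5,
            "n_assay_samples": 1 <= self.n_assay_samples <= self.n_individuals,
            "n_cohort_samples": 1 <= self.n_cohort_samples <= self.n_individuals,
            "eqtl_rate_true": 0.0 <= self.eqtl_rate_true <= 1.0,
            "eqtl_rate_null": 0.0 <= self.eqtl_rate_null <= 1.0,
            "gwas_rate_true": 0.0 <= self.gwas_rate_true <= 1.0,
            "gwas_rate_null": 0.0 <= self.gwas_rate_null <= 1.0,
            "expression_mean": self.expression_mean > 0,
            "rsnp_direct_coverage_mean": self.rsnp_direct_coverage_mean >= 0,
            "marker_coverage_mean": self.marker_coverage_mean >= 0,
            "seed": isinstance(self.seed, (int, np.integer)) and self.seed >= 0,
        }
        for name, ok in checks.items():
            if not ok:
                raise ValueError(f"invalid SimulationConfig field: {name}")


@dataclass
class TruthSet:
    """Ground truth of one simulation, for recovery tests."""

    true_rsnp_ids: set = field(default_factory=set)
    linked_pairs: set = field(default_factory=set)  # {(marker_id, rsnp_id)}
    true_deg_ids: dict = field(default_factory=dict)  # rsnp_id -> {gene_id}

    def to_json(self, path) -> None:
        payload = {
            "true_rsnp_ids": sorted(self.true_rsnp_ids),
            "linked_pairs": sorted(list(p) for p in self.linked_pairs),
            "true_deg_ids": {k: sorted(v) for k, v in sorted(self.true_deg_ids.items())},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            true_rsnp_ids=set(payload["true_rsnp_ids"]),
            linked_pairs={tuple(p) for p in payload["linked_pairs"]},
            true_deg_ids={k: set(v) for k, v in payload["true_deg_ids"].items()},
        )


def _nb_draw(rng: np.random.Generator, mean, dispersion, size) -> np.ndarray:
    """Negative binomial with mean ``mean`` and size parameter ``dispersion``.

    Variance = mean + mean^2 / dispersion; large dispersion approaches
    Poisson coverage.
    """
    k = dispersion
    p = k / (k + np.asarray(mean, dtype=float))
    return rng.negative_binomial(k, p, size=size)


# ---------------------------------------------------------------------------
# genotypes


def generate_genotype_matrix(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, TruthSet]:
    """Simulate a population genotype panel with haplotype-block LD.

    Sites are grouped into consecutive blocks of ``block_size``. Within a
    block every site is copied from a shared pair of haplotype indicators
    (rare-allele frequency drawn from ``maf_range``), then flipped
    per-site per-haplotype with probability ``block_mutation_rate``; the
    normalized Hamming distance is therefore near zero within blocks and
    near the independence expectation across blocks.

    One planted regulatory SNP is placed in each of ``n_true_rsnps``
    distinct blocks; its block-mates are recorded as linked coding
    markers in the truth set.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_sites
    n_blocks = -(-m // config.block_size)
    block_of = np.arange(m) // config.block_size

    lo, hi = config.maf_range
    block_maf = rng.uniform(lo, hi, size=n_blocks)
    # two haplotypes per individual, one indicator per block
    hap1 = rng.random((n, n_blocks)) < block_maf
    hap2 = rng.random((n, n_blocks)) < block_maf
    h1 = hap1[:, block_of]
    h2 = hap2[:, block_of]
    if config.block_mutation_rate > 0:
        mu = config.block_mutation_rate
        h1 = h1 ^ (rng.random((n, m)) < mu)
        h2 = h2 ^ (rng.random((n, m)) < mu)
    values = h1.astype(np.int8) + h2.astype(np.int8)

    positions = SITE_SPACING * (np.arange(m) + 1)
    sites = pd.DataFrame(
        {
            "site_id": [site_id("chr1", int(p)) for p in positions],
            "chrom": "chr1",
            "pos": positions,
            "ref": "A",
            "alt": "G",
        }
    )
    matrix = GenotypeMatrix(
        [f"ind{i:04d}" for i in range(n)], sites, values
    )

    truth = TruthSet()
    if config.n_true_rsnps:
        chosen_blocks = rng.choice(
            n_blocks, size=config.n_true_rsnps, replace=False
        )
        ids = np.asarray(matrix.site_ids)
        for b in chosen_blocks:
            members = np.flatnonzero(block_of == b)
            rsnp = ids[members[0]]
            truth.true_rsnp_ids.add(rsnp)
            for j in members[1:]:
                truth.linked_pairs.add((ids[j], rsnp))
    return matrix, truth


# ---------------------------------------------------------------------------
# assay allele counts


def generate_allele_counts(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    assay: str,
    truth: TruthSet | None = None,
    samples: list[str] | None = None,
) -> tuple[pd.DataFrame, TruthSet]:
    """Per-sample allele counts at heterozygous sites for one assay.

    Total coverage is negative binomial (``coverage_mean``,
    ``coverage_dispersion``); the reference-read count is binomial with
    success probability 0.5 + ``reference_bias`` at null sites and the
    planted allelic fraction (``asb_effect`` for chip, ``ase_effect`` for
    rna) at true rSNP sites. ASB and ASE effects co-occur at
    ``truth.true_rsnp_ids``.
    """
    if assay not in ASSAY_EFFECT_FIELD:
        raise ValueError(f"assay must be 'chip' or 'rna', got {assay!r}")
    truth = truth if truth is not None else TruthSet()
    if samples is None:
        k = min(config.n_assay_samples, genotypes.n_individuals)
        samples = genotypes.individuals[:k]
    # distinct stream per assay so chip and rna counts are independent
    rng = np.random.default_rng([config.seed, {"chip": 101, "rna": 202}[assay]])

    sample_idx = [genotypes.individuals.index(s) for s in samples]
    het = genotypes.values[sample_idx, :] == 1  # (n_samples, n_sites)
    effect = getattr(config, ASSAY_EFFECT_FIELD[assay])
    ids = np.asarray(genotypes.site_ids)
    is_true = np.isin(ids, sorted(truth.true_rsnp_ids))
    p_ref = np.where(is_true, effect, 0.5 + config.reference_bias)

    rows = []
    for si, sample in enumerate(samples):
        js = np.flatnonzero(het[si])
        if js.size == 0:
            continue
        total = _nb_draw(
            rng, config.coverage_mean, config.coverage_dispersion, js.size
        )
        total = np.maximum(total, 1)  # a covered het site has >= 1 read
        ref = rng.binomial(total, p_ref[js])
        sub = genotypes.sites.iloc[js]
        rows.append(
            pd.DataFrame(
                {
                    "chrom": sub["chrom"].to_numpy(),
                    "pos": sub["pos"].to_numpy(),
                    "ref": sub["ref"].to_numpy(),
                    "alt": sub["alt"].to_numpy(),
                    "ref_count": ref,
                    "alt_count": total - ref,
                    "sample": sample,
                }
            )
        )
    if rows:
        df = pd.concat(rows, ignore_index=True)
    else:
        df = pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "ref_count", "alt_count", "sample"]
        )
    df["assay"] = assay
    df["site_id"] = [site_id(c, int(p)) for c, p in zip(df["chrom"], df["pos"])]
    df["total"] = df["ref_count"] + df["alt_count"]
    return df, truth


# ---------------------------------------------------------------------------
# gene models / enhancers / catalogs


def generate_gene_models(genotypes: GenotypeMatrix) -> list[GeneModel]:
    """One single-exon gene per site, alternating strand.

    Each SNP sits 50 bp downstream of its gene's TSS, i.e. inside both the
    promoter window and the 5' UTR, so the same site carries ChIP (promoter
    binding) and RNA (transcribed) evidence — the geometry the joint
    ASB/ASE analysis assumes for promoter-proximal regulatory SNPs.
    """
    genes = []
    for i, row in genotypes.sites.iterrows():
        pos0 = int(row.pos) - 1
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            t0 = pos0 - 50
            exons = [(t0, t0 + 1500)]
            utr5 = [(t0, t0 + 200)]
            cds = [(t0 + 200, t0 + 1200)]
            utr3 = [(t0 + 1200, t0 + 1500)]
        else:
            t0 = pos0 + 50
            exons = [(t0 - 1499, t0 + 1)]
            utr5 = [(t0 - 199, t0 + 1)]
            cds = [(t0 - 1199, t0 - 199)]
            utr3 = [(t0 - 1499, t0 - 1199)]
        genes.append(
            GeneModel(
                gene_id=f"G{i:05d}",
                chrom=row.chrom,
                strand=strand,
                tss=t0 + 1,
                exons=exons,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
            )
        )
    return genes


def generate_enhancers(
    genotypes: GenotypeMatrix, every: int = 10
) -> list[EnhancerRecord]:
    """Enhancer intervals over every ``every``-th site, targeting the
    neighbouring site's gene (a distant target)."""
    recs = []
    n = genotypes.n_sites
    for i, row in genotypes.sites.iterrows():
        if i % every == 3 and i + 1 < n:
            pos0 = int(row.pos) - 1
            recs.append(
                EnhancerRecord(row.chrom, pos0 - 100, pos0 + 100, f"G{i + 1:05d}")
            )
    return recs


def generate_catalogs(
    genotypes: GenotypeMatrix, config: SimulationConfig, truth: TruthSet
) -> tuple[AnnotationCatalog, AnnotationCatalog]:
    """eQTL and GWAS catalogs with membership enriched at planted sites.

    Membership is Bernoulli per site: rate ``eqtl_rate_true`` /
    ``gwas_rate_true`` for planted rSNPs and the corresponding null rate
    elsewhere. eQTL entries get a tissue label for the tissue-normalized
    summaries.
    """
    rng = np.random.default_rng([config.seed, 7_001])
    ids = np.asarray(genotypes.site_ids)
    is_true = np.isin(ids, sorted(truth.true_rsnp_ids))

    p_eqtl = np.where(is_true, config.eqtl_rate_true, config.eqtl_rate_null)
    in_eqtl = rng.random(ids.size) < p_eqtl
    eqtl_sites = ids[in_eqtl]
    eqtl = pd.DataFrame(
        {
            "site_id": eqtl_sites,
            "tissue": rng.choice(_TISSUES, size=eqtl_sites.size),
        }
    )

    p_gwas = np.where(is_true, config.gwas_rate_true, config.gwas_rate_null)
    in_gwas = rng.random(ids.size) < p_gwas
    gwas = pd.DataFrame({"site_id": ids[in_gwas]})
    return AnnotationCatalog("eqtl", eqtl), AnnotationCatalog("gwas", gwas)


# ---------------------------------------------------------------------------
# expression cohort


def generate_cohort_counts(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    truth: TruthSet,
    samples: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """Cohort RNA-seq: a gene-by-sample count matrix plus allele coverages.

    Each planted rSNP drives its own site's gene: the gene's negative-
    binomial mean is shifted by ``eqtl_log2fc`` log2 units per minor-allele
    copy the individual carries at the rSNP. Those genes are recorded in
    ``truth.true_deg_ids``.

    Allele coverages are emitted per sample at rSNP sites (sparse direct
    coverage, mean ``rsnp_direct_coverage_mean`` — regulatory sites are
    mostly non-transcribed) and at their linked coding-marker sites (mean
    ``marker_coverage_mean``). Heterozygous individuals split reads
    binomially between alleles; homozygotes put all reads on one allele.
    """
    if config.n_true_rsnps and config.eqtl_log2fc != 0 and not truth.true_rsnp_ids:
        raise ValueError("truth set carries no planted rSNPs")
    rng = np.random.default_rng([config.seed, 9_001])
    if samples is None:
        # cohort drawn from the far end of the panel: disjoint from the
        # 19 assay donors by construction
        k = min(config.n_cohort_samples, genotypes.n_individuals)
        samples = genotypes.individuals[-k:]
    sample_idx = np.array([genotypes.individuals.index(s) for s in samples])

    ids = np.asarray(genotypes.site_ids)
    index_of = {s: i for i, s in enumerate(ids)}
    gene_ids = [f"G{i:05d}" for i in range(genotypes.n_sites)]

    # expression means: baseline, shifted per minor copy at the driving rSNP
    log2_shift = np.zeros((len(samples), genotypes.n_sites))
    for rsnp in sorted(truth.true_rsnp_ids):
        j = index_of[rsnp]
        g = genotypes.values[sample_idx, j].astype(float)
        log2_shift[:, j] = config.eqtl_log2fc * g
        if config.eqtl_log2fc != 0:
            truth.true_deg_ids.setdefault(rsnp, set()).add(gene_ids[j])
    mean = config.expression_mean * 2.0 ** log2_shift
    counts = _nb_draw(rng, mean, config.nb_dispersion, mean.shape)
    counts_df = pd.DataFrame(counts.T, index=gene_ids, columns=samples)
    counts_df.index.name = "gene_id"

    # allele coverages at rSNP and marker sites
    cov_sites: dict[str, float] = {
        r: config.rsnp_direct_coverage_mean for r in sorted(truth.true_rsnp_ids)
    }
    for marker, _ in sorted(truth.linked_pairs):
        cov_sites.setdefault(marker, config.marker_coverage_mean)
    rows = []
    for sid, cov_mean in cov_sites.items():
        j = index_of[sid]
        g = genotypes.values[sample_idx, j]
        if cov_mean <= 0:
            total = np.zeros(len(samples), dtype=int)
        else:
            total = _nb_draw(rng, cov_mean, config.coverage_dispersion, len(samples))
        # het individuals must show both alleles when the site is covered
        rare = np.where(
            g == 1,
            rng.binomial(total, 0.5),
            np.where(g == 2, total, 0),
        )
        site_row = genotypes.sites.iloc[j]
        rare_is_alt = site_row["rare_allele"] == site_row["alt"]
        alt_count = rare if rare_is_alt else total - rare
        rows.append(
            pd.DataFrame(
                {
                    "sample": samples,
                    "site_id": sid,
                    "chrom": site_row["chrom"],
                    "pos": site_row["pos"],
                    "ref": site_row["ref"],
                    "alt": site_row["alt"],
                    "ref_count": total - alt_count,
                    "alt_count": alt_count,
                }
            )
        )
    if rows:
        coverage_df = pd.concat(rows, ignore_index=True)
    else:
        coverage_df = pd.DataFrame(
            columns=["sample", "site_id", "chrom", "pos", "ref", "alt",
                     "ref_count", "alt_count"]
        )
    return counts_df, coverage_df, truth


# ---------------------------------------------------------------------------
# one-call convenience


def generate_study(config: SimulationConfig) -> dict:
    """Generate every pipeline input for one simulated study.

    Returns a dict with genotypes, truth, chip/rna allele counts, gene
    models, enhancers, eqtl/gwas catalogs, cohort counts and coverages.
    """
    genotypes, truth = generate_genotype_matrix(config)
    chip, _ = generate_allele_counts(genotypes, config, "chip", truth)
    rna, _ = generate_allele_counts(genotypes, config, "rna", truth)
    genes = generate_gene_models(genotypes)
    enhancers = generate_enhancers(genotypes)
    eqtl, gwas = generate_catalogs(genotypes, config, truth)
    cohort_counts, cohort_cov, truth = generate_cohort_counts(
        genotypes, config, truth
    )
    return {
        "config": config,
        "genotypes": genotypes,
        "truth": truth,
        "chip_counts": chip,
        "rna_counts": rna,
        "gene_models": genes,
        "enhancers": enhancers,
        "eqtl_catalog": eqtl,
        "gwas_catalog": gwas,
        "cohort_counts": cohort_counts,
        "cohort_coverage": cohort_cov,
    }


def write_study(study: dict, outdir) -> None:
    """Write all generated inputs in the formats the pipeline reads."""
    from pathlib import Path

    from . import io as io_mod

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_mod.write_allele_counts(study["chip_counts"], outdir / "chip_counts.tsv")
    io_mod.write_allele_counts(study["rna_counts"], outdir / "rna_counts.tsv")
    io_mod.write_gene_models(study["gene_models"], outdir / "gene_models.tsv")
    io_mod.write_enhancers(study["enhancers"], outdir / "enhancers.bed")
    io_mod.write_catalog(study["eqtl_catalog"], outdir / "eqtl_catalog.tsv")
    io_mod.write_catalog(study["gwas_catalog"], outdir / "gwas_catalog.tsv")
    io_mod.write_genotypes_tsv(study["genotypes"], outdir / "genotypes.tsv")
    study["cohort_counts"].to_csv(outdir / "cohort_counts.tsv", sep="\t")
    study["cohort_coverage"].to_csv(
        outdir / "cohort_coverage.tsv", sep="\t", index=False
    )
    study["truth"].to_json(outdir / "truth.json")
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(asdict(study["config"]), fh, indent=1, default=list)
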