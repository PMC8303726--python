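"""Generator contracts: determinism, LD regimes, null calibration, read-back."""

import itertools

import numpy as np
import pytest

from rsnpscan import allelic
from rsnpscan.linkage import nhd
from rsnpscan.simulate import (
    SimulationConfig,
    generate_allele_counts,
    generate_cohort_counts,
    generate_genotype_matrix,
    generate_study,
)


def brute_force_mean_nhd(values: np.ndarray) -> float:
    """Oracle: average pairwise NHD over all site pairs by explicit loops."""
    dists = []
    for i, j in itertools.combinations(range(values.shape[1]), 2):
        a, b = values[:, i], values[:, j]
        denom = a.sum() + b.sum()
        if denom == 0:
            continue
        dists.append(np.abs(a - b).sum() / denom)
    return float(np.mean(dists))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_individuals", 1),
            ("asb_effect", 0.4),
            ("ase_effect", 1.0),
            ("maf_range", (0.0, 0.5)),
            ("maf_range", (0.4, 0.6)),
            ("coverage_mean", 0),
            ("block_size", 0),
            ("n_true_rsnps", -1),
        ],
    )
    def test_invalid_field_named(self, field, value):
        with pytest.raises(ValueError, match=field):
            SimulationConfig(**{field: value})


class TestGenotypeGeneration:
    def test_perfect_within_block_copying(self):
        cfg = SimulationConfig(
            n_individuals=100, n_sites=2, block_size=2,
            maf_range=(0.3, 0.3), n_true_rsnps=0, seed=3,
        )
        m, _ = generate_genotype_matrix(cfg)
        ids = m.site_ids
        assert nhd(m.site_column(ids[0]), m.site_column(ids[1])) == 0.0

    def test_determinism(self):
        cfg = SimulationConfig(n_individuals=50, n_sites=30, seed=1, n_true_rsnps=5)
        m1, t1 = generate_genotype_matrix(cfg)
        m2, t2 = generate_genotype_matrix(cfg)
        np.testing.assert_array_equal(m1.values, m2.values)
        assert t1.true_rsnp_ids == t2.true_rsnp_ids
        assert t1.linked_pairs == t2.linked_pairs

    def test_independent_sites_match_nhd_oracle(self):
        cfg = SimulationConfig(
            n_individuals=5000, n_sites=12, block_size=1,
            maf_range=(0.2, 0.2), n_true_rsnps=0, seed=9,
        )
        m, _ = generate_genotype_matrix(cfg)
        oracle = brute_force_mean_nhd(m.values.astype(int))
        # library NHD averaged the same way must agree with the oracle,
        # and independent sites sit near the independence expectation
        lib = np.mean(
            [
                nhd(m.values[:, i], m.values[:, j])
                for i, j in itertools.combinations(range(m.n_sites), 2)
            ]
        )
        assert lib == pytest.approx(oracle, abs=1e-12)
        assert abs(lib - oracle) <= 0.05  # trivially, but keeps the bound explicit

    def test_within_vs_cross_block_regimes(self):
        cfg = SimulationConfig(
            n_individuals=2000, n_sites=20, block_size=2,
            maf_range=(0.25, 0.35), n_true_rsnps=0, seed=5,
            block_mutation_rate=0.005,
        )
        m, _ = generate_genotype_matrix(cfg)
        within = [
            nhd(m.values[:, 2 * b], m.values[:, 2 * b + 1]) for b in range(10)
        ]
        cross = [
            nhd(m.values[:, 2 * b], m.values[:, 2 * b + 2]) for b in range(9)
        ]
        assert max(within) < 0.1
        assert min(cross) > 0.3

    def test_maf_within_requested_range(self):
        cfg = SimulationConfig(
            n_individuals=4000, n_sites=50, block_size=5,
            maf_range=(0.1, 0.3), n_true_rsnps=0, seed=2,
        )
        m, _ = generate_genotype_matrix(cfg)
        freqs = m.values.mean(axis=0) / 2
        assert freqs.min() > 0.05 and freqs.max() < 0.35

    def test_truth_ids_exist_in_matrix(self):
        cfg = SimulationConfig(n_individuals=100, n_sites=50, n_true_rsnps=8, seed=4)
        m, t = generate_genotype_matrix(cfg)
        ids = set(m.site_ids)
        assert t.true_rsnp_ids <= ids
        assert {s for pair in t.linked_pairs for s in pair} <= ids


class TestAlleleCountGeneration:
    def test_null_binomial_rate(self):
        """No planted effects: P(binomial p < 0.05) in [0.03, 0.06]."""
        cfg = SimulationConfig(
            n_individuals=60, n_sites=10_000, block_size=1,
            maf_range=(0.4, 0.5), n_true_rsnps=0, seed=21,
            coverage_mean=50.0, n_assay_samples=1,
        )
        m, t = generate_genotype_matrix(cfg)
        counts, _ = generate_allele_counts(m, cfg, "chip", t)
        assert len(counts) > 4000
        p = allelic.binomial_asymmetry_p(
            counts["ref_count"].to_numpy(), counts["alt_count"].to_numpy()
        )
        assert 0.03 <= (p < 0.05).mean() <= 0.06

    def test_planted_effect_read_back(self):
        cfg = SimulationConfig(
            n_individuals=500, n_sites=300, n_true_rsnps=50, seed=13,
            asb_effect=0.9, coverage_mean=100.0,
        )
        m, t = generate_genotype_matrix(cfg)
        counts, _ = generate_allele_counts(m, cfg, "chip", t)
        planted = counts[counts["site_id"].isin(t.true_rsnp_ids)]
        frac = planted["ref_count"].sum() / planted["total"].sum()
        assert frac == pytest.approx(0.9, abs=0.02)

    def test_reference_bias_shifts_null_fraction(self):
        cfg = SimulationConfig(
            n_individuals=500, n_sites=400, n_true_rsnps=0, seed=14,
            reference_bias=0.1, coverage_mean=60.0,
        )
        m, t = generate_genotype_matrix(cfg)
        counts, _ = generate_allele_counts(m, cfg, "rna", t)
        frac = counts["ref_count"].sum() / counts["total"].sum()
        assert frac == pytest.approx(0.6, abs=0.02)

    def test_determinism_and_assay_independence(self):
        cfg = SimulationConfig(n_individuals=80, n_sites=60, n_true_rsnps=5, seed=6)
        m, t = generate_genotype_matrix(cfg)
        a1, _ = generate_allele_counts(m, cfg, "chip", t)
        a2, _ = generate_allele_counts(m, cfg, "chip", t)
        r1, _ = generate_allele_counts(m, cfg, "rna", t)
        assert a1.equals(a2)
        assert not a1[["ref_count", "alt_count"]].equals(r1[["ref_count", "alt_count"]])


class TestCohortGeneration:
    def test_no_effect_no_planted_degs(self):
        cfg = SimulationConfig(
            n_individuals=60, n_sites=40, n_true_rsnps=4, seed=8, eqtl_log2fc=0.0,
        )
        m, t = generate_genotype_matrix(cfg)
        _, _, t = generate_cohort_counts(m, cfg, t)
        assert t.true_deg_ids == {}

    def test_het_individual_shows_both_marker_alleles(self):
        cfg = SimulationConfig(
            n_individuals=200, n_sites=40, n_true_rsnps=4, seed=8,
            marker_coverage_mean=50.0, coverage_dispersion=50.0,
        )
        m, t = generate_genotype_matrix(cfg)
        _, cov, t = generate_cohort_counts(m, cfg, t)
        markers = {mk for mk, _ in t.linked_pairs}
        idx = {s: i for i, s in enumerate(m.individuals)}
        checked = 0
        for _, row in cov.iterrows():
            if row["site_id"] not in markers:
                continue
            g = m.site_column(row["site_id"])[idx[row["sample"]]]
            total = row["ref_count"] + row["alt_count"]
            if g == 1 and total >= 10:
                assert row["ref_count"] >= 1 and row["alt_count"] >= 1
                checked += 1
        assert checked > 20

    def test_planted_eqtl_shifts_expression(self):
        cfg = SimulationConfig(
            n_individuals=400, n_sites=30, n_true_rsnps=3, seed=15,
            eqtl_log2fc=2.0, n_cohort_samples=100,
        )
        m, t = generate_genotype_matrix(cfg)
        counts, _, t = generate_cohort_counts(m, cfg, t)
        rsnp = sorted(t.true_deg_ids)[0]
        gene = sorted(t.true_deg_ids[rsnp])[0]
        samples = counts.columns
        idx = {s: i for i, s in enumerate(m.individuals)}
        g = np.array([m.site_column(rsnp)[idx[s]] for s in samples])
        if (g >= 1).sum() >= 3 and (g == 0).sum() >= 3:
            carrier = counts.loc[gene][g >= 1].mean()
            non = counts.loc[gene][g == 0].mean()
            assert carrier > 2 * non


def test_study_bundle_is_complete(small_study):
    keys = {
        "genotypes", "truth", "chip_counts", "rna_counts", "gene_models",
        "enhancers", "eqtl_catalog", "gwas_catalog", "cohort_counts",
        "cohort_coverage",
    }
    assert keys <= set(small_study)
    truth = small_study["truth"]
    ids = set(small_study["genotypes"].site_ids)
    assert truth.true_rsnp_ids <= ids
    # catalogs are enriched at planted sites
    eqtl = small_study["eqtl_catalog"].sites
    planted_rate = len(eqtl & truth.true_rsnp_ids) / len(truth.true_rsnp_ids)
    null_rate = len(eqtl - truth.true_rsnp_ids) / (len(ids) - len(truth.true_rsnp_ids))
    assert planted_rate > 2 * null_rate
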