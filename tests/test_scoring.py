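"""Target mapping, ASB/ASE join, weighted z, logistic scorer, ranks, panel."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rsnpscan import scoring
from rsnpscan.io import AnnotationCatalog, EnhancerRecord, GeneModel


def phi(z: float) -> float:
    """Independent standard-normal CDF via the error function."""
    return 0.5 * math.erfc(-z / math.sqrt(2.0))


def phi_inv(q: float) -> float:
    """Independent inverse CDF by bisection on ``phi``."""
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if phi(mid) < q:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _site(sid, chrom="chr1"):
    pos = int(sid.split(":")[1])
    return {"site_id": sid, "chrom": chrom, "pos": pos}


def _gene(gene_id, tss, strand="+"):
    t0 = tss - 1
    if strand == "+":
        exons = [(t0, t0 + 1000)]
    else:
        exons = [(t0 - 999, t0 + 1)]
    return GeneModel(gene_id, "chr1", strand, tss, exons=exons)


class TestTargetMapping:
    def test_promoter_and_enhancer_and_unmapped(self):
        genes = [_gene("G", 10_000)]
        enhancers = [EnhancerRecord("chr1", 49_999, 50_100, "G2")]
        sites = pd.DataFrame(
            [_site("chr1:9800"), _site("chr1:50000"), _site("chr1:70000")]
        )
        pairs = scoring.map_asb_to_targets(sites, genes, enhancers)
        got = set(map(tuple, pairs.to_numpy()))
        assert got == {
            ("chr1:9800", "G", "promoter"),  # TSS-200 inside default window
            ("chr1:50000", "G2", "enhancer"),
        }

    def test_promoter_wins_on_duplicate_pair(self):
        genes = [_gene("G", 10_000)]
        enhancers = [EnhancerRecord("chr1", 9_700, 9_900, "G")]
        sites = pd.DataFrame([_site("chr1:9800")])
        pairs = scoring.map_asb_to_targets(sites, genes, enhancers)
        assert len(pairs) == 1
        assert pairs.loc[0, "region_type"] == "promoter"


def _asymmetry_row(sid, pos, ref, alt, p):
    return {
        "site_id": sid, "chrom": "chr1", "pos": pos, "ref": "A", "alt": "G",
        "ref_count": ref, "alt_count": alt, "total": ref + alt,
        "p_value": p, "padj": min(1.0, p * 2), "log2fc": np.log2(ref / alt),
    }


class TestJoin:
    def _inputs(self, ase_p):
        genes = [_gene("G", 10_000)]
        pairs = pd.DataFrame(
            [("chr1:9800", "G", "promoter")],
            columns=["site_id", "gene_id", "region_type"],
        )
        asb = pd.DataFrame([_asymmetry_row("chr1:9800", 9800, 30, 10, 0.05)])
        # exonic site inside G carrying the ASE evidence
        ase = pd.DataFrame([_asymmetry_row("chr1:10500", 10500, 20, 10, ase_p)])
        return pairs, asb, ase, genes

    def test_kept_when_both_p_below_threshold(self):
        cand = scoring.join_asb_ase(*self._inputs(0.05))
        assert len(cand) == 1
        row = cand.iloc[0]
        assert row["gene_id"] == "G"
        assert row["ase_site"] == "chr1:10500"
        assert row["abs_log2fc_ratio"] == pytest.approx(
            abs(np.log2(3) - np.log2(2))
        )

    def test_rejected_when_ase_p_above_threshold(self):
        cand = scoring.join_asb_ase(*self._inputs(0.15))
        assert len(cand) == 0

    def test_identical_asymmetry_gives_zero_ratio(self):
        pairs, asb, ase, genes = self._inputs(0.05)
        ase.loc[0, ["ref_count", "alt_count", "log2fc"]] = [30, 10, np.log2(3)]
        cand = scoring.join_asb_ase(pairs, asb, ase, genes)
        assert cand.loc[0, "abs_log2fc_ratio"] == 0.0


class TestWeightedZ:
    def test_balanced_ps_give_zero_z(self):
        z, p = scoring.weighted_z_combine(0.5, 1.0, 0.5, 3.0)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_equal_weights_against_independent_oracle(self):
        z, p = scoring.weighted_z_combine(0.05, 1.0, 0.05, 1.0)
        z1 = phi_inv(0.95)
        z_expected = (z1 + z1) / math.sqrt(2.0)
        assert z == pytest.approx(z_expected, abs=1e-9)
        assert p == pytest.approx(1.0 - phi(z_expected), abs=1e-12)
        assert p == pytest.approx(0.00997, abs=1e-4)

    def test_weight_scale_invariance(self):
        z1, p1 = scoring.weighted_z_combine(0.01, 1.0, 0.2, 1.0)
        z2, p2 = scoring.weighted_z_combine(0.01, 10.0, 0.2, 10.0)
        assert z1 == pytest.approx(z2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_equal_weights_match_unweighted_stouffer(self):
        rng = np.random.default_rng(3)
        p1 = rng.uniform(0.001, 0.999, 50)
        p2 = rng.uniform(0.001, 0.999, 50)
        z, _ = scoring.weighted_z_combine(p1, np.ones(50), p2, np.ones(50))
        closed = (stats.norm.isf(p1) + stats.norm.isf(p2)) / np.sqrt(2.0)
        np.testing.assert_allclose(z, closed, atol=1e-12)

    def test_degenerate_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            z, p = scoring.weighted_z_combine(0.0, 1.0, 0.5, 1.0)
        assert np.isfinite(z) and 0 < p < 1


def _simulated_logit_data(rng, n, beta0, betas):
    X = pd.DataFrame(
        np.abs(rng.normal(size=(n, 3))), columns=scoring.FEATURE_COLUMNS
    )
    eta = beta0 + X.to_numpy() @ np.asarray(betas)
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    return X, y.astype(int)


class TestEqtlLogit:
    def test_parameter_recovery_within_3_se(self):
        rng = np.random.default_rng(42)
        beta0, betas = -1.0, [0.8, -0.3, 0.5]
        X, y = _simulated_logit_data(rng, 20_000, beta0, betas)
        res = scoring.EqtlLogit(y, X).fit()
        truth = np.array([beta0, *betas])
        err = np.abs(res.params.to_numpy() - truth) / res.bse.to_numpy()
        assert (err < 3).all()

    def test_null_coefficients_not_significant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X, _ = _simulated_logit_data(rng, 5000, 0.0, [0, 0, 0])
            y = (rng.random(5000) < 0.3).astype(int)
            res = scoring.EqtlLogit(y, X).fit()
            if (res.pvalues[scoring.FEATURE_COLUMNS] > 0.01).all():
                hits += 1
        assert hits >= 18  # >= 95% of seeds within Monte-Carlo slack

    def test_single_class_labels_error(self):
        rng = np.random.default_rng(0)
        X, _ = _simulated_logit_data(rng, 100, 0, [0, 0, 0])
        with pytest.raises(ValueError, match="both label classes"):
            scoring.EqtlLogit(np.zeros(100), X)

    def test_too_few_candidates_error(self):
        rng = np.random.default_rng(0)
        X, y = _simulated_logit_data(rng, 30, 0, [0, 0, 0])
        with pytest.raises(ValueError, match="at least 50"):
            scoring.EqtlLogit(y, X)

    def test_perfect_separation_raises_advice(self):
        X = pd.DataFrame(
            {
                "abs_log2fc1": np.r_[np.zeros(40), np.ones(40) * 5],
                "abs_log2fc2": np.zeros(80),
                "abs_log2fc_ratio": np.zeros(80),
            }
        )
        y = np.r_[np.zeros(40), np.ones(40)]
        with pytest.raises(ValueError, match="separation|finite"):
            scoring.EqtlLogit(y, X).fit()

    def test_summary_layout_and_stars(self):
        rng = np.random.default_rng(1)
        X, y = _simulated_logit_data(rng, 5000, -0.5, [1.0, 0.0, 0.0])
        res = scoring.EqtlLogit(y, X).fit()
        table = res.summary()
        assert list(table.columns) == [
            "Parameter", "Regression Coefficient", "Std. Error", "p-Value", "Sign",
        ]
        assert list(table["Parameter"]) == [
            "intercept", "|log2FC1|", "|log2FC2|", "|log2FC1/FC2|",
        ]
        fc1 = table[table["Parameter"] == "|log2FC1|"].iloc[0]
        assert fc1["Sign"] == "***"


class TestLRT:
    def test_identical_models(self):
        rng = np.random.default_rng(5)
        X, y = _simulated_logit_data(rng, 1000, 0.0, [0.5, 0.2, 0.1])
        res = scoring.EqtlLogit(y, X).fit()
        with pytest.raises(ValueError, match="nested"):
            scoring.lrt_nested(res, res)

    def test_null_extra_predictor_chi2_distribution(self):
        """chi2 for one pure-noise predictor follows chi-square(1)."""
        rng = np.random.default_rng(77)
        chis = []
        for _ in range(200):
            n = 800
            X = pd.DataFrame(
                np.abs(rng.normal(size=(n, 3))), columns=scoring.FEATURE_COLUMNS
            )
            eta = -0.5 + 0.5 * X["abs_log2fc1"].to_numpy()
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            full = scoring.EqtlLogit(y, X).fit()
            red = scoring.EqtlLogit(
                y, X[["abs_log2fc1", "abs_log2fc2"]],
            ).fit()
            chi2, df, _ = scoring.lrt_nested(full, red)
            assert df == 1
            chis.append(chi2)
        ks = stats.kstest(chis, stats.chi2(1).cdf)
        assert ks.pvalue > 0.01

    def test_power_on_predictive_term(self):
        rng = np.random.default_rng(8)
        X, y = _simulated_logit_data(rng, 5000, -0.5, [0.1, 0.1, 1.5])
        full = scoring.EqtlLogit(y, X).fit()
        red = scoring.EqtlLogit(y, X[["abs_log2fc1", "abs_log2fc2"]]).fit()
        chi2, df, p = scoring.lrt_nested(full, red)
        assert p < 1e-6

    def test_different_data_rejected(self):
        rng = np.random.default_rng(9)
        X, y = _simulated_logit_data(rng, 1000, 0.0, [0.5, 0.2, 0.1])
        full = scoring.EqtlLogit(y, X).fit()
        red = scoring.EqtlLogit(y[:500], X.iloc[:500][["abs_log2fc1"]]).fit()
        with pytest.raises(ValueError, match="same data"):
            scoring.lrt_nested(full, red)


class TestPredictedProbability:
    def test_zero_model_gives_half(self):
        assert scoring.inverse_logit_score(0.0, [0, 0, 0], [1, 2, 3]) == 0.5

    def test_published_slope_example(self):
        # slopes from the published coefficient table, intercept 0
        pp = scoring.inverse_logit_score(
            0.0, [-0.547335, -0.022103, -0.125600], [1.0, 1.0, 0.0]
        )
        assert pp == pytest.approx(0.3614, abs=2e-4)

    def test_monotone_in_feature_with_negative_coef(self):
        rng = np.random.default_rng(2)
        X, y = _simulated_logit_data(rng, 8000, 0.5, [-1.0, 0.2, 0.1])
        res = scoring.EqtlLogit(y, X).fit()
        assert res.params["abs_log2fc1"] < 0
        grid = pd.DataFrame(
            {
                "abs_log2fc1": [0.0, 1.0, 2.0],
                "abs_log2fc2": 1.0,
                "abs_log2fc_ratio": 1.0,
            }
        )
        pp = res.predict(grid)
        assert pp[0] > pp[1] > pp[2]


def _scored_candidates(rng, n=10_000):
    score = rng.random(n)
    return pd.DataFrame(
        {
            "site_id": [f"chr1:{i}" for i in range(n)],
            "predicted_probability": score,
        }
    )


class TestRankEnrichment:
    def test_hits_only_in_top_bin(self):
        rng = np.random.default_rng(0)
        cand = _scored_candidates(rng, 1000)
        top = cand.nlargest(10, "predicted_probability")["site_id"]
        catalog = AnnotationCatalog("eqtl", pd.DataFrame({"site_id": top}))
        table = scoring.rank_enrichment(cand, catalog, n_ranks=100)
        assert table.table.loc[0, "n_hits"] == 10
        assert table.table["n_hits"].iloc[1:].sum() == 0

    def test_score_proportional_hits_give_strong_negative_rho(self):
        rng = np.random.default_rng(1)
        cand = _scored_candidates(rng, 10_000)
        hit = rng.random(10_000) < cand["predicted_probability"] * 0.5
        catalog = AnnotationCatalog(
            "eqtl", pd.DataFrame({"site_id": cand.loc[hit, "site_id"]})
        )
        table = scoring.rank_enrichment(cand, catalog, n_ranks=100)
        # rank 1 = highest score, so enrichment decays with rank
        assert table.spearman_rho < -0.7
        assert table.interpretation == "strong"

    def test_uniform_hits_give_weak_rho(self):
        weak = 0
        for seed in range(20):
            rng = np.random.default_rng(50 + seed)
            cand = _scored_candidates(rng, 2000)
            hit = rng.random(2000) < 0.2
            catalog = AnnotationCatalog(
                "eqtl", pd.DataFrame({"site_id": cand.loc[hit, "site_id"]})
            )
            table = scoring.rank_enrichment(cand, catalog, n_ranks=100)
            if abs(table.spearman_rho) < 0.3:
                weak += 1
        assert weak >= 19

    def test_bin_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(2)
        cand = _scored_candidates(rng, 1003)
        catalog = AnnotationCatalog("eqtl", pd.DataFrame({"site_id": []}))
        table = scoring.rank_enrichment(cand, catalog, n_ranks=100).table
        assert table["n_candidates"].sum() == 1003
        assert set(table["n_candidates"]) == {10, 11}
        assert list(table["n_candidates"])[:3] == [11, 11, 11]

    def test_more_ranks_than_candidates_error(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="exceeds"):
            scoring.rank_enrichment(
                _scored_candidates(rng, 50),
                AnnotationCatalog("eqtl", pd.DataFrame({"site_id": []})),
                n_ranks=100,
            )


class TestPanelSelection:
    def test_strict_cutoff_excludes_equal_pp(self):
        cand = pd.DataFrame(
            {
                "site_id": ["a", "b", "c"],
                "predicted_probability": [0.1929408, 0.1929409, 0.5],
            }
        )
        panel = scoring.select_panel(cand)
        assert set(panel["site_id"]) == {"b", "c"}

    def test_zero_cutoff_keeps_all(self):
        cand = pd.DataFrame(
            {"site_id": ["a", "b"], "predicted_probability": [0.01, 0.9]}
        )
        assert len(scoring.select_panel(cand, pp_cutoff=0.0)) == 2

    def test_cutoff_from_top_half_ranks(self):
        rng = np.random.default_rng(4)
        cand = _scored_candidates(rng, 1000)
        cutoff = scoring.derive_pp_cutoff(cand, n_ranks=100, top_ranks=50)
        top_half = cand.nlargest(500, "predicted_probability")
        assert cutoff == pytest.approx(top_half["predicted_probability"].min())
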