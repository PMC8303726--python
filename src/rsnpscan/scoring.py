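"""rSNP candidate construction and scoring.

Maps allele-specific binding sites to target genes (promoter or enhancer),
joins them with allele-specific expression evidence, combines the two
binomial p-values with a weighted z (Stouffer) statistic, fits a logistic
model of eQTL membership on the asymmetry features, and selects the final
panel by predicted probability.

The logistic scorer follows the Model/Results idiom: build an
:class:`EqtlLogit` from candidates and labels, ``fit()`` it, and use the
returned :class:`EqtlLogitResults` for prediction, likelihood-ratio
comparison and the summary table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from intervaltree import IntervalTree
from scipy import stats

from ._coords import promoter_interval
from .io import AnnotationCatalog, EnhancerRecord, GeneModel

FEATURE_COLUMNS = ["abs_log2fc1", "abs_log2fc2", "abs_log2fc_ratio"]
FEATURE_LABELS = {
    "abs_log2fc1": "|log2FC1|",
    "abs_log2fc2": "|log2FC2|",
    "abs_log2fc_ratio": "|log2FC1/FC2|",
}

#: published panel cutoff on predicted probability (strict >)
DEFAULT_PP_CUTOFF = 0.1929408


# ---------------------------------------------------------------------------
# target mapping and the ASB/ASE join


def map_asb_to_targets(
    asb_sites: pd.DataFrame,
    gene_models: list[GeneModel],
    enhancers: list[EnhancerRecord] | None = None,
    promoter_window: tuple[int, int] = (1000, 500),
) -> pd.DataFrame:
    """Assign ASB sites to target genes.

    A site targets gene G through G's strand-aware promoter window, or
    through an enhancer interval whose annotated target is G (a distant
    target). A site may map to several genes; a (site, gene) pair reached
    both ways is reported once as promoter.
    """
    up, down = promoter_window
    trees: dict[str, IntervalTree] = {}
    for g in gene_models:
        s, e = promoter_interval(g.tss, g.strand, up, down)
        trees.setdefault(g.chrom, IntervalTree())[s:e] = ("promoter", g.gene_id)
    for enh in enhancers or []:
        trees.setdefault(enh.chrom, IntervalTree())[enh.start:enh.end] = (
            "enhancer",
            enh.target_gene,
        )
    rows = []
    for _, site in asb_sites.iterrows():
        tree = trees.get(site["chrom"])
        if tree is None:
            continue
        for iv in tree[site["pos"] - 1]:
            region_type, gene = iv.data
            rows.append((site["site_id"], gene, region_type))
    out = pd.DataFrame(rows, columns=["site_id", "gene_id", "region_type"])
    if len(out):
        # promoter sorts before enhancer is false alphabetically; rank it
        out["_rank"] = (out["region_type"] != "promoter").astype(int)
        out = (
            out.sort_values(["site_id", "gene_id", "_rank"])
            .drop_duplicates(["site_id", "gene_id"])
            .drop(columns="_rank")
            .reset_index(drop=True)
        )
    return out


def sites_in_genes(
    sites: pd.DataFrame, gene_models: list[GeneModel]
) -> pd.DataFrame:
    """(site_id, gene_id) pairs for sites inside a gene's exons."""
    trees: dict[str, IntervalTree] = {}
    for g in gene_models:
        for s, e in g.exons:
            trees.setdefault(g.chrom, IntervalTree())[s:e] = g.gene_id
    rows = []
    for _, site in sites.iterrows():
        tree = trees.get(site["chrom"])
        if tree is None:
            continue
        for iv in tree[site["pos"] - 1]:
            rows.append((site["site_id"], iv.data))
    return pd.DataFrame(rows, columns=["site_id", "gene_id"]).drop_duplicates()


def join_asb_ase(
    pairs: pd.DataFrame,
    asb: pd.DataFrame,
    ase: pd.DataFrame,
    gene_models: list[GeneModel],
    p_threshold: float = 0.1,
) -> pd.DataFrame:
    """Join ASB target pairs with ASE evidence into rSNP candidates.

    A candidate (site, gene) survives iff the ASB site's binomial p is
    below ``p_threshold`` and the target gene contains at least one
    heterozygous site whose ASE p is below it too (the raw two-sided
    binomial p in both assays). The gene's ASE evidence is its smallest-p
    qualifying site, ties broken by site id.

    Feature columns: ``abs_log2fc1`` (ChIP), ``abs_log2fc2`` (RNA) and
    ``abs_log2fc_ratio`` = \\|log2FC1 - log2FC2\\| = \\|log2(FC1/FC2)\\|.
    """
    asb_ok = asb[asb["p_value"] < p_threshold]
    ase_ok = ase[ase["p_value"] < p_threshold]
    if len(pairs) == 0 or len(asb_ok) == 0 or len(ase_ok) == 0:
        return _empty_candidates()
    ase_genes = sites_in_genes(ase_ok, gene_models)
    ase_in_gene = ase_genes.merge(ase_ok, on="site_id")
    best_ase = (
        ase_in_gene.sort_values(["gene_id", "p_value", "site_id"])
        .drop_duplicates("gene_id")
        .set_index("gene_id")
    )
    cand = pairs.merge(
        asb_ok.set_index("site_id"),
        left_on="site_id",
        right_index=True,
    )
    cand = cand[cand["gene_id"].isin(best_ase.index)]
    if len(cand) == 0:
        return _empty_candidates()
    ase_cols = best_ase.loc[
        cand["gene_id"],
        ["site_id", "ref_count", "alt_count", "total", "p_value", "padj", "log2fc"],
    ]
    out = pd.DataFrame(
        {
            "site_id": cand["site_id"].to_numpy(),
            "gene_id": cand["gene_id"].to_numpy(),
            "region_type": cand["region_type"].to_numpy(),
            "asb_ref": cand["ref_count"].to_numpy(),
            "asb_alt": cand["alt_count"].to_numpy(),
            "asb_total": cand["total"].to_numpy(),
            "asb_p": cand["p_value"].to_numpy(),
            "asb_padj": cand["padj"].to_numpy(),
            "asb_log2fc": cand["log2fc"].to_numpy(),
            "ase_site": ase_cols["site_id"].to_numpy(),
            "ase_ref": ase_cols["ref_count"].to_numpy(),
            "ase_alt": ase_cols["alt_count"].to_numpy(),
            "ase_total": ase_cols["total"].to_numpy(),
            "ase_p": ase_cols["p_value"].to_numpy(),
            "ase_padj": ase_cols["padj"].to_numpy(),
            "ase_log2fc": ase_cols["log2fc"].to_numpy(),
        }
    )
    out["abs_log2fc1"] = np.abs(out["asb_log2fc"])
    out["abs_log2fc2"] = np.abs(out["ase_log2fc"])
    out["abs_log2fc_ratio"] = np.abs(out["asb_log2fc"] - out["ase_log2fc"])
    out["direction_concordant"] = (
        np.sign(out["asb_log2fc"]) == np.sign(out["ase_log2fc"])
    )
    return out.sort_values(["site_id", "gene_id"]).reset_index(drop=True)


def _empty_candidates() -> pd.DataFrame:
    cols = (
        ["site_id", "gene_id", "region_type"]
        + [f"asb_{c}" for c in ("ref", "alt", "total", "p", "padj", "log2fc")]
        + ["ase_site"]
        + [f"ase_{c}" for c in ("ref", "alt", "total", "p", "padj", "log2fc")]
        + FEATURE_COLUMNS
        + ["direction_concordant"]
    )
    return pd.DataFrame(columns=cols)


# ---------------------------------------------------------------------------
# weighted z combination


def weighted_z_combine(p1, w1, p2, w2) -> tuple:
    """Weighted Stouffer combination of two p-values.

    z_i = Phi^-1(1 - p_i); z = (w1 z1 + w2 z2) / sqrt(w1^2 + w2^2);
    combined p = 1 - Phi(z). Invariant to rescaling both weights. p-values
    at 0 or 1 are clamped into (0, 1) with a warning.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if (w1 <= 0).any() or (w2 <= 0).any():
        raise ValueError("weights must be positive")
    clamped = (p1 <= 0) | (p1 >= 1) | (p2 <= 0) | (p2 >= 1)
    if np.any(clamped):
        warnings.warn("p-values at 0 or 1 clamped into (0, 1)", stacklevel=2)
        p1 = np.clip(p1, 1e-300, 1 - 1e-16)
        p2 = np.clip(p2, 1e-300, 1 - 1e-16)
    z1 = stats.norm.isf(p1)
    z2 = stats.norm.isf(p2)
    z = (w1 * z1 + w2 * z2) / np.sqrt(w1**2 + w2**2)
    p = stats.norm.sf(z)
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


def add_combined_score(
    candidates: pd.DataFrame, weight_mode: str = "coverage"
) -> pd.DataFrame:
    """Attach z_combined / p_combined to a candidate table.

    Weights are the square root of each test's total read coverage
    (information content), or equal when ``weight_mode='equal'``.
    """
    out = candidates.copy()
    if len(out) == 0:
        out["z_combined"] = pd.Series(dtype=float)
        out["p_combined"] = pd.Series(dtype=float)
        return out
    if weight_mode == "coverage":
        w1 = np.sqrt(out["asb_total"].to_numpy(dtype=float))
        w2 = np.sqrt(out["ase_total"].to_numpy(dtype=float))
    elif weight_mode == "equal":
        w1 = np.ones(len(out))
        w2 = np.ones(len(out))
    else:
        raise ValueError(f"weight_mode must be 'coverage' or 'equal', got {weight_mode!r}")
    z, p = weighted_z_combine(out["asb_p"].to_numpy(), w1, out["ase_p"].to_numpy(), w2)
    out["z_combined"] = z
    out["p_combined"] = p
    return out


# ---------------------------------------------------------------------------
# the eQTL logistic model (Model / Results)


class EqtlLogit:
    """Logistic model of catalog (eQTL) membership on asymmetry features.

    Predictors are |log2FC1|, |log2FC2| and |log2FC1/FC2| with an
    intercept. Thin wrapper around statsmodels' Logit that enforces the
    candidate-table contract; ``fit()`` returns :class:`EqtlLogitResults`.
    """

    MIN_OBS = 50

    def __init__(
        self,
        labels,
        features: pd.DataFrame,
        feature_names: list[str] | None = None,
    ):
        y = np.asarray(labels, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        self.feature_names = list(feature_names or features.columns)
        X = np.asarray(features[self.feature_names], dtype=float)
        if len(y) != len(X):
            raise ValueError("labels and features disagree in length")
        if len(y) < self.MIN_OBS:
            raise ValueError(f"need at least {self.MIN_OBS} candidates, got {len(y)}")
        if y.min() == y.max():
            raise ValueError("both label classes must be present")
        self.endog = y
        self.exog = sm.add_constant(X, has_constant="add")
        self.exog_names = ["intercept"] + self.feature_names

    @classmethod
    def from_candidates(
        cls,
        candidates: pd.DataFrame,
        labels,
        feature_names: list[str] | None = None,
    ) -> "EqtlLogit":
        return cls(labels, candidates, feature_names or FEATURE_COLUMNS)

    @classmethod
    def from_catalog(
        cls, candidates: pd.DataFrame, catalog: AnnotationCatalog
    ) -> "EqtlLogit":
        labels = candidates["site_id"].isin(catalog.sites).astype(int)
        return cls.from_candidates(candidates, labels)

    def fit(self) -> "EqtlLogitResults":
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            try:
                res = sm.Logit(self.endog, self.exog).fit(disp=0)
            except (
                sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning,
            ) as exc:
                raise ValueError(
                    "perfect separation in logistic fit; refit with "
                    "regularization (e.g. fit_regularized) after reviewing "
                    "the features"
                ) from exc
        if not np.isfinite(res.bse).all():
            raise ValueError(
                "logistic fit did not converge to finite standard errors; "
                "consider a regularized refit"
            )
        return EqtlLogitResults(self, res)


@dataclass
class EqtlLogitResults:
    """Fitted eQTL logistic model: estimates, uncertainty, diagnostics."""

    model: EqtlLogit
    _res: object

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._res.params, index=self.model.exog_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self._res.bse, index=self.model.exog_names)

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(self._res.pvalues, index=self.model.exog_names)

    @property
    def llf(self) -> float:
        return float(self._res.llf)

    @property
    def nobs(self) -> int:
        return int(self._res.nobs)

    def predict(self, candidates: pd.DataFrame) -> np.ndarray:
        """Predicted probability: inverse logit of the linear predictor."""
        X = np.asarray(candidates[self.model.feature_names], dtype=float)
        X = sm.add_constant(X, has_constant="add")
        return self._res.predict(X)

    def summary(self) -> pd.DataFrame:
        """Coefficient table in the conventional published layout."""
        rows = []
        for name in self.model.exog_names:
            label = FEATURE_LABELS.get(name, name)
            p = self.pvalues[name]
            rows.append(
                {
                    "Parameter": label,
                    "Regression Coefficient": self.params[name],
                    "Std. Error": self.bse[name],
                    "p-Value": p,
                    "Sign": _stars(p),
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "coefficients": self.params.to_dict(),
            "std_errors": self.bse.to_dict(),
            "p_values": self.pvalues.to_dict(),
            "n_obs": self.nobs,
            "log_likelihood": self.llf,
        }


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def lrt_nested(
    full: EqtlLogitResults, reduced: EqtlLogitResults
) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested logistic fits.

    chi2 = 2 (llf_full - llf_reduced), df = difference in parameter count,
    p from the chi-square upper tail. The reduced model's predictors must
    be a subset of the full model's, fitted on the same observations.
    """
    full_names = set(full.model.exog_names)
    red_names = set(reduced.model.exog_names)
    if not red_names < full_names:
        raise ValueError("models are not nested (reduced must be a strict subset)")
    if full.nobs != reduced.nobs:
        raise ValueError("nested models must be fitted on the same data")
    df = len(full_names) - len(red_names)
    chi2 = 2.0 * (full.llf - reduced.llf)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    if df == 0:
        chi2 = 0.0
    return chi2, df, p


def predict_probability(results: EqtlLogitResults, candidates: pd.DataFrame) -> np.ndarray:
    """Convenience alias for :meth:`EqtlLogitResults.predict`."""
    return results.predict(candidates)


def inverse_logit_score(intercept: float, coefs, values) -> float:
    """Inverse logit of intercept + coefs . values, for explicit coefficients."""
    eta = intercept + float(np.dot(np.asarray(coefs, float), np.asarray(values, float)))
    return float(1.0 / (1.0 + np.exp(-eta)))


# ---------------------------------------------------------------------------
# rank enrichment and panel selection


@dataclass
class EnrichmentRankTable:
    """Catalog hits per score rank plus the rank correlation."""

    table: pd.DataFrame  # rank, n_candidates, n_hits
    metric: str
    ascending: bool
    spearman_rho: float
    spearman_p: float

    @property
    def interpretation(self) -> str:
        r = abs(self.spearman_rho)
        if r >= 0.7:
            return "strong"
        if r >= 0.5:
            return "moderate"
        return "low"


def rank_enrichment(
    candidates: pd.DataFrame,
    catalog: AnnotationCatalog,
    n_ranks: int = 100,
    metric: str = "predicted_probability",
    ascending: bool = False,
) -> EnrichmentRankTable:
    """Partition scored candidates into near-equal ranks and count hits.

    Candidates are sorted by ``metric`` (descending by default, so rank 1
    holds the highest scores), split into ``n_ranks`` bins whose sizes
    differ by at most one (ceil sizes first), and catalog membership is
    counted per bin. The Spearman correlation of (rank, hit count) is
    attached.
    """
    n = len(candidates)
    if n_ranks > n:
        raise ValueError(f"n_ranks={n_ranks} exceeds candidate count {n}")
    ordered = candidates.sort_values(
        [metric, "site_id"], ascending=[ascending, True], kind="mergesort"
    )
    hits = ordered["site_id"].isin(catalog.sites).to_numpy()
    base, extra = divmod(n, n_ranks)
    sizes = [base + 1] * extra + [base] * (n_ranks - extra)
    rows, start = [], 0
    for rank, size in enumerate(sizes, start=1):
        chunk = hits[start : start + size]
        rows.append((rank, size, int(chunk.sum())))
        start += size
    table = pd.DataFrame(rows, columns=["rank", "n_candidates", "n_hits"])
    if table["n_hits"].nunique() <= 1:  # constant hits: correlation undefined
        rho, pval = float("nan"), float("nan")
    else:
        rho, pval = stats.spearmanr(table["rank"], table["n_hits"])
    return EnrichmentRankTable(
        table=table,
        metric=metric,
        ascending=ascending,
        spearman_rho=float(rho),
        spearman_p=float(pval),
    )


def derive_pp_cutoff(
    candidates: pd.DataFrame,
    metric: str = "predicted_probability",
    n_ranks: int = 100,
    top_ranks: int = 50,
) -> float:
    """Minimum metric value within the top ``top_ranks`` of ``n_ranks`` bins.

    The enrichment trend persists up to a rank; the panel cutoff is the
    smallest score still inside that rank window.
    """
    n = len(candidates)
    if n_ranks > n:
        raise ValueError(f"n_ranks={n_ranks} exceeds candidate count {n}")
    ordered = candidates.sort_values(
        [metric, "site_id"], ascending=[False, True], kind="mergesort"
    )
    base, extra = divmod(n, n_ranks)
    sizes = [base + 1] * extra + [base] * (n_ranks - extra)
    n_top = sum(sizes[:top_ranks])
    return float(ordered[metric].iloc[:n_top].min())


def select_panel(
    candidates: pd.DataFrame,
    pp_cutoff: float | None = DEFAULT_PP_CUTOFF,
    combined_p_cutoff: float | None = None,
) -> pd.DataFrame:
    """Final panel: strict predicted-probability filter (pp > cutoff).

    Alternatively (or additionally) keep candidates with combined
    p <= ``combined_p_cutoff``. With both cutoffs None all candidates pass.
    """
    keep = pd.Series(True, index=candidates.index)
    if pp_cutoff is not None:
        keep &= candidates["predicted_probability"] > pp_cutoff
    if combined_p_cutoff is not None:
        keep &= candidates["p_combined"] <= combined_p_cutoff
    return candidates[keep].reset_index(drop=True)


def unique_sites(panel: pd.DataFrame) -> pd.DataFrame:
    """Deduplicate a (site, gene) panel to unique sites for overlap counts."""
    return panel.drop_duplicates("site_id").reset_index(drop=True)
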