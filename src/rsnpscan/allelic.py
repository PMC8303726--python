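"""Heterozygous-site calling and per-site allelic-asymmetry statistics.

The ASB/ASE engine: an exact two-sided binomial test of the null that both
alleles of a heterozygous SNP are equally covered, Benjamini-Hochberg
adjustment, and event classification by odds ratio. The degree of
asymmetry is |log2FC| where FC is the ref/alt fold change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: minimum minor-allele coverage for a site to count as heterozygous
MIN_MINOR_READS = 10

EVENT_NONE = "none"
EVENT_ENRICHMENT = "enrichment"
EVENT_DEPLETION = "depletion"


def call_heterozygous(
    records: pd.DataFrame,
    min_minor_reads: int = MIN_MINOR_READS,
    mode: str = "pooled",
) -> pd.DataFrame:
    """Aggregate allele counts and keep heterozygous-qualified sites.

    A position is heterozygous when its minor-allele coverage is at least
    ``min_minor_reads``. In the default pooled mode, ref/alt counts are
    summed across samples per site before the threshold is applied; in
    per-sample mode each (site, sample) pair is tested on its own counts.

    Returns one row per site (pooled) or per site/sample with columns
    site_id, chrom, pos, ref, alt, ref_count, alt_count, total.
    """
    if mode not in ("pooled", "per-sample"):
        raise ValueError(f"mode must be 'pooled' or 'per-sample', got {mode!r}")
    keys = ["site_id", "chrom", "pos", "ref", "alt"]
    if mode == "per-sample":
        keys = keys + ["sample"]
    agg = (
        records.groupby(keys, sort=True, as_index=False)[["ref_count", "alt_count"]]
        .sum()
    )
    agg["total"] = agg["ref_count"] + agg["alt_count"]
    minor = np.minimum(agg["ref_count"], agg["alt_count"])
    return agg[minor >= min_minor_reads].reset_index(drop=True)


def binomial_asymmetry_p(ref, alt) -> np.ndarray | float:
    """Exact two-sided binomial p at success probability 1/2.

    Two-sidedness by doubling the smaller tail, capped at 1 (for a
    symmetric null this coincides with the minimum-likelihood rule).
    Accepts scalars or arrays; zero total coverage is an error.
    """
    ref_a = np.atleast_1d(np.asarray(ref, dtype=np.int64))
    alt_a = np.atleast_1d(np.asarray(alt, dtype=np.int64))
    if (ref_a < 0).any() or (alt_a < 0).any():
        raise ValueError("counts must be non-negative")
    n = ref_a + alt_a
    if (n == 0).any():
        raise ValueError("zero total coverage: binomial test undefined")
    lower = stats.binom.cdf(ref_a, n, 0.5)
    upper = stats.binom.sf(ref_a - 1, n, 0.5)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    if np.isscalar(ref) or np.ndim(ref) == 0:
        return float(p[0])
    return p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def odds_ratio_log2fc(ref, alt) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ref/alt odds ratio and signed log2 fold change.

    Zero counts on either side get a 0.5 pseudocount on both (flagged in
    the returned mask) so the ratio stays finite.
    """
    ref_a = np.asarray(ref, dtype=float)
    alt_a = np.asarray(alt, dtype=float)
    pseudo = (ref_a == 0) | (alt_a == 0)
    r = np.where(pseudo, ref_a + 0.5, ref_a)
    a = np.where(pseudo, alt_a + 0.5, alt_a)
    oratio = r / a
    return oratio, np.log2(oratio), pseudo


def classify_event(
    ref: int,
    alt: int,
    padj: float,
    or_threshold: float = 1.5,
    padj_threshold: float = 0.1,
    literal_depletion: bool = False,
) -> dict:
    """Classify one site as enrichment / depletion / none.

    Significant (padj <= threshold) sites are enrichments when the
    ref/alt ratio is at least ``or_threshold`` and depletions when the
    reciprocal ratio is. ``literal_depletion`` instead applies the literal
    published rule (depletion whenever the ratio is below the threshold),
    which labels near-balanced significant sites as depleted.
    """
    oratio, log2fc, pseudo = odds_ratio_log2fc(ref, alt)
    oratio, log2fc, pseudo = float(oratio), float(log2fc), bool(pseudo)
    if padj > padj_threshold:
        event = EVENT_NONE
    elif oratio >= or_threshold:
        event = EVENT_ENRICHMENT
    elif literal_depletion or 1.0 / oratio >= or_threshold:
        event = EVENT_DEPLETION
    else:
        event = EVENT_NONE
    return {
        "odds_ratio": oratio,
        "log2fc": log2fc,
        "event": event,
        "pseudocount": pseudo,
    }


def asymmetry_table(
    het: pd.DataFrame,
    or_threshold: float = 1.5,
    padj_threshold: float = 0.1,
    literal_depletion: bool = False,
) -> pd.DataFrame:
    """Full per-site asymmetry statistics for a heterozygous-site table.

    Adds p_value, padj (BH across the table), odds_ratio, log2fc,
    abs_log2fc, event and pseudocount columns to the input.
    """
    out = het.copy()
    if len(out) == 0:
        for col in ("p_value", "padj", "odds_ratio", "log2fc", "abs_log2fc"):
            out[col] = pd.Series(dtype=float)
        out["event"] = pd.Series(dtype=str)
        out["pseudocount"] = pd.Series(dtype=bool)
        return out
    ref = out["ref_count"].to_numpy()
    alt = out["alt_count"].to_numpy()
    out["p_value"] = binomial_asymmetry_p(ref, alt)
    out["padj"] = bh_adjust(out["p_value"])
    oratio, log2fc, pseudo = odds_ratio_log2fc(ref, alt)
    out["odds_ratio"] = oratio
    out["log2fc"] = log2fc
    out["abs_log2fc"] = np.abs(log2fc)
    out["pseudocount"] = pseudo
    significant = out["padj"] <= padj_threshold
    enr = significant & (oratio >= or_threshold)
    if literal_depletion:
        dep = significant & (oratio < or_threshold)
    else:
        dep = significant & (1.0 / oratio >= or_threshold)
    out["event"] = EVENT_NONE
    out.loc[enr, "event"] = EVENT_ENRICHMENT
    out.loc[dep, "event"] = EVENT_DEPLETION
    return out
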