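"""In-silico genotyping of an RNA-seq cohort and genotype-group DE.

Regulatory SNPs are mostly non-transcribed, so their direct RNA-seq
coverage is thin. Coverage of up to ten tightly linked coding markers is
mapped onto the rSNP alleles (through each marker's allele map) and added
to the direct coverage; the genotype is then called with the 10%
minor-fraction rule, cohorts are split into heterozygous/homozygous groups
under the >=6 individuals / >=3 minor-carrier criteria, and differential
expression between the groups is delegated to a pluggable method (the
built-in stand-in is Welch's t on log2 CPM with Bonferroni correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GenotypeMatrix
from .linkage import LinkedPair

CALL_HET = "heterozygous"
CALL_HOM = "homozygous"
CALL_UNKNOWN = "unknown"

#: minor-allele fraction at or above which a call is heterozygous
HET_FRACTION = 0.10


@dataclass
class GenotypeCall:
    """One sample's in-silico genotype at one rSNP.

    ``major_coverage`` / ``minor_coverage`` are read counts mapped to the
    population-major and rare rSNP allele after marker aggregation.
    ``hom_allele`` states which allele a homozygous call is for;
    ``minor_carrier`` is True when the sample carries at least one rare
    allele (heterozygous, or homozygous for the rare allele).
    """

    sample_id: str
    rsnp_site: str
    major_coverage: int
    minor_coverage: int
    call: str
    n_markers_used: int = 0
    hom_allele: str | None = None

    @property
    def minor_carrier(self) -> bool:
        return self.call == CALL_HET or (
            self.call == CALL_HOM and self.hom_allele == "rare"
        )


def aggregate_marker_coverage(
    direct: tuple[int, int],
    markers: list[tuple[LinkedPair, tuple[int, int]]],
    max_markers: int = 10,
) -> tuple[int, int, int]:
    """Combine direct rSNP coverage with linked-marker coverage.

    ``direct`` and each marker coverage are (major, rare) read counts in
    the respective site's own allele orientation. Each marker's reads are
    routed onto the rSNP alleles through its allele map ('swapped' markers
    predict the rSNP rare allele with their major allele); markers are
    consumed in the given (NHD-ranked) order, at most ``max_markers`` of
    them. Returns (major, rare, n_markers_used) at the rSNP.
    """
    major, minor = int(direct[0]), int(direct[1])
    if major < 0 or minor < 0:
        raise ValueError("coverages must be non-negative")
    used = 0
    for pair, (m_major, m_minor) in markers[:max_markers]:
        amap = pair.allele_map
        add_major = m_major if amap["major"] == "major" else m_minor
        add_minor = m_minor if amap["rare"] == "rare" else m_major
        major += int(add_major)
        minor += int(add_minor)
        used += 1
    return major, minor, used


def call_genotype(
    coverages: tuple[int, int],
    sample_id: str = "",
    rsnp_site: str = "",
    het_fraction: float = HET_FRACTION,
    n_markers_used: int = 0,
) -> GenotypeCall:
    """Apply the minor-fraction rule to combined (major, rare) coverage.

    With zero total coverage the genotype is unknown. Otherwise the less
    covered of the two alleles is the observed minor allele: a fraction
    at or above ``het_fraction`` of the total calls a heterozygote, below
    it a homozygote for the more covered allele.
    """
    major_cov, minor_cov = int(coverages[0]), int(coverages[1])
    if major_cov < 0 or minor_cov < 0:
        raise ValueError("coverages must be non-negative")
    total = major_cov + minor_cov
    if total == 0:
        call, hom = CALL_UNKNOWN, None
    else:
        observed_minor = min(major_cov, minor_cov)
        if observed_minor / total >= het_fraction:
            call, hom = CALL_HET, None
        else:
            call = CALL_HOM
            hom = "major" if major_cov >= minor_cov else "rare"
    return GenotypeCall(
        sample_id=sample_id,
        rsnp_site=rsnp_site,
        major_coverage=major_cov,
        minor_coverage=minor_cov,
        call=call,
        n_markers_used=n_markers_used,
        hom_allele=hom,
    )


@dataclass
class CohortSplit:
    """Outcome of splitting one rSNP's cohort into genotype groups."""

    status: str  # 'ok' or 'insufficient'
    failed_criterion: str | None
    het_samples: list[str]
    hom_samples: list[str]

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def split_cohort(
    calls: list[GenotypeCall],
    min_individuals: int = 6,
    min_minor_carriers: int = 3,
) -> CohortSplit:
    """Heterozygous vs homozygous groups for one rSNP, or why not.

    Two admission criteria: the variant must be genotyped in at least
    ``min_individuals`` individuals, and the minor rSNP allele must be
    seen in at least ``min_minor_carriers`` of them. A failed criterion is
    reported by name instead of raising.
    """
    genotyped = [c for c in calls if c.call != CALL_UNKNOWN]
    if len(genotyped) < min_individuals:
        return CohortSplit("insufficient", "min_individuals", [], [])
    carriers = sum(c.minor_carrier for c in genotyped)
    if carriers < min_minor_carriers:
        return CohortSplit("insufficient", "min_minor_carriers", [], [])
    het = [c.sample_id for c in genotyped if c.call == CALL_HET]
    hom = [c.sample_id for c in genotyped if c.call == CALL_HOM]
    return CohortSplit("ok", None, het, hom)


def genotype_cohort(
    coverage: pd.DataFrame,
    matrix: GenotypeMatrix,
    rsnp: str,
    markers: list[LinkedPair],
    het_fraction: float = HET_FRACTION,
    max_markers: int = 10,
) -> list[GenotypeCall]:
    """Call every cohort sample's genotype at one rSNP.

    ``coverage`` holds per-sample allele counts (columns sample, site_id,
    ref, alt, ref_count, alt_count); counts are reoriented to each site's
    (major, rare) alleles via the genotype matrix before aggregation.
    """
    def orient(row, sid) -> tuple[int, int]:
        rare_is_alt = matrix.rare_allele(sid) == matrix.sites.loc[
            matrix.index_of(sid), "alt"
        ]
        if rare_is_alt:
            return int(row["ref_count"]), int(row["alt_count"])
        return int(row["alt_count"]), int(row["ref_count"])

    by_sample_site = {
        (r["sample"], r["site_id"]): r for _, r in coverage.iterrows()
    }
    samples = sorted(coverage["sample"].unique())
    calls = []
    for sample in samples:
        row = by_sample_site.get((sample, rsnp))
        direct = orient(row, rsnp) if row is not None else (0, 0)
        marker_cov = []
        for pair in markers:
            mrow = by_sample_site.get((sample, pair.marker_site))
            if mrow is None:
                continue
            marker_cov.append((pair, orient(mrow, pair.marker_site)))
        major, minor, used = aggregate_marker_coverage(
            direct, marker_cov, max_markers=max_markers
        )
        calls.append(
            call_genotype(
                (major, minor),
                sample_id=sample,
                rsnp_site=rsnp,
                het_fraction=het_fraction,
                n_markers_used=used,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# differential expression (pluggable)

DE_METHODS: dict = {}


def register_de_method(name: str):
    """Decorator: register a DE method callable(counts, group_a, group_b)
    returning a DataFrame with gene_id, log2fc, p_value."""

    def wrap(fn):
        DE_METHODS[name] = fn
        return fn

    return wrap


@register_de_method("builtin-welch")
def _welch_de(counts: pd.DataFrame, group_a: list[str], group_b: list[str]) -> pd.DataFrame:
    """Library-size normalized Welch test per gene.

    Counts are scaled to CPM, log2(CPM + 1) transformed, and compared
    between groups with Welch's unequal-variance t-test. A deliberately
    simple stand-in for a dedicated count-model DE package, exposed
    through the same interface.
    """
    lib = counts.sum(axis=0).astype(float)
    cpm = counts / lib * 1e6
    log = np.log2(cpm + 1.0)
    a = log[group_a].to_numpy()
    b = log[group_b].to_numpy()
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2fc": a.mean(axis=1) - b.mean(axis=1),
            "p_value": p,
        }
    )


def differential_expression(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    method: str = "builtin-welch",
    alpha: float = 0.1,
    structures: pd.Series | None = None,
) -> pd.DataFrame:
    """Genes differentially expressed between two genotype groups.

    Both groups need at least three samples. P-values are Bonferroni
    corrected (``padj``); ``deg`` flags padj < ``alpha``. When a
    per-sample ``structures`` series is given (e.g. brain structures),
    each structure is analyzed separately and results are concatenated
    with a ``structure`` column; structures lacking three samples per
    group are skipped.
    """
    if method not in DE_METHODS:
        raise ValueError(f"unknown DE method {method!r}; registered: {sorted(DE_METHODS)}")
    if structures is not None:
        frames = []
        for structure in sorted(structures.unique()):
            in_s = set(structures[structures == structure].index)
            ga = [s for s in group_a if s in in_s]
            gb = [s for s in group_b if s in in_s]
            if len(ga) < 3 or len(gb) < 3:
                continue
            sub = differential_expression(counts, ga, gb, method=method, alpha=alpha)
            sub.insert(0, "structure", structure)
            frames.append(sub)
        if not frames:
            raise ValueError("no structure has three samples per genotype group")
        return pd.concat(frames, ignore_index=True)
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError(
            "each genotype group needs at least three individuals "
            f"(got {len(group_a)} and {len(group_b)})"
        )
    res = DE_METHODS[method](counts, list(group_a), list(group_b))
    res = res.copy()
    res["padj"] = multipletests(res["p_value"], method="bonferroni")[1]
    res["deg"] = res["padj"] < alpha
    return res
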