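"""Region classification and catalog-overlap summaries.

Assigns each site the genomic classes it falls in (intronic, UTRs,
promoter, CDS; intergenic when none), counts overlap of site sets with
annotation catalogs, and normalizes per-tissue eQTL hit counts by catalog
tissue sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import pandas as pd

from ._coords import position_in_interval, promoter_interval
from .io import AnnotationCatalog, GeneModel

REGION_CLASSES = ("intronic", "utr5", "utr3", "promoter", "cds", "intergenic")


@dataclass(frozen=True)
class RegionClassification:
    site_id: str
    classes: frozenset

    def __post_init__(self):
        unknown = self.classes - set(REGION_CLASSES)
        if unknown:
            raise ValueError(f"unknown region classes: {sorted(unknown)}")
        if "intergenic" in self.classes and len(self.classes) > 1:
            raise ValueError("intergenic is exclusive of all other classes")


def classify_region(
    site: pd.Series | dict,
    gene_models: list[GeneModel],
    promoter_window: tuple[int, int] = (1000, 500),
) -> RegionClassification:
    """Multi-label genomic classification of one SNP.

    A site may be, say, promoter for one gene and intronic for an
    overlapping neighbour; all labels across overlapping genes are kept.
    Introns are gene body minus exons. Intergenic iff no feature or
    promoter of any gene covers the position.
    """
    chrom, pos = site["chrom"], int(site["pos"])
    up, down = promoter_window
    classes: set[str] = set()
    for g in gene_models:
        if g.chrom != chrom:
            continue
        ps, pe = promoter_interval(g.tss, g.strand, up, down)
        if position_in_interval(pos, ps, pe):
            classes.add("promoter")
        for label, ivs in (("utr5", g.utr5), ("utr3", g.utr3), ("cds", g.cds)):
            if any(position_in_interval(pos, s, e) for s, e in ivs):
                classes.add(label)
        span = g.span
        in_body = position_in_interval(pos, *span)
        in_exon = any(position_in_interval(pos, s, e) for s, e in g.exons)
        if in_body and not in_exon:
            classes.add("intronic")
    if not classes:
        classes = {"intergenic"}
    return RegionClassification(site["site_id"], frozenset(classes))


def classify_regions(
    sites: pd.DataFrame,
    gene_models: list[GeneModel],
    promoter_window: tuple[int, int] = (1000, 500),
) -> pd.DataFrame:
    """Per-class membership flags for a site table, plus a count summary."""
    rows = []
    for _, site in sites.iterrows():
        rc = classify_region(site, gene_models, promoter_window)
        rows.append(
            {"site_id": rc.site_id, **{c: c in rc.classes for c in REGION_CLASSES}}
        )
    return pd.DataFrame(rows)


def overlap_catalog(
    sites: list[str] | pd.Series, catalog: AnnotationCatalog
) -> tuple[int, float]:
    """Hit count and fraction of a deduplicated site set in a catalog."""
    unique = pd.unique(pd.Series(list(sites)))
    if len(unique) == 0:
        raise ValueError("empty site set")
    hits = sum(s in catalog.sites for s in unique)
    return hits, hits / len(unique)


def tissue_normalized_counts(
    hits: pd.DataFrame, totals: dict[str, int]
) -> pd.Series:
    """Per-tissue hit counts normalized by the tissue's catalog size.

    ``hits`` has site_id and tissue columns (one row per hit). Tissues
    with zero or missing totals are omitted with a warning. Sorted
    descending by normalized value.
    """
    counts = hits.groupby("tissue")["site_id"].nunique()
    out = {}
    skipped = []
    for tissue, n in counts.items():
        total = totals.get(tissue, 0)
        if total <= 0:
            skipped.append(tissue)
            continue
        out[tissue] = n / total
    if skipped:
        warnings.warn(
            f"tissues omitted for zero catalog totals: {sorted(skipped)}",
            stacklevel=2,
        )
    return pd.Series(out, name="normalized_eqtl_count").sort_values(ascending=False)
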