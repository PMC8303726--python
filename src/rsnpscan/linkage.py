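"""Linkage by normalized Hamming distance and carrier conditional probability.

LD between two SNPs is measured on rare-allele count vectors (0/1/2 per
individual) as

    NHD(a, b) = sum_i |a_i - b_i| / sum_i (a_i + b_i)

which is 0 when rare alleles always co-occur and 1 under complete
anti-association. Tightly linked expressed coding SNPs (markers) then
stand in for a non-transcribed regulatory SNP: the conditional probability
that a marker-allele carrier also carries the rSNP allele quantifies how
reliable the proxy is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

GENOTYPE_LEVELS = (0, 1, 2)


@dataclass(frozen=True)
class LinkedPair:
    """A (coding marker, rSNP) pair with its linkage evidence.

    ``orientation`` records which marker allele predicts the rSNP rare
    allele: 'direct' (rare predicts rare) or 'swapped' (the marker's major
    allele predicts the rSNP's rare allele).
    """

    marker_site: str
    rsnp_site: str
    nhd: float
    conditional_probability: float
    orientation: str = "direct"

    @property
    def allele_map(self) -> dict:
        if self.orientation == "direct":
            return {"rare": "rare", "major": "major"}
        return {"rare": "major", "major": "rare"}


def nhd(a, b) -> float:
    """Normalized Hamming distance between two rare-allele count vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("vectors must be 1-D, non-empty and of equal length")
    if not (np.isin(a, GENOTYPE_LEVELS).all() and np.isin(b, GENOTYPE_LEVELS).all()):
        raise ValueError("values must be rare-allele counts in {0, 1, 2}")
    denom = int(a.sum() + b.sum())
    if denom == 0:
        raise ValueError("NHD undefined: no rare alleles at either site")
    return float(np.abs(a.astype(int) - b.astype(int)).sum() / denom)


def find_linked_pairs(
    matrix: GenotypeMatrix,
    anchors: list[str],
    candidates: list[str],
    max_nhd: float,
) -> pd.DataFrame:
    """All (anchor, candidate) pairs with NHD at or below ``max_nhd``.

    Self-pairs are reported when a site appears in both lists (they have
    NHD zero by definition). Pairs where neither site carries any rare
    allele are skipped — NHD is undefined there.
    """
    cand_idx = np.array([matrix.index_of(s) for s in candidates])
    cand_vals = matrix.values[:, cand_idx].astype(np.int64)
    cand_sums = cand_vals.sum(axis=0)
    rows = []
    for anchor in anchors:
        av = matrix.site_column(anchor).astype(np.int64)[:, None]
        num = np.abs(cand_vals - av).sum(axis=0)
        den = int(av.sum()) + cand_sums
        ok = den > 0
        dist = np.full(len(candidates), np.inf)
        dist[ok] = num[ok] / den[ok]
        for j in np.flatnonzero(dist <= max_nhd):
            rows.append((anchor, candidates[j], float(dist[j])))
    return pd.DataFrame(rows, columns=["anchor", "candidate", "nhd"])


def carrier_contingency(
    matrix: GenotypeMatrix, site_a: str, site_b: str
) -> pd.DataFrame:
    """3x3 table of individuals by rare-allele count at two sites.

    Rows index the genotype (0/1/2 rare-allele copies) at ``site_a``,
    columns at ``site_b``. Marginals are available from the returned frame
    (`.sum(axis=...)`); the grand total is the number of individuals.
    """
    a = matrix.site_column(site_a)
    b = matrix.site_column(site_b)
    table = np.zeros((3, 3), dtype=int)
    for i, j in zip(a, b):
        table[i, j] += 1
    return pd.DataFrame(
        table,
        index=pd.Index(GENOTYPE_LEVELS, name=site_a),
        columns=pd.Index(GENOTYPE_LEVELS, name=site_b),
    )


def conditional_probability(table: pd.DataFrame | np.ndarray) -> float:
    """P(target carrier | marker carrier) from a 3x3 genotype table.

    Rows are the target (rSNP) rare-allele count, columns the marker's. A
    carrier holds at least one copy of the stated allele; the probability
    is the joint carrier count over the marker-carrier marginal.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (3, 3) or (t < 0).any():
        raise ValueError("expected a 3x3 genotype contingency table")
    marker_carriers = t[:, 1:].sum()
    if marker_carriers == 0:
        raise ValueError("no marker-allele carriers: conditional probability undefined")
    joint = t[1:, 1:].sum()
    return float(joint / marker_carriers)


def _orient(matrix: GenotypeMatrix, marker: str, rsnp: str) -> tuple[float, str]:
    """NHD under the better allele orientation of the marker.

    When the marker's *major* allele travels with the rSNP's rare allele
    (anti-association), flipping the marker vector (2 - g) recovers the
    linkage; the flipped distance being smaller marks the pair 'swapped'.
    """
    mv = matrix.site_column(marker).astype(np.int64)
    rv = matrix.site_column(rsnp).astype(np.int64)
    direct = np.inf
    if mv.sum() + rv.sum() > 0:
        direct = nhd(mv, rv)
    flipped_vec = 2 - mv
    swapped = np.inf
    if flipped_vec.sum() + rv.sum() > 0:
        swapped = nhd(flipped_vec, rv)
    if swapped < direct:
        return swapped, "swapped"
    return direct, "direct"


def select_markers(
    rsnp: str,
    coding_sites: list[str],
    matrix: GenotypeMatrix,
    cp_min: float = 0.9,
    nhd_max: float = 0.1,
    max_markers: int = 10,
) -> list[LinkedPair]:
    """Rank coding markers for one rSNP by linkage quality.

    Keeps markers with NHD <= ``nhd_max`` (under the better allele
    orientation) and carrier conditional probability >= ``cp_min``, sorted
    ascending by NHD (ties by marker id), truncated to ``max_markers``.
    """
    if not coding_sites:
        raise ValueError("coding_sites must be nonempty")
    scored = []
    rv = matrix.site_column(rsnp).astype(np.int64)
    for marker in coding_sites:
        dist, orientation = _orient(matrix, marker, rsnp)
        if not np.isfinite(dist) or dist > nhd_max:
            continue
        mv = matrix.site_column(marker).astype(np.int64)
        if orientation == "swapped":
            mv = 2 - mv
        table = np.zeros((3, 3), dtype=int)
        for i, j in zip(rv, mv):
            table[i, j] += 1
        try:
            cp = conditional_probability(table)
        except ValueError:
            continue
        if cp < cp_min:
            continue
        scored.append(LinkedPair(marker, rsnp, dist, cp, orientation))
    scored.sort(key=lambda p: (p.nhd, p.marker_site))
    return scored[:max_markers]


def linked_pairs_table(pairs: list[LinkedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.marker_site, p.rsnp_site, p.nhd, p.conditional_probability, p.orientation)
            for p in pairs
        ],
        columns=["marker_site", "rsnp_site", "nhd", "conditional_probability", "orientation"],
    )
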