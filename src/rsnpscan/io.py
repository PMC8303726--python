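"""Readers and writers for every external format the pipeline touches.

All tabular formats are plain TSV with headers; genotypes may also arrive
as diploid VCF (parsed with cyvcf2). Validation is strict: malformed rows
fail with the offending line number, missing columns fail naming the
column. Sex chromosomes and mitochondrial DNA are excluded on ingest.

Conventions: SNP positions 1-based, intervals 0-based half-open
(see :mod:`rsnpscan._coords`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._coords import is_excluded_chrom, site_id

logger = logging.getLogger(__name__)

ALLELE_COUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_count", "alt_count", "sample"]
ASSAYS = ("chip", "rna")

Interval = tuple[int, int]


# ---------------------------------------------------------------------------
# gene models / enhancers / catalogs


@dataclass
class GeneModel:
    """A gene with its TSS and feature intervals (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int  # 1-based
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be +/-")
        for name in ("exons", "cds", "utr5", "utr3"):
            ivs = sorted(getattr(self, name))
            for s, e in ivs:
                if e <= s:
                    raise ValueError(
                        f"gene {self.gene_id}: empty {name} interval ({s},{e})"
                    )
            setattr(self, name, ivs)
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")

    @property
    def span(self) -> Interval:
        """Gene body: leftmost exon start to rightmost exon end."""
        return self.exons[0][0], max(e for _, e in self.exons)


@dataclass(frozen=True)
class EnhancerRecord:
    chrom: str
    start: int  # 0-based half-open
    end: int
    target_gene: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("enhancer interval must have positive length")


@dataclass
class AnnotationCatalog:
    """A named set of annotated site ids (eQTL or GWAS style).

    ``entries`` is a DataFrame with a ``site_id`` column and optional
    ``tissue`` / ``significance`` columns; ``sites`` gives the unique ids.
    """

    name: str
    entries: pd.DataFrame

    def __post_init__(self) -> None:
        if "site_id" not in self.entries.columns:
            raise ValueError("catalog requires a site_id column")

    @property
    def sites(self) -> set[str]:
        return set(self.entries["site_id"])

    def __contains__(self, sid: str) -> bool:
        return sid in self.sites


# ---------------------------------------------------------------------------
# genotype matrix


class GenotypeMatrix:
    """Individuals x sites matrix of rare-allele counts in {0, 1, 2}.

    The rare allele at each site is the matrix-wide minor allele by
    frequency; values count copies of that allele per individual.
    """

    def __init__(
        self,
        individuals: list[str],
        sites: pd.DataFrame,
        values: np.ndarray,
        recode: bool = True,
    ):
        required = {"site_id", "chrom", "pos", "ref", "alt"}
        missing = required - set(sites.columns)
        if missing:
            raise ValueError(f"sites table missing columns: {sorted(missing)}")
        values = np.asarray(values)
        if values.shape != (len(individuals), len(sites)):
            raise ValueError(
                f"values shape {values.shape} != "
                f"({len(individuals)}, {len(sites)})"
            )
        if not np.isin(values, (0, 1, 2)).all():
            raise ValueError("genotype values must be in {0, 1, 2}")
        self.individuals = list(individuals)
        self.sites = sites.reset_index(drop=True).copy()
        self.values = values.astype(np.int8)
        if recode:
            self._recode_to_minor()
        elif "rare_allele" not in self.sites.columns:
            self.sites["rare_allele"] = self.sites["alt"]
        self._site_index = {s: i for i, s in enumerate(self.sites["site_id"])}

    def _recode_to_minor(self) -> None:
        """Flip sites where the designated allele is actually major.

        On input, values count ALT copies; after recoding they count copies
        of the matrix-wide minor allele, recorded in ``rare_allele``.
        Ties go to ALT.
        """
        freq = self.values.mean(axis=0) / 2.0
        flip = freq > 0.5
        self.values[:, flip] = 2 - self.values[:, flip]
        rare = np.where(flip, self.sites["ref"], self.sites["alt"])
        self.sites["rare_allele"] = rare

    # -- accessors ---------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> list[str]:
        return list(self.sites["site_id"])

    def site_column(self, sid: str) -> np.ndarray:
        return self.values[:, self.index_of(sid)]

    def index_of(self, sid: str) -> int:
        try:
            return self._site_index[sid]
        except KeyError:
            raise KeyError(f"site {sid!r} not in matrix") from None

    def rare_allele(self, sid: str) -> str:
        return self.sites.loc[self.index_of(sid), "rare_allele"]

    @classmethod
    def from_contingency(
        cls,
        table: np.ndarray,
        row_site: str = "siteA",
        col_site: str = "siteB",
    ) -> "GenotypeMatrix":
        """Expand a 3x3 genotype contingency table into synthetic individuals.

        Cell (i, j) holds the number of individuals with i rare-allele
        copies at ``row_site`` and j at ``col_site``. Useful for
        re-ingesting a published contingency table as a genotype matrix.
        """
        table = np.asarray(table, dtype=int)
        if table.shape != (3, 3) or (table < 0).any():
            raise ValueError("contingency table must be 3x3 with counts >= 0")
        a, b = [], []
        for i in range(3):
            for j in range(3):
                a.extend([i] * table[i, j])
                b.extend([j] * table[i, j])
        n = len(a)
        if n == 0:
            raise ValueError("contingency table is all zero")
        sites = pd.DataFrame(
            {
                "site_id": [row_site, col_site],
                "chrom": ["chrU", "chrU"],
                "pos": [1, 2],
                "ref": ["A", "C"],
                "alt": ["G", "T"],
            }
        )
        return cls(
            [f"ind{i:04d}" for i in range(n)],
            sites,
            np.column_stack([a, b]),
            recode=False,
        )


# ---------------------------------------------------------------------------
# allele-count tables


def read_allele_counts(path, assay: str) -> pd.DataFrame:
    """Read a per-sample allele-count TSV into a validated table.

    Returns columns chrom, pos, ref, alt, ref_count, alt_count, sample,
    assay, site_id, total. Rows on excluded chromosomes are dropped (count
    logged); malformed rows are hard errors naming the line.
    """
    if assay not in ASSAYS:
        raise ValueError(f"assay must be one of {ASSAYS}, got {assay!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ALLELE_COUNT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"allele-count file {path}: missing column {col!r}")
    df = df[ALLELE_COUNT_COLUMNS].copy()
    for col in ("pos", "ref_count", "alt_count"):
        try:
            df[col] = df[col].astype(int)
        except (TypeError, ValueError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(
                f"allele-count file {path}, line {line}: non-integer {col}"
            ) from exc
    for col in ("ref_count", "alt_count"):
        neg = df[col] < 0
        if neg.any():
            line = int(neg.idxmax()) + 2
            raise ValueError(
                f"allele-count file {path}, line {line}: negative {col}"
            )
    same = df["ref"] == df["alt"]
    if same.any():
        line = int(same.idxmax()) + 2
        raise ValueError(f"allele-count file {path}, line {line}: ref == alt")
    excluded = df["chrom"].map(is_excluded_chrom)
    if excluded.any():
        logger.info("dropped %d rows on excluded chromosomes", int(excluded.sum()))
        df = df[~excluded].reset_index(drop=True)
    df["assay"] = assay
    df["site_id"] = [site_id(c, p) for c, p in zip(df["chrom"], df["pos"])]
    df["total"] = df["ref_count"] + df["alt_count"]
    return df


def write_allele_counts(df: pd.DataFrame, path) -> None:
    df[ALLELE_COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def apply_position_mask(df: pd.DataFrame, mask: pd.DataFrame) -> pd.DataFrame:
    """Drop records at masked positions (e.g. indel-proximal sites).

    ``mask`` is a TSV-derived table with chrom and pos columns; masking is
    applied as an input filter because the indel calls it derives from are
    produced upstream of this package.
    """
    masked = set(zip(mask["chrom"], mask["pos"]))
    keep = [
        (c, p) not in masked for c, p in zip(df["chrom"], df["pos"])
    ]
    dropped = len(df) - sum(keep)
    if dropped:
        logger.info("position mask removed %d records", dropped)
    return df[keep].reset_index(drop=True)


def read_position_mask(path) -> pd.DataFrame:
    mask = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos"):
        if col not in mask.columns:
            raise ValueError(f"mask file {path}: missing column {col!r}")
    return mask


# ---------------------------------------------------------------------------
# genotypes (VCF or 0/1/2 TSV)


def read_genotypes(path) -> GenotypeMatrix:
    """Read genotypes from VCF (diploid GT) or the 0/1/2 TSV dialect.

    Values are recoded so they count copies of the matrix-wide minor
    allele. Multi-allelic sites are skipped with a warning; non-diploid
    genotypes are a hard error.
    """
    path = str(path)
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        return _read_genotypes_vcf(path)
    return _read_genotypes_tsv(path)


def _read_genotypes_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    individuals = list(vcf.samples)
    rows, meta, skipped = [], [], 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        if is_excluded_chrom(var.CHROM):
            continue
        gts = np.asarray(var.genotype.array())
        if gts.shape[1] != 3:  # two alleles + phase flag
            raise ValueError(f"non-diploid genotype at {var.CHROM}:{var.POS}")
        alleles = gts[:, :2]
        if (alleles < 0).any():
            raise ValueError(f"missing genotype at {var.CHROM}:{var.POS}")
        rows.append(alleles.sum(axis=1))
        meta.append((site_id(var.CHROM, var.POS), var.CHROM, var.POS, var.REF, var.ALT[0]))
    if skipped:
        warnings.warn(f"skipped {skipped} multi-allelic sites", stacklevel=2)
    sites = pd.DataFrame(meta, columns=["site_id", "chrom", "pos", "ref", "alt"])
    values = np.column_stack(rows) if rows else np.zeros((len(individuals), 0), int)
    return GenotypeMatrix(individuals, sites, values)


def _read_genotypes_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    fixed = ["site_id", "chrom", "pos", "ref", "alt"]
    for col in fixed:
        if col not in df.columns:
            raise ValueError(f"genotype TSV {path}: missing column {col!r}")
    multi = df["alt"].str.contains(",")
    if multi.any():
        warnings.warn(f"skipped {int(multi.sum())} multi-allelic sites", stacklevel=2)
        df = df[~multi].reset_index(drop=True)
    df = df[~df["chrom"].map(is_excluded_chrom)].reset_index(drop=True)
    individuals = [c for c in df.columns if c not in fixed]
    values = df[individuals].to_numpy().T
    return GenotypeMatrix(individuals, df[fixed], values)


def write_genotypes_tsv(matrix: GenotypeMatrix, path) -> None:
    out = matrix.sites[["site_id", "chrom", "pos", "ref", "alt"]].copy()
    # written as ALT-allele counts so write->read round-trips exactly
    vals = matrix.values.copy()
    flip = matrix.sites["rare_allele"].to_numpy() == matrix.sites["ref"].to_numpy()
    vals[:, flip] = 2 - vals[:, flip]
    gt = pd.DataFrame(vals.T, columns=matrix.individuals, index=out.index)
    pd.concat([out, gt], axis=1).to_csv(path, sep="\t", index=False)


def write_genotypes_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal diploid VCF (GT only, unphased)."""
    vals = matrix.values.copy()
    flip = matrix.sites["rare_allele"].to_numpy() == matrix.sites["ref"].to_numpy()
    vals[:, flip] = 2 - vals[:, flip]
    gt_strings = np.array(["0/0", "0/1", "1/1"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(matrix.sites["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.individuals)
            + "\n"
        )
        for j, row in matrix.sites.iterrows():
            gts = "\t".join(gt_strings[vals[:, j]])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.site_id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# gene models (GFF-lite TSV), enhancers (BED), catalogs (TSV)

GENE_MODEL_COLUMNS = ["gene_id", "chrom", "strand", "tss", "feature", "start", "end"]
_FEATURES = {"exon": "exons", "cds": "cds", "utr5": "utr5", "utr3": "utr3"}


def read_gene_models(path) -> list[GeneModel]:
    """Read the GFF-lite TSV: one row per feature interval per gene."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in GENE_MODEL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"gene-model file {path}: missing column {col!r}")
    genes = []
    for gid, grp in df.groupby("gene_id", sort=True):
        chroms = grp["chrom"].unique()
        if len(chroms) != 1:
            raise ValueError(f"gene {gid}: features on multiple chromosomes")
        if is_excluded_chrom(chroms[0]):
            continue
        kwargs = {v: [] for v in _FEATURES.values()}
        for _, row in grp.iterrows():
            if row.feature not in _FEATURES:
                raise ValueError(f"gene {gid}: unknown feature {row.feature!r}")
            kwargs[_FEATURES[row.feature]].append((int(row.start), int(row.end)))
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=chroms[0],
                strand=grp["strand"].iloc[0],
                tss=int(grp["tss"].iloc[0]),
                **kwargs,
            )
        )
    return genes


def write_gene_models(genes: list[GeneModel], path) -> None:
    rows = []
    for g in genes:
        for feature, attr in _FEATURES.items():
            for s, e in getattr(g, attr):
                rows.append((g.gene_id, g.chrom, g.strand, g.tss, feature, s, e))
    pd.DataFrame(rows, columns=GENE_MODEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_enhancers(path) -> list[EnhancerRecord]:
    """BED4: chrom, start, end (0-based half-open), target gene."""
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"enhancer BED {path}, line {lineno}: need 4 columns")
            chrom, start, end, gene = parts[:4]
            if is_excluded_chrom(chrom):
                continue
            recs.append(EnhancerRecord(chrom, int(start), int(end), gene))
    return recs


def write_enhancers(recs: list[EnhancerRecord], path) -> None:
    with open(path, "w") as fh:
        for r in recs:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.target_gene}\n")


def read_catalog(path, name: str) -> AnnotationCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "site_id" not in df.columns:
        raise ValueError(f"catalog file {path}: missing column 'site_id'")
    # exact duplicate rows are collapsed with a warning; the same site with
    # different annotations (e.g. tissues) is legitimate for eQTL catalogs
    n_dup = int(df.duplicated().sum())
    if n_dup:
        warnings.warn(f"catalog {name}: dropped {n_dup} duplicate entries", stacklevel=2)
        df = df.drop_duplicates().reset_index(drop=True)
    return AnnotationCatalog(name, df)


def write_catalog(cat: AnnotationCatalog, path) -> None:
    cat.entries.to_csv(path, sep="\t", index=False)
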