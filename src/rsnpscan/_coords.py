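"""Coordinate conventions, centralized.

SNP positions are 1-based (VCF convention); all intervals are 0-based,
half-open (BED convention). Every conversion between the two goes through
this module so the off-by-one rules live in exactly one place.
"""

from __future__ import annotations

EXCLUDED_CHROMS = frozenset(
    {"chrX", "chrY", "chrM", "chrMT", "X", "Y", "M", "MT"}
)


def pos_to_interval(pos: int) -> tuple[int, int]:
    """1-based position -> the 0-based half-open interval covering it."""
    return pos - 1, pos


def position_in_interval(pos: int, start: int, end: int) -> bool:
    """Is a 1-based position inside a 0-based half-open interval?"""
    return start <= pos - 1 < end


def promoter_interval(
    tss: int, strand: str, upstream: int = 1000, downstream: int = 500
) -> tuple[int, int]:
    """Strand-aware promoter window around a 1-based TSS.

    Covers ``upstream`` bases before the TSS and ``downstream`` bases from
    the TSS onward, both measured in the direction of transcription. The
    returned interval is 0-based half-open and always includes the TSS base
    itself.
    """
    if upstream < 0 or downstream <= 0:
        raise ValueError("promoter window must have upstream >= 0, downstream > 0")
    t0 = tss - 1
    if strand == "+":
        return t0 - upstream, t0 + downstream
    if strand == "-":
        # transcription runs right-to-left: upstream is to the right
        return t0 - downstream + 1, t0 + upstream + 1
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def site_id(chrom: str, pos: int) -> str:
    return f"{chrom}:{pos}"


def is_excluded_chrom(chrom: str) -> bool:
    """Sex chromosomes and mitochondrial DNA are dropped on ingest."""
    return chrom in EXCLUDED_CHROMS
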