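"""Exon-skipping splicing index from spliced alignments.

Counts reads supporting the inclusion junction (exon 4|5) and the
skipping junction (exon 4|6) of a target gene, then computes the
percent-alternative-splicing statistic

    %AS = 100 * count(4|6) / count(4|5)

Note this is a skip-to-inclusion *ratio*, not a fraction of the total
(PSI = inclusion/(inclusion+skipping) is a different quantity), so %AS
can exceed 100 when the skipping isoform dominates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pysam

from .gene_model import GeneModel, Junction, junction_for

__all__ = [
    "JunctionCountRecord",
    "SplicingIndexResult",
    "count_junction_reads",
    "compute_percent_AS",
]

_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X


@dataclass(frozen=True)
class JunctionCountRecord:
    """Per-sample junction-read counts for one inclusion/skipping pair."""

    sample_id: str
    inclusion_count: int
    skipping_count: int

    def __post_init__(self) -> None:
        if self.inclusion_count < 0 or self.skipping_count < 0:
            raise ValueError("junction counts must be nonnegative")

    @property
    def total_informative(self) -> int:
        return self.inclusion_count + self.skipping_count


@dataclass(frozen=True)
class SplicingIndexResult:
    """%AS for one sample; ``percent_AS`` is None when inclusion_count = 0."""

    sample_id: str
    percent_AS: float | None
    inclusion_count: int
    skipping_count: int
    low_coverage_flag: bool
    undefined_flag: bool = False


def _cigar_walk(read: pysam.AlignedSegment) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Return (aligned blocks, N-gap intervals), both half-open genomic."""
    blocks: list[tuple[int, int]] = []
    gaps: list[tuple[int, int]] = []
    pos = read.reference_start
    for op, length in read.cigartuples:
        if op in (0, 7, 8):  # aligned bases
            blocks.append((pos, pos + length))
        elif op == 3:  # N: spliced gap
            gaps.append((pos, pos + length))
        if op in _REF_CONSUMING:
            pos += length
    return blocks, gaps


def _supports_junction_exact(gaps: Iterable[tuple[int, int]], junction: Junction) -> bool:
    return junction.gap in gaps


def _overlaps_any(blocks: Iterable[tuple[int, int]], start: int, end: int) -> bool:
    return any(s < end and start < e for s, e in blocks)


def count_junction_reads(
    alignments: str | Path,
    model: GeneModel,
    trio: tuple[int, int, int] = (4, 5, 6),
    mode: str = "junction-exact",
    sample_id: str | None = None,
    exclude_duplicates: bool = True,
) -> JunctionCountRecord:
    """Count inclusion- and skipping-junction reads for an exon trio.

    For trio (a, m, b) the inclusion junction is a|m and the skipping
    junction a|b (the middle exon m spliced out).

    Modes
    -----
    ``junction-exact`` (default)
        A read supports a junction iff one of its spliced (CIGAR ``N``)
        gaps coincides exactly with the junction's donor/acceptor
        boundaries (0-base tolerance).
    ``exon-overlap``
        A read supports a pair iff its aligned blocks intersect both
        exons of the pair and do not intersect the intervening exon.

    Unmapped, secondary and supplementary records are excluded, as are
    duplicates by default.  Mates of a pair are counted independently but
    a query name contributes at most once per junction pair.
    """
    if mode not in ("junction-exact", "exon-overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    a, m, b = trio
    exon_a, exon_m, exon_b = model.exon(a), model.exon(m), model.exon(b)
    inclusion = junction_for(model, a, m)
    skipping = junction_for(model, a, b)

    path = Path(alignments)
    if sample_id is None:
        sample_id = path.name.removesuffix(".bam").removesuffix(".sam")
    with pysam.AlignmentFile(str(path)) as af:
        if model.chrom not in af.references:
            raise ValueError(
                f"chromosome {model.chrom!r} absent from alignment header"
            )
        lo, hi = model.span
        seen_incl: set[str] = set()
        seen_skip: set[str] = set()
        for read in af.fetch(model.chrom, lo, hi):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if exclude_duplicates and read.is_duplicate:
                continue
            if read.cigartuples is None:
                continue
            blocks, gaps = _cigar_walk(read)
            if mode == "junction-exact":
                is_incl = _supports_junction_exact(gaps, inclusion)
                is_skip = _supports_junction_exact(gaps, skipping)
            else:
                hits_a = _overlaps_any(blocks, exon_a.start, exon_a.end)
                hits_m = _overlaps_any(blocks, exon_m.start, exon_m.end)
                hits_b = _overlaps_any(blocks, exon_b.start, exon_b.end)
                is_incl = hits_a and hits_m
                is_skip = hits_a and hits_b and not hits_m
            if is_incl:
                seen_incl.add(read.query_name)
            if is_skip:
                seen_skip.add(read.query_name)
    return JunctionCountRecord(
        sample_id=sample_id,
        inclusion_count=len(seen_incl),
        skipping_count=len(seen_skip),
    )


def compute_percent_AS(
    record: JunctionCountRecord, min_informative: int = 10
) -> SplicingIndexResult:
    """%AS = 100 x skipping/inclusion; undefined (flagged) when inclusion = 0.

    ``low_coverage_flag`` is set when inclusion + skipping reads fall
    below ``min_informative`` (default 10).
    """
    if record.inclusion_count > 0:
        percent = 100.0 * record.skipping_count / record.inclusion_count
        undefined = False
    else:
        percent = None
        undefined = True
    return SplicingIndexResult(
        sample_id=record.sample_id,
        percent_AS=percent,
        inclusion_count=record.inclusion_count,
        skipping_count=record.skipping_count,
        low_coverage_flag=record.total_informative < min_informative,
        undefined_flag=undefined,
    )
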