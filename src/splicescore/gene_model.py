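"""Single-gene coding-exon models and exon-skipping arithmetic.

A :class:`GeneModel` holds the ordered coding exons of one gene
(5'→3' in transcript direction, 0-based half-open genomic coordinates).
From it we derive splice-junction coordinates (donor/acceptor pairs such
as the exon 4|5 inclusion junction and the 4|6 skipping junction) and the
transcript/protein consequence of skipping an internal exon: how many
coding nucleotides are removed, whether the reading frame is preserved,
and — when the skipped exon's boundaries fall on codon boundaries — the
exact 1-based residue range deleted from the protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gffutils

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "Junction",
    "SkipConsequence",
    "load_gene_model",
    "write_bed12",
    "junction_for",
    "exon_skip_consequence",
]


class GeneModelError(ValueError):
    """Raised for malformed annotations or invalid exon requests."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval: 0-based start (inclusive), end (exclusive)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise GeneModelError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise GeneModelError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class GeneModel:
    """Ordered coding exons of one gene.

    ``intervals`` are listed 5'→3' in transcript direction: ascending
    genomic coordinates on the + strand, descending on the − strand.
    ``cds_offset`` is the number of nucleotides of the first listed exon
    preceding the start codon (0 when the model is pure CDS).
    """

    gene_id: str
    intervals: list[GenomicInterval]
    cds_offset: int = 0
    complete: bool = True

    def __post_init__(self) -> None:
        if not self.intervals:
            raise GeneModelError(f"gene {self.gene_id!r} has zero coding exons")
        if self.cds_offset < 0:
            raise GeneModelError("cds_offset must be >= 0")
        chroms = {iv.chrom for iv in self.intervals}
        strands = {iv.strand for iv in self.intervals}
        if len(chroms) > 1 or len(strands) > 1:
            raise GeneModelError("all exons must share one chromosome and strand")
        starts = [iv.start for iv in self.intervals]
        expected = sorted(starts, reverse=self.strand == "-")
        if starts != expected:
            raise GeneModelError("exons not ordered in transcript direction")
        for a, b in zip(self.intervals, self.intervals[1:]):
            if a.overlaps(b.start, b.end):
                raise GeneModelError("exons overlap")
        if self.complete and self.cds_length < 3:
            raise GeneModelError("complete CDS must be at least one codon")
        if self.complete and self.cds_length % 3 != 0:
            raise GeneModelError(
                f"complete CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def chrom(self) -> str:
        return self.intervals[0].chrom

    @property
    def strand(self) -> str:
        return self.intervals[0].strand

    @property
    def n_exons(self) -> int:
        return len(self.intervals)

    @property
    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.intervals) - self.cds_offset

    def exon(self, index: int) -> GenomicInterval:
        """1-based exon lookup in transcript order."""
        if not 1 <= index <= self.n_exons:
            raise GeneModelError(
                f"exon index {index} out of range 1..{self.n_exons}"
            )
        return self.intervals[index - 1]

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (min start, max end) over all exons."""
        return (
            min(iv.start for iv in self.intervals),
            max(iv.end for iv in self.intervals),
        )


@dataclass(frozen=True)
class Junction:
    """A splice junction between two exons of one gene.

    ``donor`` is the genomic coordinate (0-based) of the last transcribed
    base of the upstream exon; ``acceptor`` that of the first transcribed
    base of the downstream exon.  On the − strand the donor is the exon's
    lowest genomic coordinate and the acceptor the downstream exon's
    highest, mirroring the + strand semantics.
    """

    chrom: str
    donor: int
    acceptor: int
    upstream_index: int
    downstream_index: int
    strand: str = "+"

    @property
    def gap(self) -> tuple[int, int]:
        """Half-open genomic interval of the intervening (spliced-out) region."""
        if self.strand == "+":
            return (self.donor + 1, self.acceptor)
        return (self.acceptor + 1, self.donor)

    @property
    def intron_length(self) -> int:
        lo, hi = self.gap
        return hi - lo


@dataclass(frozen=True)
class SkipConsequence:
    """Transcript/protein consequence of skipping one internal exon.

    ``deleted_aa_first``/``deleted_aa_last`` are 1-based residue indices;
    they are exact when ``residues_exact`` is True (both exon boundaries
    codon-aligned), otherwise they bound the affected codon interval.
    """

    deleted_nt: int
    frame_preserved: bool
    deleted_aa_first: int | None = None
    deleted_aa_last: int | None = None
    residues_exact: bool = False


# ---------------------------------------------------------------------------
# Annotation I/O


def _parse_bed12_line(line: str, gene_id: str | None) -> GeneModel | None:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise GeneModelError(f"BED12 line has {len(fields)} fields, expected 12")
    chrom, start, _end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
    strand = fields[5]
    if gene_id is not None and name != gene_id:
        return None
    n_blocks = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise GeneModelError("BED12 blockCount inconsistent with block lists")
    intervals = [
        GenomicInterval(chrom, start + off, start + off + size, strand)
        for off, size in zip(offsets, sizes)
    ]
    if strand == "-":
        intervals = intervals[::-1]
    return GeneModel(gene_id=name, intervals=intervals)


def _load_bed12(path: Path, gene_id: str) -> GeneModel:
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            model = _parse_bed12_line(line, gene_id)
            if model is not None:
                return model
    raise GeneModelError(f"gene not found: {gene_id!r} in {path}")


def _load_gtf(path: Path, gene_id: str) -> GeneModel:
    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    cds = [
        f
        for f in db.features_of_type("CDS")
        if gene_id in f.attributes.get("gene_id", [])
    ]
    if not cds:
        raise GeneModelError(f"gene not found: {gene_id!r} in {path}")
    strand = cds[0].strand
    # gffutils keeps GTF 1-based inclusive coordinates; convert here.
    intervals = [
        GenomicInterval(f.seqid, f.start - 1, f.end, f.strand) for f in cds
    ]
    intervals.sort(key=lambda iv: iv.start, reverse=strand == "-")
    return GeneModel(gene_id=gene_id, intervals=intervals)


def load_gene_model(path: str | Path, gene_id: str) -> GeneModel:
    """Load one gene's coding exons from a BED12 or GTF annotation.

    The format is chosen by extension (``.bed`` → BED12, ``.gtf``/``.gff``
    → GTF).  Coordinates are converted to the internal 0-based half-open
    convention at this boundary.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".bed", ".bed12"):
        return _load_bed12(path, gene_id)
    if suffix in (".gtf", ".gff", ".gff3"):
        return _load_gtf(path, gene_id)
    raise GeneModelError(f"unrecognised annotation format: {path.name}")


def write_bed12(model: GeneModel, path: str | Path) -> None:
    """Write a GeneModel as a single BED12 record (coding exons as blocks)."""
    ivs = sorted(model.intervals, key=lambda iv: iv.start)
    start = ivs[0].start
    end = ivs[-1].end
    line = "\t".join(
        [
            model.chrom,
            str(start),
            str(end),
            model.gene_id,
            "0",
            model.strand,
            str(start),
            str(end),
            "0",
            str(len(ivs)),
            ",".join(str(len(iv)) for iv in ivs) + ",",
            ",".join(str(iv.start - start) for iv in ivs) + ",",
        ]
    )
    Path(path).write_text(line + "\n")


def write_gtf(model: GeneModel, path: str | Path, source: str = "splicescore") -> None:
    """Write a GeneModel as GTF CDS features (1-based inclusive on output)."""
    rows = []
    for iv in sorted(model.intervals, key=lambda iv: iv.start):
        attrs = f'gene_id "{model.gene_id}"; transcript_id "{model.gene_id}.1";'
        rows.append(
            "\t".join(
                [
                    iv.chrom,
                    source,
                    "CDS",
                    str(iv.start + 1),
                    str(iv.end),
                    ".",
                    iv.strand,
                    "0",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Junctions and skip consequences


def junction_for(
    model: GeneModel, upstream_index: int, downstream_index: int
) -> Junction:
    """Junction joining the donor of one exon to the acceptor of a later exon.

    Indices are 1-based in transcript order and must satisfy
    ``upstream_index < downstream_index``; non-adjacent pairs (e.g. 4|6)
    describe exon-skipping junctions.
    """
    if upstream_index >= downstream_index:
        raise GeneModelError(
            f"upstream index {upstream_index} must precede downstream "
            f"{downstream_index}"
        )
    up = model.exon(upstream_index)
    down = model.exon(downstream_index)
    if model.strand == "+":
        donor, acceptor = up.end - 1, down.start
    else:
        donor, acceptor = up.start, down.end - 1
    return Junction(
        chrom=model.chrom,
        donor=donor,
        acceptor=acceptor,
        upstream_index=upstream_index,
        downstream_index=downstream_index,
        strand=model.strand,
    )


def exon_skip_consequence(model: GeneModel, skipped_index: int) -> SkipConsequence:
    """Coding consequence of skipping one internal exon.

    ``deleted_nt`` is the coding length of the skipped exon; the frame is
    preserved iff it is a multiple of 3.  The deleted residue range is
    exact when both boundaries of the skipped exon fall on codon
    boundaries (cumulative upstream coding length divisible by 3);
    otherwise the reported range is the affected codon interval, flagged
    approximate via ``residues_exact=False``.
    """
    if skipped_index in (1, model.n_exons):
        raise GeneModelError(
            f"exon {skipped_index} is terminal; only internal exons can be skipped"
        )
    exon = model.exon(skipped_index)  # validates range
    upstream_nt = (
        sum(len(model.exon(i)) for i in range(1, skipped_index)) - model.cds_offset
    )
    if upstream_nt < 0:
        raise GeneModelError(f"exon {skipped_index} lies outside the CDS")
    deleted_nt = len(exon)
    frame_preserved = deleted_nt % 3 == 0
    exact = frame_preserved and upstream_nt % 3 == 0
    if exact:
        first = upstream_nt // 3 + 1
        last = (upstream_nt + deleted_nt) // 3
    else:
        first = upstream_nt // 3 + 1
        last = math.ceil((upstream_nt + deleted_nt) / 3)
    return SkipConsequence(
        deleted_nt=deleted_nt,
        frame_preserved=frame_preserved,
        deleted_aa_first=first,
        deleted_aa_last=last,
        residues_exact=exact,
    )
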