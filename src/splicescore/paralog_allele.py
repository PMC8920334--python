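"""Pseudogene-aware base-identity counting at a duplicated locus pair.

When a gene has a near-identical pseudogene (e.g. IKBKG/IKBKGP1), read
mapping quality cannot distinguish the two loci, so standard SNV calling
is unreliable there.  Instead, for each individual we pool base calls
from every read overlapping either the primary variant site or its
homologous paralog position — deliberately applying NO mapping-quality
filter — and tally base identities.  Base calls with Phred quality below
a threshold (default 30) are excluded; individuals with fewer than a
minimum number of pooled calls (default 20) are excluded from the cohort
summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

__all__ = [
    "SiteSpec",
    "IndividualBaseCounts",
    "CohortSummary",
    "count_base_identities",
    "summarize_cohort",
]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SiteSpec:
    """The duplicated-locus site pair sharing one reference base."""

    primary_chrom: str
    primary_pos: int  # 0-based
    paralog_chrom: str
    paralog_pos: int  # 0-based
    reference_base: str
    alt_base: str | None = None

    def __post_init__(self) -> None:
        if (self.primary_chrom, self.primary_pos) == (
            self.paralog_chrom,
            self.paralog_pos,
        ):
            raise ValueError("primary and paralog sites must be distinct")
        if self.reference_base not in _BASES:
            raise ValueError(f"invalid reference base {self.reference_base!r}")
        if self.alt_base is not None and self.alt_base not in _BASES:
            raise ValueError(f"invalid alt base {self.alt_base!r}")

    @property
    def sites(self) -> tuple[tuple[str, int], ...]:
        return (
            (self.primary_chrom, self.primary_pos),
            (self.paralog_chrom, self.paralog_pos),
        )

    def swapped(self) -> "SiteSpec":
        """The same pair with primary/paralog labels exchanged."""
        return SiteSpec(
            self.paralog_chrom,
            self.paralog_pos,
            self.primary_chrom,
            self.primary_pos,
            self.reference_base,
            self.alt_base,
        )


@dataclass
class IndividualBaseCounts:
    """Pooled, quality-filtered base tallies for one individual.

    ``total`` counts A/C/G/T calls only; low-quality calls, N calls and
    non-base events (deletions / reference skips spanning a site) are
    tallied separately.
    """

    individual_id: str
    counts: dict[str, int] = field(
        default_factory=lambda: {b: 0 for b in _BASES}
    )
    n_excluded_lowqual: int = 0
    n_ambiguous: int = 0  # N calls
    n_nonbase: int = 0  # deletion / refskip over a site

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fraction(self, base: str) -> float | None:
        return self.counts[base] / self.total if self.total else None


@dataclass
class CohortSummary:
    """Cohort-level reference-base frequency summary."""

    n_individuals_pass: int
    n_individuals_fail_depth: int
    carrier_count: int
    carrier_ids: list[str]
    per_individual: pd.DataFrame  # id, total, ref_count, alt_count, ref_fraction, alt_fraction, pass_depth, is_carrier
    min_total: int
    carrier_threshold: float


def count_base_identities(
    alignments: str | Path,
    site: SiteSpec,
    individual_id: str | None = None,
    min_baseq: int = 30,
    dedup_mates: bool = False,
) -> IndividualBaseCounts:
    """Pool base calls over the primary and paralog positions of one individual.

    No mapping-quality filter is applied (any read overlapping either
    site is used); unmapped, secondary and supplementary records are
    skipped.  A read contributes at most one call per site it overlaps;
    with ``dedup_mates`` a read *pair* contributes at most one call per
    site (first mate encountered wins).  Phred+33 qualities below
    ``min_baseq`` are excluded and tallied in ``n_excluded_lowqual``.
    """
    path = Path(alignments)
    if individual_id is None:
        individual_id = path.name.removesuffix(".bam").removesuffix(".sam")
    out = IndividualBaseCounts(individual_id=individual_id)
    with pysam.AlignmentFile(str(path)) as af:
        for chrom, pos in site.sites:
            if chrom not in af.references:
                raise ValueError(f"chromosome {chrom!r} absent from header")
            if pos >= af.get_reference_length(chrom):
                raise ValueError(f"site {chrom}:{pos} beyond contig end")
            seen_names: set[str] = set()
            for read in af.fetch(chrom, pos, pos + 1):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if dedup_mates:
                    if read.query_name in seen_names:
                        continue
                    seen_names.add(read.query_name)
                qpos = None
                aligned = False
                for q, r in read.get_aligned_pairs():
                    if r == pos:
                        aligned = True
                        qpos = q
                        break
                if not aligned:
                    continue
                if qpos is None:  # deletion or reference skip over the site
                    out.n_nonbase += 1
                    continue
                base = read.query_sequence[qpos].upper()
                qual = read.query_qualities[qpos]
                if base not in _BASES:
                    out.n_ambiguous += 1
                elif qual < min_baseq:
                    out.n_excluded_lowqual += 1
                else:
                    out.counts[base] += 1
    return out


def summarize_cohort(
    counts: Sequence[IndividualBaseCounts],
    site: SiteSpec,
    min_total: int = 20,
    carrier_threshold: float = 0.10,
) -> CohortSummary:
    """Cohort reference-base frequency with a depth floor.

    Individuals with fewer than ``min_total`` pooled calls are excluded
    (counted in ``n_individuals_fail_depth``).  A passing individual is
    flagged a carrier when its pooled alt-base fraction (``site.alt_base``
    when given, otherwise the total non-reference fraction) reaches
    ``carrier_threshold``.
    """
    if not counts:
        raise ValueError("empty cohort")
    rows = []
    for c in counts:
        total = c.total
        ref = c.counts[site.reference_base]
        if site.alt_base is not None:
            alt = c.counts[site.alt_base]
        else:
            alt = total - ref
        ok = total >= min_total
        ref_frac = ref / total if total else float("nan")
        alt_frac = alt / total if total else float("nan")
        rows.append(
            {
                "individual_id": c.individual_id,
                "total": total,
                "ref_count": ref,
                "alt_count": alt,
                "ref_fraction": ref_frac,
                "alt_fraction": alt_frac,
                "n_excluded_lowqual": c.n_excluded_lowqual,
                "pass_depth": ok,
                "is_carrier": bool(ok and alt_frac >= carrier_threshold),
            }
        )
    table = pd.DataFrame(rows).set_index("individual_id")
    carriers = table.index[table["is_carrier"]].tolist()
    return CohortSummary(
        n_individuals_pass=int(table["pass_depth"].sum()),
        n_individuals_fail_depth=int((~table["pass_depth"]).sum()),
        carrier_count=len(carriers),
        carrier_ids=carriers,
        per_individual=table,
        min_total=min_total,
        carrier_threshold=carrier_threshold,
    )
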