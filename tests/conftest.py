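"""Shared fixtures: the toy locus, and helpers to write small BAM fixtures."""

from __future__ import annotations

import re
from pathlib import Path

import pysam
import pytest

from splicescore.synthetic_data import SimulationConfig, make_reference_and_model

BASE_SEED = 20260927


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=BASE_SEED)


@pytest.fixture(scope="session")
def locus(sim_config, tmp_path_factory):
    """The generated toy reference/gene-model/site-pair, shared read-only."""
    return make_reference_and_model(sim_config, tmp_path_factory.mktemp("locus"))


def cigar_query_length(cigar: str) -> int:
    return sum(
        int(n) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar) if op in "MIS=X"
    )


def write_bam(path: Path, header: dict, reads: list[dict]) -> Path:
    """Write a coordinate-sorted, indexed BAM from simple read dicts.

    Each read dict: name, pos (0-based), cigar; optional seq, quals
    (list of ints), mapq (default 60), flag (default 0).
    """
    records = []
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for r in sorted(reads, key=lambda r: r["pos"]):
            a = pysam.AlignedSegment(out.header)
            a.query_name = r["name"]
            a.flag = r.get("flag", 0)
            a.reference_id = r.get("tid", 0)
            a.reference_start = r["pos"]
            a.mapping_quality = r.get("mapq", 60)
            a.cigarstring = r["cigar"]
            qlen = cigar_query_length(r["cigar"])
            a.query_sequence = r.get("seq", "A" * qlen)
            a.query_qualities = r.get("quals", [40] * qlen)
            out.write(a)
            records.append(a)
    pysam.index(str(path))
    return path


def brute_force_junction_tally(
    bam_path: str | Path, gap: tuple[int, int]
) -> int:
    """Independent junction-read tally: parse CIGAR strings textually.

    Walks each primary read's CIGAR string with a regex and counts query
    names having an ``N`` gap exactly at ``gap`` (half-open genomic).
    """
    names: set[str] = set()
    with pysam.AlignmentFile(str(bam_path)) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_duplicate:
                continue
            pos = read.reference_start
            for n, op in re.findall(r"(\d+)([MIDNSHP=X])", read.cigarstring):
                n = int(n)
                if op == "N" and (pos, pos + n) == gap:
                    names.add(read.query_name)
                if op in "MDN=X":
                    pos += n
    return len(names)
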