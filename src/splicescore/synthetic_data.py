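"""Synthetic inputs with full ground truth for the whole pipeline.

Everything the pipeline consumes can be generated here with a fixed
seed: a toy reference genome carrying a 10-exon gene whose internal
exon 5 is 153 nt (encoding residues 174-224 of the toy protein) plus a
near-identical paralog window emulating a gene/pseudogene pair; spliced
short reads drawn from a two-isoform mixture (exon-5 inclusion vs
skipping) at configurable skipping fraction f; an RPKM-like expression
matrix in which signature-gene expression follows a planted linear model
score = alpha + beta * AS + eps against the true splicing index; and a
cohort of per-individual alignments over the duplicated locus pair with
planted variant carriers.  Each generator emits a truth record used as
the test oracle downstream.

The isoform mixture defaults to exact allocation (n_skip = round(f * N))
so the emitted skip fraction equals f up to rounding; ``mixture =
"binomial"`` draws each read's isoform independently with probability f
instead.  Reads are junction-anchored by default — every read spans the
exon-4 donor junction, giving both isoforms equal junction capture so
the counted %AS estimates 100 f/(1-f) directly; ``placement =
"uniform"`` scatters reads along the isoform instead.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .gene_model import GeneModel, GenomicInterval, write_bed12, write_gtf
from .paralog_allele import SiteSpec

__all__ = [
    "SampleSpec",
    "SpliceSimConfig",
    "ExpressionSimConfig",
    "CohortSimConfig",
    "SimulationConfig",
    "ToyLocus",
    "default_samples",
    "make_reference_and_model",
    "simulate_splice_reads",
    "simulate_expression",
    "build_cohort_manifest",
    "simulate_cohort_alignments",
]

# Toy gene geometry: exons 1-4 carry 519 coding nt (173 codons), so the
# 153-nt exon 5 is codon-aligned and encodes residues 174-224.
_EXON_LENGTHS = (120, 150, 129, 120, 153, 150, 120, 132, 120, 126)
_INTRON_LENGTH = 250
_GENE_START = 1000
_PRIMARY_SITE_OFFSET_IN_EXON5 = 76
_PARALOG_WINDOW_HALF = 150
_PARALOG_GAP = 500  # gene end -> paralog window start
_PARALOG_DIFF_OFFSETS = (40, 260)  # documented divergent positions in the window


@dataclass(frozen=True)
class SampleSpec:
    """One simulated sample: its group and true splicing index (%AS units)."""

    sample_id: str
    group: str  # "control" or "case"
    true_percent_as: float

    @property
    def skip_fraction(self) -> float:
        """Isoform skipping fraction f with 100 f/(1-f) = true %AS."""
        return self.true_percent_as / (100.0 + self.true_percent_as)


def default_samples() -> list[SampleSpec]:
    """The default study layout: 15 healthy controls and 18 case samples.

    Control splicing indices span 6.1-11.0 %AS (mean 8.55); case samples
    span 5-65 %AS, covering the range over which signature scores climb.
    """
    controls = [
        SampleSpec(f"HC{i + 1:02d}", "control", float(round(v, 3)))
        for i, v in enumerate(np.linspace(6.1, 11.0, 15))
    ]
    cases = [
        SampleSpec(f"CASE{i + 1:02d}", "case", float(round(v, 3)))
        for i, v in enumerate(np.linspace(5.0, 65.0, 18))
    ]
    return controls + cases


@dataclass
class SpliceSimConfig:
    read_length: int = 100
    n_reads: int = 2000  # per sample
    mixture: str = "exact"  # or "binomial"
    placement: str = "junction"  # or "uniform"


@dataclass
class ExpressionSimConfig:
    n_background: int = 200
    n_signature: int = 25  # per gene list
    baseline_meanlog_range: tuple[float, float] = (2.0, 4.0)
    baseline_sdlog: float = 0.15
    alpha: float = 0.0
    beta_ifn: float = 0.05  # Z units per %AS point
    beta_nfkb: float = 0.05
    sigma: float = 0.25
    gene_jitter_sd: float = 0.5


@dataclass
class CohortSimConfig:
    # 1000 Genomes super-population layout of the healthy WGS cohort.
    subgroup_sizes: dict = field(
        default_factory=lambda: {"EUR": 1158, "AFR": 8, "EAS": 17, "AMR": 14}
    )
    depth_mean: float = 30.0
    read_length: int = 100
    base_qual: int = 40
    low_qual_value: int = 20
    low_qual_rate: float = 0.05
    n_carriers: int = 0
    carrier_alt_fraction: float = 0.4
    depth_overrides: dict = field(default_factory=dict)  # individual_id -> depth


@dataclass
class SimulationConfig:
    seed: int = 0
    samples: list = field(default_factory=default_samples)
    splice: SpliceSimConfig = field(default_factory=SpliceSimConfig)
    expression: ExpressionSimConfig = field(default_factory=ExpressionSimConfig)
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)


@dataclass
class ToyLocus:
    """The generated reference, gene model and duplicated-locus site pair."""

    chrom: str
    sequence: str
    model: GeneModel
    site: SiteSpec
    fasta: Path
    bed12: Path
    gtf: Path

    @property
    def header(self) -> dict:
        return {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": self.chrom, "LN": len(self.sequence)}],
        }


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, *stream])


def _md5(items) -> str:
    h = hashlib.md5()
    for it in items:
        h.update(str(it).encode())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Reference and gene model


def make_reference_and_model(
    config: SimulationConfig, outdir: str | Path
) -> ToyLocus:
    """Write the toy reference FASTA (+ index), BED12/GTF gene model and sites.

    The chromosome carries the 10-exon gene starting at 1 kb and, 500 bp
    past the gene, a 300-bp paralog window copied from around the primary
    variant site with two documented substitutions (>= 99% identity over
    the counted window).  The primary site sits inside exon 5; the
    paralog site is the homologous position inside the copied window.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config.seed, 0)
    chrom = "chrT"

    gene_end = _GENE_START + sum(_EXON_LENGTHS) + _INTRON_LENGTH * (
        len(_EXON_LENGTHS) - 1
    )
    paralog_start = gene_end + _PARALOG_GAP
    total_len = paralog_start + 2 * _PARALOG_WINDOW_HALF + 200
    seq = rng.choice(list("ACGT"), size=total_len)

    intervals = []
    pos = _GENE_START
    for length in _EXON_LENGTHS:
        intervals.append(GenomicInterval(chrom, pos, pos + length, "+"))
        pos += length + _INTRON_LENGTH
    model = GeneModel(gene_id="TOYG", intervals=intervals)

    primary_pos = intervals[4].start + _PRIMARY_SITE_OFFSET_IN_EXON5
    window_start = primary_pos - _PARALOG_WINDOW_HALF
    window = seq[window_start : window_start + 2 * _PARALOG_WINDOW_HALF].copy()
    for off in _PARALOG_DIFF_OFFSETS:
        base = window[off]
        window[off] = rng.choice([b for b in "ACGT" if b != base])
    seq[paralog_start : paralog_start + len(window)] = window
    paralog_pos = paralog_start + _PARALOG_WINDOW_HALF

    ref_base = str(seq[primary_pos])
    alt_base = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
    site = SiteSpec(chrom, primary_pos, chrom, paralog_pos, ref_base, alt_base)

    sequence = "".join(seq)
    fasta = outdir / "reference.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i : i + 70] + "\n")
    pysam.faidx(str(fasta))

    bed12 = outdir / "toy_gene.bed"
    gtf = outdir / "toy_gene.gtf"
    write_bed12(model, bed12)
    write_gtf(model, gtf)
    (outdir / "sites.json").write_text(
        json.dumps(
            {
                "primary": [chrom, primary_pos],
                "paralog": [chrom, paralog_pos],
                "reference_base": ref_base,
                "alt_base": alt_base,
                "paralog_diff_offsets": list(_PARALOG_DIFF_OFFSETS),
            },
            indent=2,
        )
    )
    return ToyLocus(
        chrom=chrom,
        sequence=sequence,
        model=model,
        site=site,
        fasta=fasta,
        bed12=bed12,
        gtf=gtf,
    )


# ---------------------------------------------------------------------------
# Spliced reads


def _isoform_exons(model: GeneModel, skip_index: int | None) -> list[GenomicInterval]:
    return [
        iv for i, iv in enumerate(model.intervals, start=1) if i != skip_index
    ]


def _isoform_to_genomic(
    exons: list[GenomicInterval], iso_start: int, length: int
) -> list[tuple[int, int]]:
    """Map an isoform-coordinate interval to genomic aligned blocks."""
    blocks = []
    offset = 0
    remaining = length
    for iv in exons:
        iv_len = len(iv)
        if iso_start < offset + iv_len and remaining > 0:
            local = max(iso_start - offset, 0)
            take = min(iv_len - local, remaining)
            blocks.append((iv.start + local, iv.start + local + take))
            remaining -= take
        offset += iv_len
        if remaining <= 0:
            break
    if remaining > 0:
        raise ValueError("read extends past isoform end")
    return blocks


def _blocks_to_cigar(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    cig = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            cig.append((3, gap))  # N
        cig.append((0, e - s))  # M
    return cig


def simulate_splice_reads(
    config: SimulationConfig,
    locus: ToyLocus,
    outdir: str | Path,
    samples: list[SampleSpec] | None = None,
) -> dict:
    """Emit one sorted, indexed BAM per sample plus a truth table.

    Reads come from the inclusion isoform (all exons) or the skipping
    isoform (exon 5 removed) according to the sample's skipping fraction
    f.  Junction-spanning reads carry exact CIGAR ``N`` gaps at annotated
    junctions; no sequencing errors are introduced, so junction-exact
    counting has a clean oracle.  The truth table records, per sample,
    the exact number of emitted reads spanning the 4|5 and 4|6 junction
    gaps (determined from the generated alignments themselves).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sc = config.splice
    if samples is None:
        samples = config.samples
    model = locus.model
    incl_exons = _isoform_exons(model, None)
    skip_exons = _isoform_exons(model, 5)
    # exon-4 donor junction position in isoform coordinates (same in both)
    anchor = sum(len(iv) for iv in model.intervals[:4])
    gap45 = (model.exon(4).end, model.exon(5).start)
    gap46 = (model.exon(4).end, model.exon(6).start)

    truth: dict = {"samples": {}, "seed": config.seed, "config": asdict(sc)}
    for k, spec in enumerate(samples):
        rng = _rng(config.seed, 1, k)
        f = spec.skip_fraction
        n = sc.n_reads
        if sc.read_length >= sum(len(iv) for iv in skip_exons):
            raise ValueError("read length exceeds isoform length")
        if n <= 0:
            raise ValueError("per-sample depth must be positive")
        if sc.mixture == "exact":
            n_skip = int(round(f * n))
        elif sc.mixture == "binomial":
            n_skip = int(rng.binomial(n, f))
        else:
            raise ValueError(f"unknown mixture mode {sc.mixture!r}")
        iso_flags = np.zeros(n, dtype=bool)
        iso_flags[:n_skip] = True
        rng.shuffle(iso_flags)

        reads = []
        n45 = n46 = 0
        for i, is_skip in enumerate(iso_flags):
            exons = skip_exons if is_skip else incl_exons
            iso_len = sum(len(iv) for iv in exons)
            if sc.placement == "junction":
                lo = max(0, anchor - sc.read_length + 1)
                start = int(rng.integers(lo, anchor))  # covers anchor-1 and anchor
            elif sc.placement == "uniform":
                start = int(rng.integers(0, iso_len - sc.read_length + 1))
            else:
                raise ValueError(f"unknown placement {sc.placement!r}")
            blocks = _isoform_to_genomic(exons, start, sc.read_length)
            gaps = {
                (blocks[j - 1][1], blocks[j][0]) for j in range(1, len(blocks))
            }
            if gap45 in gaps:
                n45 += 1
            if gap46 in gaps:
                n46 += 1
            seq = "".join(locus.sequence[s:e] for s, e in blocks)
            reads.append((blocks[0][0], f"{spec.sample_id}_r{i}", blocks, seq))
        reads.sort(key=lambda r: r[0])

        bam = outdir / f"{spec.sample_id}.bam"
        with pysam.AlignmentFile(str(bam), "wb", header=locus.header) as out:
            for pos, name, blocks, seq in reads:
                a = pysam.AlignedSegment(out.header)
                a.query_name = name
                a.query_sequence = seq
                a.flag = 0
                a.reference_id = 0
                a.reference_start = pos
                a.mapping_quality = 60
                a.cigartuples = _blocks_to_cigar(blocks)
                a.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(seq)
                )
                out.write(a)
        pysam.index(str(bam))

        truth["samples"][spec.sample_id] = {
            "group": spec.group,
            "true_f": f,
            "true_percent_as": spec.true_percent_as,
            "expected_percent_as": 100.0 * f / (1.0 - f),
            "n_reads": n,
            "n_skip_isoform": int(n_skip),
            "emitted_inclusion_junction_reads": n45,
            "emitted_skipping_junction_reads": n46,
            "bam": str(bam),
            "checksum": _md5(
                (name, pos, blocks) for pos, name, blocks, _ in reads
            ),
        }
    (outdir / "splice_truth.json").write_text(json.dumps(truth, indent=2))
    return truth


# ---------------------------------------------------------------------------
# Expression matrix with a planted score-splicing relationship


def simulate_expression(
    config: SimulationConfig,
    outdir: str | Path,
    samples: list[SampleSpec] | None = None,
) -> dict:
    """Expression TSV + splicing TSV + gene lists with a planted linear model.

    Controls are drawn from a per-gene log-normal baseline.  For each
    case sample s and each signature (IFN, NF-kB), a target score
    t_s = alpha + beta * AS_s + eps_s (eps ~ N(0, sigma^2)) is drawn and
    the signature genes are set to mean_g + z * sd_g — mean/sd taken over
    the generated controls with ddof 1, exactly as the scorer computes
    them — with per-gene jitter centred so the mean Z across the
    signature equals t_s exactly.  Background genes stay at baseline, so
    their control-referenced Z is centred at zero in cases too.  Values
    are clipped at zero to stay RPKM-like (clipping is vanishingly rare
    at the default baseline).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ec = config.expression
    if samples is None:
        samples = config.samples
    if ec.sigma < 0:
        raise ValueError("sigma must be nonnegative")
    controls = [s for s in samples if s.group == "control"]
    cases = [s for s in samples if s.group != "control"]
    if len(controls) < 2:
        raise ValueError("need at least 2 control samples")

    rng = _rng(config.seed, 2)
    background = [f"BG{i + 1:04d}" for i in range(ec.n_background)]
    ifn_genes = [f"IFNSIG{i + 1:03d}" for i in range(ec.n_signature)]
    nfkb_genes = [f"NFKBSIG{i + 1:03d}" for i in range(ec.n_signature)]
    genes = background + ifn_genes + nfkb_genes

    meanlog = rng.uniform(*ec.baseline_meanlog_range, size=len(genes))
    n_ctrl, n_case = len(controls), len(cases)
    base_ctrl = rng.lognormal(
        meanlog[:, None], ec.baseline_sdlog, size=(len(genes), n_ctrl)
    )
    base_case = rng.lognormal(
        meanlog[:, None], ec.baseline_sdlog, size=(len(genes), n_case)
    )
    mat = pd.DataFrame(
        np.hstack([base_ctrl, base_case]),
        index=genes,
        columns=[s.sample_id for s in controls] + [s.sample_id for s in cases],
    )

    ctrl_cols = [s.sample_id for s in controls]
    mean_g = mat[ctrl_cols].mean(axis=1)
    sd_g = mat[ctrl_cols].std(axis=1, ddof=1)

    truth_samples: dict = {}
    planted = {"IFN": {}, "NFKB": {}}
    for sig_name, sig_genes, beta in (
        ("IFN", ifn_genes, ec.beta_ifn),
        ("NFKB", nfkb_genes, ec.beta_nfkb),
    ):
        m = mean_g.loc[sig_genes].to_numpy()
        d = sd_g.loc[sig_genes].to_numpy()
        for spec in cases:
            eps = rng.normal(0.0, ec.sigma)
            target = ec.alpha + beta * spec.true_percent_as + eps
            jitter = rng.normal(0.0, ec.gene_jitter_sd, size=len(sig_genes))
            z = target + (jitter - jitter.mean())
            mat.loc[sig_genes, spec.sample_id] = np.clip(m + z * d, 0.0, None)
            planted[sig_name][spec.sample_id] = target

    for spec in samples:
        truth_samples[spec.sample_id] = {
            "group": spec.group,
            "true_percent_as": spec.true_percent_as,
            "planted_ifn_score": planted["IFN"].get(spec.sample_id),
            "planted_nfkb_score": planted["NFKB"].get(spec.sample_id),
        }

    mat.index.name = "gene_id"
    mat.to_csv(outdir / "expression.tsv", sep="\t")
    splicing = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "percent_AS": [s.true_percent_as for s in samples],
        }
    )
    splicing.to_csv(outdir / "splicing.tsv", sep="\t", index=False)
    (outdir / "ifn_genes.txt").write_text("\n".join(ifn_genes) + "\n")
    (outdir / "nfkb_genes.txt").write_text("\n".join(nfkb_genes) + "\n")

    truth = {
        "seed": config.seed,
        "alpha": ec.alpha,
        "beta_ifn": ec.beta_ifn,
        "beta_nfkb": ec.beta_nfkb,
        "sigma": ec.sigma,
        "control_ids": ctrl_cols,
        "case_ids": [s.sample_id for s in cases],
        "ifn_genes": ifn_genes,
        "nfkb_genes": nfkb_genes,
        "samples": truth_samples,
    }
    (outdir / "expression_truth.json").write_text(json.dumps(truth, indent=2))
    return truth


# ---------------------------------------------------------------------------
# Duplicated-locus cohort


def build_cohort_manifest(config: SimulationConfig, outdir: str | Path | None = None) -> pd.DataFrame:
    """Cohort manifest: one row per individual with an ancestry label.

    Default subgroup sizes follow the healthy-cohort layout (1158 EUR +
    8 AFR + 17 EAS + 14 AMR = 1197 individuals).
    """
    rows = []
    for ancestry, size in config.cohort.subgroup_sizes.items():
        if size < 0:
            raise ValueError("subgroup sizes must be >= 0")
        for i in range(size):
            iid = f"{ancestry}{i + 1:04d}"
            rows.append({"individual_id": iid, "ancestry": ancestry})
    manifest = pd.DataFrame(rows, columns=["individual_id", "ancestry"])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest.assign(
            path=[str(outdir / f"{iid}.bam") for iid in manifest["individual_id"]]
        ).to_csv(outdir / "cohort_manifest.tsv", sep="\t", index=False)
    return manifest


def simulate_cohort_alignments(
    config: SimulationConfig, locus: ToyLocus, outdir: str | Path
) -> dict:
    """Per-individual BAMs over the duplicated locus pair, plus manifest + truth.

    Each individual gets a Poisson(depth_mean) number of reads (or an
    explicit ``depth_overrides`` value), each read covering exactly one
    of the two sites (chosen uniformly).  Base qualities are
    ``base_qual`` except that the call at the site drops to
    ``low_qual_value`` with probability ``low_qual_rate``.  Planted
    carriers carry the alt base in an exact round(fraction x depth)
    subset of their site calls; everyone else is pure reference.  MAPQ is
    randomised (0-60) — the counting procedure must ignore it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cc = config.cohort
    manifest = build_cohort_manifest(config, outdir)
    ids = manifest["individual_id"].tolist()
    rng = _rng(config.seed, 3)
    carrier_ids = set(
        rng.choice(ids, size=min(cc.n_carriers, len(ids)), replace=False).tolist()
    )

    site = locus.site
    truth_ind: dict = {}
    for k, iid in enumerate(ids):
        irng = _rng(config.seed, 3, k + 1)
        depth = int(cc.depth_overrides.get(iid, irng.poisson(cc.depth_mean)))
        is_carrier = iid in carrier_ids
        n_alt = int(round(cc.carrier_alt_fraction * depth)) if is_carrier else 0
        alt_flags = np.zeros(depth, dtype=bool)
        alt_flags[:n_alt] = True
        irng.shuffle(alt_flags)

        reads = []
        n_low = 0
        for j in range(depth):
            chrom, pos = site.sites[int(irng.integers(0, 2))]
            start = int(
                irng.integers(
                    max(0, pos - cc.read_length + 1), pos + 1
                )
            )
            seq = list(locus.sequence[start : start + cc.read_length])
            site_off = pos - start
            if alt_flags[j]:
                seq[site_off] = site.alt_base
            quals = np.full(len(seq), cc.base_qual, dtype=np.uint8)
            if irng.random() < cc.low_qual_rate:
                quals[site_off] = cc.low_qual_value
                n_low += 1
            reads.append(
                (start, f"{iid}_r{j}", "".join(seq), quals,
                 int(irng.integers(0, 61)))
            )
        reads.sort(key=lambda r: r[0])

        bam = outdir / f"{iid}.bam"
        with pysam.AlignmentFile(str(bam), "wb", header=locus.header) as out:
            for start, name, seq, quals, mapq in reads:
                a = pysam.AlignedSegment(out.header)
                a.query_name = name
                a.query_sequence = seq
                a.flag = 0
                a.reference_id = 0
                a.reference_start = start
                a.mapping_quality = mapq
                a.cigartuples = [(0, len(seq))]
                a.query_qualities = quals
                out.write(a)
        pysam.index(str(bam))

        truth_ind[iid] = {
            "depth": depth,
            "is_carrier": bool(is_carrier),
            "n_alt_planted": n_alt,
            "n_lowqual_planted": n_low,
            "bam": str(bam),
        }

    truth = {
        "seed": config.seed,
        "n_individuals": len(ids),
        "carrier_ids": sorted(carrier_ids),
        "site": {
            "primary": [site.primary_chrom, site.primary_pos],
            "paralog": [site.paralog_chrom, site.paralog_pos],
            "reference_base": site.reference_base,
            "alt_base": site.alt_base,
        },
        "individuals": truth_ind,
    }
    (outdir / "cohort_truth.json").write_text(json.dumps(truth, indent=2))
    return truth
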