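"""End-to-end orchestration: simulate -> splice-index -> score -> correlate -> paralog-freq.

``run_all`` executes the stages in dependency order into an output
directory, writing per-stage TSV/JSON artifacts and a consolidated
``report.json`` plus a human-readable ``summary.txt``.  Every number in
the report is taken verbatim from the stage outputs (no re-rounding),
and a fixed seed reproduces the report exactly up to the timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .paralog_allele import count_base_identities, summarize_cohort
from .signature_scores import (
    build_control_reference,
    read_expression_tsv,
    read_gene_list,
    regress_score_on_splicing,
    score_samples,
    zscore,
)
from .splicing_index import SplicingIndexResult, compute_percent_AS, count_junction_reads
from .synthetic_data import (
    SimulationConfig,
    make_reference_and_model,
    simulate_cohort_alignments,
    simulate_expression,
    simulate_splice_reads,
)

__all__ = [
    "RunConfig",
    "ConfigError",
    "StageError",
    "run_all",
    "summarize_splicing_cohort",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 at the CLI)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3 at the CLI)."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: Path
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    trio: tuple[int, int, int] = (4, 5, 6)
    mode: str = "junction-exact"
    min_informative: int = 10
    aggregator: str = "mean"
    min_baseq: int = 30
    min_total: int = 20
    carrier_threshold: float = 0.10
    run_paralog: bool = True

    def validate(self) -> None:
        if self.mode not in ("junction-exact", "exon-overlap"):
            raise ConfigError(f"invalid mode {self.mode!r}")
        if self.aggregator not in ("mean", "median", "sum"):
            raise ConfigError(f"invalid aggregator {self.aggregator!r}")
        if self.min_baseq < 0 or self.min_total < 0 or self.min_informative < 0:
            raise ConfigError("thresholds must be nonnegative")
        if not 0 <= self.carrier_threshold <= 1:
            raise ConfigError("carrier threshold must lie in [0, 1]")


def summarize_splicing_cohort(
    results: list[SplicingIndexResult], control_ids: list[str]
) -> dict:
    """Control mean %AS with a t-distribution 95% CI, plus per-case values."""
    control_vals = [
        r.percent_AS
        for r in results
        if r.sample_id in control_ids and r.percent_AS is not None
    ]
    if len(control_vals) < 2:
        raise ValueError("need >= 2 controls with defined %AS")
    arr = np.asarray(control_vals, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    n = len(arr)
    half = float(stats.t.ppf(0.975, n - 1)) * sd / np.sqrt(n) if sd > 0 else 0.0
    cases = {
        r.sample_id: r.percent_AS
        for r in results
        if r.sample_id not in control_ids
    }
    return {
        "control_n": n,
        "control_mean_percent_as": mean,
        "control_ci95": [mean - half, mean + half],
        "ci_method": "t-distribution on the control sample",
        "case_percent_as": cases,
    }


def _config_hash(config: RunConfig) -> str:
    payload = dataclasses.asdict(config)
    payload.pop("outdir", None)  # analysis parameters only, not placement
    return hashlib.md5(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except (ConfigError, StageError):
                raise
            except Exception as exc:  # noqa: BLE001 - named-stage rewrap
                raise StageError(name, str(exc)) from exc

        return wrapped

    return deco


@_stage("simulate")
def _stage_simulate(config: RunConfig):
    sim_dir = config.outdir / "sim"
    locus = make_reference_and_model(config.simulation, sim_dir)
    splice_truth = simulate_splice_reads(config.simulation, locus, sim_dir / "splice")
    expr_truth = simulate_expression(config.simulation, sim_dir / "expression")
    cohort_truth = None
    if config.run_paralog:
        cohort_truth = simulate_cohort_alignments(
            config.simulation, locus, sim_dir / "cohort"
        )
    return locus, splice_truth, expr_truth, cohort_truth


@_stage("splice-index")
def _stage_splice_index(config: RunConfig, locus, splice_truth) -> list[SplicingIndexResult]:
    results = []
    for sample_id, info in splice_truth["samples"].items():
        rec = count_junction_reads(
            info["bam"],
            locus.model,
            trio=config.trio,
            mode=config.mode,
            sample_id=sample_id,
        )
        results.append(compute_percent_AS(rec, config.min_informative))
    table = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "inclusion_count": [r.inclusion_count for r in results],
            "skipping_count": [r.skipping_count for r in results],
            "percent_AS": [r.percent_AS for r in results],
            "low_coverage_flag": [r.low_coverage_flag for r in results],
            "undefined_flag": [r.undefined_flag for r in results],
        }
    )
    table.to_csv(config.outdir / "splicing_index.tsv", sep="\t", index=False)
    return results


@_stage("score")
def _stage_score(config: RunConfig, expr_truth) -> dict[str, pd.DataFrame]:
    sim_dir = config.outdir / "sim" / "expression"
    matrix = read_expression_tsv(sim_dir / "expression.tsv")
    reference = build_control_reference(matrix, expr_truth["control_ids"])
    z = zscore(matrix, reference)
    z.to_csv(config.outdir / "zscores.tsv", sep="\t")
    tables = {}
    for name, listfile in (("IFN", "ifn_genes.txt"), ("NFKB", "nfkb_genes.txt")):
        signature = read_gene_list(sim_dir / listfile, name=name)
        table = score_samples(z, signature, aggregator=config.aggregator)
        table.to_csv(config.outdir / f"scores_{name}.tsv", sep="\t")
        tables[name] = table
    return tables


@_stage("correlate")
def _stage_correlate(
    config: RunConfig, score_tables: dict[str, pd.DataFrame], expr_truth
) -> dict:
    splicing = pd.read_csv(
        config.outdir / "sim" / "expression" / "splicing.tsv", sep="\t"
    ).set_index("sample_id")["percent_AS"]
    out = {}
    for name, table in score_tables.items():
        fit = regress_score_on_splicing(table, splicing)
        out[name] = {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "p_value": fit.p_value,
            "n": fit.n,
            "aggregator": config.aggregator,
        }
    (config.outdir / "regression.json").write_text(json.dumps(out, indent=2))
    return out


@_stage("paralog-freq")
def _stage_paralog(config: RunConfig, locus, cohort_truth) -> dict:
    counts = [
        count_base_identities(
            info["bam"], locus.site, individual_id=iid, min_baseq=config.min_baseq
        )
        for iid, info in cohort_truth["individuals"].items()
    ]
    summary = summarize_cohort(
        counts,
        locus.site,
        min_total=config.min_total,
        carrier_threshold=config.carrier_threshold,
    )
    summary.per_individual.to_csv(config.outdir / "paralog_counts.tsv", sep="\t")
    out = {
        "n_individuals_pass": summary.n_individuals_pass,
        "n_individuals_fail_depth": summary.n_individuals_fail_depth,
        "carrier_count": summary.carrier_count,
        "carrier_ids": summary.carrier_ids,
        "min_total": summary.min_total,
        "carrier_threshold": summary.carrier_threshold,
        "mean_reference_fraction": float(
            summary.per_individual.loc[
                summary.per_individual["pass_depth"], "ref_fraction"
            ].mean()
        ),
    }
    (config.outdir / "cohort_summary.json").write_text(json.dumps(out, indent=2))
    return out


def run_all(config: RunConfig) -> dict:
    """Execute all stages and return the consolidated report (also written).

    Raises :class:`ConfigError` for invalid configuration and
    :class:`StageError` (naming the failing stage) on stage failure;
    partial outputs are retained alongside a ``FAILED`` marker file.
    """
    config.validate()
    config.outdir = Path(config.outdir)
    config.outdir.mkdir(parents=True, exist_ok=True)
    marker = config.outdir / "FAILED"
    try:
        locus, splice_truth, expr_truth, cohort_truth = _stage_simulate(config)
        splice_results = _stage_splice_index(config, locus, splice_truth)
        control_ids = [
            s for s, v in splice_truth["samples"].items() if v["group"] == "control"
        ]
        splice_summary = summarize_splicing_cohort(splice_results, control_ids)
        score_tables = _stage_score(config, expr_truth)
        regressions = _stage_correlate(config, score_tables, expr_truth)
        cohort_summary = (
            _stage_paralog(config, locus, cohort_truth) if config.run_paralog else None
        )
    except StageError as exc:
        marker.write_text(f"{exc.stage}\n")
        raise

    report = {
        "provenance": {
            "package_version": __version__,
            "seed": config.simulation.seed,
            "config_hash": _config_hash(config),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
        "splicing": {
            "per_sample": {
                r.sample_id: {
                    "inclusion_count": r.inclusion_count,
                    "skipping_count": r.skipping_count,
                    "percent_AS": r.percent_AS,
                    "low_coverage": r.low_coverage_flag,
                }
                for r in splice_results
            },
            "cohort": splice_summary,
        },
        "scores": {
            name: table["score"].to_dict() for name, table in score_tables.items()
        },
        "regression": regressions,
        "paralog_cohort": cohort_summary,
    }
    (config.outdir / "report.json").write_text(json.dumps(report, indent=2))
    _write_summary(config.outdir / "summary.txt", report)
    return report


def _write_summary(path: Path, report: dict) -> None:
    lines = ["splicescore run summary", "======================="]
    coh = report["splicing"]["cohort"]
    lo, hi = coh["control_ci95"]
    lines.append(
        f"control %AS: mean {coh['control_mean_percent_as']:.1f}% "
        f"(95% CI {lo:.1f}-{hi:.1f}%, n={coh['control_n']})"
    )
    for sid, val in coh["case_percent_as"].items():
        lines.append(f"  case {sid}: %AS = {val:.1f}%" if val is not None else f"  case {sid}: %AS undefined")
    for name, reg in report["regression"].items():
        lines.append(
            f"{name} score ~ %AS: slope {reg['slope']:.4f}, "
            f"R^2 = {reg['r_squared']:.2f}, P = {reg['p_value']:.2g}, n = {reg['n']}"
        )
    if report["paralog_cohort"] is not None:
        pc = report["paralog_cohort"]
        lines.append(
            f"paralog cohort: {pc['n_individuals_pass']} pass depth, "
            f"{pc['n_individuals_fail_depth']} fail, "
            f"{pc['carrier_count']} carrier(s)"
        )
    path.write_text("\n".join(lines) + "\n")
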