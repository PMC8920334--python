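"""Control-referenced Z-scoring, gene-signature scores, and score-vs-splicing regression.

Expression values (RPKM-like, genes x samples) are transformed to Z
scores gene-by-gene against a designated healthy-control sample set:
z[g, s] = (x[g, s] - mean_g) / sd_g, with mean and sd (sample sd,
ddof 1) computed over the controls only.  A signature score for a sample
is an aggregate (mean by default) of its Z scores over a gene list, e.g.
interferon-stimulated genes or NF-kB response genes.  Scores are then
regressed on the exon-skipping splicing index by ordinary least squares.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ControlReference",
    "GeneSignature",
    "RegressionResult",
    "build_control_reference",
    "zscore",
    "score_samples",
    "regress_score_on_splicing",
    "read_expression_tsv",
    "read_gene_list",
    "default_signature",
]

logger = logging.getLogger(__name__)

_AGGREGATORS = {"mean", "median", "sum"}


@dataclass
class ControlReference:
    """Per-gene mean/sd over the healthy-control samples.

    Genes with zero variance across controls are recorded in
    ``dropped_genes`` and excluded from downstream Z scores.
    """

    control_ids: list[str]
    mean: pd.Series
    sd: pd.Series
    dropped_genes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no members")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate members")


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of score on splicing index; r_squared is the squared Pearson r."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    slope_stderr: float

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Normal-theory confidence interval for the slope (t, n-2 df)."""
        half = stats.t.ppf(0.5 + level / 2, self.n - 2) * self.slope_stderr
        return (self.slope - half, self.slope + half)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError("duplicate gene or sample identifiers")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all() or (values < 0).any():
        raise ValueError("expression values must be finite and nonnegative")
    return df


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSignature:
    """Read a one-gene-id-per-line signature file."""
    path = Path(path)
    genes = [
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return GeneSignature(name=name or path.stem, genes=tuple(dict.fromkeys(genes)))


def default_signature(name: str) -> GeneSignature:
    """Packaged editable placeholder gene lists: ``"IFN"`` or ``"NFKB"``.

    These stand in for curated interferon-stimulated and NF-kB response
    gene lists; for real-data use, supply your own curation via
    :func:`read_gene_list`.
    """
    files = {"IFN": "ifn_signature.txt", "NFKB": "nfkb_signature.txt"}
    if name not in files:
        raise ValueError(f"no default signature {name!r}; choose from {sorted(files)}")
    resource = importlib.resources.files("splicescore.data") / files[name]
    with importlib.resources.as_file(resource) as path:
        return read_gene_list(path, name=name)


def build_control_reference(
    matrix: pd.DataFrame, control_ids: Iterable[str]
) -> ControlReference:
    """Per-gene control mean/sd (ddof 1); zero-variance genes are dropped."""
    control_ids = list(control_ids)
    missing = [c for c in control_ids if c not in matrix.columns]
    if missing:
        raise ValueError(f"control ids absent from matrix: {missing}")
    if len(control_ids) < 2:
        raise ValueError("at least 2 control samples are required")
    controls = matrix[control_ids]
    mean = controls.mean(axis=1)
    sd = controls.std(axis=1, ddof=1)
    dropped = sd.index[sd == 0].tolist()
    if dropped:
        logger.warning(
            "%d gene(s) with zero control variance dropped: %s",
            len(dropped),
            ", ".join(dropped[:10]),
        )
    keep = sd.index.difference(dropped, sort=False)
    return ControlReference(
        control_ids=control_ids,
        mean=mean.loc[keep],
        sd=sd.loc[keep],
        dropped_genes=dropped,
    )


def zscore(
    matrix: pd.DataFrame, reference: ControlReference, log2_transform: bool = False
) -> pd.DataFrame:
    """Control-referenced Z matrix; dropped genes are absent from the output.

    ``log2_transform`` applies log2(x + 1) before referencing (off by
    default: Z scores are taken on the raw RPKM scale).
    """
    missing = reference.mean.index.difference(matrix.index)
    if len(missing):
        raise ValueError(f"reference genes absent from matrix: {list(missing)[:5]}")
    x = matrix.loc[reference.mean.index]
    if log2_transform:
        x = np.log2(x + 1.0)
    return x.sub(reference.mean, axis=0).div(reference.sd, axis=0)


def score_samples(
    z: pd.DataFrame, signature: GeneSignature, aggregator: str = "mean"
) -> pd.DataFrame:
    """Per-sample signature score: aggregate of Z over present signature genes.

    Returns a DataFrame indexed by sample id with columns ``score`` and
    ``n_genes_used``; the aggregator used is recorded in ``.attrs``.
    """
    if aggregator not in _AGGREGATORS:
        raise ValueError(f"aggregator must be one of {sorted(_AGGREGATORS)}")
    present = [g for g in signature.genes if g in z.index]
    absent = [g for g in signature.genes if g not in z.index]
    if not present:
        raise ValueError(f"no gene of signature {signature.name!r} present")
    if absent:
        logger.warning(
            "signature %s: %d/%d genes absent from matrix",
            signature.name,
            len(absent),
            len(signature.genes),
        )
    sub = z.loc[present]
    agg = getattr(sub, aggregator)(axis=0)
    out = pd.DataFrame({"score": agg, "n_genes_used": len(present)})
    out.index.name = "sample_id"
    out.attrs.update(
        {"signature": signature.name, "aggregator": aggregator, "sd_ddof": 1}
    )
    return out


def regress_score_on_splicing(
    scores: pd.DataFrame | Mapping[str, float] | pd.Series,
    splicing: Mapping[str, float] | pd.Series,
) -> RegressionResult:
    """Least-squares linear regression of signature score on %AS.

    Samples are paired by id; pairs with undefined values are dropped.
    Requires >= 3 pairs and a non-constant predictor.
    """
    if isinstance(scores, pd.DataFrame):
        score_series = scores["score"]
    else:
        score_series = pd.Series(dict(scores))
    as_series = pd.Series(dict(splicing)) if not isinstance(splicing, pd.Series) else splicing
    paired = pd.concat(
        {"score": score_series, "AS": as_series}, axis=1, join="inner"
    ).dropna()
    n = len(paired)
    if n < 3:
        raise ValueError(f"need >= 3 paired samples, got {n}")
    x = paired["AS"].to_numpy(dtype=float)
    y = paired["score"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("predictor (splicing index) is constant")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        n=n,
        slope_stderr=float(fit.stderr),
    )
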