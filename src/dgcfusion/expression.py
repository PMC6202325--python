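"""Exon-level expression imbalance around fusion breakpoints.

The diagnostic signal of a promoter-swap or in-frame fusion is
overexpression of the 3' partner's exons downstream of the breakpoint in
the carrier sample.  The analysis works on a per-exon expression matrix
(FPKM/RPKM), transformed to log2(x + 1) and gene-centered (each exon row
has its across-sample mean subtracted), and scores a (sample, gene,
breakpoint-exon) triple as

    score = mean(centered, exons >= k) - mean(centered, exons < k)

standardised against the same statistic over all other samples (the
empirical null).  The companion outlier analysis ranks a carrier's
gene-level expression within the cohort (rank 1 = highest).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionError",
    "ImbalanceResult",
    "load_exon_matrix",
    "write_exon_matrix",
    "center_by_gene",
    "breakpoint_imbalance_score",
    "gene_level_expression",
    "outlier_rank",
]

_META_COLUMNS = ["gene", "exon_index", "contig", "start", "end"]


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class ImbalanceResult:
    sample_id: str
    gene_name: str
    breakpoint_exon: int
    score: float
    null_mean: float
    null_sd: float
    z: float | None  # None when the null has zero spread


def load_exon_matrix(path: str | Path) -> pd.DataFrame:
    """Read an exon expression TSV into a (gene, exon_index, contig, start,
    end)-indexed DataFrame with one column per sample."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise ExpressionError(f"exon matrix missing columns: {sorted(missing)}")
    df = df.set_index(_META_COLUMNS)
    if df.columns.duplicated().any():
        raise ExpressionError("duplicate sample columns")
    if (df.values < 0).any():
        raise ExpressionError("expression values must be non-negative")
    _check_exon_indices(df)
    return df


def _check_exon_indices(matrix: pd.DataFrame) -> None:
    for gene, sub in matrix.groupby(level="gene", sort=False):
        idx = sorted(sub.index.get_level_values("exon_index"))
        if idx != list(range(1, len(idx) + 1)):
            raise ExpressionError(
                f"gene {gene}: exon_index not consecutive from 1 ({idx})"
            )


def write_exon_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.reset_index().to_csv(path, sep="\t", index=False)


def center_by_gene(matrix: pd.DataFrame, log_transform: bool = True) -> pd.DataFrame:
    """log2(x+1)-transform (optional) and center each exon row on its mean.

    Row means of the output are zero; the within-row ordering of samples is
    preserved (the transform is monotone).
    """
    if matrix.shape[1] < 2:
        raise ExpressionError("centering needs at least 2 samples")
    values = np.log2(matrix.to_numpy(dtype=float) + 1.0) if log_transform else matrix.to_numpy(dtype=float)
    centered = values - values.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=matrix.index, columns=matrix.columns)


def breakpoint_imbalance_score(
    centered: pd.DataFrame,
    gene_name: str,
    breakpoint_exon: int,
    sample_id: str,
) -> ImbalanceResult:
    """Score 3'-of-breakpoint overexpression for one sample and gene.

    ``breakpoint_exon`` is the first retained exon of the 3' partner (the
    breakpoint-consistent split): exons >= k are downstream, exons < k
    upstream.  The z-score standardises the carrier's score against the
    same statistic computed in every other sample.
    """
    if sample_id not in centered.columns:
        raise ExpressionError(f"unknown sample {sample_id!r}")
    try:
        sub = centered.xs(gene_name, level="gene")
    except KeyError as exc:
        raise ExpressionError(f"unknown gene {gene_name!r}") from exc
    exon_idx = sub.index.get_level_values("exon_index").to_numpy()
    down = exon_idx >= breakpoint_exon
    up = exon_idx < breakpoint_exon
    if not down.any() or not up.any():
        raise ExpressionError(
            f"breakpoint exon {breakpoint_exon} leaves no exons on one side "
            f"(gene {gene_name} has exons 1..{exon_idx.max()})"
        )
    vals = sub.to_numpy(dtype=float)
    scores = vals[down].mean(axis=0) - vals[up].mean(axis=0)
    scores = pd.Series(scores, index=sub.columns)
    score = float(scores[sample_id])
    null = scores.drop(sample_id)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    z = (score - null_mean) / null_sd if null_sd > 0 else None
    return ImbalanceResult(
        sample_id=sample_id, gene_name=gene_name, breakpoint_exon=breakpoint_exon,
        score=score, null_mean=null_mean, null_sd=null_sd, z=z,
    )


def gene_level_expression(
    matrix: pd.DataFrame, gene_name: str
) -> pd.Series:
    """Exon-length-weighted mean FPKM of a gene across samples."""
    try:
        sub = matrix.xs(gene_name, level="gene")
    except KeyError as exc:
        raise ExpressionError(f"unknown gene {gene_name!r}") from exc
    starts = sub.index.get_level_values("start").to_numpy()
    ends = sub.index.get_level_values("end").to_numpy()
    weights = (ends - starts + 1).astype(float)
    vals = sub.to_numpy(dtype=float)
    return pd.Series(
        (vals * weights[:, None]).sum(axis=0) / weights.sum(), index=sub.columns
    )


def outlier_rank(values: pd.Series, sample_id: str) -> tuple[int, int]:
    """Dense rank of a sample's expression, descending (1 = highest).

    Ties share the better rank; returns ``(rank, n_samples)``.
    """
    if len(values) < 2:
        raise ExpressionError("outlier ranking needs at least 2 samples")
    if sample_id not in values.index:
        raise ExpressionError(f"unknown sample {sample_id!r}")
    ranks = values.rank(method="dense", ascending=False)
    return int(ranks[sample_id]), len(values)
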