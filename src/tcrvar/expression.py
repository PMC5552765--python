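"""Gene-expression screen: rank correlation with the per-sample variation
index, Benjamini-Hochberg FDR control and positive/negative gene sets."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import IO, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ValidationError

log = logging.getLogger(__name__)


class ExpressionMatrix:
    """Genes x samples matrix of normalized expression values.

    Zero-variance genes are dropped at construction (their rank correlation
    is undefined); the number removed is kept in ``n_dropped`` and logged.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            raise ValidationError("duplicate gene ids")
        if values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        mat = values.astype(float)
        if mat.isna().any().any():
            raise ValidationError("missing values in expression matrix")
        variances = mat.var(axis=1, ddof=0)
        keep = variances > 0
        self.n_dropped = int((~keep).sum())
        if self.n_dropped:
            log.info("dropped %d zero-variance gene(s)", self.n_dropped)
        self.values = mat.loc[keep]
        self.values.index.name = "gene"
        if self.values.empty:
            raise ValidationError("no genes with nonzero variance")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)])

    @classmethod
    def from_tsv(cls, source: str | Path | IO[str]) -> "ExpressionMatrix":
        df = pd.read_csv(source, sep="\t", index_col=0)
        return cls(df)

    def to_tsv(self, sink: str | Path | IO[str]) -> None:
        self.values.to_csv(sink, sep="\t", index_label="gene")


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH adjusted q-values, order-preserving against the input."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p_values must be a non-empty 1-d vector")
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def correlate_with_tvi(
    expr: ExpressionMatrix,
    tvi: Mapping[str, float] | pd.Series,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Spearman correlation with the variation index.

    Returns a frame with columns ``gene, rho, p, q, direction`` where
    direction is ``positive``/``negative`` for genes with q below the
    threshold and ``null`` otherwise.  p-values use the two-sided t
    approximation with df = n - 2.
    """
    tvi = pd.Series(dict(tvi)) if not isinstance(tvi, pd.Series) else tvi.astype(float)
    expr_samples = set(expr.sample_ids)
    tvi_samples = set(tvi.index)
    if expr_samples != tvi_samples:
        only_expr = sorted(expr_samples - tvi_samples)
        only_tvi = sorted(tvi_samples - expr_samples)
        raise AlignmentError(
            f"sample mismatch; expression-only: {only_expr}, tvi-only: {only_tvi}"
        )
    n = len(tvi)
    if n < 5:
        raise ValidationError(f"need >= 5 samples, got {n}")
    if tvi.nunique() < 2:
        raise ValidationError("variation index is constant across samples")

    X = expr.values[list(tvi.index)].to_numpy()
    ranks = stats.rankdata(X, axis=1)
    t_ranks = stats.rankdata(tvi.to_numpy())
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    tc = t_ranks - t_ranks.mean()
    denom = np.sqrt((rc**2).sum(axis=1)) * np.sqrt((tc**2).sum())
    rho = (rc @ tc) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        tstat = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, np.finfo(float).tiny))
    p = np.clip(2.0 * stats.t.sf(np.abs(tstat), n - 2), np.finfo(float).tiny, 1.0)
    q = benjamini_hochberg(p)
    direction = np.where(
        q < fdr_threshold, np.where(rho > 0, "positive", "negative"), "null"
    )
    return pd.DataFrame(
        {"gene": expr.gene_ids, "rho": rho, "p": p, "q": q, "direction": direction}
    )


def partition_gene_sets(
    results: pd.DataFrame, fdr_threshold: float = 0.05
) -> tuple[set[str], set[str]]:
    """(positive, negative) gene sets at the given FDR threshold."""
    sig = results[results["q"] < fdr_threshold]
    positive = set(sig.loc[sig["rho"] > 0, "gene"])
    negative = set(sig.loc[sig["rho"] < 0, "gene"])
    return positive, negative
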