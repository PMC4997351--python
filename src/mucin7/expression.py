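"""Tissue-specificity calling and a sliding gene-window chromosome scan.

Per gene, expression in a target tissue (minor salivary gland in the
motivating analysis) is compared against all other samples with a
one-sided rank-sum test. Genes in the most significant 1% of p-values on
a chromosome are called tissue-specific, and a 15-gene sliding window
over chromosomal gene order locates clusters of such genes — the pattern
by which a gene inherits the expression territory of the cluster it was
born into.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import rank_sum_test, ranksum_greater_pvalues_batch


@dataclass
class ExpressionMatrix:
    """Genes × samples expression with tissue labels and gene order.

    ``values``: DataFrame, rows = genes (in chromosomal order within each
    chromosome), columns = samples. ``gene_info``: DataFrame indexed like
    ``values`` with 'chrom' and 'position' columns. ``tissues``: Series
    mapping sample -> tissue label.
    """

    values: pd.DataFrame
    gene_info: pd.DataFrame
    tissues: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.gene_info.index):
            raise ValueError("values and gene_info must share the gene index")
        if set(self.values.columns) != set(self.tissues.index):
            raise ValueError("tissue labels must cover exactly the sample columns")
        for _, sub in self.gene_info.groupby("chrom", sort=False):
            pos = sub["position"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("gene positions must be strictly increasing per chromosome")

    def chromosome(self, chrom: str) -> "ExpressionMatrix":
        mask = self.gene_info["chrom"] == chrom
        return ExpressionMatrix(
            values=self.values.loc[mask],
            gene_info=self.gene_info.loc[mask],
            tissues=self.tissues,
        )


@dataclass
class SpecificityCalls:
    pvalues: pd.Series
    specific: pd.Series  # boolean
    quantile: float
    cutoff: float


def specificity_pvalue(gene_row, tissues: pd.Series, target: str) -> float:
    """One-sided rank-sum p-value for target-tissue expression being higher."""
    row = pd.Series(gene_row) if not isinstance(gene_row, pd.Series) else gene_row
    in_target = tissues.loc[row.index] == target
    x = row[in_target].to_numpy(dtype=float)
    y = row[~in_target].to_numpy(dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("need at least one target and one non-target sample")
    if np.all(row.to_numpy() == 0):
        warnings.warn("all-zero expression row; p = 1")
        return 1.0
    return rank_sum_test(x, y, alternative="greater")


def specificity_pvalues(matrix: ExpressionMatrix, target: str) -> pd.Series:
    """Vectorized per-gene specificity p-values for the whole matrix.

    Uses the normal-approximation rank-sum (continuous data assumed); the
    scalar :func:`specificity_pvalue` is the exact-capable reference path.
    """
    in_target = (matrix.tissues.loc[matrix.values.columns] == target).to_numpy()
    if in_target.sum() == 0 or (~in_target).sum() == 0:
        raise ValueError(f"target tissue {target!r} must split the samples")
    vals = matrix.values.to_numpy(dtype=float)
    pvals = ranksum_greater_pvalues_batch(vals[:, in_target], vals[:, ~in_target])
    allzero = np.all(vals == 0, axis=1)
    pvals[allzero] = 1.0
    return pd.Series(pvals, index=matrix.values.index, name="p_value")


def call_specific(pvalues: pd.Series, quantile: float = 0.01) -> SpecificityCalls:
    """Flag the most significant ``quantile`` fraction of genes.

    The cutoff is the k-th smallest p-value with k = floor(n·quantile);
    ties at the cutoff are all included.
    """
    n = len(pvalues)
    k = int(np.floor(n * quantile))
    if k < 1:
        return SpecificityCalls(
            pvalues=pvalues,
            specific=pd.Series(False, index=pvalues.index),
            quantile=quantile,
            cutoff=float("nan"),
        )
    cutoff = float(np.sort(pvalues.to_numpy())[k - 1])
    return SpecificityCalls(
        pvalues=pvalues,
        specific=pvalues <= cutoff,
        quantile=quantile,
        cutoff=cutoff,
    )


def window_scan(flags, window_size: int = 15) -> np.ndarray:
    """Sliding-window (step 1) counts of flagged genes along gene order.

    ``flags`` is a boolean sequence in chromosomal gene order; window i
    covers genes [i, i+window_size).
    """
    f = np.asarray(flags, dtype=int).ravel()
    if f.size < window_size:
        raise ValueError(
            f"need at least {window_size} genes, got {f.size}"
        )
    cumsum = np.concatenate([[0], np.cumsum(f)])
    return cumsum[window_size:] - cumsum[:-window_size]


def scan_report(
    calls: SpecificityCalls,
    gene_order: list[str],
    focal_gene: str,
    window_size: int = 15,
) -> dict:
    """Summary of the window scan around a focal gene.

    Reports the argmax window, the best window containing the focal gene,
    the histogram of window counts, and an enrichment p-value comparing
    the focal window's gene p-values against all other genes (one-sided
    rank-sum, focal window smaller). With no flagged gene anywhere the
    enrichment p is 1 by convention.
    """
    if focal_gene not in gene_order:
        raise ValueError(f"focal gene {focal_gene!r} not in gene order")
    flags = calls.specific.loc[gene_order].to_numpy()
    counts = window_scan(flags, window_size)
    fi = gene_order.index(focal_gene)
    lo = max(0, fi - window_size + 1)
    hi = min(len(counts) - 1, fi)
    focal_windows = np.arange(lo, hi + 1)
    focal_best = int(focal_windows[np.argmax(counts[focal_windows])])
    max_window = int(np.argmax(counts))
    hist = np.bincount(counts, minlength=window_size + 1)
    if counts.max() == 0:
        enrichment_p = 1.0
    else:
        window_genes = set(gene_order[focal_best : focal_best + window_size])
        in_win = calls.pvalues.index.isin(window_genes)
        enrichment_p = rank_sum_test(
            calls.pvalues[in_win], calls.pvalues[~in_win], alternative="less"
        )
    return {
        "max_window": max_window,
        "max_window_count": int(counts[max_window]),
        "focal_window": focal_best,
        "focal_window_count": int(counts[focal_best]),
        "focal_in_max_window": bool(counts[focal_best] == counts.max()),
        "histogram": hist,
        "counts": counts,
        "enrichment_p": float(enrichment_p),
    }


def scan_chromosome(
    matrix: ExpressionMatrix,
    target: str,
    chrom: str,
    focal_gene: str | None = None,
    *,
    window_size: int = 15,
    quantile: float = 0.01,
) -> dict:
    """End-to-end scan of one chromosome: p-values → calls → window report."""
    sub = matrix.chromosome(chrom)
    pvals = specificity_pvalues(sub, target)
    calls = call_specific(pvals, quantile)
    gene_order = list(sub.values.index)
    report: dict = {"calls": calls, "n_specific": int(calls.specific.sum())}
    if focal_gene is not None:
        report.update(scan_report(calls, gene_order, focal_gene, window_size))
    else:
        counts = window_scan(calls.specific.to_numpy(), window_size)
        report.update(
            {
                "counts": counts,
                "max_window": int(np.argmax(counts)),
                "max_window_count": int(counts.max()),
                "histogram": np.bincount(counts, minlength=window_size + 1),
            }
        )
    return report
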