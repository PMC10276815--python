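"""Cluster-specificity scoring of genes in a labeled single-cell count matrix.

Implements the standard marker-gene workflow used to judge whether a
candidate is expressed selectively in one cluster (here: tip endothelial
cells) versus all other cell types pooled: library-size log-normalization,
natural-log fold-change with pseudocounts, fractions of expressing cells, a
one-sided Wilcoxon rank-sum test for positive markers, and the strict
logFC > 1 specificity rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "lognormalize",
    "cluster_marker_stats",
    "specificity_filter",
]


@dataclass
class ExpressionMatrix:
    """Cells x genes raw counts with per-cell cluster (and optional condition) labels."""

    counts: sp.csr_matrix
    gene_ids: list[str]
    barcodes: list[str]
    cell_labels: pd.Series  # index: barcode, value: cluster label
    conditions: pd.Series | None = None  # index: barcode, value: condition label

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_cells, n_genes = self.counts.shape
        if n_cells == 0 or n_genes == 0:
            raise ValueError("empty expression matrix")
        if len(self.barcodes) != n_cells:
            raise ValueError(f"{len(self.barcodes)} barcodes for {n_cells} cells")
        if len(self.gene_ids) != n_genes:
            raise ValueError(f"{len(self.gene_ids)} gene_ids for {n_genes} genes")
        if len(set(self.barcodes)) != n_cells:
            raise ValueError("duplicate barcodes")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene_ids")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValueError("counts must be non-negative integers")
        self.cell_labels = self.cell_labels.reindex(self.barcodes)
        if self.cell_labels.isna().any():
            missing = self.cell_labels.index[self.cell_labels.isna()][0]
            raise ValueError(f"barcode {missing!r} has no cluster label")
        if self.conditions is not None:
            self.conditions = self.conditions.reindex(self.barcodes)
            if self.conditions.isna().any():
                missing = self.conditions.index[self.conditions.isna()][0]
                raise ValueError(f"barcode {missing!r} has no condition label")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


def lognormalize(counts: sp.spmatrix | np.ndarray, scale: float = 1e4) -> sp.csr_matrix:
    """Library-size normalization: value = ln(1 + scale * c / cell_total).

    Zeros stay zero, so sparsity is preserved.  Cells with zero total are
    rejected (their normalized vector would be undefined).
    """
    x = sp.csr_matrix(counts, dtype=float)
    totals = np.asarray(x.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        bad = np.nonzero(totals <= 0)[0]
        raise ValueError(f"cells with zero total counts at rows {bad[:10].tolist()}")
    x = sp.diags(scale / totals) @ x
    x.data = np.log1p(x.data)
    return sp.csr_matrix(x)


def _subsample_clusters(
    labels: pd.Series, max_cells: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices keeping at most max_cells per cluster, sampled without replacement.

    Cluster order and within-cluster candidate order are fixed by sorting, so
    the same seed always keeps the same cells regardless of input order.
    """
    keep: list[np.ndarray] = []
    codes = labels.to_numpy()
    for cl in sorted(pd.unique(codes)):
        idx = np.nonzero(codes == cl)[0]
        if idx.size > max_cells:
            idx = np.sort(rng.choice(idx, size=max_cells, replace=False))
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def cluster_marker_stats(
    matrix: ExpressionMatrix,
    target_cluster: str,
    max_cells_per_cluster: int = 1000,
    seed: int = 0,
    scale: float = 1e4,
) -> pd.DataFrame:
    """Per-gene marker statistics for one cluster versus all other cells pooled.

    logfc = ln((m_in + 1) / (m_out + 1)) where m is the mean over cells of
    expm1(normalized value); the +1 pseudocount keeps the ratio finite when a
    gene is silent on one side.  The rank-sum p-value is one-sided (greater)
    and assigned only to positive-logfc genes ("positive markers only");
    BH q-values are computed over that tested set.
    """
    labels = matrix.cell_labels
    present = set(labels.unique())
    if target_cluster not in present:
        raise ValueError(f"unknown cluster {target_cluster!r}; have {sorted(present)}")

    rng = np.random.default_rng(seed)
    keep = _subsample_clusters(labels, max_cells_per_cluster, rng)
    counts = matrix.counts[keep]
    kept_labels = labels.iloc[keep]

    in_mask = (kept_labels == target_cluster).to_numpy()
    n_in = int(in_mask.sum())
    n_out = int((~in_mask).sum())
    if n_in < 3:
        raise ValueError(f"target cluster {target_cluster!r} has only {n_in} cells (< 3)")
    if n_out == 0:
        raise ValueError("no cells outside the target cluster")

    norm = lognormalize(counts, scale=scale)
    expm1 = norm.copy()
    expm1.data = np.expm1(expm1.data)

    m_in = np.asarray(expm1[in_mask].mean(axis=0)).ravel()
    m_out = np.asarray(expm1[~in_mask].mean(axis=0)).ravel()
    logfc = np.log((m_in + 1.0) / (m_out + 1.0))

    pct_in = np.asarray((counts[in_mask] > 0).mean(axis=0)).ravel()
    pct_out = np.asarray((counts[~in_mask] > 0).mean(axis=0)).ravel()

    dense = np.asarray(norm.todense())
    p = np.full(matrix.n_genes, np.nan)
    tested = np.nonzero(logfc > 0)[0]
    if tested.size:
        # vectorized Mann-Whitney over the tested genes, one-sided "greater"
        res = mannwhitneyu(
            dense[in_mask][:, tested],
            dense[~in_mask][:, tested],
            alternative="greater",
            axis=0,
        )
        p[tested] = res.pvalue

    q = np.full(matrix.n_genes, np.nan)
    if tested.size:
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "logfc": logfc,
            "pct_in": pct_in,
            "pct_out": pct_out,
            "p_value": p,
            "q_value": q,
        }
    ).set_index("gene_id", drop=False)


def specificity_filter(
    stats: pd.DataFrame, genes: list[str] | None = None, lfc_min: float = 1.0
) -> pd.DataFrame:
    """Strict specificity rule: pass iff logfc > lfc_min (and hence > 0).

    Genes absent from the stats table get verdict ``unknown`` rather than a
    silent pass.  Returns gene_id, verdict in {pass, fail, unknown}, reason.
    """
    if genes is None:
        genes = list(stats["gene_id"])
    rows = []
    for g in genes:
        if g not in stats.index:
            rows.append((g, "unknown", "gene absent from expression matrix"))
            continue
        lfc = float(stats.loc[g, "logfc"])
        if lfc > lfc_min:
            rows.append((g, "pass", f"logfc={lfc:.3f} > {lfc_min:g}"))
        else:
            rows.append((g, "fail", f"logfc={lfc:.3f} <= {lfc_min:g}"))
    return pd.DataFrame(rows, columns=["gene_id", "verdict", "reason"]).set_index(
        "gene_id", drop=False
    )
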