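"""Replicate reproducibility: pairwise Pearson and Spearman correlation of
per-gene RPKM on the common subset of moderately-to-highly expressed genes
(RPKM >= 10 in both members of each pair, inclusive).

Coefficients default to raw RPKM; a log10 option is provided and recorded in
the report since either convention appears in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from riboprof.quantify import GeneExpressionTable

DEFAULT_RPKM_THRESHOLD = 10.0


@dataclass
class CorrelationReport:
    """One row per unordered library pair: subset size, Pearson, Spearman."""

    rows: pd.DataFrame  # columns: pair, n_genes, pearson, spearman
    threshold: float
    log10: bool = False

    def to_tsv(self, path) -> None:
        out = self.rows.copy()
        for col in ("pearson", "spearman"):
            out[col] = out[col].map(
                lambda x: float(f"{x:.6g}") if pd.notna(x) else x
            )
        out.to_csv(path, sep="\t", index=False)


def common_expressed_subset(
    a: GeneExpressionTable,
    b: GeneExpressionTable,
    threshold: float = DEFAULT_RPKM_THRESHOLD,
) -> set[str]:
    """Genes present in both tables with RPKM >= threshold in both."""
    return {
        g
        for g in a.gene_ids & b.gene_ids
        if a.rpkm_of(g) >= threshold and b.rpkm_of(g) >= threshold
    }


def pearson(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Sample Pearson product-moment coefficient; None when undefined
    (length < 3 or zero variance in either vector)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def spearman(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Spearman rank correlation (mid-ranks for ties); None when undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.spearmanr(x, y).statistic)


def replicate_report(
    tables: Sequence[GeneExpressionTable],
    threshold: float = DEFAULT_RPKM_THRESHOLD,
    labels: Optional[Sequence[str]] = None,
    log10: bool = False,
) -> CorrelationReport:
    """Pairwise correlation report across replicate expression tables.

    The gene subset is resolved per pair (>= threshold in both members), and
    both coefficients are computed on that pair's RPKM vectors. Pairs whose
    subset has fewer than 3 genes are flagged undefined (NaN).
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables")
    if labels is None:
        labels = [f"rep{i + 1}" for i in range(len(tables))]
    rows = []
    for (i, a), (j, b) in combinations(enumerate(tables), 2):
        genes = sorted(common_expressed_subset(a, b, threshold))
        xa = np.array([a.rpkm_of(g) for g in genes])
        xb = np.array([b.rpkm_of(g) for g in genes])
        if log10:
            xa, xb = np.log10(xa), np.log10(xb)
        p = pearson(xa, xb) if len(genes) >= 3 else None
        s = spearman(xa, xb) if len(genes) >= 3 else None
        rows.append(
            {
                "pair": f"{labels[i]}-{labels[j]}",
                "n_genes": len(genes),
                "pearson": np.nan if p is None else p,
                "spearman": np.nan if s is None else s,
            }
        )
    return CorrelationReport(
        rows=pd.DataFrame(rows), threshold=threshold, log10=log10
    )
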