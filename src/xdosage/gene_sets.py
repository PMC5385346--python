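"""Expression categorisation and fold comparison of curated gene sets.

Built for curated X-linked sets such as testes-specific genes: label each
gene's expression level per group cell with a three-way category
(none-to-weak below 0.1 FPKM, weak-to-moderate in [0.1, 0.5],
moderate-to-high above 0.5 — boundary values fall in the lower category),
and compare aggregate expression of the set between two cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import DataError

DEFAULT_THRESHOLDS = (0.1, 0.5)
CATEGORIES = ("none_to_weak", "weak_to_moderate", "moderate_to_high")


def categorize(fpkm: float, thresholds=DEFAULT_THRESHOLDS) -> str:
    lo, hi = thresholds
    if fpkm < lo:
        return CATEGORIES[0]
    if fpkm <= hi:
        return CATEGORIES[1]
    return CATEGORIES[2]


def _select(means: pd.DataFrame, gene_list) -> pd.DataFrame:
    genes = means.index.intersection(pd.Index(gene_list))
    if len(genes) == 0:
        raise DataError("gene list does not intersect the matrix")
    return means.loc[genes]


def categorize_expression(means: pd.DataFrame, gene_list,
                          thresholds=DEFAULT_THRESHOLDS):
    """Category per gene per cell plus per-cell category counts.

    ``means`` is a group-means frame (genes x cells); categories are a pure
    threshold function of the mean FPKM, monotone in expression.
    """
    sub = _select(means, gene_list)
    cats = sub.apply(lambda col: col.map(
        lambda v: categorize(v, thresholds)))
    counts = pd.DataFrame({cat: (cats == cat).sum() for cat in CATEGORIES})
    return cats, counts


def set_fold_comparison(means: pd.DataFrame, gene_list,
                        cell_a, cell_b) -> dict:
    """Aggregate and per-gene expression folds of a gene set between two
    cells (columns of the means frame).

    Aggregate fold = mean(cell_a) / mean(cell_b) over the set; per-gene
    folds are missing where the denominator is zero.
    """
    sub = _select(means, gene_list)
    for cell in (cell_a, cell_b):
        if cell not in sub.columns:
            raise DataError(f"cell {cell} absent from means")
    a, b = sub[cell_a], sub[cell_b]
    denom = b.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        per_gene = pd.Series(np.where(b > 0, a / b, np.nan), index=sub.index,
                             name="fold")
    return {
        "aggregate_fold": float(a.mean() / denom) if denom > 0 else np.nan,
        "per_gene": per_gene,
        "n_genes": len(sub),
    }
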