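"""Paired IT vs TE lineage comparison.

Dissected blastocyst halves — the IT part (inner cell mass plus adhering
trophectoderm) and the TE-only part — give a paired test of imprinted
paternal-X inactivation: if the TE silenced one X while the ICM kept both
active, X-linked dosage would be systematically higher in IT than TE.
This module computes per-embryo IT/TE X-linked expression ratios, X:A
ratios per part, XIST levels, and the paired signed-rank tests.  Paired
tests are used throughout because the design is genuinely paired.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataError, ValidatedDataset, X_LINKED
from .dosage_core import xa_ratios

log = logging.getLogger(__name__)


def lineage_pairs(dataset: ValidatedDataset,
                  expressed_min_fpkm: float = 0.1) -> pd.DataFrame:
    """One row per embryo with paired IT/TE dosage summaries.

    ``it_mean_x``/``te_mean_x`` are mean X-linked FPKM per part, normalized
    so the IT group mean is exactly 1; ``it_te_ratio`` is computed per
    embryo before normalization.  ``it_xa``/``te_xa`` are per-part X:A
    ratios and ``xist_it``/``xist_te`` the XIST level of each part.
    Unpaired parts are excluded with a warning.
    """
    s = dataset.samples
    split = s[s["lineage"].isin(["IT", "TE"])]
    if split.empty:
        raise DataError("dataset contains no IT/TE samples")
    by_embryo = split.groupby("embryo_id")["lineage"].apply(set)
    paired = by_embryo.index[by_embryo.apply(lambda l: l == {"IT", "TE"})]
    unpaired = set(by_embryo.index) - set(paired)
    if unpaired:
        log.warning("excluding %d embryos with unpaired parts: %s",
                    len(unpaired), sorted(unpaired)[:5])
    if len(paired) == 0:
        raise DataError("no embryo has both an IT and a TE sample")
    x_genes = dataset.genes_of_class(X_LINKED)
    xa = xa_ratios(dataset, expressed_min_fpkm=expressed_min_fpkm)
    xist_genes = dataset.annotation.index[dataset.annotation["is_xist"]]
    rows = []
    for eid in sorted(paired):
        it_id = split.index[(split["embryo_id"] == eid)
                            & (split["lineage"] == "IT")][0]
        te_id = split.index[(split["embryo_id"] == eid)
                            & (split["lineage"] == "TE")][0]
        it_x = float(dataset.matrix.loc[x_genes, it_id].mean())
        te_x = float(dataset.matrix.loc[x_genes, te_id].mean())
        rows.append({
            "embryo_id": eid,
            "it_mean_x": it_x,
            "te_mean_x": te_x,
            "it_te_ratio": it_x / te_x if te_x > 0 else np.nan,
            "it_xa": xa.loc[it_id, "xa_ratio"],
            "te_xa": xa.loc[te_id, "xa_ratio"],
            "xist_it": float(dataset.matrix.loc[xist_genes, it_id].sum())
            if len(xist_genes) else np.nan,
            "xist_te": float(dataset.matrix.loc[xist_genes, te_id].sum())
            if len(xist_genes) else np.nan,
        })
    out = pd.DataFrame(rows).set_index("embryo_id")
    norm = out["it_mean_x"].mean()
    out["it_mean_x"] /= norm
    out["te_mean_x"] /= norm
    return out


def _paired_signed_rank(a: np.ndarray, b: np.ndarray) -> float:
    diff = a - b
    if np.allclose(diff, 0):
        return 1.0
    res = stats.wilcoxon(a, b, alternative="two-sided")
    return float(res.pvalue)


def lineage_xa_test(pairs: pd.DataFrame) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value for an IT-vs-TE
    difference in X:A ratio (p = 1 when all differences are zero)."""
    sub = pairs.dropna(subset=["it_xa", "te_xa"])
    if len(sub) < 3:
        raise DataError("need at least 3 complete IT/TE pairs")
    return _paired_signed_rank(sub["it_xa"].values, sub["te_xa"].values)


def xist_compare(pairs: pd.DataFrame, alpha: float = 0.01) -> dict:
    """IT vs TE XIST summary (means ± sd) and the paired signed-rank test,
    assessed at the stated alpha."""
    sub = pairs.dropna(subset=["xist_it", "xist_te"])
    if len(sub) == 0 or (sub[["xist_it", "xist_te"]].values == 0).all():
        log.warning("XIST absent from the matrix; comparison skipped")
        return {"skipped": True}
    p = _paired_signed_rank(sub["xist_it"].values, sub["xist_te"].values)
    return {
        "skipped": False,
        "it_mean": float(sub["xist_it"].mean()),
        "it_sd": float(sub["xist_it"].std(ddof=1)),
        "te_mean": float(sub["xist_te"].mean()),
        "te_sd": float(sub["xist_te"].std(ddof=1)),
        "p_value": p,
        "alpha": alpha,
        "significant": p < alpha,
    }
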