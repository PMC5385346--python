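"""Per-gene sex-differential expression within one embryo group.

Genes expressed above a floor in at least one sex are tested female vs male
with a two-sided Welch t-test on log2(FPKM+1) (a rank-sum alternative is
available).  Significant genes are partitioned by chromosome class into
X-linked (xDEG) and autosomal (aDEG) sets with direction accounting, and
helpers build volcano tables and between-group set overlaps.  p-values are
reported unadjusted at the chosen alpha by default; Benjamini-Hochberg
correction can be switched on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AUTOSOMAL, DataError, ValidatedDataset, X_LINKED

FC_PSEUDOCOUNT = 0.01


def sex_de_test(dataset: ValidatedDataset, group: str, alpha: float = 0.05,
                min_mean_fpkm: float = 0.1, method: str = "welch",
                adjust: bool = False) -> pd.DataFrame:
    """Test every sufficiently expressed gene for a sex difference.

    Returns one row per tested gene: ``p_value``, ``log2_fc`` (female over
    male group means, with a small pseudocount so the value stays finite),
    ``direction`` and ``is_significant``.  Genes with zero variance in both
    sexes and equal means get p = 1.
    """
    f_ids = dataset.samples_in(sex="female", group=group)
    m_ids = dataset.samples_in(sex="male", group=group)
    if len(f_ids) < 2 or len(m_ids) < 2:
        raise DataError(f"need >=2 samples per sex in group {group!r}")
    fmat = dataset.matrix[f_ids]
    mmat = dataset.matrix[m_ids]
    f_mean = fmat.mean(axis=1)
    m_mean = mmat.mean(axis=1)
    tested = (f_mean > min_mean_fpkm) | (m_mean > min_mean_fpkm)
    flog = np.log2(fmat.loc[tested].values + 1.0)
    mlog = np.log2(mmat.loc[tested].values + 1.0)
    if method == "welch":
        res = stats.ttest_ind(flog, mlog, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    elif method == "ranksum":
        p = np.array([stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
                      for a, b in zip(flog, mlog)])
    else:
        raise ValueError(f"unknown method {method!r}")
    # degenerate genes (no variance anywhere): equal means are a clean null
    nan = np.isnan(p)
    if nan.any():
        equal = np.isclose(flog.mean(axis=1), mlog.mean(axis=1))
        p[nan & equal] = 1.0
        p[nan & ~equal] = 0.0
    log2_fc = np.log2((f_mean[tested] + FC_PSEUDOCOUNT)
                      / (m_mean[tested] + FC_PSEUDOCOUNT))
    out = pd.DataFrame({
        "group": group,
        "p_value": p,
        "log2_fc": log2_fc,
        "direction": np.where(log2_fc >= 0, "female_high", "male_high"),
        "chrom_class": dataset.annotation.loc[tested.index[tested],
                                              "chrom_class"],
    }, index=tested.index[tested])
    if adjust:
        out["p_adjusted"] = _bh_adjust(out["p_value"].values)
        out["is_significant"] = out["p_adjusted"] < alpha
    else:
        out["is_significant"] = out["p_value"] < alpha
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate(
        (p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.clip(adj, 0, 1)


def classify_degs(degs: pd.DataFrame) -> dict:
    """Split significant genes into xDEGs and aDEGs with direction counts.

    Returns the two significant subsets plus a count/proportion summary of
    female-high vs male-high genes in each class.
    """
    sig = degs[degs["is_significant"]]
    xdeg = sig[sig["chrom_class"] == X_LINKED]
    adeg = sig[sig["chrom_class"] == AUTOSOMAL]
    counts = {}
    for name, sub in (("xdeg", xdeg), ("adeg", adeg)):
        fh = int((sub["direction"] == "female_high").sum())
        mh = int((sub["direction"] == "male_high").sum())
        counts[f"{name}_female_high"] = fh
        counts[f"{name}_male_high"] = mh
        counts[f"{name}_total"] = fh + mh
        counts[f"{name}_female_high_frac"] = fh / (fh + mh) if fh + mh else np.nan
    return {"xdeg": xdeg, "adeg": adeg, "counts": counts}


def overlap_sets(degs_a, degs_b) -> dict:
    """Venn counts (only-A, only-B, both) by gene identity, with members."""
    a = set(degs_a.index if isinstance(degs_a, pd.DataFrame) else degs_a)
    b = set(degs_b.index if isinstance(degs_b, pd.DataFrame) else degs_b)
    return {
        "only_a": len(a - b), "only_b": len(b - a), "both": len(a & b),
        "members_only_a": sorted(a - b), "members_only_b": sorted(b - a),
        "members_both": sorted(a & b),
    }


def volcano_table(degs: pd.DataFrame,
                  fc_strata: tuple[float, ...] = (2.0,)) -> pd.DataFrame:
    """Plot-ready (log2 fold change, -log10 p) table.

    Zero p-values are clipped to the smallest positive float so the log is
    finite; ``stratum`` labels which fold-change band each gene falls in.
    """
    if len(degs) == 0:
        raise DataError("no tested genes")
    p = degs["p_value"].clip(lower=np.finfo(float).tiny)
    out = pd.DataFrame({
        "log2_fc": degs["log2_fc"],
        "neg_log10_p": -np.log10(p),
    }, index=degs.index)
    bounds = sorted(np.log2(np.asarray(fc_strata, dtype=float)))
    labels = pd.Series("lt_" + format(fc_strata[0], "g"), index=out.index)
    for b, f in zip(bounds, sorted(fc_strata)):
        labels[out["log2_fc"].abs() >= b] = "ge_" + format(f, "g")
    out["stratum"] = labels
    return out
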