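"""Core X-dosage statistics.

Everything here reduces an expression matrix with sexed samples to the
headline dosage quantities: per-cell group means, per-gene female:male (F:M)
ratios and their distribution, the per-sample X:A ratio (mean X-linked over
mean autosomal FPKM; ~0.5 with one active X, ~1.0 with two), counts of
expressed genes, proportions of female-biased genes, and the nonparametric
two-sample comparisons used on ratio distributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataError, ValidatedDataset, X_LINKED, AUTOSOMAL

log = logging.getLogger(__name__)


def group_means(dataset: ValidatedDataset,
                by: tuple[str, ...] = ("sex", "group")) -> pd.DataFrame:
    """Arithmetic mean FPKM per gene within each sample cell.

    ``by`` is ``("sex", "group")`` or ``("sex", "group", "lineage")``.
    Returns a genes x cells frame whose columns are a MultiIndex over the
    ``by`` levels; empty cells are simply absent.
    """
    if not set(by) <= {"sex", "group", "lineage"}:
        raise ValueError(f"cannot group by {by}")
    cols = {}
    for key, sub in dataset.samples.groupby(list(by), sort=True):
        cols[key] = dataset.matrix[sub.index].mean(axis=1)
    if not cols:
        raise DataError("no sample cells to average")
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=list(by))
    return out


def _sex_means(means: pd.DataFrame, group: str) -> tuple[pd.Series, pd.Series]:
    for sex in ("female", "male"):
        if (sex, group) not in means.columns:
            raise DataError(f"group {group!r} has no {sex} samples")
    return means[("female", group)], means[("male", group)]


def fm_ratios(means: pd.DataFrame, group: str, min_fpkm: float = 1.0,
              pseudocount: float = 0.0) -> pd.DataFrame:
    """Per-gene female/male group-mean table with log2 ratios.

    ``log2_fm`` is missing when either sex mean is zero (unless a positive
    ``pseudocount`` is given, in which case it is added to both means).
    ``passes_min_fpkm`` flags genes whose larger sex mean exceeds
    ``min_fpkm`` — the filter used for ratio-distribution statistics.
    Restrict ``means`` to a gene class (e.g. X-linked) before calling to get
    class-specific tables.
    """
    f, m = _sex_means(means, group)
    out = pd.DataFrame({"female_mean": f, "male_mean": m})
    if pseudocount > 0:
        out["log2_fm"] = np.log2((f + pseudocount) / (m + pseudocount))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where((f > 0) & (m > 0), f / m, np.nan)
        out["log2_fm"] = np.log2(ratio, out=np.full(len(f), np.nan),
                                 where=~np.isnan(ratio))
    out["passes_min_fpkm"] = np.maximum(f, m) > min_fpkm
    return out


def fm_mean_ratio(means: pd.DataFrame, group: str,
                  annotation: pd.DataFrame | None = None,
                  gene_class: str = X_LINKED, min_fpkm: float = 1.0,
                  mode: str = "aggregate",
                  include_xist: bool = True) -> float:
    """Aggregate female-to-male expression ratio of one gene class.

    Default (``mode="aggregate"``): mean of female means over qualifying
    genes divided by the mean of male means over the same genes — robust to
    small denominators.  ``mode="per_gene"`` instead averages per-gene
    ratios over genes with a positive male mean.  Qualifying genes have
    max(sex means) > ``min_fpkm``.
    """
    sub = means
    if annotation is not None:
        keep = annotation["chrom_class"] == gene_class
        if not include_xist:
            keep &= ~annotation["is_xist"]
        sub = means.loc[means.index.intersection(annotation.index[keep])]
    f, m = _sex_means(sub, group)
    qual = np.maximum(f, m) > min_fpkm
    if not qual.any():
        raise DataError(f"no {gene_class} gene passes the FPKM filter")
    f, m = f[qual], m[qual]
    if mode == "aggregate":
        denom = m.mean()
        if denom == 0:
            raise DataError("male aggregate mean is zero")
        return float(f.mean() / denom)
    if mode == "per_gene":
        ok = m > 0
        if not ok.any():
            raise DataError("no gene with positive male mean")
        return float((f[ok] / m[ok]).mean())
    raise ValueError(f"unknown mode {mode!r}")


def xa_ratios(dataset: ValidatedDataset, expressed_min_fpkm: float = 0.1,
              include_xist: bool = True, include_par: bool = True
              ) -> pd.DataFrame:
    """Per-sample X:A summary.

    For each sample, the mean FPKM over X-linked genes expressed in that
    sample (FPKM > ``expressed_min_fpkm``) divided by the mean over
    expressed autosomal genes.  Samples without any expressed X gene get a
    missing ratio with a warning.
    """
    x_genes = dataset.genes_of_class(X_LINKED, include_xist=include_xist,
                                     include_par=include_par)
    a_genes = dataset.genes_of_class(AUTOSOMAL)
    rows = {}
    for sid in dataset.matrix.columns:
        col = dataset.matrix[sid]
        x = col.loc[x_genes]
        a = col.loc[a_genes]
        x = x[x > expressed_min_fpkm]
        a = a[a > expressed_min_fpkm]
        mean_x = x.mean() if len(x) else np.nan
        mean_a = a.mean() if len(a) else np.nan
        if len(x) == 0 or len(a) == 0 or mean_a == 0:
            log.warning("sample %s has no expressed X or autosomal genes; "
                        "X:A ratio undefined", sid)
            rows[sid] = (mean_x, mean_a, np.nan)
        else:
            rows[sid] = (mean_x, mean_a, mean_x / mean_a)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["mean_x", "mean_a", "xa_ratio"])


def fm_histogram(fm: pd.DataFrame, bin_width: float = 0.2) -> pd.DataFrame:
    """Histogram of defined, filter-passing log2 F:M ratios.

    Bins are left-closed right-open and aligned at zero; counts sum to the
    number of defined ratios that pass the FPKM filter.
    """
    vals = fm.loc[fm["passes_min_fpkm"], "log2_fm"].dropna().values
    if len(vals) == 0:
        raise DataError("no defined F:M ratio to bin")
    idx = np.floor(vals / bin_width).astype(int)
    counts = pd.Series(idx).value_counts().sort_index()
    return pd.DataFrame({
        "bin_left": counts.index * bin_width,
        "bin_right": (counts.index + 1) * bin_width,
        "count": counts.values,
    }).reset_index(drop=True)


@dataclass
class DistributionComparison:
    mw_statistic: float
    mw_p: float
    ks_statistic: float
    ks_p: float


def compare_distributions(a, b) -> DistributionComparison:
    """Two-sided Mann-Whitney U and two-sample Kolmogorov-Smirnov tests.

    Exact p-values are used where scipy supports them (small samples without
    ties).  A fully degenerate comparison (every value identical) returns
    p = 1 with a warning instead of failing.
    """
    a = np.asarray(pd.Series(a).dropna(), dtype=float)
    b = np.asarray(pd.Series(b).dropna(), dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise DataError("need at least 3 defined values per sample")
    if len(np.unique(np.concatenate([a, b]))) == 1:
        warnings.warn("degenerate comparison: all values identical; p = 1")
        return DistributionComparison(len(a) * len(b) / 2.0, 1.0, 0.0, 1.0)
    mw = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    ks = stats.ks_2samp(a, b, alternative="two-sided", method="auto")
    return DistributionComparison(float(mw.statistic), float(mw.pvalue),
                                  float(ks.statistic), float(ks.pvalue))


def sexed_xa_test(xa: pd.DataFrame, samples: pd.DataFrame, group: str,
                  paired: bool = False) -> float:
    """Two-sided rank test p-value for a male-vs-female X:A difference.

    Default is the unpaired rank-sum (Mann-Whitney) test, since whole
    blastocysts of opposite sex are independent; a signed-rank mode is
    retained for genuinely paired designs.
    """
    sel = samples.index[samples["group"] == group]
    vals = xa.loc[xa.index.intersection(sel), "xa_ratio"].dropna()
    sexes = samples.loc[vals.index, "sex"]
    f = vals[sexes == "female"].values
    m = vals[sexes == "male"].values
    if len(f) < 2 or len(m) < 2:
        raise DataError("need at least two X:A values per sex")
    if np.array_equal(np.sort(f), np.sort(m)):
        return 1.0
    if paired:
        if len(f) != len(m):
            raise DataError("paired mode requires equal sample counts")
        res = stats.wilcoxon(f, m, alternative="two-sided")
    else:
        res = stats.mannwhitneyu(f, m, alternative="two-sided", method="auto")
    return float(res.pvalue)


def expressed_counts(means: pd.DataFrame, annotation: pd.DataFrame,
                     gene_class: str = X_LINKED,
                     threshold: float = 0.1) -> dict[str, int]:
    """Number of genes of a class expressed in each group.

    Sexes are pooled by taking the larger of the two sex means, so a gene
    expressed in either sex counts; "expressed" means group mean FPKM
    strictly above ``threshold``.
    """
    genes = annotation.index[annotation["chrom_class"] == gene_class]
    sub = means.loc[means.index.intersection(genes)]
    out = {}
    for group in sub.columns.get_level_values("group").unique():
        cell = sub.xs(group, axis=1, level="group")
        out[str(group)] = int((cell.max(axis=1) > threshold).sum())
    return out


def fm_exceed_proportions(fm: pd.DataFrame,
                          folds=(1.0, 2.0)) -> dict[float, float]:
    """Fraction of defined, filter-passing genes whose female:male mean
    ratio is strictly greater than each fold."""
    sub = fm.loc[fm["passes_min_fpkm"]].dropna(subset=["log2_fm"])
    if len(sub) == 0:
        raise DataError("no defined F:M ratio")
    ratio = sub["female_mean"] / sub["male_mean"]
    return {float(f): float((ratio > f).mean()) for f in folds}
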