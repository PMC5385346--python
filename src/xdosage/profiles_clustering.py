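"""Relative-expression heatmap ordering and trajectory clustering.

Two views of X-linked gene behaviour across reprogramming states:

* :func:`heatmap_matrix` — per-sample log2 expression relative to the male
  IVF group mean, with a deterministic gene ordering from average-linkage
  hierarchical clustering (Euclidean distance), the standard heatmap row
  ordering;
* :func:`kmeans_trajectories` — k-means (k = 9 by default) on per-gene
  donor -> SCNT -> IVF relative-expression triples, summarising how genes
  move from the somatic state toward the fertilised-embryo state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .data_model import DataError, ValidatedDataset, X_LINKED
from .dosage_core import group_means

log = logging.getLogger(__name__)

DEFAULT_K = 9
DEFAULT_PSEUDOCOUNT = 0.01


def heatmap_matrix(dataset: ValidatedDataset,
                   reference_cell: tuple[str, str] = ("male", "IVF"),
                   pseudocount: float = DEFAULT_PSEUDOCOUNT,
                   gene_class: str = X_LINKED) -> pd.DataFrame:
    """Per-sample log2 relative expression of one gene class, rows ordered
    by average-linkage hierarchical clustering.

    Relative expression is log2((FPKM + pc) / (reference mean + pc)) against
    the reference cell's per-gene mean.  All-zero gene rows are dropped
    (count logged).  Rows are canonically sorted by gene id before linkage,
    so the ordering does not depend on input row order.
    """
    sex, group = reference_cell
    ref_ids = dataset.samples_in(sex=sex, group=group)
    if len(ref_ids) == 0:
        raise DataError(f"reference cell {reference_cell} has no samples")
    genes = dataset.genes_of_class(gene_class)
    sub = dataset.matrix.loc[genes]
    nonzero = sub.sum(axis=1) > 0
    if (~nonzero).any():
        log.info("dropping %d all-zero gene rows", int((~nonzero).sum()))
    sub = sub.loc[nonzero].sort_index()
    ref_mean = sub[ref_ids].mean(axis=1)
    rel = np.log2(sub.add(pseudocount).div(ref_mean + pseudocount, axis=0))
    if len(rel) > 2:
        link = hierarchy.linkage(pdist(rel.values, metric="euclidean"),
                                 method="average")
        order = hierarchy.leaves_list(link)
        rel = rel.iloc[order]
    return rel


def trajectory_matrix(dataset: ValidatedDataset, sex: str,
                      stages: tuple[str, ...] = ("DONOR", "SCNT", "IVF"),
                      reference_cell: tuple[str, str] = ("male", "IVF"),
                      pseudocount: float = DEFAULT_PSEUDOCOUNT,
                      gene_class: str = X_LINKED) -> pd.DataFrame:
    """Per-gene log2 relative expression triple across reprogramming stages
    (group means of one sex vs the reference cell mean)."""
    means = group_means(dataset)
    if reference_cell not in means.columns:
        raise DataError(f"reference cell {reference_cell} absent")
    genes = dataset.genes_of_class(gene_class)
    ref = means.loc[genes, reference_cell]
    keep = ref.index[(ref > 0) | (means.loc[genes].sum(axis=1) > 0)]
    dropped = len(genes) - len(keep)
    if dropped:
        log.info("dropping %d genes with undefined relative expression",
                 dropped)
    cols = {}
    for stage in stages:
        if (sex, stage) not in means.columns:
            raise DataError(f"no samples for ({sex}, {stage})")
        cols[stage] = np.log2((means.loc[keep, (sex, stage)] + pseudocount)
                              / (ref.loc[keep] + pseudocount))
    return pd.DataFrame(cols)


@dataclass
class ClusterAssignment:
    labels: pd.Series               # gene_id -> cluster id in 1..k
    centroids: pd.DataFrame         # one row per cluster
    frequencies: pd.Series          # genes per cluster

    @property
    def k(self) -> int:
        return len(self.centroids)


def kmeans_trajectories(traj: pd.DataFrame, k: int = DEFAULT_K,
                        seed: int = 0, n_restarts: int = 10
                        ) -> ClusterAssignment:
    """k-means (Lloyd, k-means++ seeding, best of ``n_restarts``) on the
    trajectory matrix; deterministic given ``seed``.

    If the data hold fewer distinct points than ``k``, k is reduced with a
    warning rather than failing.
    """
    if len(traj) < k:
        raise DataError(f"need at least k={k} genes, got {len(traj)}")
    n_distinct = len(np.unique(traj.values, axis=0))
    if n_distinct < k:
        log.warning("only %d distinct points; reducing k from %d",
                    n_distinct, k)
        k = n_distinct
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                algorithm="lloyd")
    labels = km.fit_predict(traj.values) + 1
    return ClusterAssignment(
        labels=pd.Series(labels, index=traj.index, name="cluster"),
        centroids=pd.DataFrame(km.cluster_centers_, columns=traj.columns,
                               index=pd.RangeIndex(1, k + 1, name="cluster")),
        frequencies=pd.Series(labels).value_counts().sort_index(),
    )
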