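"""Chromosome-scale sliding-window expression profiles.

Each chromosome is tiled with fixed-width windows (1 Mb by default); the
mean FPKM of one sample cell is summed over the genes falling in each
window, expressed relative to a reference cell (male IVF by default), and
smoothed with a centered moving average over 30 windows.  The smoothed
relative profile makes chromosome-wide dosage differences (a uniformly
elevated female X against flat autosomes) visible at a glance.

Genes are assigned to exactly one window by their start coordinate
(converted internally to 0-based half-open), so window sums conserve the
total expression of each chromosome.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_model import DataError, UNMAPPED, ValidatedDataset

log = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_SMOOTH_K = 30


def chromosome_lengths(annotation: pd.DataFrame) -> dict[str, int]:
    """Chromosome lengths inferred from the furthest annotated gene end."""
    mapped = annotation[annotation["chrom_class"] != UNMAPPED]
    return mapped.groupby("chrom")["end"].max().astype(int).to_dict()


def window_sums(dataset: ValidatedDataset, cell: tuple[str, str],
                window_bp: int = DEFAULT_WINDOW_BP,
                chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-window summed mean FPKM of one (sex, group) cell.

    Returns one row per window per chromosome with columns ``chrom,
    window_index, window_start, raw_sum``; windows tile each chromosome and
    the per-chromosome sum of ``raw_sum`` equals the summed gene means.
    """
    sex, group = cell
    sids = dataset.samples_in(sex=sex, group=group)
    if len(sids) == 0:
        raise DataError(f"no samples in cell ({sex}, {group})")
    gene_mean = dataset.matrix[sids].mean(axis=1)
    ann = dataset.annotation
    mapped = ann[ann["chrom_class"] != UNMAPPED]
    lengths = dict(chrom_lengths or chromosome_lengths(dataset.annotation))
    frames = []
    for chrom, sub in mapped.groupby("chrom", sort=True):
        length = lengths.get(chrom, int(sub["end"].max()))
        n_windows = max(1, int(np.ceil(length / window_bp)))
        start0 = sub["start"].values - 1          # to 0-based half-open
        idx = start0 // window_bp
        beyond = idx >= n_windows
        if beyond.any():
            log.warning("%d genes on %s lie beyond the declared length; "
                        "windows extended", int(beyond.sum()), chrom)
            n_windows = int(idx.max()) + 1
        sums = np.zeros(n_windows)
        np.add.at(sums, idx, gene_mean.loc[sub.index].values)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "window_index": np.arange(n_windows),
            "window_start": np.arange(n_windows) * window_bp,
            "raw_sum": sums,
        }))
    return pd.concat(frames, ignore_index=True)


def relative_profile(profile: pd.DataFrame,
                     reference_profile: pd.DataFrame) -> pd.DataFrame:
    """Add ``rel`` = raw_sum / reference raw_sum per window.

    Windows where the reference is zero become missing (NaN), never
    infinite.  The two profiles must share the exact window grid.
    """
    key = ["chrom", "window_index"]
    if not profile[key].reset_index(drop=True).equals(
            reference_profile[key].reset_index(drop=True)):
        raise DataError("profile and reference use different window grids")
    out = profile.copy().reset_index(drop=True)
    ref = reference_profile["raw_sum"].values
    with np.errstate(divide="ignore", invalid="ignore"):
        out["rel"] = np.where(ref > 0, out["raw_sum"].values / ref, np.nan)
    return out


def smooth_profile(profile: pd.DataFrame,
                   k: int = DEFAULT_SMOOTH_K) -> pd.DataFrame:
    """Add ``smoothed``: centered k-window moving average of ``rel``.

    The window shrinks at chromosome edges and missing windows are skipped,
    so the smoothed value always averages the available neighbours;
    chromosomes shorter than ``k`` windows collapse to their global mean
    (with a warning).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if "rel" not in profile.columns:
        raise DataError("profile has no 'rel' column; run relative_profile")
    out = profile.copy()
    smoothed = np.full(len(out), np.nan)
    for chrom, sub in out.groupby("chrom", sort=False):
        rel = sub.sort_values("window_index")["rel"]
        if k > len(rel):
            log.warning("k=%d exceeds the %d windows of %s; using the "
                        "global mean", k, len(rel), chrom)
            vals = pd.Series(np.full(len(rel), rel.mean()), index=rel.index)
        else:
            vals = rel.rolling(k, center=True, min_periods=1).mean()
        smoothed[out.index.get_indexer(vals.index)] = vals.values
    out["smoothed"] = smoothed
    return out


def cell_profile(dataset: ValidatedDataset, cell: tuple[str, str],
                 reference_cell: tuple[str, str] = ("male", "IVF"),
                 window_bp: int = DEFAULT_WINDOW_BP,
                 k: int = DEFAULT_SMOOTH_K) -> pd.DataFrame:
    """Convenience composition: window sums -> relative to reference ->
    smoothed, on a shared window grid."""
    lengths = chromosome_lengths(dataset.annotation)
    prof = window_sums(dataset, cell, window_bp, lengths)
    ref = window_sums(dataset, reference_cell, window_bp, lengths)
    return smooth_profile(relative_profile(prof, ref), k)
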