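"""End-to-end orchestration.

A :class:`RunConfig` either points at the three input tables (annotation,
FPKM matrix, sample sheet) or requests a simulated dataset; ``run_pipeline``
then executes every analysis stage that the available sample design
supports, writes per-stage TSVs (each tagged with the run's config hash),
and collects the headline statistics into a machine-readable
``summary.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._tsv import write_table
from .data_model import (GROUPS, X_LINKED, ValidatedDataset, load_annotation,
                         load_expression, load_samples, sample_correlation,
                         housekeeping_variability, validate_dataset,
                         verify_sex_markers)
from .dosage_core import (compare_distributions, expressed_counts,
                          fm_exceed_proportions, fm_histogram, fm_mean_ratio,
                          fm_ratios, group_means, sexed_xa_test, xa_ratios)
from .differential import classify_degs, overlap_sets, sex_de_test
from .chrom_windows import cell_profile
from .lineage import lineage_pairs, lineage_xa_test, xist_compare
from .profiles_clustering import (heatmap_matrix, kmeans_trajectories,
                                  trajectory_matrix)
from .synthetic_data import (SimulationConfig, default_paper_profile,
                             generate_dataset, generate_lineage_dataset)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # exactly one of (annotation/matrix/samples paths) or simulate=True
    annotation: str | None = None
    matrix: str | None = None
    samples: str | None = None
    simulate: bool = False
    sim_overrides: dict = field(default_factory=dict)
    lineage_embryos: int = 0          # >0 adds a paired IT/TE simulation
    groups: tuple[str, ...] = GROUPS
    seed: int = 0
    min_fpkm: float = 1.0             # F:M ratio-distribution filter
    expressed_threshold: float = 0.1  # per-sample / per-group expression floor
    alpha: float = 0.05
    window_bp: int = 1_000_000
    smooth_k: int = 30
    k_clusters: int = 9
    exclude_xist: bool = False
    pseudocount: float = 0.0
    outdir: str = "xdosage_run"
    figures: bool = False

    def __post_init__(self):
        paths = all(p is not None for p in (self.annotation, self.matrix,
                                            self.samples))
        if paths == self.simulate:
            raise ValueError("provide either the three input paths or "
                             "simulate=True, not both")
        for name in ("min_fpkm", "expressed_threshold", "alpha", "window_bp",
                     "smooth_k", "k_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def config_hash(self) -> str:
        # identifies the analysis, not the run location
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("outdir", "figures")}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_or_simulate(config: RunConfig):
    if config.simulate:
        sim = default_paper_profile(seed=config.seed)
        if config.sim_overrides:
            sim = SimulationConfig(**{**sim.to_dict(), **config.sim_overrides,
                                      "seed": config.seed})
        dataset = generate_dataset(sim, groups=config.groups)
        lin = (generate_lineage_dataset(sim, config.lineage_embryos)
               if config.lineage_embryos else None)
        return dataset, lin
    dataset = validate_dataset(load_annotation(config.annotation),
                               load_expression(config.matrix),
                               load_samples(config.samples))
    has_split = dataset.samples["lineage"].isin(["IT", "TE"]).any()
    return dataset, (dataset if has_split else None)


def _round(obj, ndigits=6):
    if isinstance(obj, dict):
        return {str(k): _round(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else round(v, ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage the sample design supports; returns the output dir."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    params = {"config_hash": chash, "seed": config.seed}
    dataset, lineage_ds = _load_or_simulate(config)

    summary: dict = {"version": __version__, "config_hash": chash,
                     "seed": config.seed}
    incl_xist = not config.exclude_xist

    # --- QC ------------------------------------------------------------
    corr = sample_correlation(dataset.matrix)
    write_table(corr, out / "sample_correlation.tsv", params)
    markers = verify_sex_markers(dataset)
    write_table(markers, out / "sex_markers.tsv", params)
    summary["sex_marker_concordance"] = float(markers["concordant"].mean())
    if dataset.annotation["is_housekeeping"].any():
        write_table(housekeeping_variability(dataset),
                    out / "housekeeping_cv.tsv", params)

    # --- dosage --------------------------------------------------------
    means = group_means(dataset)
    ann = dataset.annotation
    x_index = dataset.genes_of_class(X_LINKED, include_xist=incl_xist)
    xa = xa_ratios(dataset, config.expressed_threshold,
                   include_xist=incl_xist)
    write_table(xa, out / "xa_summary.tsv", params)
    summary["expressed_x_counts"] = expressed_counts(
        means, ann, X_LINKED, config.expressed_threshold)

    sexed_groups = [g for g in config.groups
                    if ("female", g) in means.columns
                    and ("male", g) in means.columns]
    summary["fm_mean_ratio"] = {}
    summary["xa_ratio"] = {"male": {}, "female": {}}
    summary["fm_exceed_pct"] = {}
    summary["xdeg"] = {}
    fm_lists = {}
    for g in sexed_groups:
        fm = fm_ratios(means.loc[x_index], g, config.min_fpkm,
                       config.pseudocount)
        write_table(fm, out / f"fm_ratios_{g}.tsv", params)
        write_table(fm_histogram(fm), out / f"fm_histogram_{g}.tsv", params,
                    index=False)
        fm_lists[g] = fm.loc[fm["passes_min_fpkm"], "log2_fm"].dropna()
        summary["fm_mean_ratio"][g] = fm_mean_ratio(
            means, g, ann, X_LINKED, config.min_fpkm,
            include_xist=incl_xist)
        props = fm_exceed_proportions(fm)
        summary["fm_exceed_pct"][g] = {f"gt{int(k)}": 100.0 * v
                                       for k, v in props.items()}
        for sex in ("male", "female"):
            sids = dataset.samples_in(sex=sex, group=g)
            summary["xa_ratio"][sex][g] = float(
                xa.loc[sids, "xa_ratio"].mean())
        try:
            summary.setdefault("sexed_xa_p", {})[g] = sexed_xa_test(
                xa, dataset.samples, g)
        except Exception as exc:           # small designs lack the samples
            log.info("sexed X:A test skipped for %s: %s", g, exc)

        # differential expression
        n_f = len(dataset.samples_in(sex="female", group=g))
        n_m = len(dataset.samples_in(sex="male", group=g))
        if min(n_f, n_m) >= 2:
            degs = sex_de_test(dataset, g, config.alpha,
                               config.expressed_threshold)
            write_table(degs, out / f"degs_{g}.tsv", params)
            cls = classify_degs(degs)
            write_table(cls["xdeg"], out / f"xdegs_{g}.tsv", params)
            write_table(cls["adeg"], out / f"adegs_{g}.tsv", params)
            summary["xdeg"][g] = cls["counts"]

    # distribution comparisons between groups (on X-linked F:M ratios)
    comparisons = {}
    pairs = [(a, b) for i, a in enumerate(sexed_groups)
             for b in sexed_groups[i + 1:]]
    for a, b in pairs:
        c = compare_distributions(fm_lists[a], fm_lists[b])
        comparisons[f"{a}_vs_{b}"] = {"mw_p": c.mw_p, "ks_p": c.ks_p}
    summary["fm_distribution_tests"] = comparisons

    # xDEG overlap between embryo groups sharing a DE table
    deg_groups = [g for g in sexed_groups if g in summary["xdeg"]
                  and g != "DONOR"]
    if len(deg_groups) >= 2:
        a, b = deg_groups[:2]
        xa_ids = pd.read_csv(out / f"xdegs_{a}.tsv", sep="\t", comment="#",
                             index_col=0).index
        xb_ids = pd.read_csv(out / f"xdegs_{b}.tsv", sep="\t", comment="#",
                             index_col=0).index
        ov = overlap_sets(xa_ids, xb_ids)
        summary["xdeg_overlap"] = {k: ov[k] for k in
                                   ("only_a", "only_b", "both")}

    # --- chromosome windows -------------------------------------------
    ref_cell = ("male", "IVF")
    if len(dataset.samples_in(*ref_cell)) and len(ann) >= 10:
        win_frames = []
        for g in sexed_groups:
            prof = cell_profile(dataset, ("female", g), ref_cell,
                                config.window_bp, config.smooth_k)
            prof.insert(0, "cell", f"female:{g}")
            win_frames.append(prof)
        if win_frames:
            windows = pd.concat(win_frames, ignore_index=True)
            write_table(windows, out / "window_profiles.tsv", params,
                        index=False)
            xwin = windows[windows["chrom"] == "X"]
            summary["mean_smoothed_rel_x"] = {
                cell.split(":")[1]: float(sub["smoothed"].mean())
                for cell, sub in xwin.groupby("cell")}
            if config.figures:
                _render_profiles(windows, out / "window_profiles.png")

    # --- clustering ----------------------------------------------------
    stages = ("DONOR", "SCNT", "IVF")
    if all(("female", s) in means.columns for s in stages):
        hm = heatmap_matrix(dataset)
        write_table(hm, out / "heatmap_matrix.tsv", params)
        summary["cluster_frequencies"] = {}
        for sex in ("male", "female"):
            if not all((sex, s) in means.columns for s in stages):
                continue
            traj = trajectory_matrix(dataset, sex, stages)
            clusters = kmeans_trajectories(traj, config.k_clusters,
                                           seed=config.seed)
            tab = traj.copy()
            tab["cluster"] = clusters.labels
            write_table(tab, out / f"clusters_{sex}.tsv", params)
            summary["cluster_frequencies"][sex] = {
                int(k): int(v) for k, v in clusters.frequencies.items()}

    # --- lineage -------------------------------------------------------
    if lineage_ds is not None:
        pairs_df = lineage_pairs(lineage_ds, config.expressed_threshold)
        write_table(pairs_df, out / "lineage.tsv", params)
        xist = xist_compare(pairs_df)
        summary["lineage"] = {
            "n_pairs": len(pairs_df),
            "it_mean_x": float(pairs_df["it_mean_x"].mean()),
            "it_mean_x_sd": float(pairs_df["it_mean_x"].std(ddof=1)),
            "te_mean_x": float(pairs_df["te_mean_x"].mean()),
            "te_mean_x_sd": float(pairs_df["te_mean_x"].std(ddof=1)),
            "mean_it_te_ratio": float(pairs_df["it_te_ratio"].mean()),
            "it_xa": float(pairs_df["it_xa"].mean()),
            "te_xa": float(pairs_df["te_xa"].mean()),
            "xa_p": lineage_xa_test(pairs_df),
            "xist": {k: v for k, v in xist.items() if k != "skipped"},
        }

    (out / "summary.json").write_text(
        json.dumps(_round(summary), indent=2, sort_keys=True) + "\n")
    (out / "run.log").write_text(
        f"xdosage {__version__} config_hash={chash}\n"
        + json.dumps(_round(asdict(config)), indent=2, sort_keys=True) + "\n")
    return out


def _render_profiles(windows: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = ["1", "X"] if "X" in set(windows["chrom"]) else \
        sorted(set(windows["chrom"]))[:2]
    fig, axes = plt.subplots(1, len(chroms), figsize=(5 * len(chroms), 3),
                             sharey=True)
    for ax, chrom in zip(np.atleast_1d(axes), chroms):
        sub = windows[windows["chrom"] == chrom]
        for cell, grp in sub.groupby("cell"):
            ax.plot(grp["window_start"] / 1e6, grp["smoothed"], label=cell)
        ax.axhline(1.0, color="grey", lw=0.5)
        ax.set_title(f"chr{chrom}")
        ax.set_xlabel("position (Mb)")
    np.atleast_1d(axes)[0].set_ylabel("relative expression (smoothed)")
    np.atleast_1d(axes)[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def build_report(run_dir: str | Path) -> Path:
    """Render ``summary.json`` of a completed run as a markdown report,
    refusing to mix files from different config hashes."""
    run_dir = Path(run_dir)
    summary = json.loads((run_dir / "summary.json").read_text())
    chash = summary["config_hash"]
    for tsv in sorted(run_dir.glob("*.tsv")):
        first = tsv.open().readline()
        if f"config_hash={chash}" not in first:
            raise ValueError(f"{tsv.name} comes from a different run "
                             f"(expected config_hash={chash})")
    lines = [f"# xdosage report", "",
             f"version {summary['version']}, config hash `{chash}`, "
             f"seed {summary['seed']}", ""]
    for key in ("fm_mean_ratio", "xa_ratio", "fm_exceed_pct",
                "fm_distribution_tests", "xdeg", "xdeg_overlap",
                "expressed_x_counts", "lineage"):
        if key in summary:
            lines += [f"## {key}", "```json",
                      json.dumps(summary[key], indent=2, sort_keys=True),
                      "```", ""]
    path = run_dir / "report.md"
    path.write_text("\n".join(lines))
    return path
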