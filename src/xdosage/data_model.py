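"""Domain tables, file readers, dataset validation and transcriptome QC.

The package works on three pandas tables that together describe one
experiment:

* an **annotation** table (one row per gene: coordinates, chromosome class,
  marker/curated-set flags),
* an **expression matrix** (genes x samples, FPKM, dense and non-negative),
* a **sample sheet** (sex, embryo group, lineage and embryo pairing).

:func:`validate_dataset` intersects and orders the three consistently and is
the entry point every analysis module expects.  QC helpers mirror the checks
a sexed-blastocyst RNA-seq study needs before any dosage arithmetic:
replicate concordance (Pearson r on log FPKM), housekeeping-gene coefficient
of variation per replicate group, and sex verification from XIST and
Y-linked marker expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# chromosome classes
AUTOSOMAL = "autosomal"
X_LINKED = "x_linked"
Y_LINKED = "y_linked"
MITO = "mito"
UNMAPPED = "unmapped"

SEXES = ("male", "female")
GROUPS = ("IVF", "SCNT", "SHAM", "DONOR")
LINEAGES = ("WHOLE", "IT", "TE")

FEMALE_MARKERS = ("XIST",)
MALE_MARKERS = ("UTY", "DDX3Y", "EIF2S3Y")

# Pseudoautosomal genes shared by X and Y; bovine PAR boundaries are not
# well defined, so membership is carried as a symbol list.
DEFAULT_PAR_SYMBOLS = ("ZBED1", "CD99")

ANNOTATION_COLUMNS = ("symbol", "chrom", "start", "end", "strand",
                      "chrom_class", "is_par", "is_xist",
                      "is_testes_specific", "is_housekeeping")
SAMPLE_COLUMNS = ("sex", "group", "lineage", "embryo_id")


class DataError(ValueError):
    """Hard validation failure in an input table."""


def chrom_class(chrom: str) -> str:
    """Chromosome class as a pure function of the chromosome name.

    Autosomes are integer-named (with or without a ``chr`` prefix); ``X``,
    ``Y`` and ``MT``/``M`` map to their classes; anything else (unplaced
    scaffolds etc.) is ``unmapped`` and excluded from chromosome-level
    statistics.
    """
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    cu = c.upper()
    if cu == "X":
        return X_LINKED
    if cu == "Y":
        return Y_LINKED
    if cu in ("MT", "M"):
        return MITO
    try:
        int(c)
    except ValueError:
        return UNMAPPED
    return AUTOSOMAL


def normalize_chrom(chrom: str) -> str:
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper() if c.upper() in ("X", "Y", "MT", "M") else c


def _read_symbol_list(source) -> set[str]:
    if source is None:
        return set()
    if isinstance(source, (str, Path)) and Path(source).exists():
        lines = Path(source).read_text().splitlines()
        return {ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")}
    return {str(s).strip() for s in source}


def _finalize_annotation(df: pd.DataFrame,
                         par_list=None, testes_list=None,
                         housekeeping_list=None) -> pd.DataFrame:
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise DataError(f"duplicate gene_id in annotation: {dups[:5]}")
    bad = df.index[df["end"].astype(int) < df["start"].astype(int)]
    if len(bad):
        row = df.loc[bad[0]]
        raise DataError(f"end < start for gene {row['gene_id']} "
                        f"({row['start']}..{row['end']})")
    df = df.copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["strand"] = df["strand"].fillna("unknown").replace({".": "unknown"})
    df["chrom_class"] = df["chrom"].map(chrom_class)
    par = _read_symbol_list(par_list) or set(DEFAULT_PAR_SYMBOLS)
    testes = _read_symbol_list(testes_list)
    hk = _read_symbol_list(housekeeping_list)
    sym = df["symbol"].astype(str)
    df["is_par"] = sym.isin(par) & df["chrom_class"].isin([X_LINKED, Y_LINKED])
    df["is_xist"] = sym == "XIST"
    df["is_testes_specific"] = sym.isin(testes)
    df["is_housekeeping"] = sym.isin(hk)
    n_unmapped = int((df["chrom_class"] == UNMAPPED).sum())
    if n_unmapped:
        log.warning("%d genes on unplaced scaffolds flagged unmapped", n_unmapped)
    return df.set_index("gene_id")


def _load_annotation_gtf(path, **lists) -> pd.DataFrame:
    """Reduce a GTF/GFF to one record per gene spanning min(start)..max(end)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    names = {}
    for f in db.all_features():
        gid = (f.attributes.get("gene_id") or [f.id])[0]
        if gid not in names and "gene_name" in f.attributes:
            names[gid] = f.attributes["gene_name"][0]
    rows = []
    gene_feats = list(db.features_of_type("gene"))
    if gene_feats:
        for f in gene_feats:
            gid = (f.attributes.get("gene_id") or [f.id])[0]
            sym = names.get(gid, gid)
            rows.append((f.id, sym, f.seqid, f.start, f.end, f.strand or "unknown"))
    else:  # exon/transcript-only GTF: aggregate by gene_id attribute
        agg: dict[str, list] = {}
        for f in db.all_features():
            gid = f.attributes.get("gene_id", [None])[0]
            if gid is None:
                continue
            sym = (f.attributes.get("gene_name") or [gid])[0]
            rec = agg.setdefault(gid, [sym, f.seqid, f.start, f.end, f.strand])
            rec[2] = min(rec[2], f.start)
            rec[3] = max(rec[3], f.end)
        rows = [(gid, *rec[:5]) for gid, rec in agg.items()]
    df = pd.DataFrame(rows, columns=["gene_id", "symbol", "chrom",
                                     "start", "end", "strand"])
    return _finalize_annotation(df, **lists)


def load_annotation(path, par_list=None, testes_list=None,
                    housekeeping_list=None) -> pd.DataFrame:
    """Load a gene annotation table from TSV or GTF/GFF.

    TSV input needs columns ``gene_id symbol chrom start end strand``
    (1-based inclusive coordinates, GTF convention).  GTF/GFF input is
    reduced to gene level: one record per ``gene_id`` spanning the min/max
    of its features.  Derived columns (``chrom_class``, ``is_par``,
    ``is_xist``, curated-set flags) are populated from the optional symbol
    lists (file path with one symbol per line, or an iterable).
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff", ".gff3"):
        return _load_annotation_gtf(path, par_list=par_list,
                                    testes_list=testes_list,
                                    housekeeping_list=housekeeping_list)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"gene_id", "symbol", "chrom", "start", "end", "strand"} - set(df.columns)
    if missing:
        raise DataError(f"annotation is missing columns: {sorted(missing)}")
    return _finalize_annotation(df, par_list=par_list, testes_list=testes_list,
                                housekeeping_list=housekeeping_list)


def load_expression(path) -> pd.DataFrame:
    """Load a genes x samples FPKM matrix from TSV (first column gene ids)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
    cols = header.rstrip("\n").split("\t")[1:]
    if len(cols) != len(set(cols)):
        raise DataError("duplicated sample ids in expression header")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        raise DataError("duplicated gene ids in expression matrix")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise DataError(f"non-numeric expression value at gene "
                        f"{df.index[r]!r}, sample {df.columns[c]!r}")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().values)[0]
        raise DataError(f"missing expression value at gene "
                        f"{df.index[r]!r}, sample {df.columns[c]!r}")
    if (numeric.values < 0).any():
        r, c = np.argwhere(numeric.values < 0)[0]
        raise DataError(f"negative FPKM at gene {df.index[r]!r}, "
                        f"sample {df.columns[c]!r}")
    return numeric.astype(float)


def load_samples(path) -> pd.DataFrame:
    """Load and validate the sample sheet.

    Required columns: ``sample_id sex group``; ``lineage`` defaults to
    ``WHOLE`` and ``embryo_id`` to empty when absent.  Enumerations are
    case-insensitive.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = {"sample_id", "sex", "group"} - set(df.columns)
    if missing:
        raise DataError(f"sample sheet is missing columns: {sorted(missing)}")
    if "lineage" not in df.columns:
        df["lineage"] = "WHOLE"
    if "embryo_id" not in df.columns:
        df["embryo_id"] = ""
    df["lineage"] = df["lineage"].replace("", "WHOLE")
    df["sex"] = df["sex"].str.lower()
    df["group"] = df["group"].str.upper()
    df["lineage"] = df["lineage"].str.upper()
    for col, allowed in (("sex", SEXES), ("group", GROUPS), ("lineage", LINEAGES)):
        bad = sorted(set(df[col]) - set(allowed))
        if bad:
            raise DataError(f"unknown {col} value(s) {bad}; allowed: {allowed}")
    if df["sample_id"].duplicated().any():
        raise DataError("duplicate sample_id in sample sheet")
    return _validate_samples(df.set_index("sample_id")[list(SAMPLE_COLUMNS)])


def _validate_samples(df: pd.DataFrame) -> pd.DataFrame:
    split = df["lineage"].isin(["IT", "TE"])
    if (df.loc[split, "embryo_id"] == "").any():
        sid = df.index[split & (df["embryo_id"] == "")][0]
        raise DataError(f"sample {sid!r} has lineage IT/TE but empty embryo_id")
    dup = df.loc[split].groupby(["embryo_id", "lineage"]).size()
    if (dup > 1).any():
        eid, lin = dup.index[dup > 1][0]
        raise DataError(f"embryo {eid!r} has more than one {lin} sample")
    return df


@dataclass
class ValidatedDataset:
    """Consistently ordered annotation + expression matrix + sample sheet."""

    annotation: pd.DataFrame
    matrix: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.DataFrame | None = field(default=None, repr=False)

    def genes_of_class(self, cls: str, include_xist: bool = True,
                       include_par: bool = True) -> pd.Index:
        ann = self.annotation
        keep = ann["chrom_class"] == cls
        if not include_xist:
            keep &= ~ann["is_xist"]
        if not include_par:
            keep &= ~ann["is_par"]
        return ann.index[keep]

    def samples_in(self, sex: str | None = None, group: str | None = None,
                   lineage: str | None = None) -> pd.Index:
        s = self.samples
        keep = pd.Series(True, index=s.index)
        if sex is not None:
            keep &= s["sex"] == sex
        if group is not None:
            keep &= s["group"] == group
        if lineage is not None:
            keep &= s["lineage"] == lineage
        return s.index[keep]


def validate_dataset(annotation: pd.DataFrame, matrix: pd.DataFrame,
                     samples: pd.DataFrame) -> ValidatedDataset:
    """Intersect the three inputs, preserve matrix ordering, and check the
    dataset invariants (non-negative dense matrix, at least one autosomal and
    one X-linked gene).  Dropped ids are reported via logging."""
    genes = matrix.index[matrix.index.isin(annotation.index)]
    n_dropped_genes = matrix.shape[0] - len(genes)
    if n_dropped_genes:
        log.warning("dropping %d matrix genes absent from annotation",
                    n_dropped_genes)
    cols = matrix.columns[matrix.columns.isin(samples.index)]
    n_dropped_samples = matrix.shape[1] - len(cols)
    if n_dropped_samples:
        log.warning("dropping %d matrix samples absent from sample sheet",
                    n_dropped_samples)
    if len(genes) == 0 or len(cols) == 0:
        raise DataError("empty gene or sample intersection between inputs")
    mat = matrix.loc[genes, cols].astype(float)
    if mat.isna().any().any():
        raise DataError("expression matrix contains missing values")
    if (mat.values < 0).any():
        raise DataError("expression matrix contains negative values")
    mat.index.name = "gene_id"
    ann = annotation.loc[genes]
    ann.index.name = "gene_id"
    smp = _validate_samples(samples.loc[cols])
    smp.index.name = "sample_id"
    classes = set(ann["chrom_class"])
    if AUTOSOMAL not in classes or X_LINKED not in classes:
        raise DataError("dataset needs at least one autosomal and one "
                        "X-linked gene")
    return ValidatedDataset(annotation=ann, matrix=mat, samples=smp)


# ---------------------------------------------------------------------------
# QC

def sample_correlation(matrix: pd.DataFrame, log_transform: bool = True,
                       pseudocount: float = 1.0) -> pd.DataFrame:
    """Sample-by-sample Pearson correlation, by default on log2(FPKM+1).

    Symmetric with unit diagonal; zero-variance samples yield missing (NaN)
    correlations rather than an error.
    """
    if matrix.shape[1] < 2:
        raise DataError("need at least two samples for correlation")
    mat = np.log2(matrix + pseudocount) if log_transform else matrix
    corr = mat.corr(method="pearson")
    degenerate = mat.std(axis=0, ddof=0) == 0
    corr.loc[degenerate, :] = np.nan
    corr.loc[:, degenerate] = np.nan
    np.fill_diagonal(corr.values, np.where(degenerate, np.nan, 1.0))
    return corr


def housekeeping_variability(dataset: ValidatedDataset,
                             gene_list: Iterable[str] | None = None
                             ) -> pd.DataFrame:
    """Per-gene coefficient of variation (sd/mean of FPKM) within each
    (sex, group) replicate cell, for the housekeeping genes.

    ``gene_list`` holds gene symbols; when omitted the annotation's
    ``is_housekeeping`` flag is used.  Cells with mean 0 report NaN.
    """
    ann = dataset.annotation
    if gene_list is None:
        genes = ann.index[ann["is_housekeeping"]]
    else:
        symbols = _read_symbol_list(gene_list)
        genes = ann.index[ann["symbol"].isin(symbols) | ann.index.isin(symbols)]
    if len(genes) == 0:
        raise DataError("no housekeeping genes found in the dataset")
    out = {}
    for (sex, group), sub in dataset.samples.groupby(["sex", "group"], sort=True):
        vals = dataset.matrix.loc[genes, sub.index]
        mean = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        cv = sd / mean.where(mean > 0)
        out[f"{sex}:{group}"] = cv
    return pd.DataFrame(out)


def verify_sex_markers(dataset: ValidatedDataset,
                       female_markers: Sequence[str] = FEMALE_MARKERS,
                       male_markers: Sequence[str] = MALE_MARKERS,
                       min_fpkm: float = 1.0) -> pd.DataFrame:
    """Predict each sample's sex from marker expression and compare it with
    the sample sheet.

    A sample is called female when any female marker (XIST) is at or above
    ``min_fpkm`` and every male marker (UTY, DDX3Y, EIF2S3Y) is below it;
    male in the converse case; ambiguous otherwise.  Ambiguity is a value,
    not an error.
    """
    ann = dataset.annotation
    f_genes = ann.index[ann["symbol"].isin(set(female_markers))]
    m_genes = ann.index[ann["symbol"].isin(set(male_markers))]
    if len(f_genes) == 0 and len(m_genes) == 0:
        raise DataError("none of the sex-marker genes are present in the matrix")
    f_on = (dataset.matrix.loc[f_genes] >= min_fpkm).any(axis=0) \
        if len(f_genes) else pd.Series(False, index=dataset.matrix.columns)
    m_on = (dataset.matrix.loc[m_genes] >= min_fpkm).any(axis=0) \
        if len(m_genes) else pd.Series(False, index=dataset.matrix.columns)
    predicted = pd.Series("ambiguous", index=dataset.matrix.columns,
                          name="predicted_sex")
    predicted[f_on & ~m_on] = "female"
    predicted[m_on & ~f_on] = "male"
    out = predicted.to_frame()
    out["sheet_sex"] = dataset.samples["sex"]
    out["concordant"] = out["predicted_sex"] == out["sheet_sex"]
    return out
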