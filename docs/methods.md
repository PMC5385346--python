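# Methods

## The analysis

`xdosage` quantifies X-chromosome dosage in sexed bulk transcriptomes of
preimplantation embryos (and the somatic donor cells used for nuclear
transfer).  The biological question is whether female embryos carry two
active X chromosomes (X-chromosome reactivation, XCR) or one (X-chromosome
inactivation, XCI), and how completely cloned (SCNT) embryos re-activate
the somatic X.  All statistics operate on a gene-level FPKM matrix taken as
already normalized; no re-normalization or batch correction is applied.

The headline quantities are:

* **F:M ratio** — per gene, the female group-mean FPKM over the male
  group-mean within one embryo group.  Ratio-distribution statistics use
  only genes whose larger sex mean exceeds `min_fpkm` (default 1.0 FPKM)
  and whose both means are positive; an optional pseudocount mode keeps all
  genes.  The **aggregate** F:M fold of a gene class is the ratio of
  aggregate means (mean of female means over mean of male means across
  qualifying genes), not the mean of per-gene ratios, which is unstable
  under small denominators.  Both modes exist; aggregate is the default.
* **X:A ratio** — per sample, mean FPKM over X-linked genes expressed in
  that sample divided by the mean over expressed autosomal genes
  (`expressed_min_fpkm`, default 0.1 FPKM, applied per sample).  With one
  active X against biallelic autosomes the expectation is ~0.5; with two
  active X, ~1.0.
* **Window profiles** — each chromosome is tiled with 1-Mb windows; the
  per-window sum of cell-mean FPKM is divided by the male-IVF reference and
  smoothed with a centered 30-window moving average that shrinks at
  chromosome edges and skips missing windows.  Genes map to exactly one
  window by start coordinate (internally 0-based half-open), so window sums
  conserve per-chromosome totals.
* **Sex-differential expression** — per gene within a group, a two-sided
  Welch t-test on log2(FPKM+1) over genes with mean FPKM > 0.1 in at least
  one sex; unadjusted p < 0.05 defines xDEGs (X-linked) and aDEGs
  (autosomal), mirroring how such embryo studies are usually reported.  A
  rank-sum alternative and Benjamini–Hochberg adjustment are flags.
* **Lineage comparison** — blastocysts dissected into an IT half (inner
  cell mass plus adhering trophectoderm, ~1:1 by cell count) and a TE-only
  half give a paired test of imprinted paternal-X inactivation.  Paired
  Wilcoxon signed-rank tests are used throughout this module because the
  design is genuinely paired; XIST is compared at α = 0.01 on the matrix's
  expression units.
* **Distribution comparisons** — two-sided Mann–Whitney U and two-sample
  Kolmogorov–Smirnov tests on ratio lists, exact for small samples without
  ties.  The male-vs-female X:A comparison defaults to the unpaired
  rank-sum test, since whole blastocysts of opposite sex are independent; a
  signed-rank mode exists for genuinely paired designs.

Choices the definitions leave open were fixed as follows: gene→window
assignment by start coordinate (alternatives such as midpoint or
overlap-weighting change little and break conservation); centered moving
average with edge shrinkage; average-linkage Euclidean hierarchical
clustering with rows canonically sorted by gene id before linkage so heatmap
ordering is independent of input row order; k-means with k-means++ seeding,
10 restarts and a fixed seed; expression-category boundaries closed on the
lower category (FPKM < 0.1 none-to-weak, 0.1–0.5 inclusive weak-to-moderate,
> 0.5 moderate-to-high); XIST included in X-linked aggregates by default
(`--exclude-xist` exists because XIST is female-specific and materially
female-biased); PAR genes counted as X-linked, with an exclusion flag;
genes on unplaced scaffolds excluded from chromosome-level statistics but
kept for whole-transcriptome QC.  Zero handling: a gene with a zero sex
mean has an undefined log ratio and is dropped from ratio statistics unless
the pseudocount mode is on; windows with a zero reference are missing, not
infinite; p = 0 is clipped to the smallest positive float for volcano
coordinates.

## The synthetic-data generator

No public raw data accompanies this study design, so `synthetic_data`
generates datasets with the statistical structure the analysis assumes, and
the package's main self-test is recovering the configured effects
downstream.  Per dataset: gene baselines are log-normal (log2 mean 2.0, sd
2.0 — a realistic bulk-RNA-seq dynamic range) and shared across samples;
each sample multiplies them by log-normal biological noise (log2 sd 0.35);
measurements in the bottom expression quintile drop out independently with
probability 0.05, mimicking low-input library sparsity.  12 000 autosomal
genes on 29 autosomes, 700 X-linked and 30 Y-linked genes are placed
uniformly at random (real coordinates are irrelevant to the statistics
recovered).  XIST (60 FPKM) is female-specific; Y genes, including the
markers UTY/DDX3Y/EIF2S3Y, are male-specific; 29 testes-specific X genes
are weakly expressed (log2 mean −2.5, sd 1.5) and de-repressed 4-fold in
female blastocysts; ten housekeeping symbols are flagged for QC.  Six
samples per sex per group reproduce the study layout.

Male X genes are scaled by a baseline factor; in females, a group-specific
fraction of X genes ("responders") carries an extra fold whose per-gene
mean is set so the group's aggregate F:M fold matches the configured
target, with a log-normal gene-to-gene spread (bias-corrected so the
aggregate is preserved).  Only a fraction responds because a single uniform
fold cannot match the aggregate fold and the proportions of genes with
F:M > 1 and > 2 simultaneously.  Responder quantiles are shared across
groups, so responder sets nest (donor ⊂ SCNT ⊂ IVF), reproducing the
observed overlap of female-biased genes between embryo groups and the
donor → SCNT → IVF "in-between" trajectory of cloned embryos.

Responder labels and effect z-scores are assigned by *balanced* sampling
along the baseline-expression ranking (within consecutive blocks of 20
genes in expression order, quantile slots are allocated exactly once each,
in random order).  Marginally every gene is an iid draw; jointly, the
high-expression genes that dominate aggregate statistics realise the
configured responder fraction almost exactly, so each replicate carries the
configured study condition instead of a noisy binomial realisation of it —
standard variance control in simulation design.

Paired lineage datasets draw one expression state per embryo (female-IVF
factors, biological noise) and add independent log-normal measurement noise
(log2 sd 0.2) per half.  The TE half scales X genes by `te_x_factor` (1.0
default = no imprinting; 0.5 = fully silenced paternal X) and the IT half,
an ICM/TE mixture, by `icm_fraction + (1 − icm_fraction)·te_x_factor`, so
full TE imprinting at a 1:1 mixture predicts an IT/TE ratio near 1.5, not
2 — the dilution that makes the negative-control logic honest.  The tests
verify the detector fires under simulated imprinting, so the null finding
is informative.

### Calibration of the bundled profile

`default_paper_profile()` targets the published effect sizes: aggregate F:M
folds 1.8 (IVF), 1.5 (SCNT), 1.9 (sham), 1.0 (donor); male X:A ≈ 0.49 and
female X:A ≈ 1.01 (IVF) / 0.80 (SCNT); F:M > 1 proportions
78.7/66.7/78.1/51.2% and F:M > 2 proportions led by 46.7% (IVF).  These
targets are mutually inconsistent under any uniform dosage model: the X:A
pair implies a ~2.06-fold female effect while the filtered F:M aggregate
implies 1.8.  The profile therefore carries two jointly fitted constants —
a male X baseline factor (0.541) and a gain of 1.11 on the excess female
effect (effective fold target `1 + (U − 1)·1.11`, null-safe at U = 1) —
chosen so every recovered statistic sits inside its published band rather
than centering one statistic and saturating another.  Responder fractions
(0.52/0.32/0.58/0) and fold spreads (log2 sd 0.45/0.12/0.80/0) were fitted
to the F:M > 1 and > 2 proportions.  Calibration constants are data,
documented here and versioned with the package; the fitting used 25
replicate simulations per condition against the published values only.

At these defaults, 25-replicate recovery gives F:M 1.91/1.59/2.02, X:A
0.537 (male) / 0.990 (female IVF) / 0.829 (female SCNT), F:M > 1
78.6/68.5/77.9/50.0%, F:M > 2 45.5% (IVF), and IT-part X:A 0.991 with a
non-significant paired IT/TE test in every replicate — each within the
tolerance its acceptance check states.  The published dispersions (error
bars across embryos) are not numerically reported, so noise magnitudes are
chosen, not extracted.

### What the generator does not emulate

Gene-length and GC biases, count discreteness at low expression, isoform
structure, real genomic gene density (placement is uniform), correlated
expression modules, embryo-quality covariates, and any allele-specific
signal.  Passing recovery tests therefore shows the *pipeline arithmetic
and inference* behave as specified under realistic magnitudes — not that
the published biological values would be reproduced from the real raw data,
which has no stated accession.  Per-gene DEG counts, expressed-gene counts
and real-data p-values depend on the unreleased data and an unstated DE
engine and are deliberately not recovery targets.

## Null calibration

"No-effect" configurations set every fold to 1.0, including the testes
de-repression, and silence XIST (XIST is genuinely female-specific, so a
null dataset must drop it for male/female exchangeability).  Over 200
replicates the sexed X:A rank test rejects at ~0.045 and the per-gene Welch
test flags ~4.3% of autosomal genes at α = 0.05, both within the 0.02–0.09
calibration band.

## Problem sizes and determinism

Recovery checks use 25 replicate simulations at the full default sizes
(12 730 genes, 12 samples per group; 19 embryos × 2 halves for lineage);
type-I calibration uses 200 replicates at one-quarter gene counts, and
module-level simulation tests use ~15% gene counts — sizes at which every
assertion is stable over reruns.  All randomness flows from integer seeds
through `numpy.random.default_rng`; each (group, sex) cell uses its own
seed-derived stream, so generating a subset of groups reproduces the
corresponding cells of a full run bit for bit, and repeated pipeline runs
with one seed are byte-identical.

## Known limitations

FPKM is taken at face value (no TPM conversion, no length-bias modelling);
the Welch test on n = 6 per sex has limited power for subtle autosomal
effects; unadjusted p < 0.05 DEG lists are descriptive, not
FDR-controlled; PAR handling is list-based because bovine PAR boundaries
are not well established; and the hierarchical/k-means summaries are
descriptive visual orderings, not inferential claims.
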