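# Methods

`scprot` implements the post-search quantitation and analysis procedure for
label-free single-cell DIA proteomics: starting from a long-format precursor
identification/intensity report, it produces filtered, imputed,
MaxLFQ-summarized, batch-corrected, histone-normalized protein matrices,
iBAQ abundance ranks, GO-term rollups, and a PCA with PC–phenotype
correlation. This note documents the models, the defaults and why they were
chosen, the synthetic data the tests rely on, and the known limitations.

## Filtering cascade

Records flow through six stages in a fixed order; a `FilterReport` logs
in/out counts at each so the manifest reconciles exactly with the input.

1. **q-value** — keep records with q-value strictly below the threshold
   (default 0.01). The boundary is exclusive: q = 0.01 is removed.
2. **Species unambiguity** — a record is kept only if *every* accession of
   its protein group is the target organism (default *Homo sapiens*).
   Peptides shared between a human and a bovine protein (serum carry-over)
   cannot be attributed and are removed wholesale. The check uses the
   protein-group annotations of the export rather than remapping peptides
   to proteomes; this matches the granularity of the input but cannot
   rescue a peptide that the search engine grouped too broadly.
3. **Keratin removal** — a record is removed if *any* group member's gene
   matches `^KRT[0-9]+` (case-insensitive). Keratin-associated proteins
   (`KRTAP*`) are deliberately excluded from the pattern: they are distinct
   gene products, not the dust/skin contaminant class. The rule is
   overridable with an explicit gene list.
4. **Matrix construction** — records pivot to a precursor × cell matrix of
   log2 intensities with explicit missingness. Duplicate
   (precursor, run) pairs are an integrity error by default
   (`on_duplicate="max"` resolves them by the larger intensity).
5. **Per-cell minimum** — cells identifying fewer than `min_precursors`
   (default 500, strict `<`) precursors are dropped. Counts are taken
   *after* the record-level filters, i.e. contaminants do not help a cell
   pass QC.
6. **Coverage** — precursors observed in fewer than `min_coverage`
   (default 50 %) of the *remaining* cells are dropped before imputation.
   The boundary is inclusive: exactly-50 % coverage is retained, reading
   "< 50 % removed" literally. The denominator is the post-QC cell count
   (the pipeline order implies it; an all-cells denominator would make the
   coverage filter depend on cells that no longer exist downstream).

## Relative scale and imputation

Each precursor row is centred by subtracting the median of its observed
values (median 0 per row afterwards; idempotent). Centring happens at the
**precursor** level: at this point of the pipeline precursor rows are the
only rows in existence, and the subsequent imputation initialises missing
entries at 0, which only makes sense on centred data. A
`center_level="protein"` option applies a second centring after
summarization instead.

Missing entries are filled by iterative truncated-SVD reconstruction
(svdImpute): initialise missing entries to 0, take the rank-*k* SVD of the
current matrix, overwrite *only* the missing entries with the rank-*k*
reconstruction, and repeat until the relative change of the imputed entries
(`‖Δimputed‖₂/‖imputed‖₂`) falls below `tol`. Observed entries are never
modified. Defaults: `k = 5`, `tol = 1e-2`, `max_iter = 100` — standard
practice for this imputation family; all exposed in the config.
Non-convergence returns the current matrix with a flag and a warning.

## MaxLFQ summarization

For one protein group with precursor log2 matrix `x` (precursor × cell):

* for every cell pair (a, b) with at least `min_shared` (default 1)
  precursors observed in both, the protein ratio is
  `r_ab = median_j (x_jb − x_ja)`;
* the per-cell abundances `w` minimise `Σ (w_b − w_a − r_ab)²` over all
  defined pairs, solved by least squares independently on each connected
  component of the cell-pair graph;
* the additive gauge freedom of each component is fixed by anchoring the
  mean of its estimates to the mean of all observed precursor values in its
  cells; cells with no observations stay missing.

With a single precursor this reduces to the precursor profile itself; the
estimator is shift-equivariant and invariant (in between-cell differences)
to per-precursor offsets. The "large-ratio stabilization" and
sample-normalization extras of the original label-free method are out of
scope — this is the pairwise-median/least-squares core. After imputation
the matrix is complete and every component spans all cells; the solver
still handles missing values so it can be used pre-imputation.

## Batch correction

Chip-to-chip (batch) effects are removed with a parametric empirical-Bayes
location/scale adjustment. Per protein *g*: batch means are fitted by least
squares, the grand effect `α_g` is the batch-size-weighted mean, the pooled
variance `σ²_g` is the mean squared residual from the batch means, and the
standardized data `z = (x − α_g)/σ_g` yield per-batch location `γ̂_gk` and
scale `δ̂²_gk` estimates. Normal (location) and inverse-gamma (scale)
priors per batch are moment-matched across proteins, and the posterior
`(γ*, δ*²)` is found by the standard closed-form iteration. Adjusted
values are `(z − γ*)/δ* · σ_g + α_g`. Parametric priors are the default of
the cited method family; a non-parametric mode is not provided.

Two deliberate details:

* a variance floor of 1e-8 guards zero-variance proteins (possible after
  imputation);
* after adjustment every protein row is re-centred exactly on its original
  grand mean. The reference implementation preserves the grand mean only
  approximately; making it exact is a no-cost invariant that downstream
  stages can rely on. A test cross-checks the implementation against
  Bioconductor `sva::ComBat` through `Rscript` on a small matrix; after
  row-centring both outputs agree to ~1e-8, confirming the re-centring is
  the only difference.

A single batch returns the input unchanged (bit-identical) with a warning;
a batch with fewer than two cells is a parameter error.

## Histone normalization

Histone abundance tracks chromatin content (ploidy), not cytoplasmic
volume, which makes the histone level a per-cell reference. For each cell
the median relative abundance over histone-flagged proteins is subtracted
from all proteins of that cell; afterwards the per-cell histone median is
exactly 0, and the operation is idempotent and shift-equivariant. Histone
genes default to the shipped list of HGNC cluster symbols (plus a pattern
fallback covering legacy `HIST*` aliases); at least 3 histone proteins
(configurable) must be present, otherwise the stage fails listing what was
detected. The stage runs **after** batch correction.

## iBAQ

Intensity-based absolute quantification uses the **pre-normalization
linear** intensities of the post-QC matrix: per protein group and cell, the
summed observed precursor intensity divided by the number of theoretically
observable tryptic peptides of the group's lead accession (first accession
of the group — deterministic; a longest-sequence option was considered and
rejected as needlessly surprising). Digestion cleaves C-terminal of K/R;
defaults are zero missed cleavages and no proline rule, because the method
definition constrains only the peptide length window, 6–50 residues. Both
are exposed as flags. The summary statistic is the median over cells of
log10(iBAQ); the table can be restricted to the top-N most abundant
proteins observed in more than half of the cells (N = 500 by default).

## GO rollup, PCA, eigencor

**Rollup.** Per gene set: the member protein with the most observed values
is the reference (ties: higher median abundance, then lexicographic
accession — the chain is not standardised anywhere, so it is fixed here
deterministically); every other member is shifted by the median difference
to the reference over shared cells; the term profile is the per-cell median
of the shifted members. Terms mapping to fewer than `min_members`
(default 3) proteins are dropped. Annotation comes from a static GMT file —
live annotation services are replaced to keep runs hermetic.

**PCA.** Cells are observations, proteins (or terms) variables; centred,
unscaled by default (the matrix is already relative log2 abundance on a
shared scale; `--scale` is available). Computed by SVD with a deterministic
sign convention: the largest-|loading| element of each component is made
positive. Explained variance fractions are `s_i²/Σs²`; singular values at
the level of the floating-point residue of the input are treated as zero so
that degenerate (no-variation) data reports zero explained variance rather
than normalising noise.

**Eigencor.** Pearson correlation of the first `n_components` (default 10)
score vectors with each numeric phenotype variable (cell diameter by
default), two-sided t-test p-values (n − 2 df), Benjamini–Hochberg
correction across the whole component × variable grid (the multiplicity
procedure is a package choice; α = 0.05 default). Constant variables
report a missing correlation with a warning.

## Synthetic data generator

The generator emulates the statistical structure of a nanowell-chip
single-cell DIA experiment with known ground truth; every downstream stage
has a recovery test against the realized truth record.

True log2 intensity of precursor *j* (protein *p*) in cell *c*:

    x_jc = α_p + β_j + s·(log2 d_c − mean log2 d) + ν_c + m_{t(p),c}
           + b_{chip(c)} + λ_{chip(c)}·ε,   ε ~ N(0, noise_sd)

with protein base abundances `α_p ~ N(14, 2)` (log2 of linear intensity),
precursor offsets `β_j ~ N(0, 1)`, diameters `d_c` uniform on 17–36 µm
(the sorting gate), size coefficient `s` (default 1), per-cell nuisance
`ν_c` (default off), module effects `m` for disjoint blocks of proteins
sharing a gene set (10 modules × 12 proteins, sd 0.5), and per-chip
additive shift `b` (sd 0.5) and noise scale `λ`. Observation is the product
of an MNAR channel — Bernoulli with logistic probability
`σ(slope·(x − midpoint))`, slope 0 meaning always observed — and an MCAR
channel (rate 3 %). A configurable fraction (5 %) of precursors belongs to
contaminant proteins, alternating bovine entries and human keratins; half
of the bovine precursors are emitted as ambiguous human+bovine groups.
q-values exceed 0.01 for a configurable 5 % of records. Protein sequences
are random, built from unique tryptic fragments of 6–30 residues so the
iBAQ denominator is exact by construction.

**Histones and the size term.** Histone proteins do *not* receive the
diameter term (configurable via `histones_track_size`): chromatin scales
with ploidy, not cell volume, and that distinction is precisely what makes
histone normalization compatible with a diameter-linked first principal
component. The normalization stage is instead tested by injecting the
shared per-cell nuisance `ν_c` — which histones do carry — and checking
that the recovered factors track it (r > 0.99). Histones are drawn 2 log2
units more abundant than average, reflecting their real abundance and
guaranteeing they survive the coverage filter.

**Study-scale defaults** (`default_study_scale`): 48 cells on two chips of
24, ~1100 proteins at ~3.2 precursors each, MNAR midpoint 13 and slope 0.6
with 3 % MCAR. Under these conditions a run yields roughly 1.9 k
identified precursors and 0.9 k proteins per cell after filtering, with
~60 % of precursors at ≥50 % coverage — the same order of magnitude as a
real single-cell DIA experiment of this design, which is what the defaults
are calibrated to represent (not an exact reproduction of any particular
dataset). The number of chips for a 48-cell experiment is not dictated by
the chip format; two chips of 24 keep the batch-correction path exercised
by default.

What the generator does **not** emulate: retention-time structure, spectral
interference, ionization competition, match-between-runs effects,
doublets/image QC, correlated (protein-complex) noise beyond the block
modules, and any non-logistic missingness. Passing recovery tests
therefore show algorithmic correctness under the stated model, not
robustness to every artefact of real data.

## Numerical choices and degenerate inputs

* Medians are interpolating (`numpy` convention) for even counts.
* `svd_impute` requires every row and column to have an observed value and
  `k < min(rows, cols)`; the coverage filter guarantees the former in the
  pipeline.
* MaxLFQ anchors per connected component; isolated cells with observations
  get their mean observed value, cells without observations stay missing.
* ComBat symmetry: relabelling batches permutes internal order only; the
  corrected matrix is identical.
* All-missing rows are rejected by `median_center_rows` (the coverage
  filter prevents them upstream).
* Zero intensity parses as missing; negative intensity is a format error
  naming the row.
* The whole pipeline is deterministic given the config; the only stochastic
  component is the generator, governed by a single seed.

## Problem sizes

Unit tests run on matrices of tens of rows; the end-to-end recovery tests
use the study-scale generator (48 cells, ~3.5 k precursors), which runs the
full pipeline in a few seconds. The acceptance script performs two such
runs plus kernel-oracle sweeps (100 random MaxLFQ instances, 100 random
digests) in well under a minute. These sizes were chosen so that the full
validation cycle is quick enough to run on every change while still
exercising the pipeline at the scale of a real chip experiment.

## Known limitations

* Species filtering trusts the export's protein-group organism labels.
* Only parametric empirical-Bayes priors are implemented for batch
  correction (no non-parametric mode, reference batch, or covariates).
* iBAQ digests the lead accession only; isoform-aware digestion is not
  attempted.
* The GO rollup consumes one static GMT; namespace filtering (e.g.
  restricting to biological-process terms) is expected to happen upstream
  when the GMT is prepared.
* PCA is unscaled by default; variables with inflated residual variance
  weigh correspondingly more.
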