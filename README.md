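# scprot

Post-search quantitation and analysis pipeline for **label-free single-cell
DIA proteomics**. Starting from a long-format precursor report (one row per
precursor × run, as exported by a DIA search engine), `scprot` produces the
analysis-ready protein matrices and summaries a single-cell proteomics
study needs:

* a six-stage filtering cascade (q-value, species unambiguity, keratin
  contaminants, per-cell identification minimum, precursor coverage) with
  fully reconciled stage counts;
* median-relative scaling and iterative-SVD imputation of the precursor
  matrix;
* MaxLFQ protein summarization — per protein group, per-cell abundances
  `w` minimise `Σ_(a,b) (w_b − w_a − r_ab)²` where
  `r_ab = median_j (x_jb − x_ja)` over precursors shared by cells a and b;
* empirical-Bayes (ComBat-style) location/scale batch correction across
  nanowell chips, followed by histone-median per-cell normalization;
* iBAQ absolute abundance — summed precursor intensity divided by the
  number of theoretically observable tryptic peptides (6–50 residues) —
  with abundance ranks;
* GO-term rollup (reference-based member alignment, median summary), PCA
  with deterministic sign convention, and Pearson correlation of PC scores
  with cell phenotype (diameter), BH-corrected.

Because real single-cell raw data require an instrument and a commercial
search engine, the package ships a first-class **synthetic data generator**
that emulates the statistical structure of a chip-based single-cell DIA
experiment (cell-size scaling, chip batch effects, gene-module covariation,
MNAR + MCAR missingness, bovine/keratin contaminants) with a complete
ground-truth record, so that every stage has a recovery test.

It is aimed at proteomics researchers and method developers who want a
tested, scriptable reference implementation of this processing chain.

## Worked example

Simulate a 48-cell experiment (two chips of 24) and run the full pipeline:

```bash
$ scprot simulate --outdir demo/data --seed 7
wrote 99871 records for 48 cells
  report: demo/data/precursor_report.tsv
  fasta: demo/data/proteins.fasta
  metadata: demo/data/cells.tsv
  gmt: demo/data/genesets.gmt
  truth: demo/data/truth.json

$ scprot run-all --report demo/data/precursor_report.tsv \
    --fasta demo/data/proteins.fasta --metadata demo/data/cells.tsv \
    --gmt demo/data/genesets.gmt --outdir demo/run
pipeline complete: 820 proteins x 48 cells -> demo/run
  PC1 ~ diameter_um: r=0.942 p_bh=1.81e-22 *
  PC10 ~ diameter_um: r=-0.112 p_bh=8.80e-01
  PC6 ~ diameter_um: r=-0.105 p_bh=8.80e-01
```

The ~100 k simulated precursor records reduce to 820 quantified protein
groups across 48 cells. The first principal component of the corrected
protein matrix correlates with cell diameter at r = 0.94
(Benjamini–Hochberg p ≈ 2e-22) — the generator plants a unit cell-size
coefficient, and the pipeline recovers that size axis as PC1; the remaining
components show no diameter association, as they should. `demo/run/`
contains the precursor and protein matrices (TSV, log2), the
batch-corrected/normalized matrix, the iBAQ table, the GO-term matrix, the
eigencor table, PCA scores/loadings (JSON), and a manifest with the exact
record counts of every filtering stage.

The same stages are available individually (`scprot filter`, `quantify`,
`normalize`, `analyze`) and as library functions:

```python
import scprot

ds = scprot.simulate_dataset(scprot.default_study_scale(seed=7))
result = scprot.run_pipeline(ds.records, ds.annotations, ds.metadata,
                             ds.genesets, scprot.PipelineConfig())
result.eigencor.table.head()
```

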