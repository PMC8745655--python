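# mirsig

A tested, reusable pipeline for miRNA drug-resistance expression profiling:

- **normalization** — across-sample quantile normalization and per-feature
  median-polish summarization of probe-level log2 intensities (the RMA
  numerical core; an optional simplified background floor-shift is provided).
- **diffexpr** — per-contrast differential expression: pooled two-sample
  effects, an empirical-Bayes moderated t-statistic (prior df and prior
  variance estimated by digamma/trigamma moment matching), Benjamini–Hochberg
  FDR adjustment, and signed fold-change conversion (down-regulation reported
  as −1/ratio).
- **selection** — per-line directional calls (|fold| > 5 and adjusted
  p < 0.05 by default) and the two-tier resistance-signature rule:
  a miRNA is retained when it changes significantly more than 5-fold in
  *both* cell lines resistant to the same drug, or at least 10-fold in any
  single resistant line. Classification (up-only / down-only / mixed),
  per-line change counts and per-drug up/down signatures are derived from
  the call table.
- **integration** — aggregation of miRNA→gene target edges from multiple
  databases (union with per-edge provenance and a validated flag), retention
  of miRNA–target pairs whose signed folds are inverse and both pass the
  cut-offs within one cell line, GO-keyword subsetting of target genes, and
  network export (SIF / GraphML / round-trippable TSV).
- **synthetic** — simulation of the full experiment (5 groups × 4
  replicates, planted signed folds, Gaussian log2 noise) together with
  matching target edges, inverse-regulated mRNA folds, GO labels and decoy
  edges, plus recovery metrics against the known ground truth.
- **io / pipeline / cli** — TSV/CSV readers and writers for every
  interchange format, the packaged 46-miRNA fold/adjusted-p fixture
  (checksum-guarded), YAML-configurable orchestration and a `mirsig` CLI.

## CLI

```sh
mirsig fixtures table1                 # show the packaged 46-miRNA table
mirsig select --fixture --out sel.tsv  # two-tier selection + JSON summary
mirsig simulate --outdir sim --seed 1  # synthetic experiment + resources
mirsig de sim/expression.tsv de-out    # all resistant-vs-reference contrasts
mirsig select de-out/fold_table.tsv --out sel.tsv
mirsig integrate --mir-de mir.tsv --gene-de sim/mrna_de.tsv \
    --targets TargetScan=edges.tsv --go sim/go.tsv --outdir net
mirsig run config.yaml                 # full pipeline from a YAML config
```

Thresholds are configurable everywhere (`--fold-cut`, `--fold-cut-single`,
`--alpha`); fold comparisons are strict (`> 5`), the single-line tier uses
`>= 10`, and significance is strict (`< 0.05`). The applied thresholds are
recorded in the pipeline log.

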