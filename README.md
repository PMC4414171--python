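# epcat

Discovery of unannotated, disease-associated transcript loci from
multi-cohort expression matrices, plus the downstream evaluation stages:

- **copa_outlier** — median/MAD outlier transform of log2 expression rows,
  one-sided outlier calling with a `2·MAD/0.6745` threshold, and the
  feature-level filters (unannotated, no control outliers, ≥ 5% cancer
  outliers).
- **epcat_grouping** — strand-aware grouping of retained features into
  candidate loci (< 250 kb gaps, Spearman ρ ≥ 0.5 between outlier
  profiles), reconciliation of loci across ≥ 2 cohorts, ≥ 12-probe
  filtering, deterministic naming (`EPCAT{chrom}{F|R}{ordinal}`) and
  positional classification against gene annotation.
- **regulation** — Welch's t-test treatment screens with
  Benjamini–Hochberg correction and fold-change calls, driver
  coexpression, and ChIP-seq peak support with 50 kb flanks.
- **prognosis** — exact k=2 medoid dichotomization, a 10,000-iteration
  label-permutation association test, BH correction, and
  Kaplan–Meier/log-rank analysis.
- **diagnostics** — Mann–Whitney empirical AUC, multi-start
  derivative-free AUC maximization for linear marker panels, binary
  staining-score panels, Fisher's exact test and positivity-rate
  bookkeeping.
- **conservation** — 50 bp windowed conservation scoring of exon
  sequence and rank-sum comparisons against coding/repeat controls.
- **synthetic_data** — seeded simulators for expression cohorts with
  implanted outlier loci, annotation, clinical follow-up, peaks and
  conservation tracks, so every stage is testable against ground truth.
- **cli_io** — TSV/BED/bedGraph readers and writers, pipeline
  configuration and the command-line interface.

## CLI

```bash
# write a synthetic multi-cohort fixture with known ground truth
epcat simulate --out demo --seed 1

# full discovery (outliers -> grouping -> reconciliation -> naming -> classes)
epcat discover --in demo --out results

# per-dataset outlier tables only
epcat discover --in demo --out results --stage outliers

# every stage enabled by the available inputs
epcat run-all --in demo --out results --seed 1
```

`regulate`, `prognose`, `diagnose` and `conserve` run individual stages.
Stage parameters (gap, correlation, probe and flank thresholds, permutation
count, …) can be overridden with a YAML file passed via `--config`; the
defaults are the published analysis constants.

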