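# tsnetwork

Tissue-specific coexpression network analysis. From a multi-tissue
expression matrix, the package:

1. **preprocess** — reads a gene/transcript × sample TSV, scales every array
   to a common median, collapses transcripts to genes (smallest CDS-covering
   transcript kept), and averages replicates into per-tissue profiles;
2. **specificity** — scores each gene with the tissue-specificity index
   `TSI = Σ(1 − exp_i / exp_max) / (n − 1)` (0 = housekeeping,
   1 = single-tissue), assigns the maximum-expression tissue, and selects the
   top quantile (default 20%) of genes maximal in a target tissue group;
3. **network** — builds a Pearson coexpression network (edges at signed
   r ≥ 0.80 by default) over the selected genes and partitions it with a
   from-scratch Markov Cluster (MCL) implementation (expansion, inflation,
   pruning on a column-stochastic flow matrix);
4. **enrichment** — one-sided hypergeometric overrepresentation of GMT gene
   sets in the selected genes, Benjamini–Hochberg adjusted, plus a
   permutation alternative;
5. **constraint** — mean derived-allele-frequency (DAF) comparison between
   gene sets with percentile bootstrap CIs (default 500 replicates, 95%);
6. **synthdata** — seeded generators for all inputs with ground-truth
   manifests: a one-factor log-normal expression model with planted
   tissue-restricted modules, and Beta-distributed per-SNP DAF tables with a
   planted constraint shift.

A small CHD (congenital heart disease) candidate gene set ships as a GMT
fixture (`tsnetwork.datasets.load_chd_candidates`).

## CLI

```sh
# synthetic input bundle with known ground truth
tsnetwork simulate --outdir data/ --seed 17

# stage by stage
tsnetwork specificity --expression data/expression.tsv --samples data/samples.tsv \
    --target-tissues heart01,heart02 --fraction 0.2 --out spec.tsv
tsnetwork network --expression data/expression.tsv --samples data/samples.tsv \
    --corr-samples target --target-tissues heart01,heart02 \
    --threshold 0.80 --inflation 2.0 --outdir net/
tsnetwork enrich --gmt sets.gmt --selected selected.gmt \
    --universe data/expression.tsv --out enrichment.tsv
tsnetwork daf --variants data/variants.tsv --set-a specific.gmt \
    --set-b background.gmt --reps 500 --seed 17 --out daf.json

# or everything from one YAML config (keys mirror PipelineConfig fields)
tsnetwork run --config config.yaml
```

`tsnetwork run` writes every stage's outputs plus `manifest.json` with
parameters and SHA-256 checksums; identical config + seed reproduces
identical checksums.

Example `config.yaml`:

```yaml
expression: data/expression.tsv
sample_annotation: data/samples.tsv
gene_sets: data/gene_sets.gmt      # optional, enables enrichment
variants: data/variants.tsv        # optional, enables DAF comparison
target_tissues: [heart01, heart02, heart03]
fraction: 0.2
correlation_threshold: 0.80
corr_samples: target               # or: all
seed: 17
outdir: results
```

## Notes

- Correlation is computed on natural-log expression by default
  (`log_transform_correlation` / `--log`): the synthetic one-factor model's
  analytic within-module correlation `loading² / (loading² + noise_sd²)`
  holds on the log scale, and log intensities are standard for coexpression.
  Pass `--no-log` / `log_transform_correlation: false` for linear-scale r.
- `corr_samples: target` correlates over target-tissue samples only;
  `all` uses every sample. Both are exposed because either choice is
  defensible.
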