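# tfcoop

Predict cooperative transcription-factor (TF) pairs in yeast-style
regulatory data by combining two significance tests per TF pair:

1. **Target-gene overlap** — a hypergeometric tail probability that the two
   TFs share at least the observed number of target genes, given their
   target-set sizes and the gene-universe size (default 6576).
2. **Nucleosome co-depletion** — a one-sided Fisher exact tail probability
   that the two TFs' best binding sites are simultaneously nucleosome-free
   in at least the observed number of shared-target promoters.

The cooperativity score of a pair is `-log10(P_overlap) - log10(P_nu)`;
pairs scoring strictly above a threshold (default 120) are predicted
cooperative. Both tails are computed with log-gamma binomial coefficients
and log-sum-exp, so p-values far below float underflow still produce
finite scores.

A TF's target genes are the union of documented-regulation evidence and
genes whose promoters carry a binding site passing the posterior filter
(default ≥ 0.3); when several sites of one TF map to a gene, only the
highest-posterior site is used for the occupancy call.

## Layout

| Module | Contents |
| --- | --- |
| `tfcoop.data` | Domain types, TSV/BED readers and writers, packaged fixture loaders |
| `tfcoop.targets` | Posterior filtering, best-site selection, target-set construction, pair enumeration |
| `tfcoop.scoring` | Overlap and co-depletion p-values, contingency tables, scoring, prediction, network export |
| `tfcoop.evaluation` | PPI-partner-overlap index, benchmark-overlap index, precision/recall, evidence summaries, similarity hook |
| `tfcoop.simulate` | Synthetic dataset generator with planted cooperative pairs, recovery check |
| `tfcoop.cli` | `tfcoop` command-line interface |

Two plain-text fixtures ship with the package: a 27-row annotation table
of predicted pairs (`fixtures/predicted_pairs_annotation.tsv`) and a
27-pair benchmark of known cooperative pairs from curated protein
complexes (`fixtures/benchmark_pairs.tsv`).

## Input formats

* Regulation: 2-column TSV `tf<TAB>gene`.
* Binding sites: BED6+1 `chrom start end tf posterior strand gene`
  (0-based half-open coordinates).
* Nucleosome occupancy: BED3 of occupied intervals.
* PPI / benchmark pairs: 2-column TSV, undirected.

## CLI

```sh
tfcoop simulate --out-dir data/ --seed 1           # synthetic dataset (20 TFs, 3 planted pairs)
tfcoop score --regulation data/regulation.tsv --tfbs data/tfbs.bed \
             --nucleosome data/nucleosome.bed --total-genes 600 \
             --out results.tsv
tfcoop predict --results results.tsv --score-threshold 120 \
               --out predicted.tsv --network-out network.tsv
tfcoop evaluate --predicted predicted.tsv --ppi data/ppi.tsv --out report.json
tfcoop sweep --regulation data/regulation.tsv --tfbs data/tfbs.bed \
             --nucleosome data/nucleosome.bed --total-genes 600 \
             --ppi data/ppi.tsv --out sweep.tsv
```

`score --disable-nucleosome` forces the co-depletion term to p = 1
(ablation). Any command accepts `--config file.json` with default option
values; explicit flags win. Exit codes: 0 success, 1 data error,
2 usage error.

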