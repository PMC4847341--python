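# dppnet

Build dynamic probabilistic protein networks from a static
protein–protein interaction (PPI) network plus a time-course gene
expression matrix, and identify protein complexes on them with a
two-phase core-attachment algorithm.

The pipeline:

1. **Activity calling** — per gene, compute the sample mean/SD over the
   (cycle-collapsed) time course and three variance-damped k-sigma
   thresholds; each time point gets an activity probability level
   (0.99 / 0.95 / 0.68 / 0) by which threshold the expression clears.
2. **Network construction** — annotate each PPI vertex with its active
   time points and levels; keep an edge only if its endpoints share at
   least one active time point (the edge carries that intersection).
3. **Complex detection** — enumerate maximal cliques (size ≥ 3), keep
   those whose members share a common active time point, score them by
   joint activity probability × summed edge topology scores, select
   cores greedily with overlap pruning, add high-weight edges outside
   the chosen cliques as two-member cores, then attach neighbor
   proteins whose average connection weight at the core's time point
   beats a threshold.
4. **Evaluation** — match predictions to a benchmark complex set by
   neighborhood affinity (> 0.2) and report precision, recall,
   F-score, Sn, PPV and accuracy.

A synthetic-data module generates PPI/expression/benchmark files with
planted ground-truth complexes, so everything is testable offline, and
implements the expression-shuffling control.

## CLI

All commands are under the `dppn` entry point; every flag can also be
supplied through `--config file.yaml`.

```sh
# generate a synthetic dataset with one planted 8-clique active at T10
cat > spec.json <<'EOF'
{"n_proteins": 200, "planted": [{"size": 8, "time": 10}],
 "background_edge_prob": 0.01, "seed": 1}
EOF
dppn simulate --spec spec.json --out demo/

# activity table, network + active-protein distribution
dppn activity --expr demo/expression.tsv --out demo/activity.tsv
dppn build --ppi demo/ppi.tsv --expr demo/expression.tsv --out demo/run

# detect complexes and evaluate against the benchmark
dppn detect --ppi demo/ppi.tsv --expr demo/expression.tsv \
    --core-thresh 0.09 --extend-thresh 0.05 --out demo/run
dppn evaluate --pred demo/run.complexes.tsv \
    --benchmark demo/benchmark.tsv --out demo/report.json

# threshold sweep and the shuffling control
dppn sweep --ppi demo/ppi.tsv --expr demo/expression.tsv \
    --benchmark demo/benchmark.tsv --grid "0.05:0.05,0.09:0.05" \
    --out demo/sweep.tsv
dppn shuffle --expr demo/expression.tsv --seed 7 --out demo/shuffled.tsv
```

Input formats: the PPI network is a two-column TSV of protein IDs; the
expression matrix is a TSV with a header row of time labels and gene
IDs in the first column (GEO series-matrix `!` comment lines are
skipped); benchmarks are one complex per line, whitespace-separated
IDs. Multi-cycle time courses (default 3 × 12 columns) are collapsed
to one cycle by per-position mean.

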