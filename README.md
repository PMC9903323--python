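# lfqdap

Downstream analysis of label-free quantitative proteomics data: feature
selection, mode-between normalization, peptide-to-protein rollup, moderated
differential expression testing, spike-in benchmarking, and a synthetic
data simulator with known ground truth.

## What it does

Starting from a peptide-level report (generic long TSV, simplified
MaxQuant `peptides.txt`, or simplified DIA-NN report) plus a sample
metadata table, the pipeline:

1. **dataio** — parses reports into a canonical long table and builds a
   log2 peptide-by-sample abundance matrix with explicit missing cells
   (never imputed anywhere).
2. **filtering** — keeps peptides detected in enough replicates of every
   group in scope (absolute count or fraction), drops proteins with too
   few peptides, optionally keeps only the top-M peptides per protein;
   dataset-wide or per contrast.
3. **normalization** — per-sample additive log2 scaling: `median`,
   `var_overall` (variation minimization over all samples), `vwmb`
   (within-group variation minimization, then between-group
   foldchange-mode alignment), `mwmb` (pairwise-mode within, mode
   between), `modebetween`, and `modebetween_protein` — between-group
   mode alignment computed on the protein-rolled matrix and applied to
   the peptide matrix, chainable after any other method. Plugins can be
   registered by name.
4. **rollup** — protein profiles by intensity `sum`, Tukey median polish
   (`tmp`), or MaxLFQ-style pairwise-ratio reconstruction (`maxlfq`).
5. **dea** — two-group moderated t-statistics with an empirical-Bayes
   variance prior (`ebayes`) or a peptide-count-dependent prior trend
   (`deqms`), Benjamini–Hochberg FDR, and an optional foldchange
   threshold estimated by a group-label permutation test.
6. **benchmark_qc** — ROC curves and partial AUC at 95% specificity
   against ground truth, distance-to-best across normalization/DEA
   grids, background foldchange centering, confusion counts, and QC
   tables (detected counts, CV, leave-one-out variation impact, PCA).
7. **simulate** — spike-in datasets with power-law peptides-per-protein,
   intensity-dependent noise, per-sample loading offsets, left-censored
   plus random missingness, and a regulated subset at configurable
   foldchange and up/down asymmetry. Registered scenarios:
   `insilico_1p2fold`, `challenging_lowload`, `null`, `asymmetric_down`.

Samples flagged `exclude` in the metadata stay visible to QC but never
enter filtering, normalization, or testing.

## Command line

```sh
# simulate a benchmark scenario (TSVs + truth JSON)
lfq-dap simulate --scenario insilico_1p2fold --seed 1 --out scratch/sim

# run the full pipeline
lfq-dap run --peptides scratch/sim/insilico_1p2fold_peptides.tsv \
            --samples scratch/sim/insilico_1p2fold_samples.tsv \
            --norm vwmb,modebetween_protein --rollup maxlfq \
            --dea ebayes,deqms --alpha 0.01 --out scratch/run

# QC tables
lfq-dap qc --peptides ... --samples ... --out scratch/qc

# normalization x DEA benchmark grid from a YAML config
lfq-dap benchmark --grid grid.yaml --out scratch/bench
```

`grid.yaml` keys: `scenario`, `seeds`, `norm_chains`, `dea_algorithms`,
`rollup`, optional `fc`.

## Python API

```python
from lfqdap.simulate import simulate_scenario
from lfqdap.dea import run_dea, DeaConfig
from lfqdap.model import Contrast

dataset, truth = simulate_scenario("asymmetric_down", seed=1)
results = run_dea(
    dataset, [Contrast("A_vs_B", "A", "B")],
    DeaConfig(algorithms=["ebayes", "deqms"],
              norm_chain=["vwmb", "modebetween_protein"]),
)
```

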