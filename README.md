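# refstab

Reference-gene stability analysis for RT-qPCR, end to end:

* **qpcr_data** — wide-format (assays × samples) Cq / relative-quantity
  matrices, technical-replicate averaging, the efficiency-corrected
  Cq → quantity transform, and a packaged 19-experiment × 11-assay
  M-value table (candidate reference genes under diverse cancer-cell
  perturbations, experiments A–S) with per-experiment descriptions.
* **genorm** — expression-stability statistics: pairwise variation (SD of
  log2 expression ratios), the per-gene stability measure M, stepwise
  exclusion ranking, per-sample normalization factors (geometric means) and
  the sequential V-value criterion with the 0.15 cutoff.
* **rank_aggregation** — consensus ordering of weighted ranked lists:
  weighted Spearman footrule objective (per-list min–max normalized M-values
  attached to positions), Borda-count baseline, an exhaustive optimizer for
  small instances, and a cross-entropy Monte Carlo optimizer (guaranteed no
  worse than Borda, reproducible from a seed).
* **synthetic_data** — a qPCR simulator with log-normal gene noise, a shared
  per-sample mRNA-content factor and optional treatment effects, plus the
  closed-form expected-M oracle `mean_k sqrt(sigma_j^2 + sigma_k^2)`.
* **pipeline** — orchestration, dual-format (JSON + text) reports and the
  `refstab` command-line interface.

## CLI

```sh
# simulate an experiment with known ground truth
refstab simulate --n-genes 6 --n-samples 20 --sigma 0.1,0.2,0.2,0.3,0.4,0.8 \
    --perturb G02=2.0 --seed 1 --out-dir scratch/sim

# per-experiment stability analysis (Cq or quantity input)
refstab stability scratch/sim/cq.tsv --value-kind cq --out-dir scratch/stab

# consensus across experiments (stability reports or a wide M-value table)
refstab aggregate scratch/stab/*.stability.json --method ce --seed 1

# one-command consensus over the packaged 19-experiment table
refstab reproduce-table1 --seed 0
```

Exit codes: 0 success, 2 validation/format error, 3 I/O error.

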