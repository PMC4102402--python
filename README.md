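# schurdle

Semi-continuous ("Hurdle") modeling of bimodal single-cell gene expression.

Single-cell expression measurements (nCounter single-cell profiling,
multiplexed qPCR, and similar count-based assays) are strongly bimodal: a
gene in a given cell is either "on", with a clearly positive log count, or
"off", with a count at or near background. Standard linear models and
ANOVA ignore this structure and lose power. `schurdle` implements a
complete analysis framework for such data:

- **Thresholding** — separate signal from background per gene with a
  two-component Gaussian mixture fitted by empirical-Bayes MAP estimation
  (ECM), then truncate noise-classified observations to zero, yielding the
  *expression threshold* value `et` (0 = no detectable expression).
- **Normalization** — align the locations of signal and noise clusters
  across PCR plates within experimental batches, then translate each gene
  so its minimum normalized value is zero.
- **QC** — robust z-score (median/MAD) filtering of empty and outlying
  cells; removal of genes with detectable expression below 1% in any cell
  line; computation of the per-cell detection rate `ngeneson` (the
  fraction of panel genes on in a cell, a proxy for amplification
  efficiency used as a nuisance covariate).
- **Differential expression** — the two-part hurdle GLM: a logistic
  regression on the detection indicator and a Gaussian model on the
  positive values, sharing a design of cell-line and cell-cycle effects
  (sum-to-zero coded), optional interactions, and `ngeneson`.
- **Deviance partitioning** — the proportion of a gene's deviance
  explained by the cycle, a hurdle analog of R².
- **Co-expression networks** — L1-penalized neighborhood selection split
  into discrete and continuous components, with nuisance covariates left
  unpenalized and penalties calibrated to a fixed edge budget.
- **Synthetic data** — a generator with the exact statistical structure
  the framework assumes, with full ground truth, so every stage is
  testable end-to-end.

## The model

For cell *k*, write `et_k` for a gene's thresholded log2 expression. The
hurdle regression is

```
logit Pr(et_k > 0)      = α₀ + α_line(k) + β_cyc(k) + γ_line(k),cyc(k) + α_z·z_k
E[et_k | et_k > 0]      = α₀' + α'_line(k) + β'_cyc(k) + γ'_line(k),cyc(k) + α'_z·z_k + ε_k
```

with sum-to-zero constraints on the factor effects (Σα = Σβ = 0, zero row
and column sums for the interaction matrix γ) and `z_k` = ngeneson. The
joint log-likelihood is additive in the two parts, so the likelihood-ratio
statistics for "no cycle effect" add, and the combined statistic
Λ = Λ_d + Λ_c is referred to χ² with the degrees of freedom doubled (4 for
three phases under the sum constraint). A union–intersection alternative
rejects when either component rejects at α/2. The cycle deviance ratio is
(D₀ − D₁)/D₀ for the cycle-free (D₀) versus full (D₁) model, using GLM
deviances (−2·loglik for the Bernoulli part, residual sum of squares for
the Gaussian part), which reduces exactly to the OLS R² for zero-free data.

Networks follow Meinshausen–Bühlmann neighborhood selection: each gene is
regressed on all others' `et` with an L1 penalty (logistic on the
indicator; linear on the positive values), covariates unpenalized; nonzero
coefficients propose edges; neighborhoods are symmetrized by union and the
discrete/continuous networks combined with per-edge provenance.

## Worked example

```python
from schurdle import (SimulationSpec, simulate_dataset, threshold_table,
                      apply_qc, test_all_genes, deviance_all_genes)
from schurdle.qc import attach_ngeneson

spec = SimulationSpec(n_genes=20, cells_per_group=30,
                      cycle_effect_genes=(0, 1, 2, 3), cycle_effect_size=1.2,
                      seed=7)
raw, truth = simulate_dataset(spec)          # 540 cells x 20 genes
et_table, fits = threshold_table(raw)        # mixture thresholding -> et
et_table = attach_ngeneson(et_table)
clean, removed, kept = apply_qc(et_table)    # cell + gene filters
res = test_all_genes(clean)                  # hurdle cycle test per gene
dev = deviance_all_genes(clean)              # cycle deviance ratios
```

Output of the summary lines:

```
540 cells x 20 genes after QC (0 cells removed)
median expression frequency: 0.70
significant after Bonferroni (alpha=0.05): 4 of 20 genes
gene_id  lam    p_adj peaktime
   G001  179 2.17e-36        S
   G003  131 3.74e-26    G0/G1
   G002  121 5.38e-24     G2/M
most cycle-explained gene: G001 (deviance ratio 0.21)
```

The four genes generated with a cycle effect are exactly the four flagged
significant; `lam` is the combined likelihood-ratio statistic on 4 degrees
of freedom, `p_adj` the Bonferroni-adjusted p-value, and `peaktime` the
phase of maximum mean expression — which matches each gene's planted peak.
The deviance ratio says cell cycle explains 21% of the best gene's
stochastic variability; everything else is residual.

A command-line interface mirrors the stages:

```sh
schurdle simulate --spec spec.json --out sim/
schurdle threshold sim/cell_table.csv --out et.csv
schurdle filter et.csv --out clean.csv
schurdle test clean.csv --out tests.csv
schurdle network clean.csv --edges 60 --split 30,30 --adjust-cycle on --out edges.tsv
```

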