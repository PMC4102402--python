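# Methods

This note documents the statistical procedures implemented in `schurdle`,
the defaults they use, and the choices made where the design was open.

## Thresholding by empirical-Bayes mixture modeling

Log2-transformed counts (`lcount = log2(count + 1)`) of a bimodally
expressed gene form a noise cluster near zero and a signal cluster at a
gene-specific positive mean. Separation proceeds in two stages.

**Omnibus MLE.** A two-component Gaussian mixture is fitted by EM to the
pool of positive values across all genes, guaranteeing both clusters are
represented. Observed zeros (count 0) are pinned to the noise cluster:
a zero count cannot be signal, and the point mass would otherwise distort
the Gaussian fit. EM runs from a deterministic set of starts (2-means and
several quantile/range splits) to 500 iterations or relative objective
change < 1e−8, and the highest-likelihood run is kept. Two safeguards
address well-known mixture pathologies: (i) runs whose smaller component
standard deviation falls below 1% of the pooled standard deviation are
rejected when a non-degenerate run exists — on count data the likelihood
is effectively unbounded at components collapsed onto repeated discretized
values (log2 of counts 1, 2, 3, …), and such spikes describe the
discretization, not a cluster; (ii) if the best run still falls below the
single-Gaussian log-likelihood the convergence flag is lowered, since the
mixture family contains the single Gaussian and a worse fit means a bad
local optimum (typical on unimodal data). Clusters are always relabeled so
the noise mean is the smaller.

**Empirical-Bayes prior.** The omnibus fit seeds a conjugate prior per
cluster *j*: mean ~ Normal(μ̂_j, σ²_j/κNt) and variance ~
Inverse-Gamma(a, b_j), with shape a = (κNt − 3)/2 and scale
b_j = (a + 1)·σ̂²_j so the prior mode equals the omnibus variance, giving
each cluster's location/scale an effective weight of κNt = 15
pseudo-observations at the defaults κ = 3, Nt = 5. The signal mixing
proportion has a Beta(5, 5) prior — weight equal to 10 observations.

**Per-gene MAP by ECM.** Each gene is fitted by Expectation Conditional
Maximization against this prior: responsibilities, then the Beta-MAP
update of the mixing proportion (π̂ = (n_signal + 4)/(n + 8) at the final
responsibilities), then shrunken means, then the joint posterior mode of
the variances. The prior keeps both clusters alive for genes observed in
only one mode (a gene 100% on retains a noise cluster at the prior center
with prior-only weight). A gene whose MAP clusters are separated by less
than 0.5 pooled standard deviations is treated as effectively unimodal and
falls back to the omnibus-derived classification, preventing arbitrary
splits of unimodal genes.

**Truncation.** An observation with posterior probability strictly greater
than .5 of belonging to the noise cluster is set to zero; everything else
(including the exact boundary) is kept unchanged. The result is the
expression-threshold value `et`; `et > 0` always equals the input value.

## Normalization

Plates shift cluster locations. Within each experimental batch (plates
processed together), preliminary signal/noise labels come from the
thresholding machinery applied per batch; then ordinary least squares fits

    lcount ~ gene + cluster + plate:cluster

with plate-within-cluster intercepts sum-coded, and each record is
corrected by its plate's deviation of the cluster intercept from the
across-plate mean. Only locations move: within-plate, within-cluster
differences are preserved exactly, and no variance harmonization is
attempted (a non-pooled, location-only batch adjustment). A plate×cluster
cell with no observations contributes no correction (warned). Each gene is
then translated so its minimum normalized value is exactly zero —
well-defined because no gene is expressed in 100% of cells under the
preliminary clustering — and the normalized data are re-thresholded
jointly across batches to produce the final `et`.

A design point left open by the location-alignment idea is whether gene
main effects enter the regression or each gene is aligned separately; a
shared gene term per batch is used (the minimal model consistent with
subtracting per-plate cluster intercepts), which pools information across
genes when estimating plate offsets.

## Quality control

`ngeneson` (z_k) is the fraction of panel genes with `et > 0` in cell *k*;
it is highly correlated with the cell's log-sum of expression
(log2 Σ(2^lcount − 1), the analog of log total read count) and is carried
as a nuisance covariate downstream. Cell filtering removes: cells with no
expressed gene (unconditionally); cells flagged on at least `nOutlier = 2`
of the two robust z-score criteria — expression proportion with
|z| > SigmaProportion = 2 and positive-expression mean with
|z| > SigmaContinuous = 5. Robust z uses median/MAD with the 1.4826
normal-consistency constant; a zero MAD falls back to the standard
deviation with a warning. With nOutlier = 2 both criteria must fire — a
cell outlying in only one is kept. The positive-expression mean is
computed over expressed genes only (the alternative, zeros included,
would mix the two modes the framework exists to separate).

Gene filtering then removes genes with detectable expression below 1% in
*any* cell line, evaluated after cell filtering (cells first, then genes);
`ngeneson` is recomputed on the retained panel.

## The hurdle model and its tests

Both parts share one design: intercept, cell-line effects, cycle effects,
optional line×cycle interactions, and `ngeneson`. Factors are sum-to-zero
coded (the interaction has zero row and column sums), which makes every
test statistic invariant to the choice of reference level; the invariance
is asserted numerically in the test suite. The discrete part is a
Bernoulli GLM fitted by IRLS; under perfect separation a fixed ridge of
1e−6 is applied and the fit flagged. The continuous part is OLS on the
strictly positive `et` with the maximum-likelihood (n-denominator)
variance, so log-likelihoods — hence deviances — are comparable across
nested models; REML is deliberately not used. Genes expressed in all or no
cells contribute only the available component, with degrees of freedom
reduced and a per-gene flag.

**Combined LRT.** For the cycle null, component Wilks statistics
Λ_d = D0_d − D1_d and Λ_c = D0_c − D1_c (each −2·Δloglik, clamped at 0)
are added and referred to χ² with the component degrees of freedom summed:
three phases under a sum constraint give 2 + 2 = 4. The default
differential-expression contrast drops cycle main effects with no
interactions in either model (an ANOVA-like comparison adjusting for
additive cell-line effects and efficiency); the deviance analysis below
uses the richer model with interactions. Additivity Λ = Λ_d + Λ_c is exact
by construction and asserted exactly.

**Union–intersection test.** The joint null is the intersection of the
component nulls, so rejecting when either component rejects at level α/2
bounds the overall size at α (Bonferroni). The component level is exposed
as an option; α/2 is the default because it is the size-controlling
choice. Monte-Carlo checks at 1000 null genes confirm both the χ²(4)
calibration of the combined test (empirical size ≈ 0.05 at 900 cells) and
the union bound. At a few hundred cells the χ²(4) reference is visibly
anticonservative (size ≈ 0.07 at 270 cells); the calibration property is
therefore stated at the ~900-cell scale the framework targets.

**Deviance ratio.** The full model (cycle mains + interactions) is
compared with the model omitting every cycle term. Deviances follow the
GLM convention — Bernoulli: −2·loglik (saturated log-likelihood is zero);
Gaussian: residual sum of squares — and the cycle deviance ratio is
(D₀ − D₁)/D₀ ∈ [0, 1], directly analogous to the coefficient of
determination; for data with no zeros it *equals* the OLS partial R² of
the cycle terms (asserted to 1e−8). Summing −2·loglik for the Gaussian
part instead would break both properties (the ratio could leave [0, 1] and
no longer reduces to R²), which is why the RSS convention is used even
though the likelihood-ratio tests above use −2·loglik differences. The
deflated ratio divides by the maximum ratio across genes (or a supplied
value), an upper bound on cycle-attributable variability under the
assumption that the top gene is fully cycle-regulated. Omitting `ngeneson`
inflates residual deviance and attenuates the ratio; the directional
effect is asserted on efficiency-confounded simulations.

**Peak time.** A gene's peak phase is the phase with maximum mean `et`
(zeros included) over all cells; ties resolve to the earliest phase in
cycle order (G0/G1 < S < G2/M) and are flagged.

## Co-expression networks

Each gene *g* is regressed on all other genes' `et` (standardized to unit
variance inside the fit, so one penalty is meaningful across genes;
coefficients are reported on the original scale):

- discrete: L1-penalized logistic regression of 1{et_g > 0} on all cells;
- continuous: L1-penalized linear regression of et_g on the cells where
  gene *g* is positive, with the other genes' full `et` (zeros included)
  as predictors — the conditioning is on the target's positivity only.

Covariates (`ngeneson`, cell line, and — when adjusting — cycle with
line×cycle interactions) are never penalized, implemented through
per-parameter penalty weights. The penalized logistic solve profiles all
parameters jointly; the penalized linear solve projects the unpenalized
block out of the response and predictors first (Frisch–Waugh), which is
exact for squared error.

Nonzero gene coefficients propose edges; a component's network is the
union-symmetrized edge set over all gene-wise regressions. A single
penalty per component is calibrated by geometric bisection to a target
edge count (edge count is checked for monotonicity along the path and a
violation warns); when edges enter in batches and jump past the budget,
entering edges are ranked by their largest absolute standardized
coefficient and trimmed to the budget. Discrete and continuous networks at
budgets E/2 each are combined by union, with provenance
discrete/continuous/both per edge. "Raw" comparison networks use the same
machinery on un-thresholded `lcount`.

Why adjustment matters is an identity on conditional covariances:
cov(X, Y) = E[cov(X, Y | F)] + cov(E[X|F], E[Y|F]) for any clustering
factor F. Unadjusted co-expression includes the second (marginal) term —
genes that merely shift together across phases look connected; including
the factor as an unpenalized covariate isolates the first (cellular) term.
The implementation of the decomposition uses population-style (divisor n)
covariances so the identity is exact to floating point. On simulations
where six genes share cycle-driven shifts and one gene pair has a planted
conditional dependence, the cycle-adjusted network at a matched edge
budget retains the planted pair and drops the cycle-induced edges.

No stability selection, bootstrap edge confidence, or consistency theory
is attempted for the network estimator.

## Synthetic data generator

The generator is the exact inverse of the fitting model. Defaults describe
the assay the framework targets:

| parameter | default | meaning |
|---|---|---|
| lines × phases | 3 × 3 | H9/MB231/PC3 × G0/G1, S, G2/M |
| cells_per_group | 34 | cells per line × phase × plate |
| freq_range | (0.56, 0.9) | per-gene baseline expression frequency (interquartile range of real panels) |
| signal_mean_range | (6, 11) | per-gene signal-cluster mean, log2 scale |
| signal_sd | 1.0 | within-cluster sd, log2 scale |
| noise mean/sd | 0.5 / 0.5 | noise cluster: Normal(0.5, 0.5) truncated at zero (the near-zero background mode) |
| line effect sds | 0.5 | cell-line effects on logit-frequency and positive mean |
| efficiency_sd | 0.5 | per-cell shift; enters the positive mean with weight 1 and the logit with weight 2 |
| plate_shift_sd | 0.25 | plate intercept shift on signal draws |

Per cell × gene: on/off is Bernoulli through the logistic model; "on"
draws Normal around the linear predictor of the positive mean; "off" draws
from the truncated-normal noise cluster. Values become integer counts
(round(2^v − 1)) and back to `lcount`, reproducing the discretization of
real count data at the low end. The per-cell efficiency shift moves both
model parts, inducing the strong `ngeneson`–logsum correlation (> 0.8 at
defaults) that real plates show. Cycle-effect genes are assigned a peak
phase round-robin, mirroring a real panel in which cycle genes peak
throughout the cycle — if all planted genes peaked in the same phase,
`ngeneson` would be collinear with phase, a confounding the real assay
does not have. Conditional-dependence edges are planted by letting a
child gene's logit (and half-weight, its positive mean) depend on the
standardized `et` of its parent, generated in topological order. The
ground-truth record carries every coefficient, the per-record cluster
label, the peak-phase map and the planted edges.

What the generator does *not* emulate: molecular amplification kinetics
(efficiency is a phenomenological per-cell shift), heavy-tailed or skewed
positive expression, dropout that depends on expression level within the
"on" mode, and correlated noise between genes beyond the planted
structure. Passing tests therefore demonstrate correctness of the
estimators under the model's own assumptions and realistic dimensions,
not robustness to every feature of real data.

## Problem sizes and numerical choices

- Monte-Carlo calibrations use 1000 null genes at 900 cells (10
  independent datasets × 100 genes) and 150–200 datasets for coefficient
  recovery; the acceptance script's full-pipeline run uses 936 cells × 120
  genes with a third of the genes cycle-regulated. These sizes were chosen
  to put standard errors of measured rates near 0.01 while keeping a full
  run to about a minute.
- EM/ECM: relative objective tolerance 1e−8, 500 iterations max,
  deterministic initialization (no RNG), variance floor 1e−8.
- IRLS: statsmodels defaults, 100 iterations; separation fallback ridge
  1e−6 (flagged).
- Penalty calibration: geometric bisection, 30 iterations after
  bracketing by doubling/halving; ties at the final bracket are resolved by
  coefficient magnitude.
- Degenerate inputs: all-equal data refuse a mixture fit; a gene absent
  from a table is an error naming the gene; p-values outside [0, 1] are an
  error; `D₀ < D₁` (numerically) clamps the cycle deviance at zero and
  flags the gene.

## Known limitations

- The exact prior construction of the original flowClust-based pipeline is
  not public in closed form; the Normal-Inverse-Gamma + Beta conjugate
  prior used here matches its stated weights (κNt per cluster, Beta(5,5))
  but per-gene thresholds can differ slightly in borderline genes.
- The χ²(4) null is asymptotic; at a few hundred cells the combined test
  runs slightly anticonservative.
- Deviance ratios mix a Bernoulli deviance (dimensionless) with a Gaussian
  RSS (scale-dependent); the ratio is well-defined but its split between
  components depends on the expression scale.
- Network penalties are calibrated to an edge budget, not to an error
  rate; edge sets should be read as a ranked summary of conditional
  association, not as tested hypotheses.
- Generalized linear mixed models (random plate effects and the like) are
  out of scope.
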