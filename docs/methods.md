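# Methods

`cafsig` models the prediction of immune-checkpoint-inhibitor (ICI)
response from cancer-associated-fibroblast (CAF) marker-gene expression,
and the spatial relationship between CAF subtypes and T-cell states in
tumour sections. This note describes the statistics the package computes,
the assumptions behind them, the synthetic data they are exercised on, and
the numerical choices made where the design was genuinely open.

## Single-sample signature scoring

The core statistic is a per-sample rank-weighted running-sum enrichment
score (the ssGSEA statistic). For a sample with expression over N genes
and a gene set S, genes are ordered by expression descending; walking down
the ordering, the in-set empirical CDF steps by `rank^alpha` (ranks
ascending in expression, averaged over ties; the walk's tie order is fixed
by gene id so results are reproducible) normalized over in-set genes,
while the out-of-set CDF steps uniformly by `1/(N − |S|)`. The score is
the sum of (in-set CDF − out-of-set CDF) over all N positions. `alpha`
defaults to 0.25, the convention of the original implementation; with
`normalize=True` scores are divided by the max−min range across samples.
Because the statistic is rank-based it is invariant to any strictly
increasing transform of a sample's expression.

The **Caf.Sig score** of a signature pair is

    Caf.Sig = score(up-regulated set) − score(down-regulated set)

with both sides computed by the same scorer and parameters. Up/down sets
are oriented to non-responders (genes higher in non-responders go up), so
a higher Caf.Sig score predicts non-response. `partition_signature`
derives such a pair from labelled expression by the sign of each
candidate gene's group-mean difference; exact ties are excluded. The
scores are reported raw (un-normalized) by default; whether the original
analysis normalized across samples is not decidable from its description,
and the choice does not affect any rank-based downstream statistic.

A simpler mean-module scorer (mean of set genes minus the mean of
expression-matched control genes drawn from 25 equal-count average-
expression bins, 100 controls per set gene, seeded) is provided as an
independent concordance check. Other single-sample scorers (AUCell,
UCell, GSVA, singscore) are out of scope.

### Single-cell QC

`qc_filter` removes a cell iff UMI > 40 000, or genes < 500, or genes
> 5 000, or mitochondrial fraction > 20% — all comparisons strict, taking
the stated rules literally, so cells exactly at a boundary survive. The
removal log names every triggering rule per cell.

## Ensemble model search

The model search emulates building a predictive signature by crossing
feature-selection methods with classifiers and electing the combination
with the best cross-cohort AUC:

1. Cohorts are reduced to their shared gene space and each gene is
   z-scored within each cohort (mean 0, SD 1). This per-cohort
   standardization is the package's stand-in for a dedicated empirical-
   Bayes batch-correction step; it removes exactly the additive
   per-(cohort, gene) shifts the generator plants.
2. The feature selector runs once on the pooled training cohorts.
   Combinations selecting fewer than `min_genes = 5` model genes are
   omitted from the leaderboard.
3. The classifier's hyperparameters are tuned by leave-one-out
   cross-validation (LOOCV) on the pooled training data, maximizing the
   AUC of the held-out scores; the winner is refit on the full pool.
4. AUC is recorded per cohort: training cohorts are scored with their
   LOOCV *held-out* predictions (resubstitution would be trivially
   optimistic), validation cohorts with the refit model. Group means
   (training / internal / external) are averaged into the overall mean;
   the leaderboard sorts by it, breaking exact ties by fewer model genes,
   then combination id (parsimony first). The tie key is rounded to 10
   decimals so a genuine tie of group means is not broken by
   floating-point noise.

The default manifest holds exactly **113** combinations: 9 feature-
selection-capable methods (lasso, elastic net, ridge coefficient ranking,
forward stepwise, random-forest / gradient-boosting / XGBoost importance,
PLS loadings, recursive feature elimination with a linear SVM) × 12
classifiers (random forest, lasso, ridge, elastic net, stepwise GLM,
componentwise boosted GLM, LDA, PLS-GLM, GBM, XGBoost, RBF-SVM, Gaussian
naive Bayes) = 108, plus 5 standalone embedded-sparsity models (lasso,
ridge, elastic net, boosted GLM, stepwise) whose own non-zero coefficients
define the model genes. The manifest is an explicit, editable fixture —
the count is a configuration contract, and one consistent construction of
a 113-entry grid from 12 algorithms.

Design choices within the search:

* **Selector penalties.** The lasso / elastic-net selectors use a fixed
  regularization strength (C = 1 on standardized data). The classifier is
  the tuned component; fixing the selector's penalty keeps the selected-
  set size stable across signal strengths and avoids degenerate empty
  selections when the signal is weak. Rank-only selectors take the top
  k = 20 genes by absolute coefficient/importance (configurable).
* **Leakage stance.** Selection happens once on the pooled training group
  and only classifier hyperparameters are tuned inside LOOCV, mirroring a
  train-then-validate workflow. Because selection sees the full training
  labels, the training-group AUC is optimistic for the *selection* step —
  which is exactly why ranking also uses internal and external cohorts
  never touched by selection or tuning, and why the null-calibration
  experiment (below) checks that this optimism cannot masquerade as
  signal.
* **Risk score.** Linear models emit the linear predictor
  Σ β_g x_g + β_0; non-linear models the predicted non-response
  probability. Both are monotone in the model's ranking, so AUC is
  unaffected by the choice; both orientations are higher = non-response.
* **Positive class** is the non-responder everywhere.
* **LOOCV AUC caveat.** Pooled held-out scores are slightly pessimistic
  at very small n (each held-out sample's class is underrepresented in
  its fold); the effect vanishes by n ≈ 100.

Desk-scale estimator settings (random forest 15 trees / depth 5, GBM 30
trees, XGBoost 20 trees with histogram splits, elastic net saga with 300
iterations, small hyperparameter grids) keep one 20-combination search in
the tens of seconds on a single core; all are configurable through the
registry. The reduced 20-combination manifest used by the documented
experiments crosses the embedded-sparsity selector family (lasso, elastic
net — the family containing the winning Lasso selection) with ten
classifiers: sparsity-adaptive selectors are the right instrument for a
gene-recovery experiment, since fixed-k selectors cap recall at k/40 by
construction.

### Per-gene odds-ratio meta-analysis

For each model gene, a univariate logistic regression of non-response on
(by default z-scored) expression is fit per cohort; log-ORs are pooled by
inverse variance (fixed effect, the default) or DerSimonian–Laird (random
effects), with Wald 95% CIs and the Q heterogeneity statistic. Cohorts
with perfect separation, a single outcome class, or constant expression
are excluded and flagged. Report-level p-values get Benjamini–Hochberg
adjustment in the pipeline output.

## Spatial proximity

For every reference-type cell in a section, the **k-distance** to a target
type is the mean Euclidean distance to its k nearest target-type cells in
the same section (k = 10 by default, the mapping tool's convention; the
cell itself is excluded when reference and target types coincide).
Distances are never computed across sections. Target types are ranked per
section by the median of the per-reference-cell k-distances (1 = nearest;
average ranks on ties). A (section, type) pair with fewer than k target
cells is missing and conservatively assigned that section's worst rank so
every section contributes a full rank list.

**Robust rank aggregation (RRA)** integrates the per-section rankings.
For a type with normalized ranks r = rank/n_types across m sections,
sorted ascending, the rho score is

    rho = min_k  P( Bin(m, r_(k)) ≥ k )  =  min_k  Σ_{j≥k} C(m,j) r_(k)^j (1 − r_(k))^{m−j}

— the smallest binomial tail probability that at least k of m uniform
draws would fall at or below the k-th observed normalized rank. A small
rho marks a type ranked consistently nearer than chance. Because rho is a
minimum over m order statistics, it is corrected by Bonferroni over the
number of types compared: `corrected = min(1, n_types · rho)`; under
uniform rankings the corrected score controls the false-call rate
conservatively (empirically well below nominal). The aggregate runs
separately within responder and non-responder sections, and
`compare_groups` contrasts pooled per-cell k-distances between groups with
a two-sided Mann–Whitney test.

## Evaluation battery

ROC curves sweep the unique scores (ties step diagonally), so the
trapezoidal AUC equals the Mann–Whitney concordance probability with
half-credit ties. Confusion matrices use the inclusive rule (positive iff
score ≥ threshold); the Youden threshold (max sensitivity + specificity −
1) is the default for reports. Calibration uses 10 equal-width bins over
[0, 1]; empty bins are emitted with n = 0. Decision-curve analysis
reports, per threshold probability pt on a 0.01–0.99 grid,

    NB(pt) = TP/N − (FP/N) · pt/(1 − pt)

against the treat-all closed form π − (1 − π)·pt/(1 − pt) and treat-none
(identically 0). Logistic comparisons (uni- and multivariate) use
maximum-likelihood fits with Wald CIs; perfect separation is flagged and
carries no Wald inference.

## Synthetic data: what it emulates, and what it does not

**Cohorts.** Gaussian log2 expression: per-gene baseline means N(6, 1)
shared across cohorts, additive per-(cohort, gene) batch shifts
N(0, 0.5), residual noise N(0, 1). Non-responders receive ±1.5-SD shifts
on 20 up and 20 down planted genes (defaults; all configurable). Five
cohorts of 100 samples, half non-responders, emulate a multi-cohort ICI
compendium at desk scale — the real compendium spans 14 cohorts of
heterogeneous size, which matters for absolute AUC values but not for the
recovery properties tested here. No counts, dropout, or library-size
structure is simulated: the generator supports rank-based scoring and
linear modelling on log-scale data, nothing finer.

**Sections.** A parent–offspring (Neyman–Scott-like) process: 25
reference-type cells uniform in a 1000×1000 box; each of 250 target-type
cells sits at a uniformly chosen reference cell plus an isotropic
N(0, sigma²) displacement, clipped to the box. Sigma is group-specific,
so "which type is nearest" is a planted, recoverable ground truth.
`cells_per_type` deliberately exceeds `n_reference_cells` so each
reference cell owns a real offspring cluster (~10 cells ≥ k); if every
parent had a single offspring the k-distance would be dominated by
parent spacing and the dispersion knob would barely register. Defaults
plant the study's qualitative contrast — effector T cells nearest the
reference type in responders (sigma 30 vs 90/150), exhausted T cells
nearest in non-responders — at dispersion ratio 3. Boundary clipping
slightly compresses large-sigma types; at the default box size this is
negligible.

**QC tables.** Clean cells draw UMI in [5000, 30000), genes in
[800, 4500), mito in [0, 15); each planted violator exceeds exactly its
designated rule's threshold while remaining clean elsewhere.

Passing tests on these generators show that the statistics recover
planted structure under their own assumptions (Gaussian noise, additive
batch effects, isotropic clusters); they do not certify performance on
real data with heavy-tailed counts, correlated genes, confounded cohorts,
or irregular tissue geometry.

## Documented experiments

`cafsig.experiments` fixes the seeds and problem sizes:

* **Signature recovery** — default cohort design, reduced 20-combination
  manifest, split 2 training / 1 internal / 2 external cohorts: winner's
  external AUC and planted-gene recall.
* **Null calibration** — identical search at effect size 0, 20
  replicates: the winner's external AUC should average near 1/2 (guards
  against selection-induced optimism).
* **Spatial recovery** — 100 replicates of the default section design:
  rate at which the planted-nearest type tops the RRA aggregate per
  group, and at which the group contrast reaches p < 0.05.
* **RRA null error rate** — share of types called at corrected rho < 0.05
  when rankings are uniform permutations.

Problem sizes were chosen so the full suite runs comfortably on a single
core; they are the package's desk-scale study conditions, not tuning
knobs.

## Known limitations

* The 113-entry manifest is one consistent construction; the original
  enumeration is not recoverable from its description.
* LOOCV is O(n) model fits per hyperparameter candidate; the search is
  not intended for cohorts beyond a few hundred pooled training samples
  without switching to a cheaper CV scheme.
* The strict-mode nesting of feature selection inside each LOOCV fold is
  intentionally not the default, matching the train-then-validate
  narrative being emulated; the external cohorts are the unbiased check.
* RRA here aggregates full rank lists (missing entries filled with the
  worst rank); partial-list normalization is a documented alternative,
  not implemented.
* Calibration of non-probability scores (margins squashed through a
  sigmoid) is not a calibrated probability; calibration curves are only
  meaningful for models with native probability outputs.
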