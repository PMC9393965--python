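# Methods

## Problem and overall procedure

`cyclemark` identifies marker genes that distinguish cell-cycle phases
(G1, S, G2M) from a labeled cells × genes TPM matrix, and turns them into
quantitative threshold rules. The workflow is a composition of five
well-defined stages:

1. **All-relevant filtering (shadow features).** Every gene is paired with
   a "shadow": a row-permuted copy that preserves the gene's marginal
   distribution but destroys any label association. A random forest is fit
   on the expanded matrix and each column's per-tree impurity importances
   are condensed into a z-score (mean/sd across trees). A gene scores a
   *hit* when its z exceeds the iteration's maximum shadow z. Hit counts
   accumulate over iterations with fresh shadows each time and are tested
   against Binomial(t, 1/2), two-sided at level α (default 0.05) with
   Bonferroni correction across the *full* gene universe and across the t
   re-examinations (threshold α/(2·d·t)). Correcting by the full universe
   rather than the shrinking undecided count matters: genes surviving to
   late iterations were selected by the full scan, and on noise-only data
   the lenient shrinking-count correction eventually confirms the
   strongest chance-correlated genes. The shadow pool is kept at five or
   more columns for the same reason. Significantly many hits → confirmed,
   significantly few → rejected; decisions are final. Genes undecided
   after `max_iter` iterations (default 100) are tentative and resolved
   by policy (default: rejected, so downstream stages see only
   well-supported genes); under that policy the loop stops early once no
   undecided gene could reach the confirmation threshold even with a
   perfect future hit streak, which cannot change the outcome.
2. **Three importance rankings** of the confirmed genes:
   - *mRMR* — greedy selection maximizing mutual information with the
     phase label while penalizing the average mutual information with the
     genes already selected; MI is computed in bits from empirical joint
     frequencies of a discretized matrix.
   - *MCFS* — relative importance accumulated over s·t CART trees fitted
     on random m-gene projections with stratified 2:1 train/test splits;
     each node splitting on gene g contributes
     wAcc^u · IG(node) · (n_node/n_root)^v, where wAcc is the tree's
     balanced accuracy on its test part and IG the node's Gini impurity
     decrease.
   - *SHAP* — mean absolute exact tree-path attribution over a multiclass
     LightGBM model fitted with default settings, summed over classes and
     averaged over cells. Attributions satisfy local accuracy: base value
     plus attributions equals the raw model output (checked to 1e-6 at
     every fit).
3. **Incremental feature selection.** For each ranked list and classifier
   (random forest with 100 trees, RBF-kernel SVM, 5-NN, CART decision
   tree), every top-k prefix is scored by stratified cross-validation;
   metrics are computed once on the pooled out-of-fold predictions. The
   headline metric is the multiclass Matthews correlation coefficient —
   the correlation of the one-hot encodings of predicted and true labels,
   with the convention that a vanishing variance term yields 0.
4. **Optimal and feasible subsets.** The optimal prefix is the smallest k
   attaining the curve's maximum MCC; the feasible prefix is the smallest
   k whose MCC reaches (1−τ) of that maximum (τ default 0.05). The
   feasible rule replaces visual inspection of curves with a reproducible
   threshold; the curve is exported so a human can override the feasible
   size explicitly. The three feasible subsets (from the random-forest
   curves) are intersected to obtain genes supported by all rankings.
5. **Rule extraction.** A CART tree is refit on all cells using the
   decision-tree-optimal prefix and converted into one rule per leaf: the
   conjunction of threshold conditions along the root-to-leaf path, with
   repeated conditions on a gene merged into the tightest interval.
   Because rules are exactly the tree's leaves, their regions partition
   feature space and applying them reproduces the tree's predictions
   exactly.

## The synthetic study design

The generator emulates a FUCCI-sorted three-phase single-cell experiment:
three labeled classes of 346 (G1), 387 (G2M) and 334 (S) cells by
default; 2,000 genes of which 20 per phase are planted markers; the rest
exchangeable noise. Expression is log-normal
(`exp(N(base_log_mean, log_sd²))`, defaults 3.0 and 1.0), a marker gene's
log-mean is shifted by `effect_size · log_sd` (default 2.0) in its own
phase, each entry is zeroed with probability `dropout_rate` (default
0.3), all-zero cells are redrawn, and each cell is rescaled to sum to
10⁶ (TPM). Markers are up-regulated by default; a `symmetric` flag
alternates up/down shifts for testing rule directions.

What the generator does **not** model: library-size and gene-length
effects, count noise (negative binomial), batch effects, doublets, and
the continuous pseudotime structure of a real cell cycle. Passing tests
therefore demonstrate that the pipeline recovers class-dependent location
shifts against exchangeable noise on a TPM scale — not that it resolves
correlated, graded expression programs in real atlases.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| Boruta α | 0.05 | two-sided binomial level, Bonferroni-corrected |
| Boruta `max_iter` | 100 | iteration cap before tentative resolution |
| Boruta `n_trees` / `max_depth` | 100 / 7 | internal forest; depth balances the importance null (deep trees spread importance onto shadows and mask markers, very shallow trees favor chance-correlated genes) |
| discretization | z-score, cuts at ±0.5 sd, 3 states | empirical MI input for mRMR; equal-frequency binning available |
| mRMR criterion | difference | relevance − mean redundancy; quotient available (redundancy floored at machine ε) |
| MCFS s, m, t, u, v | 200, ⌈0.05·d⌉, 5, 1, 1 | subsets, genes/subset, splits/subset, exponents |
| CV folds | 10, stratified | classes are unbalanced, so folds are stratified |
| τ (feasible) | 0.05 | relative MCC tolerance defining the feasible prefix |
| classifier defaults | RF 100 trees; SVM RBF; 5-NN Euclidean; CART Gini | SVM/KNN standardized per training fold; tree methods consume raw TPM |

## Numerical and design choices

- **MCC zero-variance convention:** constant predictions (or constant
  truth) return 0, the "random-like" interpretation.
- **Pooled CV metrics:** one metric bundle per (subset, classifier) from
  the pooled out-of-fold prediction vector, not a fold average.
- **Tie-breaks:** mRMR ties (to numerical equality, 1e-9) go to the
  earlier input column; MCFS/SHAP score ties are lexicographic on gene
  id; equal-MCC prefixes resolve to the smallest k (parsimony); leaf
  class ties follow the fitted tree's own argmax so that rule application
  agrees with the tree everywhere — a deliberate choice favoring exact
  rule fidelity over a fixed phase order.
- **Seeding:** every stochastic stage takes an explicit seed; the
  pipeline fans one global seed out into per-stage seeds via a seed
  sequence, making two runs with the same config byte-identical. The
  synthetic data seed belongs to the data specification, not to the
  analysis seed fan-out.
- **Degenerate inputs:** zero-variance genes are flagged at read time,
  excluded from ranking engines, retained in the matrix for index
  stability; single-class tree training yields a one-leaf tree; all-zero
  synthetic cells are redrawn because their TPM is undefined.
- **Empty confirmed set:** on data with no signal the filter confirms
  nothing and the pipeline aborts with the stage name (partial outputs
  kept) unless `fallback_all` is set, in which case all non-constant
  genes are ranked with a warning.

## Problem sizes used by the test suite and acceptance script

Simulation-backed checks run on two frozen designs chosen once for
single-CPU execution: the full design (1,067 × 2,000, 60 markers) for the
shadow-filter recovery checks, and a desk-scale design with identical
signal structure — classes (87, 97, 84), 400 genes, 60 markers, effect
2.0, dropout 0.3 — for ranking, IFS-curve and intersection checks, whose
cost is dominated by the ~0.1 s floor of each 100-tree forest fit and
therefore scales with curve length × folds. Desk-scale curves use 3-fold
CV and prefix caps of 60 (primary) / 40 (acceptance script) / 20
(secondary) points. Stochastic properties are assessed over 10 seeds with
a majority criterion.

## Known limitations

- Ranking full transcriptome-sized gene universes with mRMR is quadratic
  in the number of genes; the intended use is ranking the Boruta-confirmed
  subset (hundreds of genes).
- The feasible-subset rule is a declared surrogate for human inspection
  of IFS curves; different τ values yield different (nested) subsets, and
  the CLI accepts an explicit override.
- MCFS relative importance depends on s, m, t; with small s, rarely drawn
  genes get RI 0 and rank by id among themselves.
- SHAP importances come from one model family (gradient-boosted trees)
  and inherit its inductive bias.
- On real atlases the three rankings need not agree as cleanly as on
  synthetic data; the intersection of feasible subsets can be small or
  empty, which the pipeline reports rather than treats as an error.
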