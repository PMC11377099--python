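# Methods

## Helical-parameter schema

The registry fixes 17 parameters in a canonical order: the intra-base-
pair set (shear, stretch, stagger, buckle, propeller, opening), the
inter-base-pair step set (shift, slide, rise, tilt, roll, twist), four
axis parameters (X/Y displacement, inclination, tip) and the overall
axis bend. Rotational parameters (buckle, propeller, opening, tilt,
roll, twist, inclination, tip, axis bend) are in degrees, translational
ones in ångströms. Axis bend is treated as rotational: it is an angular
quantity and groups with the rotational attributes in downstream
summaries.

Step-wise quantities are defined between successive base pairs, so a
25-mer has only 24 of them while the feature schema needs a common
1–25 level axis. Each step is indexed by its 3′-side base pair (step
i→i+1 stored at level i+1), leaving level 1 undefined. After the
two-base terminus trim this convention makes "bases 3–23" well defined
for all 17 parameters and produces the 17 × 21 = 357 feature count.

## File dialect

Canal-style series files are plain whitespace-delimited text: column 1
is the snapshot time in ns, the remaining columns are base-pair levels;
`#` lines are comments and the literal token `NA` marks undefined cells
(level 1 of step parameters). One file per parameter, named
`<prefix>_<parameter>.ser`. Values are written with six decimals, so a
write/read round trip preserves values to 1e−6 and the defined mask
exactly. Duplicate time stamps are rejected (window trimming depends on
a strict time order). The manifest is a TSV with columns
`gene site sequence methylated_positions adducted hotspot replicate
dataset_tag series_prefix`; booleans are 0/1.

## Feature extraction

* **Equilibration window.** Frames with t ≥ start (and t < end when an
  end is given) are retained. The default start is 10% of each
  record's own span — 10 ns of the nominal 100 ns — so bundles with a
  different span are treated proportionally.
* **Temporal aggregation.** One statistic per (base, parameter) over
  the retained, defined frames; the default is the mean (the standard
  ensemble-average summary), with sd and median selectable. The sd uses
  ddof=0 so a single-frame series has a defined value. A cell with no
  defined frame is an error naming parameter and base.
* **Replicates** remain separate rows; train/test splitting is at row
  level. (Row-level splits let replicates of one site straddle train
  and test; the deployment stage therefore reports on entire unseen
  bundles generated independently.)
* Feature names use an em dash (`14—propeller`); an ASCII hyphen is
  accepted on input.

## Classifier benchmark

The 15 algorithms (nearest neighbours; linear/polynomial/RBF SVM;
Gaussian process; gradient boosting; decision tree; extra trees; random
forest; multilayer perceptron; AdaBoost; Gaussian naive Bayes; QDA;
SGD; LDA) run at scikit-learn defaults. Per seed: a stratified 80/20
split, 10-fold CV accuracy on the training 80% (model-assessment
record), held-out test metrics, and train-test gap = train accuracy −
test accuracy. Multiclass precision/recall/F1 use support-weighted
averaging, which makes accuracy equal weighted recall — the pattern
seen in this kind of benchmark table. ROC AUC is macro-averaged
one-vs-rest with thresholds at unique score values; classes absent from
the evaluation set are skipped with a warning. The default seed list is
0–9. An algorithm that cannot fit a given split (e.g. QDA when a class
has fewer samples than features) is recorded as missing with a warning
rather than aborting the run.

## Random forest and deployment

The grid search enumerates the candidate grid in insertion order and
keeps the first maximum of mean 10-fold CV accuracy, so ties are
deterministic. The shipped default grid spans n_estimators {50, 89,
100, 200}, max_depth {2, 4, 8, none}, max_features {sqrt, log2},
min_samples_leaf {1, 2}, min_samples_split {2, 4}, bootstrap {on, off};
the optimized configuration used throughout (89 trees, depth 4, sqrt,
leaf 1, split 2, bootstrap off) is one of its points.

Deployment evaluates a stratified random ceil(0.95·n) of the unseen
rows (largest-remainder quotas per class, so sampled class counts match
the full set within one). Rows are first put into a canonical order by
their unique metadata key, which makes the evaluated subset — and every
reported metric — independent of the row order of the input file. The
unused 5% plays no role. The window-robustness check rebuilds features
with the analysis window shortened from the tail by a stated fraction
of the span, retrains and redeploys with identical seeds, and reports
metric deltas; with a zero reduction the deltas are exactly zero.

## Feature scoring

Scoring runs on adduct-bound rows with the binary hotspot label.

* **RF importance, CV.** Impurity importances averaged over the 10
  stratified folds' refits, descending; ties keep column order.
* **RFE.** A hand-rolled elimination loop: each round averages
  fold-refit importances and removes the weakest `step` features
  (integer, or a fraction of the starting count). The ranking is the
  reverse elimination order, with within-round order by importance at
  removal, so it is total for any step. Default step is 1; the
  acceptance script and heavier tests use step 0.1 (≈36 features per
  round on the full schema), which preserves the top of the ranking
  while keeping run times in seconds.
* **Lasso.** L1-penalized logistic regression on internally
  standardized features (ranking is therefore scale-invariant), penalty
  chosen by 10-fold CV unless a fixed C is given; ranked by |coef|,
  zero-coefficient features after all others in column order.

Consolidation takes each selector's top n = ⌈0.10 · p⌉ features (36 of
357; the ceiling makes 0.10 × 357 → 36) and scores rank r as
n − r + 1, i.e. 36 for the best, 1 for the 36th, 0 otherwise — the only
off-by-one resolution in which exactly the selected features have
nonzero scores and 0 means excluded. Totals are summed across the three
selectors (raw importances are never rescaled or mixed); global ranks
break ties by matrix column order. The selected set is all features
with nonzero total, hence between n and 3n members.

## Regional GC comparison

Regional GC is the G+C fraction over 1-based inclusive positions 2–12
(methylated C counts as C). This printed range spans eleven bases even
though it is conventionally described as a 10 bp window; the
implementation honors the positional range and exposes both endpoints
as parameters. The comparison is a two-sided permutation test on the
difference of group-mean GC fractions: exhaustive over all C(n₁+n₂, n₁)
group assignments when that count is ≤ 20 000 (exact at the study's
group sizes; 6 vs 6 gives 924 assignments and a smallest attainable
two-sided p of 2/924 ≈ 0.00216), otherwise 10 000 seeded Monte-Carlo
draws with the observed assignment included. Welch's t is available as
an alternative. GC is computed on the adducted strand only; duplex
complementarity makes the value strand-invariant.

## Synthetic data generator

The generator emulates the statistical structure the analysis relies
on, not the physics:

* **Design.** One record per (site, adduct state, replicate). The
  reference-scale preset uses 6 hotspot and 6 nonhotspot sites (named
  after the classic *TP53* codons), triplicate, ± adduct → 72 records;
  bundled cII/lacZ tables provide 5 hotspot + 2 nonhotspot sites each
  with synthetic stand-in sequences.
* **Trajectories.** 1000 frames spanning 0–100 ns (so the 10% window
  drop retains 900). Each (parameter, level) series is a stationary
  AR(1) Gaussian process x_t = φ·x_{t−1} + ε_t (φ = 0.3 by default)
  around B-DNA-like baselines — twist 34°, rise 3.4 Å, deviatory
  parameters centred on 0 — with parameter-typical marginal sds
  (degrees-scale parameters 3–8°, displacement parameters 0.15–1 Å).
  A per-series offset (0.2 × marginal sd, one draw per series) models
  replicate-to-replicate variation.
* **Planted effects** add a mean shift (optionally a variance scaling)
  at chosen (parameter, base) cells, gated on the record's (hotspot,
  adducted) condition. The reference preset plants three kinds of
  signal: local adduct distortion near the lesion (any adducted
  duplex), intrinsic hotspot topology present with or without the
  adduct, and a hotspot-specific adduct response at three cells
  (`23—tip`, `23—rise`, `13—propeller`) that serve as feature-scoring
  recovery targets. All shifts are ≥ 3 marginal sd. The combination is
  deliberate: a four-class problem is only learnable if adduct state
  and hotspot state each leave their own signature, which mirrors the
  empirical observation that adducts distort locally while hotspot and
  nonhotspot duplexes differ even unbound.
* **Sequences.** 25-mers with C fixed at position 6 (methylated) and G
  at 7; every other position is drawn G/C with probability equal to
  the regional GC target (0.80 for hotspot, 0.35 for nonhotspot site
  sets by default), so hotspot sequences are GC-rich around the lesion.
* **Methylation** is metadata-only by default (no dynamical
  perturbation), consistent with treating CpG methylation as having
  limited influence on the observed dynamics; planted effects can
  emulate a perturbation when needed.
* A "Val" analogue is the same configuration re-generated under a new
  seed, mirroring a re-simulation of identical starting structures.

Everything is deterministic given the configuration seed; identical
seeds produce byte-identical series files.

**What passing tests do and do not show.** The generator reproduces
first and second moments, temporal autocorrelation and replicate
variation, but real trajectories have cross-parameter and cross-level
correlations, non-Gaussian tails, slow conformational transitions and
fraying dynamics that it does not model. Passing the suite demonstrates
that the pipeline recovers planted structure under its stated
assumptions — not that the biological findings themselves are
reproduced, which requires the original trajectory data.

## Problem sizes and numerical choices

The test suite and acceptance script run the full 72 × 357
reference-scale matrix for dataset arithmetic, feature selection and
deployment; benchmark-harness properties use narrower toy bundles
(25-mer, 60 frames, 4 sites) where the quantity under test does not
depend on scale, and the permuted-label null calibration uses a
96 × 3 matrix so that covariance-based classifiers remain full-rank
inside their CV folds. Ten seeds are used for recovery rates. Ties are
broken by stable sorts throughout (column order), and all stochastic
components take explicit integer seeds.

## Known limitations

* The analysis operates on per-simulation time averages; per-frame
  learning and distributional features (variance is available as an
  alternative aggregator) are out of scope.
* Backbone torsions and groove geometry are outside the 17-parameter
  schema.
* Deployment across gene contexts with imbalanced site sets (5 vs 2)
  inherits that imbalance; no reweighting is applied.
* The generator's independence across parameters and levels makes the
  feature-selection problem easier than on real data, where correlated
  distortion spreads importance across neighbouring cells.
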