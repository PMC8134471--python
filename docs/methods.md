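# Methods

## Connectivity model

A connectome is a symmetric K×K matrix of Fisher z-transformed Pearson
correlations between node time courses, computed per subject and per task
condition from the raw task time series (task-evoked activity is not
removed; long task blocks make this approximate a continuous-performance
measure). Correlations are clipped to |r| ≤ 1 − 10⁻⁷ before `arctanh`, so a
degenerate perfect correlation maps to a large finite z (≈ 8.4) instead of
infinity; this keeps every downstream edge-wise statistic finite. The
diagonal is stored as zero and never enters the feature space —
self-connectivity is undefined under the Fisher transform.

Edges are flattened in one canonical order, the row-major upper triangle
((i,j), i < j, i then j ascending). Fixing a single ordering makes saved
masks and exported edge lists portable across runs; `vectorize`/
`devectorize` are exact inverses on the off-diagonal. Time-series files
carry a `node_id` column and rows are matched to the atlas by id, not file
position, so a reordered file cannot silently scramble nodes.

## CPM procedure

For each fold of k-fold cross-validation (k = 10 by default):

1. **Selection.** Each edge is correlated with the behavior across training
   subjects only. Edges with r > 0 and p < α form the positive network,
   r < 0 and p < α the negative network (α = 0.01 by default; the threshold
   is configurable and echoed into every output). The selection statistic is
   Pearson by default, with Spearman and partial-Pearson alternatives.
   Zero-variance edges are excluded from both networks.
2. **Strength.** Each network is reduced to one scalar per subject: the sum
   of that subject's edge values over the network mask. An empty mask gives
   strength 0.
3. **Model.** Behavior is regressed on the strength scores by ordinary least
   squares. The `combined` form uses both strengths; `positive_only` /
   `negative_only` fit a single predictor, reproducing the decomposition
   into independent positive and negative predictive models. Constant or
   collinear predictors are dropped with a logged warning; if nothing
   usable remains the fold predicts the training mean — this keeps
   permutation runs, where empty selection is common, well defined.

Held-out subjects are predicted by the fold model that excluded them, so no
quantity computed on a test subject ever influences training (covariate
values of test subjects included). Performance is the Spearman ρ between
assembled out-of-fold predictions and observed behavior — rank-based to
avoid distributional assumptions on a skewed bounded score — plus
RMSE = √(1/n Σ(actual − predicted)²).

The cross-validation is repeated `n_iterations` times (default 100) with
fold assignments drawn from seeds `seed+1 … seed+n_iterations`. The
reported model is the run holding the lower-middle order statistic of ρ
(the ⌈n/2⌉-th smallest): choosing a concrete run, rather than interpolating
between the two middle runs of an even count, guarantees concrete fold
networks exist to localize; the scalar can differ from the interpolated
median by at most the gap between the two middle runs. Consensus networks
are the edges selected in at least `consensus_fraction` of the median run's
folds (default 1.0, i.e., every fold — the strictest rule; the fraction is
exposed because looser conventions exist).

### Covariate adjustment

Two modes, selected by `covariate_mode` and recorded in output:

- `partial` (default): edge selection uses partial correlations of edge and
  behavior given the covariates, computed within the training fold only
  (degrees of freedom n − c − 2).
- `residualize_behavior`: behavior is residualized on the covariates inside
  each training fold before selection and fitting, and evaluation correlates
  predictions with the residualized behavior.

Both keep held-out subjects' covariates out of training. The partial mode is
the default because it adjusts the selection statistic itself, the step where
confounds enter CPM.

## Permutation inference

Cross-validated predictions in different folds share training data, so
parametric p-values overstate the degrees of freedom. Significance is
assessed by shuffling the behavior–connectome correspondence (covariates
stay attached to their subjects), re-running the cross-validated analysis
per shuffle, and computing the one-tailed

    p = (#{ρ_null > ρ_observed} + 1) / (n_perm + 1)

with strict inequality: ties count toward the null. The floor is
1/(n_perm+1) and p = 1 is attainable. Each permutation runs one
cross-validation pass with fresh fold assignments by default: a full
100-iteration median per shuffle is computationally disproportionate, and
under the null a single run is exchangeable with the observed statistic
when the observed model also uses one run. Both knobs
(`iterations_per_perm`, `reuse_folds`) are exposed. Note that when the
observed statistic is the median of many iterations while permutations use
one run each, the test becomes mildly conservative — the variance-reduced
observed statistic is less likely to reach the null's tail. The calibration
analysis therefore uses a single-run observed model, where rejection at
α = 0.05 is exact to within 1/(n_perm+1) granularity.

## Model comparison

Two models evaluated against the same behavior vector give dependent
correlations. They are compared with Steiger's z for correlated correlations
sharing one variable (the pooled-correlation variant): Fisher-transformed
ρ's, with the covariance correction evaluated at the average correlation,
and a two-tailed normal p (the tail choice is recorded in output). All three
correlations entering the test are Spearman — the evaluation metric — so the
comparison is performed on the rank scale, with the prediction–prediction
correlation computed from the stored prediction vectors.

## Localization

A consensus mask is summarized by: per-node degree (selected edges incident
to the node; sums to twice the edge count); the hemisphere partition
(ipsilateral-left, ipsilateral-right, interhemispheric); the long/short-range
split at a centroid-distance threshold (default 60 mm — a conventional cut,
defined nowhere anatomically, always reported alongside results) with a
1-df χ² goodness-of-fit; and symmetric edge-count matrices over the 10
canonical networks and over macroscale regions. The χ² null defaults to the
long/short proportions among *all* atlas edges at the same threshold, asking
whether the predictive network over-represents either range relative to the
connectome as a whole; an equal-odds (50/50) null is available but is
usually a strawman, since the atlas geometry itself is not range-balanced.

## Synthetic data generator

The generator emulates the assumed data-generating process of the analysis,
directly on the Fisher-z scale: each edge is `baseline_e + signal + noise`
with per-edge baselines ~ N(0.3, 0.15) drawn once, noise ~ N(0, 0.2), and
planted positive/negative edges adding ±β·(standardized behavior), with
β = σ·r/√(1−r²) so the population edge–behavior correlation equals
`effect_r` (unit slope in the σ = 0 noiseless limit, where |r| → 1).
Generating z-edges directly, rather than simulating time series, gives exact
control of the planted effect size; realistic fMRI noise spectra, motion
artifacts, and hemodynamics are out of scope, so passing tests demonstrate
the statistical machinery, not robustness to fMRI physics.

Behavior scores are a discretized gamma: a standard-normal latent is pushed
through the gamma quantile function, rounded, and clipped to 0–12. The gamma
parameters (shape 0.80197, scale 2.27540) were root-found so the discretized
distribution's mean and SD equal the target moments 1.79 and 2.04 exactly; a
single n=69 draw still shows sampling noise, especially in the SD of so
skewed a score. The latent-normal construction doubles as a Gaussian copula:
setting `behavior_motion_r` correlates the score with log-motion while
preserving its marginal distribution, which is how the confound scenario
(association carried entirely by motion, via `n_confound_edges` coupled to
motion) is built. Covariates mimic the study cohort: age uniform 8–22 y, sex
0/1 with 45% female, motion lognormal with mean 0.07 mm and SD 0.03 mm,
ADHD/anxiety symptom scores mildly coupled to the behavior, medication
flags, a parent-report score rank-correlated ≈ 0.55 with the child report
(five subjects missing by default), and a 1–9 state-frustration rating.

With `condition_specific` (default), all planted terms appear only in the
frustration matrices; nonfrustration matrices share the per-edge baselines
but are otherwise pure noise, reproducing the state-dependence the analysis
targets. Every dataset is a deterministic function of its seed.

## Numerical choices and problem sizes

- Selection p-values use the t reference via `scipy.special.stdtr`,
  vectorized over all edges of a fold; |r| = 1 maps to p = 0.
- Fold sizes differ by at most one; assignments derive from
  `numpy.random.default_rng(seed)`.
- Symmetry of input matrices is enforced to 10⁻¹⁰; asymmetric input is an
  error, not silently symmetrized.
- Spearman ρ of a constant vector is undefined; a degenerate run (no edges
  selected anywhere, constant predictions) records ρ = 0 with a flag, which
  keeps null distributions defined while marking the run.
- Validation and calibration analyses use scaled-down designs chosen to
  exercise the full pipeline at desk scale: 60-node atlases (1,770 edges)
  for recovery, 40-node (780 edges) for the 100-dataset null-calibration
  grid with 200 permutations per dataset, against the real atlas's 268 nodes
  (35,778 edges) and the conventional 1,000 permutations, which the code
  supports unchanged.

## Known limitations

- The permutation p is exactly invariant to positive affine transforms of
  the behavior, but not to general monotone transforms: out-of-fold
  predictions from different folds sit on different scales, so their pooled
  ranks can shift under a nonlinear transform even with rank-based
  selection. Per-fold ranks are invariant; the pooled statistic is only
  approximately so.
- The median-of-iterations observed statistic versus single-run permutations
  makes the default test slightly conservative (see above); exact
  calibration holds for the single-run observed model.
- The generator plants linear, additive, homoscedastic signal; CPM's own
  assumptions. It cannot detect misspecification that real data might show
  (nonlinearity, heteroscedastic motion coupling, site effects).
- Listwise deletion for missing behavior assumes missingness unrelated to
  the deleted subjects' connectivity.
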