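# Methods

## The problem and the model

Electronic-health-record repositories accumulate laboratory results and
vital signs whose values are occasionally *implausible* — extremely unlikely
to be a fact about any patient (a negative A1c, a troponin of 40,000).
Rule-based screening needs a curated cutoff per observation type and per
institution, which does not scale.  `labsieve` implements an unsupervised
alternative built on two linked assumptions:

1. absent systematic error, implausible records are **sparse** in a large
   extract of any single observation type; and
2. if the values are clustered well, clusters with very small populations
   are where the implausible records live.

For one observation type with values `x(1..n)`, the detector:

1. **shuffles** the rows (seeded), so any source ordering cannot leak into
   the partition;
2. **partitions** them into folds of at most `n_fold` points; folds are
   processed independently (the unit of parallelism), with the coupled
   default `alpha = 1/n_fold`;
3. per fold, **standardises** the values to zero mean and unit sample SD
   and raises them to the **3rd power**.  Cubing a z-score is monotone, so
   nothing is reordered, but both tails are stretched relative to the bulk,
   which is where implausible values concentrate;
4. **approximates the number of clusters** `k` by iterative small-sample
   estimation (below);
5. runs **hybrid hierarchical–K-means** (HK-means): a Ward-linkage
   agglomerative cut at `k` supplies the initial centroids, then Lloyd
   iterations (`C(i) = argmin_k ||x(i) − μ(k)||²`, `μ(k) =` cluster mean)
   refine the partition until assignments stop changing.  Hierarchical
   initialisation removes K-means' dependence on random starting centroids;
6. takes a **census** `p_1..p_k` of cluster populations and flags every
   point whose cluster satisfies `p_k ≤ floor(alpha · fold_length)` —
   with `alpha = 1/n_fold` exactly the singleton clusters.

The sparsity ratio `alpha` is the central tunable.  Eight settings are
pre-wired (`labsieve.ALPHA_GRID`, 1/500 … 1/10,000): liberal ratios flag
more aggressively (higher sensitivity, lower specificity); stringent ratios
approach perfect specificity at the cost of missing grouped implausibles.

## Cluster-number approximation

Scalable `k` selection uses iterative subsampling: draw S = 10 seeded
subsamples of m = 500 points (one estimate on the whole fold when it is no
larger than m), select `k` on each by BIC over one-dimensional Gaussian
mixture fits for k = 1..k_max (default 10), and return the rounded mean of
the subsample estimates.

The mixture fits use a hand-vectorised EM specialised to one dimension.
Components are initialised from the Ward-cut partition of the subsample at
the same `k` (group means, variances and proportions; the linkage tree is
built once per subsample and cut repeatedly).  This gap-aware start
matters: with generic quantile initialisation, EM routinely fails to place
a component on one or two extreme tail points — the likelihood surface has
a local optimum that splits the bulk instead — and `k` is under-estimated
exactly in the folds that contain more than one implausible value.
Numerical guards: component variances are floored at 1e-6 of the data
variance (prevents likelihood divergence on singleton components without
drowning genuinely tight ones); EM runs at most 30 iterations to a relative
log-likelihood tolerance of 1e-6 (it ranks candidate `k`, it does not need
a polished likelihood — detection results on the benchmark are unchanged
versus 100 iterations at 1e-8); the BIC search stops after two consecutive
non-improving `k`.  Inputs are standardised inside the estimator, making it
invariant under affine transforms of the values.

## Numerical and design choices

- **"Scale" = z-score standardisation** (centre, unit sample SD).  Min–max
  scaling was rejected: cubing after min–max would emphasise only the upper
  tail, not both.  The centred values are pre-normalised by their maximum
  absolute deviation so the variance can neither underflow nor overflow;
  strict rank preservation consequently holds up to floating-point
  absorption of sub-ulp differences.
- **Per-fold transform**: standardisation and cubing happen inside each
  fold, so a fold's flags depend only on its own values — the property that
  makes folds embarrassingly parallel.  The flag threshold of a short
  trailing fold uses its own length, not the nominal fold size; a trailing
  single-point fold cannot be clustered and is reported unflagged with a
  warning.
- **Ward linkage on Euclidean distance** for the hierarchical cut.  For
  folds above 2,000 points the linkage runs on a seeded subsample of 2,000
  and the Lloyd refinement assigns the rest; O(n²) linkage on 10,000-point
  folds buys nothing since it only seeds K-means.
- **Lloyd details**: assignment ties go to the lowest cluster index;
  clusters that lose all points are dropped (k reduced), never re-seeded;
  at most 100 iterations, convergence = unchanged assignments.  The
  within-cluster sum of squares is recorded after every assignment step and
  is non-increasing by construction.
- **Flag rule uses non-strict inequality** (`p_k ≤` threshold) and the
  threshold is `floor(alpha · fold_length + 1e-9)` — the epsilon guards the
  floor against the binary representation of rational ratios like 1/3000.
- **HK-means is a heuristic.**  On tiny adversarial instances the Ward cut
  can be suboptimal and Lloyd can converge to a stable non-global fixed
  point (e.g. sorted values [−7.82, −2.92, −2.57, 0.40, 5.99] at k = 2:
  WSS 34.78 against the true optimum 32.86).  On a fixed battery of 1-D
  instances with 20–50 points the refined partition is never below the
  dynamic-programming optimum, matches it in the majority of instances, and
  the mean optimal-to-achieved WSS ratio exceeds 0.95.  Sparse-cluster
  flagging needs well-separated tail points isolated, not a certificate of
  global optimality, so the heuristic's occasional boundary misplacements
  are immaterial to the detector.
- **CAD baselines** are global (full-series mean/SD), with strict
  inequality at the cutoff.  The Mahalanobis critical value is stored as
  the printed constant 3.717526 (the square root of 13.82) rather than a
  recomputed chi-square quantile, for bit-faithfulness to the comparison
  actually run; in one dimension both baselines reduce to the same rule
  with different cutoffs, which the tests assert.
- **Paired detector comparison** uses an exact two-sided binomial
  (McNemar-style) test on the truly-plausible rows where exactly one
  detector flags, null proportion 1/2.  The choice of test here is this
  package's own; it is exact at the small discordance counts the sparse
  regime produces.
- **Silver-standard bounds are inclusive** (a value equal to a bound is
  plausible), and sensitivity is reported as NaN when an observation type
  has no truly implausible rows, rather than 0 or 1.
- Duplicate result rows (same patient/time) are treated as independent
  observations; the readers keep every parseable row.

## The synthetic generator

The generator emulates the regime the detector assumes, not any particular
assay: a lognormal body (non-negative, right-skewed, like most analytes)
rejection-sampled into the plausibility interval `[low, high]`, plus
Bernoulli contamination at rate 0.000576 (0.0576%, the average
implausibility prevalence observed across large silver-standard labelled
extracts) with magnitudes uniform between 2× and 50× beyond the violated
bound — separable but not trivially infinite, honest for sensitivity
measurement.  Truth labels are recomputed from the final values with the
same interval rule the evaluator uses, so generator and evaluation can
never disagree.  The optional systematic-error mode multiplies a fraction
of rows by 100, emulating the unit-error pathology (0.41 recorded as 41)
that breaks the sparsity assumption; in this regime the flagger is
expected to stay highly specific but lose sensitivity, and the scenario is
included in the benchmark suite to document exactly that.

The default benchmark used by the acceptance machinery is ten seeded series
of n = 100,000 (lognormal log-mean 4, log-SD 0.5 inside [0, 1000],
upper-tail contamination at the default rate), swept over the eight
pre-wired ratios with fold size coupled as `1/alpha`.  These sizes keep a
full sweep on one CPU in the tens of minutes while leaving ~58 expected
contaminants per series, enough for stable sensitivity means.

What the generator does **not** emulate: per-assay unit mixtures,
patient-level longitudinal correlation, batch effects, heaped/rounded
reporting, or multimodal reference populations.  Passing benchmarks
therefore demonstrate that the method recovers sparse, tail-placed
implausibles from a skewed body — the regime the method claims — and say
nothing about implausibles hiding inside the plausible range, which
univariate clustering cannot separate by construction.

## Known limitations

- One-dimensional, one observation type at a time; no demographic or
  comorbidity dimensions.
- Grouped implausibles (two or more nearly identical errors in one fold)
  can exceed the flag threshold and escape at stringent ratios; this is
  inherent to the sparsity assumption, and the liberal 1/500 setting
  recovers most of them only because fold sizes are small.
- The cluster-number estimator is a documented stand-in for scalable
  sampling-based k approximation, not a reconstruction of any particular
  published implementation; its criterion (BIC) is pluggable.
- Static extracts only; no streaming operation.
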