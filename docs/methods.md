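# Methods

This note documents the models behind `organmap`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical decisions a user should know before trusting a result.

## Study design assumed

A two-group in vivo design: control (`CON`) and treated (`RPA`) animals;
bulk RNA-seq (FPKM-like, non-negative) of seven vital organs — heart,
liver, spleen, lung, kidney, brain, adrenal — at n = 3 per group, and a
serum NMR metabolite feature table at n = 7 (CON) / 6 (RPA). All stages
only require two groups and feature-by-sample tables, so other designs of
similar shape work unchanged.

## Differential expression

Per gene: Welch's t-test on log2(x + 1) (pseudocount 1, configurable),
Benjamini–Hochberg adjustment across all genes of the organ, and a
linear-scale fold change of group means (treated/control). A DEG must
pass **both** FC > 1.5 (or < 1/1.5; the down-threshold is the reciprocal,
i.e. the criterion is symmetric on the log scale) and FDR < 0.05. Both
cutoffs are strict inequalities. Fold change uses means, not medians; the
choice is a config key. Welch rather than pooled variance because n = 3
per group gives no basis for assuming equal variances. The stage is a
plain function of the matrix, so a count-model test could be substituted
without touching downstream code.

Genes constant across all samples get p = 1 (they cannot be
differential); a group with fewer than 2 samples is an error since no
variance estimate exists.

## Organ effect model

**PC01 summary.** Genes are mean-centered but not variance-scaled —
FPKM magnitudes carry information and unit-scaling 3-sample genes mostly
amplifies noise (scaling is available by flag). The per-sample scores on
the first principal axis and its explained-variance ratio ("contribution
rate") summarize the organ. The SVD sign is fixed by orienting scores so
the treated-group mean is ≥ the control mean; the radar score uses |y|
and is invariant to this convention (property-tested: y is invariant
under positive affine transforms of the scores and flips sign under
negative ones).

**Amplification.** y = (treated mean − control mean) / (pooled max −
pooled min) of the PC01 scores; |y| ≤ 1 by construction. All-identical
scores (zero range) are an error naming the organ.

**Fuzzy weighting.** The DEG total x (up + down by default; up-only and
down-only are options) is fuzzified by four trapezoidal membership
functions with knots 300, 400, 550, 650, 800, 900: term 1 ("least") is
full below 300 and falls linearly to 0 over [300, 400]; term 2 ("less")
rises over [300, 400], plateaus on [400, 550], falls over [550, 650];
term 3 ("more") likewise over [550, 650], [650, 800], [800, 900]; term 4
("most") rises over [800, 900] and is full above 900. The four functions
partition unity for every x ≥ 0 (property-tested over the integer grid
[0, 2000]). The max-operator rule maps x to the weight of the maximal
term: 0.3, 0.5, 0.7 or 0.9. Exact ties occur only at the crossover
midpoints (x = 350, 600, 850); the default tie rule picks the larger
weight — more DEGs read as a stronger effect — making the weight a
monotone step function of x. The knots, weights, term names and tie rule
live in `FuzzyWeightSpec` and can be replaced wholesale.

**Radar score.** |y| × weight per organ, plotted on a polar chart with
one axis per organ in input order. SVG output pins the hash salt and
omits the creation date, so identical inputs give identical bytes.

## OPLS-DA and the metabolite screen

Single binary response, Trygg–Wold algorithm: after mean-centering and
unit-variance scaling (default; Pareto and center-only available, and
recorded in the model), the predictive weight vector w ∝ Xᵀy is computed
once — each orthogonal score is exactly orthogonal to y, so w is
invariant under the filtering. For each of `n_ortho` components (default
1) the y-orthogonal part of the loading is split off, its component
removed from X; one predictive PLS component is then fitted on the
filtered matrix.

* R²X = fraction of preprocessed-X variance captured by all components
  (non-decreasing in `n_ortho`); R²Y = fraction of class variance fitted.
* Q² = 1 − PRESS/SS under stratified K-fold CV (default 7 folds, the
  chemometrics convention), refitting the entire model — including
  orthogonal filtering — inside each fold. Stratification keeps both
  classes in every training fold at n ≈ 13.
* VIP is computed on the predictive component only (the
  discriminant-relevant variation; several multi-component VIP variants
  exist and this one is the least ambiguous for OPLS): with a single
  component the defining formula collapses to VIPⱼ = √p · |wⱼ| / ‖w‖,
  so mean(VIP²) = 1 holds exactly (property-tested on random models).

Constant features are dropped with a warning before scaling. In the
separable-data limit R²Y → 1 as orthogonal components are added; with
`n_ortho = 0` the model is exactly single-component PLS-DA and its
predictions are tested for equality against an independently coded NIPALS
PLS1 oracle and against scikit-learn's PLS.

**Screen.** A feature is a differential metabolite when VIP > 1.0
(strict) and a two-sample t-test gives p < 0.05 (strict; Welch by
default, pooled available). Output is sorted by descending VIP — the
conventional screen tabulation. No multiplicity correction is applied to
the screen's t-tests, matching standard practice where VIP acts as the
primary filter; at 60 features this admits a few false positives by
design, which the tests quantify.

**Correlation network.** Pairwise Pearson r across samples; two-sided
p-values from the exact t transform; BH adjustment (configurable, also
Bonferroni or none); edges kept at |r| ≥ 0.6 and adjusted p < 0.05
(defaults; both are config keys — no canonical thresholds exist for this
kind of network). Signs are stored so negative co-variation is
representable. Constant features are excluded with a warning.

## Dimension-reduction × classifier benchmark

Six reductions: PCA, t-SNE, Laplacian eigenmaps, Isomap, LLE (scikit-
learn) and a per-sample 1-D discrete wavelet transform (Daubechies-4,
maximal depth), retaining the k coefficients with largest cross-sample
variance. Default k = 2, configurable. Inputs are standardized per
feature before embedding. The manifold methods have no out-of-sample
transform, so embeddings are computed once on all samples and repeated
stratified k-fold CV runs on the coordinates; this mild transduction is
shared by all cells and is the standard way such recognition tables are
produced. The scheme and seeds are recorded in the result.

Five classifiers: Gaussian NB; random forest (100 trees); BPNN = one
hidden layer of ⌈(d + 2)/2⌉ units trained by L-BFGS with α = 0.01 and
five seeded restarts keeping the best training fit (L-BFGS on ~20
samples otherwise lands in init-dependent local minima); kNN (k = 3);
SVM with RBF kernel and γ = 'scale' applied to the raw embedding
coordinates. The SVM deliberately does **not** standardize embedding
dimensions: coordinates arrive variance-ordered (PCA, WT) or on a common
scale, and per-dimension standardization inflates pure-noise axes to
parity with the signal axis, breaking the separable-data ⇒ 100% property
the harness is validated against. Cell values are mean held-out accuracy
in percent; row and column means give the per-reduction and
per-classifier summaries. Per-cell fit timings are logged at debug level
but never asserted — they are hardware facts, not properties of the
method.

**ROC feature model.** Inside each CV training split, features are
ranked by absolute Welch t-statistic and the top m (default 20) kept —
selection inside the split, so held-out scores are leakage-free. An
RBF-SVM (standardized inputs here: raw features have heterogeneous
scales) produces held-out decision scores pooled across all splits into
one ROC curve; AUC is its trapezoidal integral. The 95% CI is a
percentile bootstrap (default 1000 resamples) over the pooled (score,
label) pairs; a selection-frequency table across splits exposes which
features drive the model.

## Synthetic data generator

Expression: per-gene baseline ~ Uniform(2, 10) in log2 space; sample
values add Gaussian noise (sd 0.4 default) and are exponentiated, giving
non-negative FPKM-like values. The first `n_true_degs` genes of an organ
receive a treated-group shift of `effect_size × noise_sd` log2 units,
signs alternating +,−,+,… so up/down counts are reproducible exactly.
Metabolome: baselines ~ Uniform(5, 20), Gaussian noise (sd 1.0),
differential features shifted by `metab_effect_size × metab_noise_sd`
with alternating signs; optional (i, j, ρ) triples regenerate feature j
as a ρ-correlated copy of feature i for network tests. Each organ and
the metabolome draw from independent RNG streams derived from
(seed, name) via CRC32 — outputs are pure functions of the config,
insensitive to call order.

Default effect configuration: organ response is modeled mainly through
the **number** of affected genes — liver 920, brain 626, adrenal 400,
others ≈ 100–150 (of 3000; counts scale proportionally if the gene count
is changed) — with standardized per-gene effects of 6 (liver, brain), 4
(adrenal) and < 1 elsewhere, strong enough for a meaningful fraction to
be detectable at n = 3 as in the motivating design. Liver and brain
counts are the totals reported in the study this design emulates.

What the generator does **not** emulate: RNA-seq count noise
(overdispersion, library-size effects — expression is i.i.d. log-normal),
gene–gene correlation within organs, NMR spectral artifacts (baseline,
peak overlap, binning), or any real metabolite identities. Passing tests
therefore demonstrate the pipeline's statistical correctness under a
clean generative model, not performance on real spectra or counts.

## Numerical choices and degenerate inputs

* BH monotonicity and strict-inequality thresholds are relied on by
  tests; boundary cases (FC exactly 1.5, VIP exactly 1.0) are excluded.
* PCA/OPLS-DA use exact SVD / closed-form NIPALS steps — no iterative
  tolerance is involved at these problem sizes.
* All-constant matrices, single-class labels, zero PC01 range, unknown
  organ or method names, k beyond a method's limit, duplicate feature
  IDs and non-numeric cells raise errors naming the offender.
* Test and validation problem sizes (e.g. 300–2000 genes, 100–200
  simulation replicates, 30 permutations, 50 radar-ranking runs) were
  chosen as the smallest sizes at which the Monte-Carlo error is clearly
  below the margins being asserted.

## Known limitations

* At n = 3 per group the DEG caller recovers only ~40–85% of truly
  affected genes depending on effect size; organ weights computed from
  *recovered* counts are therefore conservative relative to weights from
  the true counts. This mirrors the real small-n setting.
* The fuzzy knots (300…900) are calibrated to DEG-count scales of a few
  hundred to ~1000; studies with very different DEG yields should
  supply their own `FuzzyWeightSpec`.
* The benchmark's transductive embeddings mean its accuracies measure
  class structure in the embedded sample set, not out-of-sample
  generalization; the ROC feature model is the leakage-free alternative
  and should be preferred for biomarker claims.
* Q² uses one CV scheme (stratified K-fold); leave-one-out or Monte-
  Carlo CV would give slightly different values at these sample sizes.
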