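# Methods

`crossomics` benchmarks machine-learning models that predict one
microbiome omics layer from another — transcripts (mTx), proteins
(mPx) or metabolites (mBx) from genes (mGx) or multi-omics
concatenations — and asks two questions: *which output features can be
predicted reliably across resampled cohorts*, and *is predicted data
useful for a downstream disease-classification task*.  Real paired
cohorts are rare and cannot be redistributed, so the package ships a
synthetic-cohort generator with planted ground truth; every pipeline
property is validated by parameter recovery on that generator.

## Preprocessing

Abundance tables are samples × features, nonnegative, tagged with
modality and scale (relative fractions or raw counts).

* **Total-sum scaling (TSS).** Each sample row is divided by its sum so
  rows sum to 1 (closure).  All later steps assume compositional rows.
* **Zero imputation.** Relative tables receive ε = 1e-7 added to every
  entry; count tables receive a pseudocount of 1.  Relative tables are
  re-closed after imputation so the CLR transform still operates on a
  composition (the re-closure is this package's choice; it changes
  entries by at most a factor 1 + Dε).
* **Feature filtering.** Two variants of a prevalence-at-abundance
  rule.  *Lenient*: keep a feature iff its relative abundance reaches
  5e-5 (0.005%) in strictly more than 10% of samples and it has at most
  95% zeros.  *Strict*: threshold 1e-4 (0.01%), plus an exclusion of
  features below 1e-6 (0.0001%) in more than 10% of samples — exact
  zeros count as below that cut, which makes strict filtering very
  aggressive on sparse modalities (on a 70%-zero synthetic table it
  removes everything; the lenient filter is the pipeline default).
  All "more than 10%" comparisons are strict; a tie at exactly 10%
  fails.  Filtering can run globally (reproducing a fixed published
  preprocessing) or on the training slice of each split (the
  leakage-free mode used by the leakage audit); global is the default.
* **EC de-stratification.** Taxon-stratified functional features
  (`"1.1.1.1|g__Escherichia"`) are summed per EC number; the delimiter
  defaults to `|` and is configurable.  Total mass per sample is
  conserved.
* **Pairing.** Input and output tables are restricted to their common
  samples; multi-omics inputs are column-concatenated with
  modality-prefixed feature ids.

## Transforms

* **CLR** `clr(x)_i = log(x_i / g(x))`, `g` the row geometric mean;
  requires strictly positive closed rows; output rows sum to 0.
* **arcsin-sqrt** `arcsin(√x_i)`; handles zeros without imputation.
* **Quantile-to-normal.** Per feature, the empirical CDF of the
  *training* values composed with Φ⁻¹.  The convention is pinned for
  bit-stability: plotting positions (rank − ½)/n with average positions
  for ties, linear interpolation between training quantiles, unseen
  values clamped to the training range.  Constant training features map
  to all-zeros with a warning.  Fitted state serializes to JSON.

Each regressor declares a default input/output pairing; the elastic
net uses quantile/quantile (the MelonnPan-style treatment, extended to
the outputs), the forest arcsin/arcsin, the network quantile/quantile.
Predictions are evaluated against the truth mapped through the *same
fitted output transform*.  For per-feature monotone transforms this is
identical to comparing on the raw scale, because the evaluation
statistic is rank-based; CLR is not per-feature monotone (it subtracts
a row statistic), so the transformed-space convention is stated here
explicitly.

## Partitioning

Splits operate on patients, never samples: longitudinal samples of one
patient are correlated, and sample-level splits would leak patients
across sides.  Within each diagnosis class (UC / CD / HC), patients
are shuffled by a per-split seed and divided 80/20 with the test count
rounded up, so per-class test counts stay within one patient of the
stratified target.  Ten splits with seeds 0–9 are the default
protocol; plans serialize to JSON.  Inner cross-validation (elastic-net
penalty selection, classifier search) uses patient-grouped folds built
the same way.

## Models

* **Elastic net** (the reference model): one linear model per output
  feature, L1/L2 mixing fixed at 0.5, penalty chosen per feature by
  10-fold patient-grouped cross-validation over a 13-point grid
  10⁻⁴…10¹.  Constant transformed outputs get a flagged constant
  predictor.
* **Random forest**: one multi-output `RandomForestRegressor` with
  library defaults and seed 42.
* **Feed-forward network**: multi-output MLP (2 hidden layers,
  256/128, ReLU, Adam, L2 1e-3, 400 epochs, seeded).  Optional
  training-set augmentation appends jittered copies (Gaussian noise,
  SD = 0.1 × per-feature training SD, in transformed space) until the
  set is `augmentation_factor` × its original size.  A configuration
  with no hidden layers is trained as an exactly linear model.  These
  architecture values are this package's declared defaults.
* **Autoencoder + elastic net** (multi-omics only): a linear encoder
  W, decoder V and regression head U minimising
  ‖X − XWV‖² + λ‖Y − XWU‖² by exact alternating least squares — each
  block update is a closed-form minimiser, so the recorded joint loss
  is non-increasing without any learning-rate tuning, and training is
  deterministic (PCA initialisation with fixed sign convention).  After
  training, the elastic net is fitted on the frozen latents XW.
  Defaults: latent dimension 16, λ = 1, 30 cycles.
* **Feature-selection pre-training**: 10 patient-grouped folds on the
  training partition; per fold a forest is fitted and per-feature
  Spearman scored on the fold's validation part; scores are averaged
  and the top `keep_fraction` of output features retained (floor; ties
  broken by feature id).

## Evaluation

Per output feature, Spearman's rank correlation between prediction and
truth on the held-out samples (average ranks for ties; a constant
vector makes the statistic undefined and is recorded as 0 with a
flag).  Across the 10 splits: per-feature mean and SD; the reported
summary is the mean over the top-k features by per-feature mean
(k = 50 on real-scale tables; ties at the boundary resolved by feature
id) with the error defined as the mean per-feature SD over those
features.

Robustness analyses: pairwise Jaccard similarity of the top-25%
best-predicted sets across splits or input types, with the all-way
intersection as the "core" set; association of feature variance
(test-set truth, averaged over splits) with prediction quality
(two-sided Spearman); Fisher's exact test (scipy's exact
hypergeometric implementation) for over-representation of EC classes
(first EC digit) among the top 10/25/50% of features; Mann–Whitney U
for between-model and between-classifier comparisons (exact null when
both samples are ≤ 50 without ties, normal approximation with tie
correction otherwise).

## Downstream classification

UC and CD collapse to one IBD label.  Fairness protocol: for one
input→output task, all data sources (input features, predicted
features, ground-truth features) use the same samples, and each
training set is subsampled to exactly equal IBD/HC counts,
deterministically under the split seed.  The classifier is a random
forest tuned by randomized search (balanced-accuracy scoring,
patient-level stratified 5-fold inner CV, refit on the balanced
training set); the search grid — trees 100…1000, depth {None, 4…32},
min leaf {1…8}, feature subsampling {sqrt, log2, 0.3} — is a declared
package default.  The search runs 50 iterations by default; the
bundled acceptance runs use 5 iterations, a problem-size choice (a
measurement on the reference cohort showed 3 vs 5 vs 10 iterations
changes the mean balanced accuracy by < 0.01, so search depth is not
what limits accuracy at these sizes).  A stratified-sampling dummy
classifier is the chance baseline.  Metrics: balanced accuracy
(headline), ROC-AUC, and IBD-class precision/recall/F1; ROC-AUC on a
single-class test set is reported as missing.

## Synthetic cohorts

The generator emulates the statistical regime of paired gut-microbiome
data; no generative description of real cohorts exists, so all
distributional choices are declared stand-ins:

* Input latents `z = μ_i + a_patient + class shift + ε`, with feature
  baselines μ ~ N(0,1), patient intercepts a ~ N(0, 0.5²) shared by a
  patient's samples (the within-patient correlation that motivates
  patient-level splits), and unit noise.
* Planted signal outputs are sparse linear combinations (5 parents,
  weights ±U(0.5, 1.5)/√5) of the **row-centered** latents — centering
  is exactly what survives closure, so the planted map is linear in
  CLR space and elastic-net recovery is a valid oracle — plus Gaussian
  noise scaled so var(signal)/var(noise) = `signal_strength`.
  Non-signal outputs are independent noise.
* Diagnosis (UC/CD/HC at 0.3/0.3/0.4) is assigned per patient; IBD
  samples receive an additive log-scale shift (`class_effect_size`,
  default 1.0) on `n_class_features` features in both modalities, with
  the output-side class features drawn from the signal outputs first so
  the class signal is predictable from the inputs.
* Observation: latents are exponentiated, closed to sum 1, zeroed to
  the per-feature target sparsity, and re-closed.  Zeros default to
  detection-limit censoring on the composition (the lowest relative
  abundances of each feature are recorded as zero — the dominant
  mechanism for zeros in sequencing/MS data, and one that preserves the
  monotone planted map); independent Bernoulli masking is available via
  `zero_mechanism="bernoulli"`.
* One seed feeds named substreams (labels, intensity, presence, noise),
  so changing one component's draw count leaves the others untouched.

The reference fixture is 40 patients × 5 visits (200 samples), 100
input / 50 output features, 10 signal outputs at signal-to-noise 5,
seed 0, with no structural zeros (sparsity is exercised explicitly by
the sparsity-targeted tests and the `sparse` analysis cohort, which
uses 70% / 50% zero-inflation).  What passing recovery tests show is
that the pipeline's estimation, splitting and scoring machinery are
correct under the planted model; they do not show that real cohorts
satisfy that model — real data add compositional dependence beyond
closure, batch effects, nonlinear coupling between layers and
technology-specific noise that the generator deliberately omits.

## Numerical choices and degenerate inputs

Closure tolerance 1e-9; CLR requires strictly positive rows and
refuses un-imputed zeros; abundance matrices are materialised
C-contiguous so reductions are bit-reproducible regardless of the
originating container's memory layout (this makes the leakage audit's
bit-identity assertion meaningful).  Constant features: flagged
score 0 in evaluation, constant predictor in the elastic net, all-zero
quantile mapping with a warning.  Ties: average ranks in all rank
statistics; top-k boundaries and feature selections break ties by
feature id so every ranking is deterministic.  All-zero sample rows
are rejected with the sample named; generator configurations whose
sparsity would zero out a feature or a sample everywhere are rejected
up front.

## Known limitations

The generator's linear planted map favours the elastic net by
construction; relative model rankings on synthetic data (elastic net >
forest > network at these sizes) should not be read as statements
about real cohorts.  On the reference cohort the ground-truth-trained
IBD classifier reaches a mean balanced accuracy of ≈ 0.79 over the 10
default splits — the fixed log-shift of 1.0 lands on the
higher-variance signal outputs and is partly redistributed by closure,
and test sets hold only 8 patients, so split means carry an SD of
≈ 0.02.  The strict filter's low-abundance rule counts zeros as
low-abundance values, which can empty heavily zero-inflated
modalities.  The autoencoder is linear; a nonlinear encoder-decoder
family is represented only by its linear member.
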