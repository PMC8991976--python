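# Methods

This note documents the models and procedures implemented in `g2pbench`,
the assumptions behind them, the defaults that matter, and what the
synthetic data generator does and does not emulate.

## The problem

Genomic selection predicts phenotypes of crop lines from genome-wide SNP
genotypes. The package benchmarks four non-linear model families —
XGBoost, random forest, a 1D convolutional network (CNN) and a multilayer
perceptron (DNN) — on that task, then closes the loop from prediction
back to biology: the fitted XGBoost model is interpreted feature-by-
feature, the most informative SNPs are clustered into genomic Regions of
Importance (ROIs), those regions are cross-checked against an independent
single-marker association scan, and finally the marker panel is reduced
to the target regions and the benchmark re-run to quantify how much
signal a small targeted panel retains.

## Preprocessing

Input is a VCF of diploid biallelic SNP calls plus a phenotype table.
Calls map to four states (ref-hom, het, alt-hom, missing). Filters, in a
fixed order chosen for reproducibility:

1. **Line filter** — drop lines with strictly more than 1% missing calls
   (fraction `line_max_missing = 0.01`; "more than" is strict, so a line
   at exactly 1% stays).
2. **SNP filter** — keep SNPs with minor allele frequency ≥ 0.05
   (computed over non-missing calls; the minor allele is whichever is
   rarer in sample) and missing rate strictly below 10%. A SNP with every
   call missing has no defined MAF and is dropped with a log warning.
3. **Sequential thinning** — keep every `keep_every`-th SNP in genome
   order (default 20, a 95% reduction). Thinning exists for panels of
   millions of markers; desk-scale configs set `keep_every = 1`.

**One-hot encoding.** Each SNP contributes one binary column per genotype
class *observed at that SNP* (a class absent from the sample would be a
constant-zero column and is not emitted). A missing call encodes as
all-zero across the SNP's columns — no imputation. The `FeatureIndex` is
a bijection from column position to (SNP, genotype class), so any model
feature can be decoded back to a SNP and an allele pair (e.g. het at
ref=A/alt=T renders "A/T"). Decoding an id not emitted by that particular
encoding raises rather than silently answering from the wrong index.

**Holdout.** 20% of lines (round-half-up), uniform at random without
replacement; an optional stratified mode exists but is off by default
because the sampling design here is simple random exclusion.
Train/holdout disjointness is enforced by line id at evaluation time and
an overlap is a hard error, not a warning.

## Model families

All four families consume the same one-hot matrix; the CNN reads it as a
length-`n_features` single-channel sequence in genome order.

* **XGBoost** — `hist` tree method, single-threaded for bit
  reproducibility. Multiclass tasks use `multi:softprob` with the class
  count; binary tasks `binary:logistic`; regression the default squared
  error. Hyperparameters are tuned (below) or left at library defaults.
* **Random forest** — 100 trees, square-root feature subsampling, fixed
  random state.
* **CNN** — three 1D convolution stages with 12/10/8 filters and kernels
  14/10/8 (ReLU), dropout 0.20 between stages 1–2 and 0.10 between 2–3,
  then max-pool of size 2, batch normalisation, flatten, and dense layers
  48/32/16 each followed by batch normalisation. The kernel/pool chain
  consumes 30 positions, so the CNN requires at least 31 input features
  and says so when given fewer.
* **DNN** — dense layers 200/100/64/32/16 (ReLU), dropout 3/2/1% after
  the first three, batch normalisation after the final dense layer.
* **Output heads** — 1 linear node (regression), 1 sigmoid node
  (binary), `n_classes` softmax nodes (multiclass).

The two networks run on the package's own small numpy engine
(`g2pbench.nn`): dense, valid-padding 1D convolution, batch
normalisation, inverted dropout, max pooling, and the Adamax optimiser at
learning rate 0.003 with mini-batches of 1/50th of the training-set size.
Everything is deterministic under a seed.

Training-loop choices (the architecture fixes everything except how long
to train): at most 200 epochs with early stopping on a 10% validation
slice of the training data, patience 20, restoring the best weights seen.
Two stabilisation choices matter at small sample sizes: output heads are
**zero-initialised**, so the untrained network predicts the base rate (or
the mean, for regression), and the untrained network is the first
"best weights" candidate, so training can never end worse on the
validation slice than where it started. Regression targets are
standardised internally (mean/SD of the training fold) and predictions
mapped back, so the Adamax step size is scale-free.

## XGBoost hyperparameter search

Bayesian (sequential model-based) optimisation over the space:
learning_rate [0.01, 1] (log), min_child_weight [0, 10], max_depth
[0, 50] (integer; 0 = unlimited under `hist`), max_delta_step [0, 20],
subsample / colsample_bytree / colsample_bylevel [0.01, 1], reg_lambda
[1e-9, 1000] (log), reg_alpha [1e-9, 1] (log), gamma [1e-9, 0.5] (log),
n_estimators [50, 200] (integer), scale_pos_weight [1e-6, 500] (log,
binary tasks only). The objective is mean 3-fold inner-CV accuracy
(classification) or negative RMSE (regression). A handful of random
evaluations seed a Gaussian-process surrogate (Matérn 5/2 on the unit
hypercube, log-scaled dimensions where the range spans decades);
subsequent iterations take the expected-improvement maximiser over a
256-point candidate pool. Default budget 25 iterations; deterministic
under the search seed.

## Cross-validation and metrics

k = 10 folds, stratified for classification and plain for regression,
shuffled under a fixed seed. All k fold models are trained; the one with
the best fold-validation score (highest accuracy / lowest RMSE) is kept
as-is and used for holdout prediction — it is not re-fit on the full
training set.

* classification: accuracy = 100 × correct/total;
* regression: **RMSE as a percentage of the trait mean**, where the
  denominator is the mean of the *full* (train + holdout) trait values,
  fixed per trait before splitting, so the figure is comparable across
  models and datasets. An algebraic identity used as a test oracle: the
  constant-at-mean predictor scores exactly 100 × SD/mean on the
  evaluated set.

**Comparison summaries.** "XGB−DL" for classification is the mean over
traits of XGB accuracy minus the unweighted mean of the CNN and DNN
accuracies; for regression it is the DL mean error minus the XGB error,
so a positive number always favours the tree model. The best-model tally
counts the winning family per trait × dataset cell; ties break toward
the earlier family in the fixed order XGB, RF, CNN, DNN (and are logged).

## Interpretation: gain ranking and ROIs

Feature importance uses the booster's **gain** — the total training-
objective improvement of all splits on a feature. Ranking operates per
one-hot feature (so one SNP can appear under several genotype classes;
an optional per-SNP aggregation that sums a SNP's column gains is
available but off by default). Gain ties break by (chromosome, position)
for a stable order. The top 20 features are decoded to SNPs via the
feature index.

**ROI clustering** chains the ranked SNPs per chromosome by single
linkage: two SNPs join when their gap is ≤ 100 kbp, and a chain with at
least 3 *distinct* SNPs becomes an ROI spanning its min/max member
positions. Chaining (nearest-neighbour gaps) rather than a clique
criterion (all pairwise gaps) is used because the constraint is stated
on nearest neighbours; the two differ only on chains longer than the
gap bound. Duplicate entries of one SNP count once toward the size but
all contribute to the ROI's summed gain.

**Target regions** for panel reduction are the ROI spans, optionally
flanked (`flank_bp`, default 0, clipped at position 1), merged where
they overlap. When a trait yields no ROI, the fallback is a ±250 kbp
window around each top-ranked SNP — an explicit package decision for the
"no ROI" case, conservative and configurable.

## GWAS scan

The scan is deliberately a covariate-adjusted single-marker
generalised-linear-model scan, **not FarmCPU**: the iterative
pseudo-QTN fixed/random-effect alternation is out of scope, and this
scan stands in wherever a threshold-comparable locus list is needed.
Population structure is captured by the top 3 principal components of
the column-centred dosage matrix (missing dosages imputed to the per-SNP
mean before both the PCA and the scan).

* Continuous traits: exact t-test of the dosage coefficient in
  `y ~ dosage + PCs`, vectorised over SNPs by residualising phenotype
  and dosages against the covariates (Frisch–Waugh) with the correct
  residual degrees of freedom.
* Binary traits: Rao score test of adding the dosage to the logistic
  null `y ~ PCs` (null fitted once; the per-SNP statistic is closed-form
  and vectorised). The reported effect is the one-step coefficient.
* Multiclass traits: one-vs-rest score tests per class; each SNP reports
  its minimum p multiplied by the class count (Bonferroni over classes),
  capped at 1. This is a package convention, logged as such.

Monomorphic SNPs cannot be tested and record p = 1 with a log flag.
Significance uses the Bonferroni-style threshold α/m with α = 0.05 over
the m tested markers. ROI–locus overlap pairs each ROI with the
significant loci inside its span widened by a proximity window
(default 250 kbp).

## Synthetic data generator

The generator produces what the analysis assumes and nothing more:

* **Genome map** — uniform SNP placement along each chromosome;
  strictly increasing positions; random distinct ref/alt bases.
* **Genotypes** — each line is two independent haplotypes (near
  Hardy–Weinberg). LD is modelled by tiling chromosomes into blocks of
  `ld_block_span_bp`; within a block each haplotype holds one latent
  uniform draw, and each SNP copies the latent indicator with
  probability `within_block_correlation` or draws a fresh Bernoulli
  otherwise. This keeps per-SNP marginal allele frequencies exact while
  giving tunable local r², without coalescent machinery. Target MAFs are
  uniform over `maf_range`; a coin flip decides which allele is minor.
  An optional two-subpopulation mode shifts per-subpopulation allele
  frequencies by up to `subpop_divergence`, giving the structure signal
  that the scan's PC covariates are meant to absorb. Missingness is
  uniform at random — the pipeline filters on rates, not mechanism.
* **Categorical traits** — a penetrance table maps the genotype at 1–2
  major loci to class probabilities (degenerate rows give a perfectly
  predictable trait, the end-to-end smoke case; a dominant two-class
  helper and a codominant three-class helper are provided). Missing
  causal genotypes fall back to the SNP's modal call.
* **Continuous traits** — additive dosage model; Gaussian noise scaled
  to `var(g)·(1−h²)/h²` so realised variance explained matches the
  target heritability (pure unit-variance noise at h² = 0); a baseline
  of 50 keeps the mean positive because the regression metric divides by
  the mean.

What the generator does **not** emulate: coalescent genealogies,
recombination maps, allele-frequency spectra of real germplasm panels,
genotype likelihoods or dosage uncertainty, multi-allelic sites, indels,
dominance or epistasis (an interaction term can be added by composing
traits, but none is generated by default), and any real soybean LD
landscape — block span and correlation defaults are free parameters, not
estimates. Consequently, passing tests demonstrate that the machinery is
correct and well calibrated under the stated generative model; they do
not demonstrate prediction accuracy on real crop data.

## Numerical and design choices

* Seed discipline: one master seed per experiment; each stage derives
  its seed by a fixed offset, so stages are independently reproducible.
  XGBoost/random-forest stages are bit-reproducible (single-threaded,
  fixed random state); network training is reproducible because the
  engine is pure numpy under seeded generators.
* Filter direction readings: "over 1% missing" for lines is strict;
  the SNP missing-rate rule is read as retain-if-below-10%.
* Holdout size rounds half-up; degenerate fractions (empty train or
  holdout) are rejected.
* Coordinates are 1-based; region intervals are closed on both ends
  (VCF convention); region extraction keeps genome order and reports the
  retained fraction.
* Monomorphic / degenerate inputs: constant phenotypes are rejected in
  the scan; single-class labels are rejected in tuning; a class with
  fewer members than k is rejected by stratified CV with the class named.
* Deep-learning stages are optional per config (`include_dl`); when off,
  comparisons cover XGBoost and random forest only and the report says
  so. If a reduced panel has fewer encoded features than the CNN's
  31-feature minimum, the CNN is skipped on that panel with a warning.

## Problem sizes in tests and the acceptance script

Simulation-backed checks run at desk scale, chosen so the full suite and
the acceptance script each complete in minutes on one CPU: panels of
160–5,000 SNPs, 200–2,000 lines, 10-seed repetition for recovery and
power rates, 200 replicates for the type-I-error rate, and 300–1,000
fuzz cases for oracle-equivalence and round-trip checks. The
`make_demo_config` helper builds a 200-line, 160-SNP two-chromosome
run whose causal locus is the highest-MAF SNP in the panel, so all three
genotype classes are populated and stratified 10-fold CV is feasible.

## Known limitations

* The GWAS stand-in tests marginal association only; it will not
  iterate pseudo-QTNs or fit kinship random effects, so its locus lists
  are conservative in structured populations beyond what 3 PCs capture.
* Gain-based ranking is only defined for the tree-ensemble models;
  CNN/DNN attribution (e.g. SHAP) is out of scope.
* The numpy network engine is single-threaded and desk-scale; it is not
  intended for panels beyond a few tens of thousands of features.
* With the all-zero encoding for missing calls, a line with many missing
  genotypes shrinks toward the intercept/base rate; the 1% line filter
  keeps this effect negligible.
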