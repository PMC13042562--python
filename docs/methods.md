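# Methods

This note documents the models and procedures implemented in `pathomil`, the
defaults and why they were chosen, what the synthetic-data generators emulate
(and what they deliberately do not), and the package's numerical choices and
known limitations.

## Pipeline overview

The pipeline turns a bag of H&E tiles per patient into a scalar prognostic
score in five stages:

1. **preprocess** — tiling, background removal, Macenko stain normalization,
   Z-scoring, augmentation;
2. **patch_scorer** — patient-level prognosis labels, backbone training,
   two-decimal patch probabilities/labels, Grad-CAM heatmaps;
3. **mil_features** — per-patient histogram and TF-IDF bag-of-words encodings
   over a fixed vocabulary, fused into 206 features;
4. **signature** — correlation filter → univariate Cox screen → LASSO-Cox,
   yielding the linear pathomics score and a log-rank-optimal risk cutoff;
5. **survival_eval** — KM/log-rank, Cox models, frailty model, Harrell's C,
   time-dependent AUC, heterogeneity, subgroup analyses.

## Preprocessing

Tiles are non-overlapping 512 × 512 squares on a 0-based, row-major grid with
half-open pixel intervals; partial edge tiles are discarded, which makes the
tiling exactly invertible over the covered region. Magnification (nominally
20×) is treated as metadata; no pyramid resampling is performed.

A tile is background when the fraction of pixels whose darkest channel
exceeds 220 is strictly greater than 0.5. Both constants are arguments: the
qualitative rule ("predominantly white") admits a family of thresholds, and
these defaults are intended as a sensible, configurable center of that
family. Filtering runs after tiling and before color normalization, because
normalization is undefined on tiles without tissue.

Macenko normalization uses optical density `OD = -log((I+1)/256)` — the +1
keeps zero-intensity pixels finite — with standard published constants:
tissue mask `OD > 0.15` in all channels, angular percentile α = 1, maximum
concentrations at the 99th percentile. The two stain vectors are the α and
100−α angular percentiles of tissue ODs inside the plane of the top two
singular vectors, sign-fixed nonnegative, hematoxylin ordered before eosin by
red-channel OD. Applying a normalization solves least-squares concentrations
in the source basis, rescales them by the ratio of target to source maximum
concentrations, and recomposites in the target basis; concentrations are not
clipped at zero, so pixels slightly outside the two-stain cone round-trip
faithfully (output RGB is clipped to 8 bits). On Beer–Lambert phantoms this
makes self-normalization exact to ±2 intensity levels. Fitting requires at
least 100 tissue pixels; all-white input raises `NormalizationError`.
Phantoms contain no white background, so tests fit them with a permissive
`od_threshold=0.03`; the 0.15 default is for real H&E tiles, where it
excludes near-white pixels.

Augmentation crops to 448/512 of the side (448 on a standard tile; the crop
size is configurable since only "random cropping" is specified), resizes
back bilinearly, and flips horizontally/vertically with probability 1/2
each, all driven by an explicit seed.

## Patch scoring

Prognosis labels: recurrence (event) at ≤ 12 months → *poor*; recurrence-free
for more than 36 months (event or censoring after 36) → *good*; everything
else → *intermediate*. Intermediate patients are excluded from classifier
training but retained for signature construction and evaluation, since only
the two extreme classes define the classification task while the survival
model uses all patients.

Training uses softmax cross-entropy, per-epoch learning rates from the cosine
schedule `eta_t = eta_min + (eta_max−eta_min)/2·(1+cos(π·T_cur/T_i))`, and
early stopping once validation loss has failed to improve for
`early_stop_patience` consecutive evaluations (one evaluation per epoch).
Reference configurations are stored as printed: conventional CNNs at initial
rate 0.01 for 8 epochs; transformer-style models at 0.001 for 16 epochs with
patience 128.

The backbone is a plugin contract — `predict_proba(tiles)` plus
`activations_and_gradients(tile, class)` — and the shipped reference backbone
is a deliberately small NumPy CNN: inputs downsampled to 32 × 32 and
Z-scored, one 5 × 5 convolution (8 filters, stride 2), ReLU, global average
pooling, and a linear softmax head initialized at zero so the class
orientation is learned from data rather than inherited from random
initialization. It trains on a CPU in seconds and separates the synthetic
two-class tiles essentially perfectly; it is the test vehicle for the
training loop, scoring contract and Grad-CAM, not a model of histology.

Patch probabilities are rounded half-even to two decimals (the common
binary-float convention; only "two decimal places" is prescribed), so every
emitted probability lies in the 101-value vocabulary {0.00, …, 1.00} and
`pred = [prob > 0.5]`. WSI-level aggregation defaults to the mean patch
probability (median and majority vote are available); no aggregation rule is
prescribed, and the mean is the least committal choice. The AUC confidence
interval is a patient-level percentile bootstrap with 2000 resamples.

Grad-CAM weights each final-layer channel by the spatial mean of the
target-class logit gradient, applies ReLU to the weighted sum, upsamples
bilinearly, and min-max scales to [0, 1]; an all-nonpositive map returns
zeros and a uniformly positive map returns ones.

## Multi-instance aggregation

The vocabulary is the *fixed* set of 101 two-decimal probabilities plus the 2
labels, not the corpus-observed unique values: only a fixed vocabulary yields
the 101 + 2 + 101 + 2 = 206 dimensionality on every cohort, which the rest of
the pipeline depends on.

Histogram blocks count term occurrences per patient and min-max normalize
within one patient across the bins of one block (a flat block maps to zeros).
The per-patient scope keeps each patient's representation self-contained; a
cross-cohort scope would tie a patient's features to whichever cohort they
are embedded in.

BoW blocks use raw term counts with smoothed IDF,
`idf(t) = ln((1+N)/(1+df(t))) + 1`, and per-patient L2 normalization of each
block — the common default TF-IDF convention, adopted because no specific
variant is prescribed. IDF is fitted on the training corpus and frozen for
application cohorts to avoid information leakage. L2 normalization makes the
BoW blocks (like the histogram blocks) invariant to duplicating every patch
in a bag, so feature values measure the distribution of patch predictions,
not slide size.

## Signature

The cascade runs in fixed order; each stage only sees survivors of the
previous one, recorded in a provenance log. The correlation filter scans
features in fixed column order and greedily keeps a feature unless |r| > 0.9
with an already-kept feature (first kept wins — the choice of which collinear
feature is "redundant" is otherwise arbitrary, and a deterministic rule keeps
fits reproducible). The univariate screen fits one proportional-hazards model
per feature on unbinned values and keeps Wald p < 0.05, unadjusted for
multiplicity, mirroring the stated per-feature rule; Wald p-values are used
because the screen's fits already produce them (score and likelihood-ratio
variants differ negligibly at these sample sizes).

LASSO-Cox standardizes features to unit variance internally and reports
coefficients on the original scale. The penalty path is 100 log-spaced values
from the smallest all-zero penalty down four decades (glmnet-style); the
optimum minimizes 10-fold cross-validated partial-likelihood deviance in the
Verweij–van Houwelingen form, `-2·[pl_full(β_k) − pl_without-fold-k(β_k)]`
summed over folds, with fold assignment deterministic under the seed. Ties
use the Breslow approximation throughout the package. An all-zero solution at
the optimum raises `SignatureError` — on null data, refusing to produce a
signature is the correct behavior.

The pathomics score is `Σ β_i x_i` over selected features. The risk cutoff is
fitted on training scores by an exhaustive log-rank scan (below); the
direction of risk (above/below the cutoff) is stored in the model because it
depends on the signs the LASSO happens to assign. Penalty values reported for
the original clinical cohorts (0.179 for RFS, 0.022 for OS) are retained as
configuration references only; they are functions of private data.

## Survival evaluation

*Optimal cutoff* — an exhaustive scan over midpoints of adjacent sorted
unique scores, keeping candidates that leave at least 10% of patients on each
side, maximizing the two-group log-rank χ² with ties resolved toward the
smaller cutoff. This is a transparent surrogate for X-tile-style cutpoint
software whose internal criterion is not published. No Miller–Siegmund
correction is applied to the χ² at the selected cutoff; it is flagged as
optimism-prone and should not be read as an honest p-value.

*Cox models* — fitted by Newton–Raphson on the Breslow partial likelihood
with step-halving, Wald CIs and p-values; `cox_score_test` exposes the score
statistic at β = 0, which equals the log-rank χ² for a binary split. The
mixed-effects model adds a shared log-normal frailty per center, estimated by
penalized partial likelihood (frailties ridge-penalized by b'b/2θ) with the
frailty variance maximizing the Laplace-approximate marginal likelihood
`ppl(β̂, b̂) − ½·log|θ·I_bb + I|`, searched on [1e-4, 4] with an explicit
comparison against the no-frailty boundary. Log-normal frailty was chosen
over gamma because it composes naturally with the penalized-likelihood
machinery already in place; at the variances of interest the two are close.

*Discrimination* — Harrell's C counts concordant usable pairs with score ties
at one half; it takes risk scores (higher = riskier), so pathomics scores
with "low score = high risk" orientation are negated by the caller.
Time-dependent AUC is the cumulative-case/dynamic-control estimator with
KM-based inverse-probability-of-censoring weights; with no censoring before
the horizon it reduces exactly to the binary AUC of (event ≤ t). Horizons
beyond follow-up are reported as missing. Default horizons are 12/36/60
months for OS and 12/24/36 for RFS.

*Heterogeneity* — Cochran's Q with inverse-variance weights,
`I² = max(0, (Q−df)/Q)·100`, and a DerSimonian–Laird random-effects pooled
log-HR. Subgroup analyses fit the covariate within each stratum, skipping
strata with fewer than two events or constant covariates; Bonferroni
correction is available as a flag for subgroup tables and off by default for
single pre-specified comparisons. CI level is fixed at 95%, p-values
two-sided, time in months throughout.

## Synthetic data: what it emulates and what it does not

`gen_tiles` draws pale-pink background tiles with Poisson-distributed dark
blue-purple blobs; class 1 has higher blob density, emulating nucleus-dense
tumor tissue versus sparse stroma. `gen_beer_lambert_tile` renders
`pixel = 255·exp(−(c₁s₁ + c₂s₂))` from known unit stain vectors — the oracle
for Macenko fitting. Test phantoms use a U-shaped (Beta(0.4, 0.4)) mixing
fraction so that many pixels are nearly pure in one stain; the angular
extremes of the OD cloud then reach the true stain directions, which is the
geometric assumption Macenko estimation itself makes.

`gen_cohort` draws one standard-normal latent risk `r` per patient that
drives everything: patch probabilities are Beta-distributed around
`logistic(κ·r)` with fixed concentration 8 (a realistic within-patient
heterogeneity; no patch-level distribution is prescribed by the problem) and
rounded to two decimals; survival times are proportional-hazards Weibull with
shape 1.2 and log-hazard `θ·r + center frailty + chemo effect + CA19-9
effect`, scaled so the median at zero log-hazard is 24 months for OS and 16
for RFS (matching clinical PDAC time scales); RFS is the minimum of the
recurrence and death processes. High CA19-9 is sampled with log-odds
`ca199_assoc·r`; chemotherapy and CA19-9 hazard effects may differ between
the latent-risk halves (sample-median split), which is what the subgroup
analyses are designed to detect. Censoring is administrative — uniform on
[6, 60] months for a randomly chosen `censor_rate` fraction of patients,
truncated below the patient's event time so the nominal rate is realized.
Defaults: θ = 1, κ = 1.5, censoring 30%, 50 patches per patient.

These generators validate the *statistical machinery*: that the aggregation
preserves the latent-risk signal carried by patch probabilities, that the
selection cascade finds it, and that the survival statistics recover known
effects at realistic sizes. They do not emulate histology rendering, scanner
artifacts, batch effects in staining, spatial correlation between patches, or
informative censoring — so passing tests demonstrate correctness of the
pipeline's computations, not clinical performance on real slides.

## Problem sizes used in the test suite

Recovery checks run at the sizes a desk-scale study of this design needs for
stable answers: signature recovery on cohorts of 300 training / 300 held-out
patients × 50 patches (10 seeds, mean held-out C ≥ 0.60 at θ = 1, κ = 1.5);
screen type-I error on 200 null cohorts of 500 patients; frailty-variance
recovery on 600 patients × 12 centers (10 seeds per truth); subgroup
interaction on 800 patients × 20 seeds; backbone separability on 200 tiles of
64 px. Tile fixtures use 32–128 px tiles — every operation is
size-parametric, so the 512-px default exercises identical code paths.

## Known limitations

- The reference backbone is intentionally minimal; real prognostic
  performance requires a modern pretrained network plugged in via the scorer
  contract (not bundled).
- The cutoff's log-rank χ² is maximally selected and optimistic; report it
  with external validation, as the evaluation module's design assumes.
- The frailty model profiles a single variance component for one grouping
  factor; crossed or nested random effects are out of scope.
- No competing-risks handling: RFS treats death as part of the composite
  endpoint, and censoring is assumed independent.
- Proprietary WSI containers (.svs pyramids) are not parsed; inputs are
  ordinary raster images (PNG/TIFF).
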