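# pathomil

A multi-instance pathomics prognosis pipeline for H&E histopathology, built
for methodologists and computational-pathology engineers who want every stage
of a slide-to-risk-score workflow as tested, reusable components: tile
preprocessing with Macenko stain normalization, patch-level prognosis scoring
with a pluggable deep-learning backbone, histogram + TF-IDF bag-of-words
aggregation of patch predictions into a fixed 206-dimensional patient
representation, three-tier feature selection into a LASSO-Cox signature, and
log-rank-optimized risk stratification with a full survival-evaluation suite.
Everything is exercised on synthetic tiles and synthetic cohorts with known
generating structure, so the pipeline is testable end to end without access
to clinical whole-slide images.

## The method

**Preprocessing.** Whole-slide-sized images are cut into non-overlapping
512 × 512 tiles; tiles that are predominantly white background are discarded.
Staining is standardized by Macenko color normalization — optical densities
`OD = -log((I+1)/256)` of tissue pixels are projected onto the plane of their
top two singular vectors, stain vectors are taken at the 1st/99th angular
percentiles, and concentrations are rescaled into a target stain basis —
followed by per-channel Z-scoring. Training-time augmentation is random
cropping plus independent horizontal/vertical flips.

**Patch scoring.** Patients are labeled by recurrence-free survival
(recurrence within 12 months = poor prognosis, recurrence-free beyond 36
months = good; intermediate patients are excluded from classifier training),
and every tile inherits its patient's label. A pluggable backbone (a small
NumPy reference CNN ships with the package) is trained with softmax
cross-entropy under a cosine-decay learning-rate schedule

    eta_t = eta_min + (eta_max - eta_min)/2 * (1 + cos(pi * T_cur / T_i))

with early stopping on validation loss, and emits per-tile probabilities
rounded to two decimals plus binary labels. Gradient-weighted class-activation
(risk-activation) heatmaps localize the image regions driving a prediction.

**Multi-instance aggregation.** Each patient's bag of patch predictions is
summarized over the fixed vocabulary of 101 two-decimal probabilities and 2
labels, once as a min-max-normalized histogram and once as an L2-normalized
TF-IDF bag-of-words, then fused by concatenation:

    feature_fusion = Histo_prob (101) ⊕ Histo_pred (2) ⊕ Bow_prob (101) ⊕ Bow_pred (2)

giving 206 features per patient regardless of cohort or patch counts.

**Signature.** A three-tier cascade reduces the 206 features: a Pearson
correlation filter (|r| > 0.9), a univariate Cox screen (Wald p < 0.05), and
an L1-penalized Cox model with the penalty chosen by 10-fold cross-validated
partial-likelihood deviance. The pathomics score is the linear predictor
`Score = Σ β_i x_i` over the selected features, and an exhaustive log-rank
scan (an X-tile-style surrogate) fits the high/low-risk cutoff.

**Evaluation.** Kaplan–Meier curves with log-rank tests, Cox proportional
hazards models (Breslow ties, Wald inference), a mixed-effects Cox model with
log-normal per-center frailty, Harrell's C-index, IPCW time-dependent AUC,
Cochran's Q / I² center heterogeneity with a DerSimonian–Laird pooled effect,
and per-stratum subgroup analyses (CA19-9, adjuvant chemotherapy).

## Worked example

Fit a signature on one synthetic cohort and evaluate it on an independent one
(both cohorts couple patch probabilities and Weibull survival times to the
same latent risk):

```python
import numpy as np
from pathomil import (CohortSpec, SelectionConfig, build_feature_table,
                      fit_signature, gen_cohort, harrells_c, score_table,
                      time_dependent_auc)

spec = dict(n_patients=300, patches_per_patient=50, risk_effect_theta=1.0,
            prob_shift_kappa=1.5, censor_rate=0.3)
train = gen_cohort(CohortSpec(**spec, seed=0))
table, idf = build_feature_table(train.bags)
outcomes = ([b.os.time for b in train.bags], [b.os.event for b in train.bags])
model = fit_signature(table, outcomes, SelectionConfig(endpoint="OS", seed=0))
print(f"selected {len(model.selected)} / 206 features at lambda = {model.lambda_opt:.4f}")
print(f"risk cutoff = {model.cutoff:.3f} (high risk {model.high_risk_side} the cutoff)")

test = gen_cohort(CohortSpec(**spec, seed=1000))
table2, _ = build_feature_table(test.bags, fitted=idf)   # frozen IDF weights
scores = score_table(model, table2).to_numpy()
risk = scores if model.high_risk_side == "above" else -scores
out2 = (np.array([b.os.time for b in test.bags]),
        np.array([b.os.event for b in test.bags]))
print(f"held-out Harrell's C = {harrells_c(risk, out2):.3f}")
auc = time_dependent_auc(risk, out2, [12.0, 36.0, 60.0])
print("held-out AUC(t):", {int(k): round(v, 3) for k, v in auc.items()})
```

This prints:

```
selected 14 / 206 features at lambda = 0.0677
risk cutoff = 0.848 (high risk above the cutoff)
held-out Harrell's C = 0.707
held-out AUC(t): {12: 0.736, 36: 0.78, 60: 0.831}
```

The signature selects 14 of the 206 aggregated features; on the independent
cohort the score orders survival with concordance 0.707 (0.5 = chance), and
the time-dependent AUC shows the score discriminating 1-, 3- and 5-year
overall survival. Because the generator couples everything to a single
standard-normal latent risk, concordance near 0.70 is close to the ceiling
achievable at this effect size.

The same flow is available from the shell:

```bash
pathomil simulate  --spec cohort.json --out sim/
pathomil aggregate --patches sim/patches.csv --clinical sim/clinical.csv \
                   --split train --idf idf.json --out features.csv
pathomil select    --features features.csv --clinical sim/clinical.csv \
                   --endpoint os --out model.json
pathomil stratify  --model model.json --features features.csv \
                   --clinical sim/clinical.csv --out strata.csv
pathomil evaluate  --strata strata.csv --clinical sim/clinical.csv \
                   --report report.json
```

plus `pathomil tile / normalize / score / cam` for the imaging stages.

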