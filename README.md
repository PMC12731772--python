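# t2drisk

Fuzzy-enhanced multi-class risk stratification for Type 2 Diabetes Mellitus
(T2DM) from routinely observable lifestyle indicators.

Screening programs in low-resource settings often cannot rely on laboratory
biomarkers. This package implements a lifestyle-only pipeline for early risk
assessment: a cohort of participants described by eleven simple columns
(age, sex, family history, smoking, drinking, daily thirst and urination
frequency, height, weight, fatigue, diabetes outcome) is stratified into
four ordered risk classes — **A** low risk, **B** moderate risk, **C** high
risk, **D** diagnosed diabetic — and each class is mapped to concrete,
budget-conscious diet and physical-activity recommendations.

## Method

1. **Fuzzy risk labeling.** The six graded lifestyle features are min–max
   normalized to [0, 1] and combined into a convex composite score
   x = Σ_f w_f z_f (weights default to the features' association effect
   sizes). The score passes through the S-shaped membership function

   μ(x; a, b) = 0 for x ≤ a; 2((x−a)/(b−a))² up to the midpoint;
   1 − 2((x−b)/(b−a))² up to b; 1 for x ≥ b,

   and μ maps to bands A = [0, 0.4), B = [0.4, 0.7), C = [0.7, 1), D = {1}.
   A diagnosed record (outcome 1) is always forced to μ = 1, class D.
2. **Classification.** A feed-forward network (64–32–16 hidden units, ReLU,
   softmax over 4 classes, Adam, dropout 0.2, L2 10⁻³, early stopping)
   learns the class labels from the ten normalized original features —
   never from the fuzzified score.
3. **Monotone-spline probability calibration.** Per class, one-vs-all: sort
   the raw predicted probabilities, fit pool-adjacent-violators isotonic
   regression against the binary indicators, interpolate the pooled blocks
   with a monotone cubic (PCHIP), then renormalize row-wise,
   P̃_i = F_i(P̂_i) / Σ_j F_j(P̂_j), so every calibrated row lies on the
   probability simplex.
4. **Evaluation.** Accuracy, per-class precision/recall/F1 with macro and
   weighted averages, Cohen's κ, and one-vs-rest ROC–AUC via the
   tie-corrected Mann–Whitney rank statistic; ANOVA F-statistics rank
   feature importance.
5. **Recommendation.** A deterministic rule engine (editable YAML rule base)
   renders each class into diet / activity / monitoring / referral items
   and a class-appropriate exercise chart.

Because the underlying study cohort is private, the package ships a seeded
synthetic cohort generator whose age-band allocation, per-band case counts
and pooled marginals are calibrated to the published summary tables; every
stage is developed and tested against it.

## Worked example

```python
from t2drisk import CohortConfig, T2DRiskModel, generate_cohort

cohort = generate_cohort(CohortConfig(seed=1))   # 1939 rows, 11 columns
results = T2DRiskModel(cohort, seed=1).fit()
print(results.summary())
```

prints (abridged):

```
T2D lifestyle risk model
========================
observations: 1939   train: 1357   test: 582
class counts: A=802  B=524  C=71  D=542
epochs trained: 92

test partition (raw)
accuracy : 91.24%
kappa    : 86.91%
C           100.00%    4.76%    9.09%       21
macro AUC: 98.52%

test partition (calibrated)
accuracy : 91.92%
kappa    : 88.06%
C            59.09%   61.90%   60.47%       21
macro AUC: 98.62%

top features by ANOVA F: urination (1148), fatigue (422), thirst (354), weight (140)
```

The held-out accuracy (91.9%) and κ (88.1%) show the network recovers the
risk bands from the raw features, and the calibration pass is what makes
the rare high-risk class C usable: its recall rises from 4.8% to 61.9%
after the monotone-spline renormalization. `results.recommend("C")` then
returns the high-risk plan (1500–1700 kcal/day diet, 40 min/day morning
walking, …).

The same run is available from the shell:

```bash
t2drisk pipeline --seed 1 --out-dir run/   # all artifacts + manifest
t2drisk simulate --seed 1 --out cohort.csv
t2drisk recommend --risk-class C
```

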