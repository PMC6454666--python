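# evidfuse

Evidential fusion of clinical risk-model outputs for binary outcome
prediction, built for the setting where several imperfect risk models —
machine-learned classifiers emitting probabilities and traditional integer
risk scores such as GRACE — each see part of the truth about a patient's
risk of a major adverse cardiac event (MACE) during an acute coronary
syndrome (ACS) admission. Rather than picking one model or averaging them,
`evidfuse` treats each model's output as a piece of *evidence* of
model-specific reliability and fuses them with Dempster–Shafer theory,
producing a continuous decision value, a class label, and an explicit
belief/plausibility interval quantifying the remaining ignorance.

It is aimed at biostatisticians and clinical-ML practitioners who already
have per-patient scores from several models and want a principled,
explainable ensemble over those scores (no base-model training happens
here).

## Method

Given base models $i = 1,\dots,m$ with raw outputs $O_{i,j}$ for patient
$j$ and binary outcomes $r_j$:

1. **Threshold calibration.** Each model gets the operating threshold
   $\mathrm{Threshold}_i$ whose ROC point lies closest to the top-left
   corner $(0,1)$; unbounded scores are first min-max normalized,
   $A_{i,j} = (O_{i,j}-\min_i)/(\max_i-\min_i)$.
2. **Rough-set weights.** Dichotomized outputs
   ($1 \iff$ score $>$ threshold) and the outcomes form a decision table.
   Model $i$'s significance is the conditional-entropy change
   $\omega_i = |H(R \mid A\setminus\{a_i\}) - H(R \mid A)|$ (natural log),
   and its weight is $w_i = \omega_i / \sum_k \omega_k$ — models whose
   dichotomized output is redundant get weight 0.
3. **Rescaling.** A piecewise-linear map sends each channel's threshold to
   0.5: $A^*_{i,j} = 0.5\,A_{i,j}/T_i$ below threshold, and
   $0.5\,(A_{i,j}-T_i)/(1-T_i)+0.5$ above, putting all channels on a
   common evidential scale.
4. **Weighted evidence.** Each model contributes the mass assignment
   $m_i(1) = w_i A^*_{i,j}/(w_i+1)$, $m_i(0) = w_i(1-A^*_{i,j})/(w_i+1)$,
   $m_i(\Theta) = 1/(w_i+1)$ over the frame $\Theta = \{$MACE, no MACE$\}$;
   low-weight models approach total ignorance.
5. **Fusion and decision.** Dempster's rule combines the $m$ sources
   (conflict renormalized by $1/(1-K)$); the decision value
   $R_j = m(1)/(m(0)+m(1))$ is thresholded at a cut-off itself calibrated
   on the training decision values.

## Worked example

The package embeds a published 10-patient ACS excerpt with the outputs of
four base models (SVM, L1-logistic regression, CART, GRACE), their
calibrated thresholds (0.2348, 0.2689, 0.2584, 106.5), rough-set weights
(0.5363, 0.1765, 0.1177, 0.1696), GRACE normalization bounds (37, 201) and
the decision-value cut-off 0.4759:

```python
from evidfuse import EvidentialEnsembleClassifier, worked_example

ex = worked_example()
est = EvidentialEnsembleClassifier.from_parameters(
    ex.calibrations(), ex.weight_vector(), ex.decision_threshold
)
detail = est.predict_detail(ex.score_matrix.scores)
print(detail[["decision_value", "prediction", "belief", "plausibility"]].round(4))
```

prints

```
            decision_value  prediction  belief  plausibility
patient_id
1                   0.8632           1  0.4806        0.9238
2                   0.2845           0  0.1548        0.6105
3                   0.3784           0  0.2046        0.6640
4                   0.4190           0  0.2260        0.6866
5                   0.4404           0  0.2371        0.6988
6                   0.7999           1  0.4396        0.8900
7                   0.4523           0  0.2433        0.7053
8                   0.3397           0  0.1833        0.6436
9                   0.5839           1  0.3146        0.7758
10                  0.3931           0  0.2123        0.6721
```

Patient 1 carries strong concordant evidence (decision value 0.86, belief
0.48 with plausibility 0.92 for MACE) and is called positive; patient 2's
evidence points the other way. Eight of the ten calls match the recorded
outcomes. The same pipeline is available end-to-end from the shell:

```bash
evidfuse demo                      # the table above, cell-by-cell vs reference
evidfuse simulate -o cohort.csv --n 2000 --seed 1
evidfuse fit cohort.csv -o model.json
evidfuse predict model.json cohort.csv -o predictions.csv
evidfuse evaluate cohort.csv --k 5 --seed 1
```

A synthetic-cohort generator (`evidfuse.simulate`) emulates correlated
base-model score channels — including a bounded-integer GRACE-like channel
— for testing and experimentation.

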