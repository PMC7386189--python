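# kbdose

Knowledge-based voxel dose prediction for online adaptive MR-guided
radiotherapy (MRgRT) of abdominal tumors.

## The problem

In online adaptive MRgRT the plan of the day is re-optimized in minutes
while the patient lies on the table, so it never receives the scrutiny of
a fully optimized offline plan — and under *isotoxicity* planning (hard GI
organ-at-risk constraints take priority over target coverage) there is no
fixed coverage benchmark to judge it against. `kbdose` predicts the 3D
dose distribution inside the gross tumor volume (GTV) **from anatomy
alone** — no beam angles, no fluence — so that the achievable quality of a
new plan can be estimated before or after it exists, and plans that fall
short of what their geometry allows can be flagged for re-optimization.

## The model

For every voxel $v$ inside the GTV, 16 geometric input variables are
computed from the planning structures (GTV; PTV = GTV + 5 mm; OAR_CRIT =
nearby GI organs; OAR_5mm = OAR_CRIT + 5 mm; PTV_OPT = PTV − OAR_5mm):
neighborhood occupancy of OAR_5mm within 5/10/15/20 mm, the GTV overlap
fraction, distances to the GTV centroid and surface, and signed minimum
distances to the OAR_5mm, PTV_OPT and (OAR_5mm − OAR_CRIT) surfaces
(negative = overlap; the non-negative OAR_5mm distance is capped at
16 mm, beyond which it no longer correlates with dose).

A feed-forward network $f_\theta:\mathbb{R}^{16}\to\mathbb{R}$ with one
hidden layer of 2 tanh units (37 parameters) maps these to the normalized
dose $D(v)/R_x$. Training minimizes MSE with batch Levenberg–Marquardt on
an 85/15 train/validation split, stopping after 6 consecutive validation
error increases or 200 epochs; the whole training is repeated 50 times
(fresh initialization and split) and predictions are averaged over the
ensemble. Evaluation is patient-wise cross-validation (groups of five
patients, training voxels subsampled 1/20 per plan), reporting per-plan
dose errors and the DVH metrics V95, V100, D95 and $D_\mathrm{mean}$.
Inferior plans are those whose observed V95, V100 or D95 error falls
outside the 95% prediction interval, mean error ± 1.96 · SD; flagged plans
are dropped from the training pools and the model retrained (two rounds).

Because clinical cohorts cannot ship with the code, a seeded phantom
generator produces abdominal-style cohorts (blob-perturbed GTVs with
adjacent, sometimes overlapping OARs) and isotoxicity-shaped doses with a
known noiseless ground truth
$g(v) = c + (h-c)\,\mathrm{clip}(d(v), 0, F)/F$, where $d$ is the signed
distance to OAR_5mm, $c$ the OAR constraint fraction, $h$ the hotspot
plateau and $F = 16$ mm the falloff — an exact function of the implemented
features, so closed-loop recovery is testable.

## Worked example

Train on a small synthetic cohort and predict a held-out patient
(`examples/04_train_and_predict.py`):

```
$ python examples/04_train_and_predict.py
training on 4240 sampled voxels from 10 plans
10 members trained; epochs per member: 23..155
held-out plan pat005_plan1:
  mean error     =  -0.07 Gy (-0.13 % Rx)
  mean |error|   =   0.90 Gy
```

The held-out plan's dose is recovered to within ~1 Gy per voxel from
contours alone; the residual is the plan-specific heterogeneity the model
deliberately does not see. Cross-validation with a planted inferior plan
(`examples/05_cross_validation_and_outliers.py`) prints the fitted 95%
prediction intervals and flags the degraded plan:

```
flagged as inferior: ['pat000_plan0', 'pat006_plan0']
     plan_id  v95_actual  v95_predicted  v95_error
pat000_plan0        30.7           73.7      -43.0
```

i.e. plan `pat000_plan0` achieved V95 = 30.7% although its geometry
supports ~74% — exactly the situation the flagging exists to catch. The
other examples cover structure derivation, the feature matrix, and DVH
metrics. A thin CLI wraps the same workflow
(`kbdose simulate | cross-validate | refine | report ...`).

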