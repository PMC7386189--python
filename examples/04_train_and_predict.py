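"""Train a network ensemble and predict a new patient's 3D GTV dose from
structures alone.

Trains on voxels sampled from a small synthetic cohort, then predicts the
dose for an unseen patient and compares it with that plan's delivered
dose. No beam information enters the model: prediction needs only the GTV
and OAR contours.
"""

import numpy as np

from kbdose import (
    PhantomConfig,
    TrainConfig,
    generate_cohort,
    predict_dose,
    sample_training_voxels,
    train_ensemble,
)

cohort = generate_cohort(PhantomConfig(n_patients=6, plans_per_patient=2, seed=5))
train_plans, test_plan = cohort[:-2], cohort[-1]  # hold out the last patient

x, y = sample_training_voxels(train_plans, ratio=0.3, seed=5)
print(f"training on {len(y)} sampled voxels from {len(train_plans)} plans")

model = train_ensemble(x, y, TrainConfig(seed=5), n_repeats=10)
epochs = [h.n_epochs for h in model.histories]
print(f"10 members trained; epochs per member: {min(epochs)}..{max(epochs)}")

pred = predict_dose(model, test_plan.structs, rx=test_plan.rx)
gtv = test_plan.structs.gtv.voxels
err = test_plan.dose.dose[gtv] - pred.dose[gtv]
print(f"held-out plan {test_plan.plan_id}:")
print(f"  mean error     = {err.mean():6.2f} Gy ({err.mean()/test_plan.rx*100:5.2f} % Rx)")
print(f"  mean |error|   = {np.abs(err).mean():6.2f} Gy")
# The model predicts the smooth geometry-driven dose; residuals reflect
# plan-specific heterogeneity it deliberately does not see.
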