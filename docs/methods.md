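# Methods

## Scope and model

`kbdose` implements a knowledge-based prediction of the 3D dose
distribution inside the gross tumor volume (GTV) for online adaptive
MR-guided radiotherapy of abdominal targets planned under isotoxicity:
hard dose constraints on the critical GI organs (OAR_CRIT) take priority
over target coverage, so the dose inside the tumor is governed almost
entirely by the geometry between the target and the expanded organ
(OAR_5mm). The model maps 16 per-voxel geometric variables to dose
normalized to the prescription (Rx: 50 Gy for SBRT with a 36 Gy OAR
constraint, 67.5 Gy hypofractionated with a 50 Gy constraint). No
beam-geometry information is used, by design: predictions must be
available before a deliverable plan exists.

## Grid and distance conventions

* Voxel grids are axis-aligned; the world coordinate of index
  `(i, j, k)` is `origin + index × spacing`. Default spacing is 3 mm
  isotropic (typical of clinical dose grids) and configurable; distances
  are Euclidean between voxel centers, in mm.
* A mask's *surface* is its set of voxels 6-connected to background
  (voxels on the array boundary count as surface). The signed distance of
  a voxel to a structure is the distance to the nearest surface-voxel
  center, negative inside the structure. Surface voxels are at exactly 0.
* Isotropic expansion includes a voxel iff its center lies within the
  margin (inclusive) of some input-voxel center — a deterministic tie
  rule, exactly matched by the brute-force oracles in the test suite.
* Distances to an *empty* structure are +∞ by convention; before feature
  assembly all signed distances are clamped to the grid's physical
  diagonal so the network always receives finite inputs while "far away"
  semantics survive. Distance transforms use `scipy.ndimage`
  (exact Euclidean EDT); neighborhood occupancy counts use FFT
  convolution with the counts rounded back to exact integers.
* Resolution sensitivity: all distances are computed on the dose grid.
  On coarser grids voxel-center distances are biased by up to half a
  voxel diagonal; the oracle tests bound the implementation error at that
  level, but users comparing across resolutions should recompute features
  rather than rescale them.

## Feature variables

Columns `f01–f16`, a frozen order: occupancy of OAR_5mm within
5/10/15/20 mm (percent of *in-grid* voxels in a Euclidean ball — no
zero-padding dilution at grid edges); percent of the GTV overlapped by
OAR_5mm (plan constant); distance to the GTV centroid (unweighted mean of
voxel centers); maximum centroid-to-surface radius (plan constant); depth
below the GTV surface and its square root; and the signed minimum
distances to OAR_5mm, PTV_OPT and the (OAR_5mm − OAR_CRIT) shell, each
split into non-negative and non-positive parts with 0 on the inactive
side (networks need dense inputs). The non-negative OAR_5mm distance is
capped at 16 mm — beyond that range the distance–dose correlation is
flat — and the cap applies to that variable only; the signed square root
uses `sign(d)·√|d|` to preserve overlap information. Both choices are
configurable in principle but fixed here as the documented contract.

## Network and training

One hidden layer of 2 tanh units and a linear output — 37 free
parameters. Inputs are min–max normalized to [−1, 1] with statistics
fitted on the training split only (z-score available); zero-variance
columns cannot be scaled and are mapped to a constant 0, recorded on the
normalizer, with the 16-input architecture left intact. Targets are
dose/Rx, not further normalized.

Training is batch Levenberg–Marquardt on the MSE: solve
`(JᵀJ + μI) δ = −Jᵀr` with the residual Jacobian J, accept the step if
the training MSE decreases (μ × 0.1, floored at 1e-12 to keep the solve
well-posed when silenced columns zero out Jacobian columns), otherwise
reject and retry with μ × 10 up to μ = 1e10. One epoch is one accepted
LM pass over the full training split. Weights start from small
fan-in-scaled uniform values, seeded. The sampled voxels are split 85/15
into training/validation; training stops after 6 *consecutive* strict
validation-MSE increases or 200 epochs, and the weights with the best
validation MSE seen are restored. An ensemble repeats this 50 times with
fresh seeds for the split and the initialization (the training voxel
sample itself is drawn once per cross-validation fold and shared across
repeats, matching the stated ordering of the protocol; re-drawing per
repeat would be a one-line change) and averages member outputs.

## Cross-validation, intervals, refinement

Patients are partitioned at random (seeded) into groups of five plus one
remainder group; each group serves once as the test set, and the
ensemble for a fold trains only on plans of the other groups — no plan is
ever predicted by a model that saw any plan of the same patient (asserted
at run time). Per plan, training voxels are drawn without replacement at
a 1/20 ratio (round-half-up, minimum 1).

The 95% prediction interval of a metric is mean error ± 1.96 × sample SD
over plans, pooled across folds. A plan is inferior if its V95, V100 or
D95 error falls outside the corresponding interval; flagging is two-sided
by default (an observed metric far *above* prediction is equally
atypical; the one-sided variant is a switch). Refinement iterates
cross-validate → fit intervals → flag → drop flagged plans from the
training pools, two rounds by default; discarded plans keep receiving
predictions for reporting.

## Synthetic cohorts

The generator emulates what an adaptive abdominal service accumulates:
per patient, a blob-perturbed ellipsoidal GTV (radius 10–25 mm ≈ 4–65 cc,
smooth radial perturbation amplitude 15%) with an adjacent OAR whose
surface offset from the GTV surface spans −4…+8 mm (negative = overlap
with the PTV, the hallmark isotoxicity geometry); one simulation plan
plus adapted plans in which only the OAR moves (≤ 4 mm per axis), since
the large majority of adapted fractions involve no GTV re-contour.
Roughly 5 patients in 53 are hypofractionated, the rest SBRT.

The noiseless normalized dose is
`g(v) = c + (h − c) · clip(d(v), 0, F)/F` with `d` the signed distance to
OAR_5mm, `c` the constraint fraction (36/50 or 50/67.5), `h = 1.05` the
plateau and `F = 16 mm` the falloff. For `d ≤ 0` the dose sits flat at
the constraint floor, so a voxel on the OAR_CRIT surface receives exactly
the constraint dose; the falloff range deliberately equals the feature
cap so the learning problem is realizable from the implemented inputs —
that realizability is the package's core closed-loop test. Delivered
dose adds a smooth heterogeneity field (white noise Gaussian-filtered at
9 mm correlation length, scaled to 3% of Rx) and, in ~10% of plans, one
localized Gaussian hotspot (σ = 5 mm, peak bounded by the 150% Rx clip):
occasional, beam-geometry-like structure the model cannot and should not
predict. A planting utility scales the dose by a factor (e.g. 0.8)
inside a random half-space of the GTV to create ground-truth inferior
plans for detection tests.

What the generator does *not* emulate: real fluence/beam-arrangement
dose texture, MR imaging artifacts, breathing motion, inter-organ
deformation beyond rigid OAR shifts, and cohort-level case-mix
correlations. Passing the closed-loop tests therefore demonstrates that
the pipeline recovers a dose law expressible in its own features, not
clinical-grade accuracy on patient data.

## Numerical and degenerate-input choices

* DVH: Vx uses an inclusive threshold; Dp is the inverse empirical CDF
  ("largest dose with ≥ p% coverage"), exact on toy inputs and verified
  against an exhaustive threshold scan; D0 is the maximum dose. %Rx dose
  errors are computed per voxel before averaging; GTV voxels are weighted
  equally.
* Error summaries use the sample SD (n−1); a single-plan cohort reports
  SD 0 with a `degenerate_sd` flag. A zero-spread interval degenerates to
  a point and warns.
* Empty GTV → error; empty OAR → valid (empty expansions, PTV_OPT = PTV,
  saturated distance features). Phantom generation retries infeasible
  geometry 40 times before raising.
* All randomness derives from one run seed through named hash-derived
  substreams (folds, sampling, initialization, noise), so every artifact
  is byte-reproducible from its seed.

## Problem sizes used in the shipped checks

Oracle-equivalence tests run 50 random phantoms up to 16³ voxels against
pairwise-enumeration oracles. The closed-loop check uses the noiseless
default cohort — 20 patients × 3 plans at 3 mm — with the full 50-repeat
ensemble; cross-validated per-voxel MAE comes out near 0.02% of Rx,
versus the 2% acceptance bound. Interval calibration uses 1e5 Gaussian
errors; outlier detection uses 20 replicate cohorts of 60 plans (32³
grid) with 3 planted degraded plans each, scoring sensitivity and
false-flag rate with the generator's ground truth as the predictor (the
function the trained model demonstrably recovers), which keeps 20
replicates well inside a desktop-minutes budget.

## Known limitations

* The union of three two-sided 95% intervals flags more than 5% of plans
  on a *null* cohort (~10% here): V95/V100 errors are skewed and
  ceiling-bounded, so per-metric nominal coverage does not compose to a
  5% union rate. This mirrors practice — the reference workflow flagged
  ~8% of real plans over two rounds — and is intrinsic to the detection
  rule, not a calibration defect of this implementation.
* Dose prediction is limited to GTV voxels; OAR DVH evaluation,
  conformity/homogeneity indices and replanning optimization are out of
  scope.
* The 2-node architecture is a deliberate ceiling; the code does not
  support deeper/wider variants, which are known to overfit this feature
  set without improving accuracy.
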