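# Methods

`olst` implements a screening analysis for high autistic trait in
5-year-old children based on the one-legged standing test (OLST): four
timed stands (two per leg, alternating, capped at 20 s) on a 48-cm
pressure mat, recorded synchronously at 20 Hz with frontal-camera
skeletal keypoints. The pipeline extracts 16 posturographic and
kinematic variables, trains linear support-vector machines to separate
High from Low autistic-trait children (SRS-2 totals above the
sex-specific screening cutoffs, boys 53.5 / girls 52.5), and interprets
the fitted models.

## Feature model

All variables except the longest stand are computed on the first two
seconds of the first trial — the two-to-one-leg weight transfer, a
feed-forward balance action. At 20 Hz this is a 40-frame window.

**COP estimation.** Each pressure frame's center of pressure is the
pressure-weighted centroid of its active cells (cells above 5% of the
frame maximum; frames are valid with ≥ 3 active cells and total
pressure above 10% of the trial median). The plantar contact region is
summarized per trial by its pressure-weighted second-moment ellipse;
the COP trajectory is rotated so that the ellipse major axis
(anteroposterior, along the foot) is the Y axis and the minor axis
(mediolateral) the X axis.

**COP sway (4 variables).** Total sway-path length (sum of consecutive
point distances, cm); mean sway speed (path length / elapsed time,
cm/s); approximate entropy (Pincus ApEn with embedding m = 2, tolerance
r = 0.2·SD per axis, Chebyshev distance, self-matches counted, averaged
over the X and Y series — the posturography standard; all three knobs
are arguments); convex-hull sway area (cm², 0 for degenerate point
sets).

**Overall balance (2 variables).** Longest stand across the four trials
(s, right-censored at 20 s); COM–COP distance: the mean absolute
mediolateral gap between the keypoint-derived center of mass and the
COP after mean-offset alignment. The COM uses Dempster segment mass
fractions (head+neck 0.081, trunk 0.497, upper arms 0.028, forearms+
hands 0.022, thighs 0.100, shanks+feet 0.061 each) over straight-line
segments between landmarks; only the mediolateral axis is compared
because a frontal camera provides no depth, and the unknown camera–mat
calibration is removed by matching means over the window.

**COP–joint coupling (10 variables).** Ten joint angles per frame from
the 15-landmark skeleton: neck and shoulder-line inclinations against
the horizontal; interior angles at the elbows (shoulder–elbow–wrist),
trunk left/right (neck–mid-hip–hip), hips (shoulder–hip–knee) and knees
(hip–knee–ankle). Angle math runs on y-up coordinates; landmarks below
confidence 0.1 invalidate a frame for the angles that use them. Each
coupling variable is the Pearson correlation between the first
difference of the mediolateral COP coordinate and the first difference
of one angle series ("change in COP" vs "change in angle"; the
scalarization is configurable to the anteroposterior axis or the
resultant magnitude). Features with under 50% valid frames, or with
zero-variance differences, are recorded as missing — listwise exclusion
per category, never imputation.

## Screening model

Labels: High iff the SRS-2 total strictly exceeds the sex cutoff (the
half-point cutoffs make ties impossible for integer scores). Three
variable categories are modelled: *conventional* (4 sway + 2 balance),
*proposed* (10 coupling correlations), *combined* (all 16).

The classifier is a soft-margin linear SVM, hinge loss with an L2
penalty (the intercept is penalized too, as in common linear-SVM
solvers), features z-scored with training-fold statistics. The solver
is an in-package numba-compiled dual coordinate descent: model search
multiplies leave-one-out cross-validation (LOOCV) by thousands of
candidate (subset, cost) pairs, and per-fit overhead dominates that
workload in a general-purpose library. The suite cross-checks it
against an independent reference implementation of the same objective
and against direct numerical minimization. Pipeline fits use tolerance
1e-4 with a 300-epoch cap and warm-started LOOCV folds; the solution of
the strictly convex primal is unique, so results do not depend on data
order beyond that tolerance.

**Model search.** The variable subset and cost C are selected jointly
by LOOCV accuracy, ties broken by higher sensitivity, then fewer
variables, then smaller C. The cost grid defaults to {0.001, 0.01, 0.1,
1, 10}. Subsets are enumerated exhaustively for the 6-variable
conventional category; the 10- and 16-variable categories default to
sequential forward floating selection (exhaustive enumeration is
available behind a flag but costs 2^16−1 subsets). Two evaluation modes
exist:

* `paper_faithful` — selection and reported metrics share one LOOCV on
  the full table. This mirrors how best-model tables are commonly
  reported and is optimistically biased, since selection sees every
  held-out outcome.
* `nested` — selection is repeated inside each outer LOOCV fold and
  only outer held-out predictions are scored. The inner criterion is a
  stratified 5-fold CV rather than an inner LOOCV: an inner LOOCV
  multiplies cost by the training-set size for no measurable benefit at
  n = 125.

**Probabilities.** High-group probabilities come from Platt scaling
(regularized maximum likelihood with smoothed targets, Newton with
backtracking) fitted to *out-of-fold* decision values, so probability–
SRS correlations are not inflated by training fit.

## Interpretation

For a linear model on (assumed independent) features the Shapley value
of feature j for row i is exactly w_j(x_ij − x̄_j) with base value the
mean decision value; it is computed in closed form (a sampling
estimator would only add noise). Attributions are computed on the
scored feature rows against the final full-data refit of the selected
model. Probability–SRS association uses the tie-corrected Spearman
rank correlation with p from t = r_s·√((n−2)/(1−r_s²)) on n−2 df.
Cohort summaries use Welch's t (Welch–Satterthwaite df) for age and
SRS and an uncorrected Pearson χ² (df 1) for the sex ratio.

## Synthetic cohorts

No recordings from the original study were deposited, so the generator
produces cohorts with the statistical structure the analysis assumes.
Defaults reproduce the study protocol: 64 boys and 62 girls; High-group
fractions 9/64 and 10/62 in expectation; SRS-2 totals drawn from
truncated normals (High: mean 69.79, SD 23.66 above the cutoff; Low:
mean 31.24, SD 11.48 below it); 4 trials at 20 Hz capped at 20 s; a
48×48-cell grid of 1-cm cells on the 48-cm mat (the sensor's true
resolution is unpublished; this is a configuration choice).

A latent severity — the child's SRS percentile within the cohort,
mapped to [0, 1] — drives every group contrast through a single dial.
Responses use the shaped severity g = severity² (exponent
configurable), concentrating contrast in the high-trait tail where the
screening cutoff sits. With severity the cohorts show:

* smaller sway: mediolateral OU sway SD 1.2 cm at g = 0 falling by
  0.85 cm/unit g (anteroposterior 1.4× larger; OU mean reversion
  1.2 s⁻¹, exact discretization, stationary start);
* more regular sway: a sinusoid (0.6–1 Hz, random phase) mixed in with
  weight 1.2·g (capped at 0.95), lowering approximate entropy;
* shorter stands: exponential fall time with hazard 0.12·g s⁻¹,
  right-censored at the cap;
* stronger joint–COP coupling: angle series follow baseline +
  gain·(1.0 + 14·g)·COP_x + noise, where COP_x includes both the sway
  and the mediolateral weight-shift excursion of the transition ramp
  (the feed-forward transfer moves COP and posture together); per-angle
  gains lie between −0.8 and 1.0 and angle noise is 0.8° damped by
  factor (1 − 0.6·g) — higher severity, more stereotyped movement;
* a COM–COP gap: the whole skeleton translates with gain 1.8 per cm of
  COP_x plus 0.25 cm of COM-only noise.

Pressure frames render two elliptical footprints (semi-axes 3.5 × 8 cm)
during a 0.5-s two-to-one-foot weight-shift ramp, then the stance foot
alone; per frame, an anisotropic Gaussian profile over the footprint
cells is iteratively tilted until the pressure-weighted centroid
matches the simulated COP to within half a cell. Keypoints come from a
forward-kinematics template (110-cm stature, 3 px/cm) that exactly
realizes the driving angle series; landmark confidences are high with
rare (0.2%) dropouts.

Effect magnitudes were chosen by simulating severity-vs-feature
contrast curves until every qualitative contrast the analysis assumes
was strongly realized, and are fixed defaults documented above.

**What the generator does not emulate:** ground-reaction physics, 3-D
kinematics, pose-estimation failure modes (occlusion, identity swaps),
sensor noise floors and saturation, or age/sex differences in balance.
Passing tests therefore demonstrate that the pipeline recovers known
structure of this form — not that the screening accuracy would transfer
to real children.

## Reproducibility

The original study's printed results — the best-model accuracy table
(1.000/1.000/1.000 and 0.976/0.842/1.000), the per-participant SHAP
plots and the probability–SRS correlations (0.301/0.411/0.316) — were
computed on participant recordings that are **not** publicly available,
and are therefore **not reproducible** here. The package instead
verifies (i) the metric arithmetic on the published confusion pattern,
(ii) every numerical primitive against independent oracles, and (iii)
parameter recovery and null calibration on synthetic cohorts:
strong-effect cohorts yield combined-category LOOCV accuracy ≥ 0.9 and
positive probability–SRS correlations across seeds, while zero-effect
cohorts keep nested LOOCV accuracy at the majority rate and expose the
optimism of non-nested selection. Problem sizes in the checks (126
children, 10 seeds per stochastic claim) match the study's cohort size.

## Numerical notes and limitations

* Degenerate inputs: constant series give ApEn 0 by convention;
  collinear point sets give hull area 0; zero-variance difference
  series give a missing correlation; a trial with every frame invalid
  is an error, and a first trial shorter than 0.5 s (10 valid frames)
  marks the participant's window features missing.
* The foot-frame rotation is identified only up to 180° (eigenvector
  sign); features used downstream are invariant to this.
* LOOCV decision values are deterministic given the table; row order
  affects nothing beyond solver tolerance.
* With ~19 positives, sensitivity is quantized in steps of ~0.05;
  accuracy differences below 1/126 are not resolvable by LOOCV.
* The trunk-angle vertex (mid-hip, between trunk midline and the
  mid-hip→hip segment) and the mediolateral COP scalarization for the
  coupling features are documented conventions; the study's exact
  definitions are not published in enough detail to pin them.
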