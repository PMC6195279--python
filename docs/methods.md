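# Methods

`reachrank` implements a prognostic-modelling pipeline for upper-limb
stroke rehabilitation: per-trial reach kinematics are summarised into a
subject-level design matrix, change in a clinical outcome score is
regressed on it with penalized linear models under repeated
cross-validation, and features are ranked by two complementary stability
criteria. Because the motivating patient dataset is not publicly
deposited, the package ships a synthetic cohort generator with a known
sparse ground truth; every downstream stage is exercised and tested
against that generator.

## Synthetic reaches

A reach from home position **h** to target **g** is modelled as a
superposition of minimum-jerk displacement bursts. The normalized
minimum-jerk profile is

    s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5,   tau in [0, 1],

whose speed peaks at `15 D / (8 T)` for amplitude `D` and duration `T`
(used as a closed-form check on the speed computation). A single-burst
reach is one profile of amplitude `g - h`. A reach with `k > 1`
submovements uses a primary burst covering 60% of the straight-line
distance, deflected laterally by a configurable aiming-error fraction
(default 0.15 of the reach distance), followed by `k - 1` equal
corrective bursts whose vector amplitudes sum exactly to the remainder —
so a noiseless reach always terminates on the target to machine
precision. Bursts have length `1.2 T / k` with evenly spaced onsets
(20% overlap), which keeps the speed profile's local maxima separable up
to `k = 5`. Superposition (rather than segmented replanning) was chosen
because it makes the planted number of speed peaks exactly controllable;
no generative model of submovements is claimed beyond that.

Gaussian i.i.d. position noise (default sd 2 mm) is added last;
smoothing is deliberately left to the analysis side so generator and
estimator concerns stay separate. Each trial gets a lognormal reaction
delay (median 0.15 s) before the first burst and a 0.5 s stationary hold
at the target.

Cohort covariates are drawn from the published baseline distributions of
the 26-patient study the pipeline re-implements, pooled over its two
13-subject arms: age 55.4 ± 10.9 yr, height 68.7 ± 3.7 in, mass
202.2 ± 38.5 lb, months since stroke 64.6 ± 57 (truncated positive),
intake upper-extremity Fugl-Meyer 37.2 ± 6.8 truncated to the
eligibility window [25, 49], intake Wolf Motor Function time
10.5 ± 12.5 s (truncated > 0.5), Box-and-Blocks 27.3 ± 12.4; the eight
binary indicators (sex, handedness, affected side, affected = dominant,
stroke type, three lesion sites) are independent Bernoulli draws at the
pooled observed proportions. No attempt is made to model the real
correlation structure among covariates, bimanual arm coupling, or any
intervention effect; the `treatment` indicator is carried through the
cohort table but excluded from the default design. Consequently the
generator supports tests of *recovery* (can the pipeline find planted
effects?) but says nothing about how strongly real kinematics predict
real clinical change.

Outcomes are simulated as `y = b0 + Z_std beta + eps`, with `beta`
sparse ("consequential covariates"). The default support —
`initial_uefm`, `age`, `height`, `max_max_perpendicular_distance`,
`mean_pre_movement_speed` — spans the clinical, demographic, and
movement domains and was chosen among generated columns with only mild
mutual correlation so that support recovery is identifiable; movement
summaries derived from the same trials are strongly cross-correlated
(e.g. mean maximum speed vs. mean arrest-period ratio at r ≈ 0.97 in
the generator), and planting an effect there turns recovery into an
arbitrary choice among an equivalence class. The noise sd is calibrated
so that var(signal)/var(total) equals a requested signal fraction
(default 0.7).

Randomness is governed by one master seed; per-subject and per-trial
generators are derived as `SeedSequence([seed, stream, subject, trial])`
so any subset of the cohort is reproducible in isolation, and every
stage is bit-reproducible under a fixed seed.

## Trial metrics

Twelve metrics are computed per trial. Positions are low-pass filtered
(zero-phase 2nd-order Butterworth, default corner 10 Hz) and
differentiated by central differences; speed is the velocity norm.
Movement onset is the first linear-interpolated crossing of 0.06 m/s
after the cue (interpolation removes sample-rate bias in reaction time).
Definitions that the source literature leaves open are fixed as follows
and are switchable through `KinematicsConfig`:

* *Initial direction error*: angle between the velocity at the first
  counted speed peak after onset and the home-to-target line (the peak
  velocity is less noise-sensitive than the velocity at threshold
  crossing).
* *Initial movement ratio*: distance from home at the first local speed
  minimum after the first peak, over the straight-line distance — the
  fraction of the reach covered by the first launch.
* *Pre-movement speed*: trapezoidal mean speed between cue and onset.
* *Speed peaks*: local maxima of the smoothed speed with height and
  prominence at least 5% of the trial's maximum. The 5% floors are the
  smallest round values at which noiseless minimum-jerk bursts are
  counted exactly; a monotone profile whose maximum sits on the boundary
  still counts as one burst.
* *Arrest period ratio*: time below 10% of the trial's maximum speed
  over trial duration, with threshold crossings linearly interpolated
  within straddling sample intervals. (Classifying whole intervals at
  their midpoints leaves an O(h) discretization error that violates
  resampling stability at the 1% level; interpolation removes it.)

Trial time runs from cue to last sample. Undefined metrics (a trial that
never crosses the onset threshold, a stationary trial) are flagged
missing and excluded from that subject's summaries — never imputed.
All metrics are invariant under rigid rotation + translation of
(positions, home, target) to 1e-9 relative, verified in tests; the
ratio-type metrics are additionally invariant to uniform spatial
scaling, while maximum speed, perpendicular distance, and pre-movement
speed scale linearly.

## Design matrices

Per subject, each metric's mean, maximum, and sample variance (n−1
denominator) over non-missing trials give 36 movement summaries; a
summary needs at least 2 trials, else it is flagged. With the 15
clinical/demographic covariates the first-order design has
3·12 + 15 = 51 named columns. The second-order design appends squares
and all pairwise products (51 + 51 + 1275 = 1377 columns before
cleaning), then drops constant and exact-duplicate columns — squares of
0/1 indicators always duplicate their base, so a fully varying schema
cleans to 1369. Binary×binary interactions are kept (co-occurrence
information). Subjects with any flagged summary are excluded from model
fits (complete-case); mean imputation is available behind a config flag.

Standardization is always computed from a stated row subset (the
training folds) and applied to all rows; zero-variance columns are
dropped and recorded, and the scaling record supports exact inverse
transformation of fitted coefficients. Column statistics are computed
per column, independent of sibling columns, so fits on different feature
subsets of the same table are bitwise comparable (blocked 2-D reductions
would otherwise perturb last-ulp values when the table width changes);
for the same reason all arrays handed to numerical kernels are made
C-contiguous first.

## Penalized models

The elastic net is fixed in the convention

    (1/N) ||y - b0 - X b||_2^2 + lam [ a ||b||_1 + (1-a) ||b||_2^2 ],

with unpenalized intercept; `a = 1` is the LASSO, `a = 0` ridge, and the
mixing grid {0, 0.1, …, 1.0} is run as separate families. Coordinate
descent is delegated to scikit-learn via the exact correspondence
`alpha_sklearn = lam (1 - a/2)`, `l1_ratio = a / (2 - a)`; pure ridge
uses an SVD solve. The mapping is verified against three independent
oracles: soft-thresholding on a centered orthonormal design
(`b_j = S(x_j' y / N, lam/2)` when `x_j' x_j = N`), ridge normal
equations, and a proximal-gradient minimizer of the objective itself on
random instances (agreement ≈ 1e-13, tested at 1e-5).

Penalty strength is chosen by the one-standard-error rule on a k-fold
cross-validation curve over 100 log-spaced penalties from `lam_max`
(the smallest penalty with all-zero solution,
`max_j |2 x_j'(y - ybar)| / (N a)`) down to `lam_max/1000`: the chosen
penalty is the largest whose mean fold error is within one standard
error of the minimum. Least-angle regression reuses the same rule over
path length (fewest steps within one SE); random forests
(bootstrap + per-split feature subsetting, default 50 000 trees as in
the study design, far fewer in tests) serve as a non-linear benchmark
whose impurity importances are reported as diagnostics only — they are
unreliable at cohort-scale n.

Evaluation is `repeats × k`-fold cross-validation (default 100 × 4).
Within each training split, standardization statistics and the penalty
(by an inner 4-fold 1-SE selection — nested, so reported performance
contains no selection leakage; whether the original analysis nested its
selection is not documented, and a pre-chosen penalty can be supplied
instead) are computed from training rows only. Each repeat pools its
out-of-fold predictions into one RMSE and one adjusted
R² = 1 − (1 − R²)(n − 1)/(n − p_sel − 1), with p_sel the mean number of
selected features across the k folds; when p_sel ≥ n − 1 the adjusted
value is undefined and flagged (this happens systematically for ridge
and terminal LARS at n = 26 with 51 predictors — plain R² is reported
alongside). Fold partitions are a deterministic function of the master
seed and repeat index alone, never of the feature columns.

## Feature ranking

*Selection frequency* (sufficiency): the proportion of repeated-CV LASSO
fits in which a feature's coefficient is nonzero at the chosen penalty.
The default counts each fold-level fit (k·repeats fits); per-repeat
consensus modes (`any` / `majority` / `all`) are available since the
aggregation level is not uniquely determined by the procedure's verbal
description. Correlated features behave as motifs — the LASSO keeps
whichever member it meets first — so proportions of near-duplicates
trade off against each other and should be read group-wise.

*Exclusion delta* (necessity): for each feature j and each repeat,
Δ_j = adjR²(full) − adjR²(without j), refit on identical fold partitions
and inner seeds in both arms (common random numbers; this paired design
makes Δ_j exactly zero, repeat by repeat, for a column the model never
sees, and substantially reduces the variance of every paired
difference). The distribution over repeats is summarised by median and
quartiles; no multiple-testing adjustment is applied — the distributions
are descriptive. A feature whose removal is compensated by correlated
survivors can show Δ_j ≈ 0 despite being genuinely informative.

## Problem sizes and what the tests show

The test suite and acceptance script run: structural count identities on
the 26 × 20 cohort; solver-oracle agreement on (n = 20, p = 8)
instances across the mixing grid; kinematic closed forms at 100 Hz;
ground-truth recovery on five replicate synthetic studies at n = 200
subjects × 20 trials with the 5-feature support at signal fraction 0.7
under 100 × 4-fold LASSO (support features are each selected in ≥ 80%
of fits, the median null feature in ≤ 20%); paired exclusion deltas at
(n = 80, p = 10) with 100 repeats; and byte-identical repetition of a
full pipeline run. n = 200 makes recovery statistically comfortable
while a whole replicate study (generation → metrics → 100×4 CV) stays
around a minute; at the study's own n = 26 the same pipeline yields
out-of-fold R² near zero on synthetic data — an honest reflection of
nested evaluation on an overdetermined design, and the reason recovery
claims are made at n = 200 only.

## Known limitations

* The generator's covariates are mutually independent and its outcome
  model is linear-Gaussian; passing recovery tests does not certify
  behaviour under real covariate correlation, discrete outcome scales,
  or model misspecification.
* Movement summaries inherit strong cross-correlations from the shared
  trajectory model, which is realistic in kind but not calibrated in
  magnitude.
* Selection frequency and exclusion deltas are descriptive stability
  measures, not inference; no error control is attempted.
* The Wolf Motor Function time score is inversely related to ability;
  outcomes are modelled as signed change scores throughout and the sign
  is a matter of interpretation, not of processing.
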