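# reachrank

Predicting change in post-stroke clinical outcome scores from baseline
reach kinematics — a tested re-implementation of a prognostic-modelling
pipeline for upper-limb stroke rehabilitation, with a synthetic cohort
generator standing in for the (undeposited) patient data.

## The problem

After a rehabilitation intervention, which baseline characteristics of a
chronic stroke survivor predict how much their clinical scores — the
Upper-Extremity Fugl-Meyer (UEFM, motor ability, higher = better) and
the Wolf Motor Function Test (WMFT, timed function, higher = worse) —
will change? The setting is "high p, low n": for each of N = 26
subjects, 20 centre-out reaches yield p = 12 movement metrics per trial
(reaction time, trial time, initial direction error, pre-movement speed,
maximum speed, initial movement ratio, speed ratio, path length ratio,
number of speed peaks, maximum perpendicular distance, percentage of
movement in the target direction, arrest period ratio), summarised per
subject by mean X̄ᵢⱼ, maximum Mᵢⱼ, and variance Vᵢⱼ. Together with
q = 15 demographic/clinical covariates Zᵢₗ this gives the first-order
design of p\* = 3p + q = 51 features

    xᵢ = [X̄ᵢ₁, …, X̄ᵢₚ, Mᵢ₁, …, Mᵢₚ, Vᵢ₁, …, Vᵢₚ, Zᵢ₁, …, Zᵢ_q],

and a second-order design (> 1300 columns) adds squares and pairwise
interactions.

## The method

Change scores are regressed on xᵢ with the elastic net,

    min_{β₀,β} (1/N)‖y − β₀ − Xβ‖² + λ[α‖β‖₁ + (1−α)‖β‖₂²],

over the mixing grid α ∈ {0, 0.1, …, 1.0} (ridge → LASSO), plus
least-angle regression (LARS) and random forests as benchmarks. λ is
chosen by the one-standard-error rule — the largest λ whose mean
cross-validation error is within one SE of the minimum — *inside* each
training split (nested selection), and every model family is evaluated
by 100 repeats of 4-fold cross-validation, pooling out-of-fold
predictions into per-repeat RMSE and adjusted R². Features are then
ranked two ways:

* **selection frequency** (sufficiency): the proportion of repeated-CV
  LASSO fits in which a feature's coefficient is nonzero;
* **exclusion Δⱼ** (necessity): the drop in cross-validated adjusted R²
  when feature j is removed and the model refit on identical fold
  partitions, as a full distribution over repeats.

Because the patient cohort is not deposited, the package includes a
first-class synthetic-data module: minimum-jerk reaches with a planted
number of corrective submovements, cohort covariates drawn from the
study's published baseline distributions, and a sparse linear outcome
model with known "consequential covariates" and calibrated signal
fraction. See `docs/methods.md` for model details and design choices.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study at
the original design size (26 subjects × 20 reaches), writing artifacts
under `results/study/`:

```sh
python analysis/01_simulate_cohort.py    # cohort.csv + 520 trajectories
python analysis/02_extract_kinematics.py # trial_metrics.csv (520 rows)
python analysis/03_assemble_features.py  # 26x51 design + outcomes
python analysis/04_fit_models.py         # repeated-CV model comparison
python analysis/05_rank_features.py      # stability ranking + chart
```

`04_fit_models.py` prints, for the default seed:

```
    lasso: out-of-fold R^2 -0.080, adjusted R^2 -0.222 ± 0.158, RMSE 6.34 (100 repeats)
     enet: out-of-fold R^2 -0.067, adjusted R^2 -0.413 ± 0.364, RMSE 6.30 (25 repeats)
    ridge: out-of-fold R^2 -0.089, adjusted R^2 undefined (>= n features selected), RMSE 6.37 (25 repeats)
     lars: out-of-fold R^2 -0.097, adjusted R^2 -0.186 ± 0.194, RMSE 6.39 (25 repeats)
       rf: out-of-fold R^2 -0.020, adjusted R^2 undefined (>= n features selected), RMSE 6.16 (25 repeats)
intercept: out-of-fold R^2 -0.094, adjusted R^2 -0.094 ± 0.067, RMSE 6.38 (100 repeats)
```

Read this as the honest face of the high-p/low-n problem: with 51
candidate predictors, 26 subjects, and leakage-free nested evaluation,
no family beats the intercept-only baseline by a meaningful margin on
synthetic data at signal fraction 0.7, and the dense families (ridge,
terminal LARS, forest) select so many features that adjusted R² is
undefined at n = 26. `05_rank_features.py` then prints the stability
ranking:

```
top 10 by selection proportion:
  height                              selected 0.39  delta median +0.007  r +0.57
  max_max_perpendicular_distance      selected 0.32  delta median -0.013  r -0.49
  initial_uefm                        selected 0.30  delta median -0.024  r -0.47
  var_initial_direction_error         selected 0.28  delta median +0.000  r +0.53
  age                                 selected 0.24  delta median +0.000  r -0.34
  ...
4/5 consequential covariates in the top 10: age, height, initial_uefm,
max_max_perpendicular_distance
```

Even though prediction fails at this sample size, selection frequency
still concentrates on genuinely consequential covariates — four of the
five planted effects reach the top 10, with proportions far below 1
(the "no concrete statements" regime). The same pipeline at n = 200
recovers the planted support essentially perfectly (each support
feature selected in ≥ 99% of fits, median null feature ≈ 0%) — sample
size, not the machinery, is the binding constraint. The ranking chart
written alongside mirrors the study-style presentation: red diamonds
for selection proportion, blue per-repeat dots and quartile boxes for
the exclusion-adjusted R², outcome correlations per row.

A `reachrank` CLI wraps the same stages
(`reachrank simulate|extract|assemble|fit|rank|all --config cfg.yaml
--seed N --out DIR`), and the library API
(`reachrank.simulate`, `.kinematics`, `.features`, `.models`,
`.ranking`, `.pipeline`) is what the scripts, tests, and CLI all call.

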