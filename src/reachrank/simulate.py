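"""Synthetic cohort, trajectory, and outcome generation.

The generator emulates the study design the pipeline targets: a cohort of
chronic stroke survivors (default N = 26) each performing 20 centre-out
reaches to 4 pseudorandomly chosen targets, with demographic/clinical
covariates drawn from the published baseline distributions, and a sparse
linear outcome model with known ground truth so that feature-recovery
behaviour can be tested end to end.

Reaches are built as a primary minimum-jerk displacement toward the target
plus a configurable number of smaller, overlapping minimum-jerk corrective
bursts, then i.i.d. Gaussian position noise. Every draw is controlled by a
single master seed; per-subject and per-trial streams are derived through
``numpy.random.SeedSequence([seed, subject, trial])`` so any subset of the
cohort is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import Trajectory

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_trajectory",
    "simulate_cohort",
    "simulate_outcomes",
    "noise_sd_for_signal_fraction",
    "COVARIATE_COLUMNS",
    "BINARY_COVARIATES",
]

# Baseline covariate distributions, pooled over the two 13-subject study
# arms: continuous -> (mean, sd, lower, upper); binary -> P(1).
CONTINUOUS_COVARIATES: dict[str, tuple[float, float, float | None, float | None]] = {
    "age": (55.4, 10.9, 18.0, 95.0),
    "height": (68.7, 3.7, 48.0, 90.0),          # inches
    "mass": (202.2, 38.5, 80.0, 400.0),         # pounds
    "months_since_stroke": (64.6, 57.0, 6.0, None),
    "initial_uefm": (37.2, 6.8, 25.0, 49.0),    # intake range 25-49
    "initial_wmft": (10.5, 12.5, 0.5, None),    # seconds; higher = worse
    "initial_bb": (27.3, 12.4, 0.0, None),      # blocks moved
}

BINARY_COVARIATES: dict[str, float] = {
    "female": 10 / 26,
    "left_dominant_arm": 5 / 26,
    "left_affected_arm": 14 / 26,
    "affected_is_dominant": 11 / 26,
    "hemorrhagic_stroke": 9 / 26,
    "cortical_lesion": 13 / 26,
    "subcortical_lesion": 15 / 26,
    "brainstem_lesion": 4 / 26,
}

#: The q = 15 subject covariates, in canonical column order.
COVARIATE_COLUMNS = (
    "age",
    "height",
    "mass",
    "months_since_stroke",
    "female",
    "left_dominant_arm",
    "left_affected_arm",
    "affected_is_dominant",
    "hemorrhagic_stroke",
    "cortical_lesion",
    "subcortical_lesion",
    "brainstem_lesion",
    "initial_uefm",
    "initial_wmft",
    "initial_bb",
)


@dataclass
class SimConfig:
    """Conditions for one synthetic cohort.

    Defaults mirror the study design: 20 reaches per subject to 4 targets
    placed 15 cm from the home position, 100 Hz sampling, ~1 s reaches with
    up to 5 corrective submovements and 2 mm sensor noise.
    """

    n_subjects: int = 26
    n_trials: int = 20
    n_targets: int = 4
    reach_distance: float = 0.15        # metres
    reach_duration: float = 1.0         # seconds of actual movement
    n_submovements_range: tuple[int, int] = (1, 5)   # inclusive
    noise_sd: float = 0.002             # metres
    sample_rate: float = 100.0          # Hz
    seed: int = 0
    reaction_delay_mean: float = 0.15   # seconds, lognormal-ish delay after cue
    hold_time: float = 0.5              # stationary tail at the target
    lateral_error_frac: float = 0.15    # initial aiming error, fraction of D

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.reach_distance <= 0:
            raise ValueError("reach_distance must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        lo, hi = self.n_submovements_range
        if lo < 1 or hi < lo:
            raise ValueError("n_submovements_range lower bound must be >= 1")


@dataclass
class GroundTruth:
    """Sparse linear data-generating process for the outcome.

    ``coefficients`` maps feature names to effects in outcome units per
    standardized feature unit; the support is the set of features with a
    nonzero coefficient (the consequential covariates).
    """

    coefficients: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def support(self) -> set[str]:
        return {k for k, v in self.coefficients.items() if v != 0.0}


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk displacement profile on [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _perpendicular_unit(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A unit vector orthogonal to u with a random azimuth about it."""
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, u)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    phi = rng.uniform(0, 2 * np.pi)
    return np.cos(phi) * e1 + np.sin(phi) * e2


def simulate_trajectory(
    home: np.ndarray,
    target: np.ndarray,
    n_submovements: int = 1,
    duration: float = 1.0,
    noise_sd: float = 0.0,
    sample_rate: float = 100.0,
    seed: int = 0,
    *,
    reaction_delay: float = 0.0,
    hold_time: float = 0.0,
    lateral_error_frac: float = 0.15,
    primary_fraction: float = 0.6,
    subject_id: str = "s0",
    trial_index: int = 0,
) -> Trajectory:
    """Simulate one reach from ``home`` to ``target``.

    The reach is a primary minimum-jerk burst covering ``primary_fraction``
    of the straight-line distance (with an initial lateral aiming error for
    multi-burst reaches) followed by ``n_submovements - 1`` smaller
    corrective bursts whose displacements sum exactly to the remainder, so
    a noiseless reach terminates on the target to machine precision. The
    cue is at t = 0; movement starts after ``reaction_delay``.
    """
    home = np.asarray(home, dtype=float)
    target = np.asarray(target, dtype=float)
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sample_rate < 20:
        raise ValueError("sample_rate below 20 Hz cannot resolve submovements")
    if n_submovements < 1:
        raise ValueError("n_submovements must be >= 1")
    if np.allclose(home, target):
        raise ValueError("home and target must differ")

    rng = np.random.default_rng(seed)
    reach = target - home
    dist = np.linalg.norm(reach)
    u = reach / dist

    if n_submovements == 1:
        onsets = np.array([reaction_delay])
        durations = np.array([duration])
        amplitudes = [reach]
    else:
        n = n_submovements
        d = 1.2 * duration / n                 # burst length, 20% overlap
        g = (duration - d) / (n - 1)           # onset spacing
        onsets = reaction_delay + g * np.arange(n)
        durations = np.full(n, d)
        lateral = lateral_error_frac * dist * _perpendicular_unit(u, rng)
        primary = primary_fraction * dist * u + lateral
        correction = ((1 - primary_fraction) * dist * u - lateral) / (n - 1)
        amplitudes = [primary] + [correction] * (n - 1)

    t_end = reaction_delay + duration + hold_time
    n_samples = int(round(t_end * sample_rate)) + 1
    times = np.arange(n_samples) / sample_rate
    pos = np.tile(home, (n_samples, 1))
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        pos = pos + np.outer(_min_jerk((times - onset) / dur), amp)
    if noise_sd > 0:
        pos = pos + rng.normal(0.0, noise_sd, size=pos.shape)

    return Trajectory(
        times=times, positions=pos, home=home, target=target,
        cue_time=0.0, subject_id=subject_id, trial_index=trial_index,
    )


def _trial_seed(master: int, subject: int, trial: int) -> int:
    """Counter-based per-trial seed: reproducible for any cohort subset."""
    return int(
        np.random.SeedSequence([master, 2, subject, trial]).generate_state(1)[0]
    )


def default_targets(reach_distance: float, n_targets: int = 4) -> np.ndarray:
    """Target locations on a frontal arc at the configured reach distance."""
    az = np.linspace(-60, 60, n_targets) * np.pi / 180
    return reach_distance * np.column_stack(
        [np.sin(az), np.cos(az) * np.cos(0.3), np.full(n_targets, np.sin(0.3))]
    )


def _draw_truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float | None,
    hi: float | None,
    size: int,
) -> np.ndarray:
    """Rejection-sampled truncated normal (bounds are wide; few retries)."""
    out = rng.normal(mean, sd, size)
    lo_ = -np.inf if lo is None else lo
    hi_ = np.inf if hi is None else hi
    bad = (out < lo_) | (out > hi_)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo_) | (out > hi_)
    return out


def simulate_cohort(cfg: SimConfig) -> tuple[pd.DataFrame, list[Trajectory]]:
    """Generate the subject table and all reach trajectories for a cohort.

    Returns a DataFrame with one row per subject (all baseline covariates
    plus a ``treatment`` arm indicator, half the cohort each) and a flat
    list of ``n_subjects * n_trials`` trajectories. Target locations cycle
    pseudorandomly over ``cfg.n_targets`` positions on a frontal arc.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    n = cfg.n_subjects

    cols: dict[str, np.ndarray] = {
        "subject_id": np.array([f"s{i:03d}" for i in range(n)]),
    }
    for name in COVARIATE_COLUMNS:
        if name in CONTINUOUS_COVARIATES:
            mean, sd, lo, hi = CONTINUOUS_COVARIATES[name]
            cols[name] = np.round(_draw_truncated_normal(rng, mean, sd, lo, hi, n), 2)
        else:
            cols[name] = (rng.random(n) < BINARY_COVARIATES[name]).astype(int)
    arm = np.zeros(n, dtype=int)
    arm[rng.permutation(n)[: n // 2]] = 1
    cols["treatment"] = arm
    subjects = pd.DataFrame(cols)

    lo, hi = cfg.n_submovements_range
    trajectories: list[Trajectory] = []
    targets = default_targets(cfg.reach_distance, cfg.n_targets)
    for i in range(n):
        srng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1, i]))
        for k in range(cfg.n_trials):
            tgt = targets[srng.integers(cfg.n_targets)]
            n_sub = int(srng.integers(lo, hi + 1))
            delay = float(srng.lognormal(np.log(cfg.reaction_delay_mean), 0.4))
            traj = simulate_trajectory(
                home=np.zeros(3),
                target=tgt,
                n_submovements=n_sub,
                duration=cfg.reach_duration,
                noise_sd=cfg.noise_sd,
                sample_rate=cfg.sample_rate,
                seed=_trial_seed(cfg.seed, i, k),
                reaction_delay=delay,
                hold_time=cfg.hold_time,
                lateral_error_frac=cfg.lateral_error_frac,
                subject_id=f"s{i:03d}",
                trial_index=k,
            )
            trajectories.append(traj)
    return subjects, trajectories


def simulate_outcomes(
    features: pd.DataFrame, truth: GroundTruth, seed: int = 0
) -> pd.Series:
    """Draw outcomes y = b0 + Z_std @ beta + N(0, noise_sd) from ``truth``.

    Features named in ``truth.coefficients`` must be columns of
    ``features``; they are standardized (population mean/sd over the table)
    before the linear predictor is formed, so coefficients are in outcome
    units per standard deviation of the feature.
    """
    missing = sorted(set(truth.coefficients) - set(features.columns))
    if missing:
        raise KeyError(f"ground-truth features not in table: {missing}")
    rng = np.random.default_rng(seed)
    y = np.full(len(features), truth.intercept, dtype=float)
    for name, beta in truth.coefficients.items():
        col = features[name].to_numpy(dtype=float)
        sd = col.std()
        if sd > 0:
            y += beta * (col - col.mean()) / sd
    if truth.noise_sd > 0:
        y = y + rng.normal(0.0, truth.noise_sd, size=len(y))
    return pd.Series(y, index=features.index, name="outcome")


def noise_sd_for_signal_fraction(
    features: pd.DataFrame, truth: GroundTruth, signal_fraction: float
) -> float:
    """Noise sd that makes var(signal)/var(total) equal ``signal_fraction``."""
    if not 0 < signal_fraction <= 1:
        raise ValueError("signal_fraction must be in (0, 1]")
    signal = simulate_outcomes(
        features, GroundTruth(truth.coefficients, truth.intercept, 0.0), seed=0
    ).to_numpy()
    var_sig = signal.var()
    return float(np.sqrt(var_sig * (1 - signal_fraction) / signal_fraction))
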