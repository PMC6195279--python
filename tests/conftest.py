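"""Shared fixtures: synthetic cohorts and hand-built trajectories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from reachrank.features import assemble_first_order, summarize_subjects
from reachrank.kinematics import Trajectory, extract_trial_metrics
from reachrank.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort26():
    """Study-sized cohort: 26 subjects x 20 reaches, fixed seed."""
    cfg = SimConfig(n_subjects=26, n_trials=20, seed=7)
    subjects, trajectories = simulate_cohort(cfg)
    return cfg, subjects, trajectories


@pytest.fixture(scope="session")
def trial_metrics26(cohort26):
    _, _, trajectories = cohort26
    rows = [extract_trial_metrics(t).to_dict() for t in trajectories]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def feature_table26(cohort26, trial_metrics26):
    _, subjects, _ = cohort26
    return assemble_first_order(summarize_subjects(trial_metrics26), subjects)


def path_trajectory(points: np.ndarray, home, target, duration: float = 1.0,
                    samples_per_leg: int = 50) -> Trajectory:
    """Trajectory following straight legs through ``points`` at uniform
    parameter speed (geometry-only metrics: PLR, PMTD, MPD)."""
    points = np.asarray(points, dtype=float)
    legs = [
        np.linspace(points[i], points[i + 1], samples_per_leg, endpoint=False)
        for i in range(len(points) - 1)
    ]
    pos = np.vstack(legs + [points[-1:]])
    times = np.linspace(0, duration, len(pos))
    return Trajectory(times, pos, np.asarray(home, float), np.asarray(target, float))


def bump_trajectory(amplitudes, directions, width: float = 0.2,
                    gap: float = 0.3, sample_rate: float = 200.0,
                    lead: float = 0.0) -> Trajectory:
    """Trajectory whose speed profile is a train of sin^2 bursts.

    Burst i has peak speed ``amplitudes[i]`` along unit vector
    ``directions[i]``; bursts are disjoint (width < gap), so speed drops to
    zero between them. Home is the start; target is the end position.
    """
    amplitudes = np.asarray(amplitudes, float)
    directions = np.asarray(directions, float)
    n = len(amplitudes)
    t_end = lead + gap * (n - 1) + width
    times = np.arange(int(round(t_end * sample_rate)) + 1) / sample_rate
    vel = np.zeros((len(times), 3))
    for i in range(n):
        t0 = lead + i * gap
        in_burst = (times >= t0) & (times <= t0 + width)
        phase = (times[in_burst] - t0) / width
        vel[in_burst] += np.outer(
            amplitudes[i] * np.sin(np.pi * phase) ** 2, directions[i]
        )
    dt = np.diff(times)
    pos = np.vstack([np.zeros(3),
                     np.cumsum(0.5 * (vel[:-1] + vel[1:]) * dt[:, None], axis=0)])
    target = pos[-1] if np.linalg.norm(pos[-1]) > 0 else np.array([1.0, 0, 0])
    return Trajectory(times, pos, np.zeros(3), target)
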