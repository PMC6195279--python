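"""Per-trial reach kinematics.

Computes the twelve movement metrics used to summarise a single
centre-out reach from a time-stamped 3-D hand trajectory: reaction time,
trial time, initial direction error, pre-movement speed, maximum speed,
initial movement ratio, speed ratio, path length ratio, number of speed
peaks, maximum perpendicular distance, percentage of movement in the
target direction (PMTD), and arrest period ratio (APR).

Metrics that are undefined for a trial (e.g. a reach that never crosses
the movement-onset speed threshold) are returned as NaN and the reason is
recorded on the ``TrialMetrics.flags`` list; they are never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

logger = logging.getLogger(__name__)

#: Field names of the 12 per-trial movement metrics, in canonical order.
METRIC_NAMES = (
    "reaction_time",
    "trial_time",
    "initial_direction_error",
    "pre_movement_speed",
    "max_speed",
    "initial_movement_ratio",
    "speed_ratio",
    "path_length_ratio",
    "num_speed_peaks",
    "max_perpendicular_distance",
    "pmtd",
    "arrest_period_ratio",
)


@dataclass
class Trajectory:
    """One reach: hand positions over time plus home/target geometry.

    Parameters
    ----------
    times : array of float, seconds, strictly increasing
    positions : (n, 3) array of float, metres
    home, target : length-3 arrays, metres; must differ
    cue_time : float, seconds — when the target appeared
    """

    times: np.ndarray
    positions: np.ndarray
    home: np.ndarray
    target: np.ndarray
    cue_time: float = 0.0
    subject_id: str = "s0"
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.home = np.asarray(self.home, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.times.ndim != 1 or self.times.size < 10:
            raise ValueError("trajectory needs at least 10 samples")
        if self.positions.shape != (self.times.size, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"({self.times.size}, 3)"
            )
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.allclose(self.home, self.target):
            raise ValueError("home and target must differ")

    @property
    def reach_vector(self) -> np.ndarray:
        return self.target - self.home

    @property
    def reach_distance(self) -> float:
        return float(np.linalg.norm(self.reach_vector))


@dataclass
class SpeedProfile:
    """Tangential speed of the hand over time (m/s, nonnegative)."""

    times: np.ndarray
    speed: np.ndarray

    @property
    def max_speed(self) -> float:
        return float(np.max(self.speed))


@dataclass
class KinematicsConfig:
    """Tunable detection parameters shared by the metric functions.

    smooth_cutoff
        Zero-phase low-pass corner frequency applied to positions before
        differentiation, Hz. ``None`` disables smoothing.
    v_thresh
        Movement-onset speed threshold, m/s.
    floor_frac, prominence_frac
        A local speed maximum counts as a peak only if its height and
        prominence both exceed these fractions of the trial's maximum speed.
    """

    smooth_cutoff: float | None = 10.0
    v_thresh: float = 0.06
    floor_frac: float = 0.05
    prominence_frac: float = 0.05


@dataclass
class TrialMetrics:
    """The 12 movement metrics for one trial; NaN marks a missing value."""

    reaction_time: float = np.nan
    trial_time: float = np.nan
    initial_direction_error: float = np.nan
    pre_movement_speed: float = np.nan
    max_speed: float = np.nan
    initial_movement_ratio: float = np.nan
    speed_ratio: float = np.nan
    path_length_ratio: float = np.nan
    num_speed_peaks: float = np.nan
    max_perpendicular_distance: float = np.nan
    pmtd: float = np.nan
    arrest_period_ratio: float = np.nan
    subject_id: str = "s0"
    trial_index: int = 0
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, float]:
        out = {name: getattr(self, name) for name in METRIC_NAMES}
        out["subject_id"] = self.subject_id
        out["trial_index"] = self.trial_index
        return out


def _smooth_positions(traj: Trajectory, cutoff: float | None) -> np.ndarray:
    """Zero-phase low-pass of the position samples (linear, so metric
    invariances under rigid motion are preserved)."""
    if cutoff is None:
        return traj.positions
    dt = np.diff(traj.times)
    fs = 1.0 / np.median(dt)
    # filtfilt assumes uniform sampling; skip smoothing otherwise
    if np.max(np.abs(dt - np.median(dt))) > 1e-6 * np.median(dt):
        return traj.positions
    if cutoff >= 0.5 * fs:  # at/above Nyquist: nothing to remove
        return traj.positions
    b, a = butter(2, cutoff / (0.5 * fs))
    padlen = min(3 * max(len(a), len(b)), traj.positions.shape[0] - 1)
    return filtfilt(b, a, traj.positions, axis=0, padlen=padlen)


def compute_velocity(
    traj: Trajectory, smooth_cutoff: float | None = 10.0
) -> np.ndarray:
    """(n, 3) hand velocity by central differences (one-sided at the ends)."""
    pos = _smooth_positions(traj, smooth_cutoff)
    return np.gradient(pos, traj.times, axis=0)


def compute_speed(traj: Trajectory, smooth_cutoff: float | None = 10.0) -> SpeedProfile:
    """Tangential speed: norm of the time-derivative of (smoothed) position."""
    vel = compute_velocity(traj, smooth_cutoff)
    return SpeedProfile(times=traj.times, speed=np.linalg.norm(vel, axis=1))


def _first_crossing(speed: SpeedProfile, t_from: float, v_thresh: float) -> float:
    """First time >= t_from with speed >= v_thresh, linearly interpolated
    between samples at the crossing; NaN if the threshold is never crossed."""
    t, v = speed.times, speed.speed
    mask = t >= t_from
    if not mask.any():
        return np.nan
    idx = np.nonzero(mask)[0]
    if v[idx[0]] >= v_thresh:
        return float(t_from)
    above = idx[v[idx] >= v_thresh]
    if above.size == 0:
        return np.nan
    i = above[0]
    t0, t1, v0, v1 = t[i - 1], t[i], v[i - 1], v[i]
    if v1 == v0:
        return float(t1)
    frac = (v_thresh - v0) / (v1 - v0)
    return float(max(t0 + frac * (t1 - t0), t_from))


def reaction_time(
    traj: Trajectory, speed: SpeedProfile, v_thresh: float = 0.06
) -> float:
    """Seconds from target appearance to the speed threshold crossing."""
    onset = _first_crossing(speed, traj.cue_time, v_thresh)
    if np.isnan(onset):
        logger.warning(
            "subject %s trial %d: speed never reached %.3g m/s; "
            "reaction time missing", traj.subject_id, traj.trial_index, v_thresh,
        )
        return np.nan
    return onset - traj.cue_time


def movement_onset(
    traj: Trajectory, speed: SpeedProfile, v_thresh: float = 0.06
) -> float:
    """Absolute time of the movement-onset threshold crossing (NaN if never)."""
    onset = _first_crossing(speed, traj.cue_time, v_thresh)
    if np.isnan(onset):
        logger.warning(
            "subject %s trial %d: no movement onset detected",
            traj.subject_id, traj.trial_index,
        )
    return onset


def _peak_indices(speed: SpeedProfile, floor_frac: float, prominence_frac: float) -> np.ndarray:
    vmax = speed.max_speed
    if vmax <= 0:
        return np.array([], dtype=int)
    idx, _ = find_peaks(
        speed.speed, height=floor_frac * vmax, prominence=prominence_frac * vmax
    )
    return idx


def _first_peak_after(
    speed: SpeedProfile, t_from: float, floor_frac: float, prominence_frac: float
) -> int | None:
    """Index of the first counted speed peak at or after t_from.

    Falls back to the global argmax when peak detection finds nothing after
    t_from (e.g. a monotone rise to a boundary maximum).
    """
    idx = _peak_indices(speed, floor_frac, prominence_frac)
    idx = idx[speed.times[idx] >= t_from]
    if idx.size:
        return int(idx[0])
    later = speed.times >= t_from
    if not later.any() or speed.max_speed <= 0:
        return None
    sub = np.nonzero(later)[0]
    return int(sub[np.argmax(speed.speed[sub])])


def initial_direction_error(
    traj: Trajectory,
    onset: float,
    speed: SpeedProfile | None = None,
    cfg: KinematicsConfig | None = None,
) -> float:
    """Angle in [0, pi] between the hand velocity at the first speed peak
    after movement onset and the straight home-to-target direction."""
    cfg = cfg or KinematicsConfig()
    if np.isnan(onset):
        return np.nan
    if speed is None:
        speed = compute_speed(traj, cfg.smooth_cutoff)
    i = _first_peak_after(speed, onset, cfg.floor_frac, cfg.prominence_frac)
    if i is None:
        return np.nan
    vel = compute_velocity(traj, cfg.smooth_cutoff)[i]
    nv = np.linalg.norm(vel)
    if nv == 0:
        return np.nan
    cosang = np.dot(vel, traj.reach_vector) / (nv * traj.reach_distance)
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def pre_movement_speed(speed: SpeedProfile, cue_time: float, onset: float) -> float:
    """Mean speed between target appearance and movement onset (m/s)."""
    if np.isnan(onset):
        return np.nan
    if onset <= cue_time:
        return float(np.interp(cue_time, speed.times, speed.speed))
    # trapezoidal mean over [cue_time, onset), endpoints by interpolation
    grid = speed.times[(speed.times > cue_time) & (speed.times < onset)]
    t = np.concatenate(([cue_time], grid, [onset]))
    v = np.interp(t, speed.times, speed.speed)
    return float(np.trapezoid(v, t) / (onset - cue_time))


def speed_ratio(
    speed: SpeedProfile, onset: float, cfg: KinematicsConfig | None = None
) -> float:
    """Speed of the first launch divided by the trial's maximum speed."""
    cfg = cfg or KinematicsConfig()
    if np.isnan(onset) or speed.max_speed <= 0:
        return np.nan
    i = _first_peak_after(speed, onset, cfg.floor_frac, cfg.prominence_frac)
    if i is None:
        return np.nan
    return float(speed.speed[i] / speed.max_speed)


def path_length_ratio(traj: Trajectory) -> float:
    """Hand-path length over the straight-line home-to-target distance."""
    seg = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
    return float(np.sum(seg) / traj.reach_distance)


def num_speed_peaks(
    speed: SpeedProfile,
    prominence_frac: float = 0.05,
    floor_frac: float = 0.05,
) -> float:
    """Count of speed peaks above the height/prominence floors; 0 with a
    warning for a trial that never moves."""
    if speed.max_speed <= 0:
        logger.warning("stationary trial: no speed peaks")
        return 0.0
    idx = _peak_indices(speed, floor_frac, prominence_frac)
    if idx.size == 0:
        # boundary maximum (monotone profile): still one burst of movement
        return 1.0
    return float(idx.size)


def max_perpendicular_distance(traj: Trajectory) -> float:
    """Largest orthogonal distance of the hand from the home-target line."""
    u = traj.reach_vector / traj.reach_distance
    rel = traj.positions - traj.home
    perp = rel - np.outer(rel @ u, u)
    return float(np.max(np.linalg.norm(perp, axis=1)))


def pmtd(traj: Trajectory) -> float:
    """Percentage of movement in the target direction.

    Signed projections of successive path segments onto the home-to-target
    unit vector, summed and divided by total path length; segments moving
    away from the target contribute negatively. In [-100, 100].
    """
    u = traj.reach_vector / traj.reach_distance
    deltas = np.diff(traj.positions, axis=0)
    total = np.sum(np.linalg.norm(deltas, axis=1))
    if total == 0:
        return np.nan
    return float(100.0 * np.sum(deltas @ u) / total)


def arrest_period_ratio(speed: SpeedProfile) -> float:
    """Fraction of trial time spent below 10% of the trial's maximum speed.

    Speed is treated as piecewise linear between samples; intervals that
    straddle the threshold contribute the linearly interpolated sub-interval
    below it, so the ratio is stable under resampling.
    """
    vmax = speed.max_speed
    if vmax <= 0:
        logger.warning("stationary trial: arrest period ratio undefined")
        return np.nan
    thresh = 0.10 * vmax
    dt = np.diff(speed.times)
    v0, v1 = speed.speed[:-1], speed.speed[1:]
    lo = np.minimum(v0, v1)
    hi = np.maximum(v0, v1)
    frac = np.where(
        hi <= thresh, 1.0,
        np.where(lo >= thresh, 0.0, (thresh - lo) / np.maximum(hi - lo, 1e-300)),
    )
    total = speed.times[-1] - speed.times[0]
    return float(np.sum(frac * dt) / total)


def initial_movement_ratio(
    traj: Trajectory,
    speed: SpeedProfile,
    onset: float,
    cfg: KinematicsConfig | None = None,
) -> float:
    """Distance covered by the end of the first speed burst, relative to the
    straight-line target distance.

    The first burst ends at the first local speed minimum after the first
    counted speed peak; a single-burst reach therefore has ratio near 1.
    """
    cfg = cfg or KinematicsConfig()
    if np.isnan(onset):
        return np.nan
    i = _first_peak_after(speed, onset, cfg.floor_frac, cfg.prominence_frac)
    if i is None:
        return np.nan
    v = speed.speed
    end = len(v) - 1
    for j in range(i + 1, len(v) - 1):
        if v[j] <= v[j - 1] and v[j] <= v[j + 1]:
            end = j
            break
    dist = float(np.linalg.norm(traj.positions[end] - traj.home))
    return dist / traj.reach_distance


def extract_trial_metrics(
    traj: Trajectory, cfg: KinematicsConfig | None = None
) -> TrialMetrics:
    """Compute all 12 metrics for one trial.

    Sub-metrics that are undefined propagate as NaN with the reason appended
    to ``flags``; downstream summaries skip flagged values.
    """
    cfg = cfg or KinematicsConfig()
    m = TrialMetrics(subject_id=traj.subject_id, trial_index=traj.trial_index)
    speed = compute_speed(traj, cfg.smooth_cutoff)

    m.trial_time = float(traj.times[-1] - traj.cue_time)
    m.max_speed = speed.max_speed
    m.path_length_ratio = path_length_ratio(traj)
    m.max_perpendicular_distance = max_perpendicular_distance(traj)
    m.pmtd = pmtd(traj)
    m.arrest_period_ratio = arrest_period_ratio(speed)
    m.num_speed_peaks = num_speed_peaks(speed, cfg.prominence_frac, cfg.floor_frac)

    onset = movement_onset(traj, speed, cfg.v_thresh)
    if np.isnan(onset):
        m.flags.append("no movement onset: speed threshold never crossed")
    else:
        m.reaction_time = onset - traj.cue_time
        m.pre_movement_speed = pre_movement_speed(speed, traj.cue_time, onset)
        m.initial_direction_error = initial_direction_error(traj, onset, speed, cfg)
        m.speed_ratio = speed_ratio(speed, onset, cfg)
        m.initial_movement_ratio = initial_movement_ratio(traj, speed, onset, cfg)

    if speed.max_speed <= 0:
        m.flags.append("stationary trial: speed-dependent metrics missing")
    for f in fields(TrialMetrics):
        if f.name in METRIC_NAMES and np.isnan(getattr(m, f.name)):
            if not any(f.name in fl for fl in m.flags):
                m.flags.append(f"{f.name} missing")
    return m
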