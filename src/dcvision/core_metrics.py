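"""Shared data model and the startle/freeze computations.

Every modality in the pipeline (sparse video tracking, load platform, depth
camera, marker kinematics) is reduced to a per-frame nonnegative motion
statistic — a :class:`MotionSeries`.  The two Defence Cascade readouts are
then computed identically for all of them:

* **startle magnitude** — the peak of the series in a short window
  (default 0.7 s) after stimulus onset;
* **freeze duration** — the total time the series stays below a threshold
  for continuous runs of at least ``min_freeze_s`` (default 0.4 s) inside
  the post-stimulus record window (default 30 s).

The freeze threshold is empirical and is calibrated against observer-coded
ground-truth durations by repeated k-fold cross-validation
(:func:`calibrate_threshold`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold

__all__ = [
    "AnalysisConfig",
    "MotionSeries",
    "StartleResult",
    "FreezeResult",
    "ThresholdCalibration",
    "diff_kinematics",
    "startle_magnitude",
    "detect_freezes",
    "calibrate_threshold",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis constants shared by all modalities.

    Parameters
    ----------
    startle_window_s
        Length of the post-stimulus window scanned for the startle peak,
        in seconds.
    min_freeze_s
        Minimum continuous sub-threshold run that counts as a freeze,
        in seconds.  Shorter runs are discarded (they lack the sustained
        immobility of a true freeze).
    record_window_s
        Length of the post-stimulus record evaluated for freezes, seconds.
    top_k
        Number of fastest tracked points averaged per frame.
    n_init_points
        Tracker capacity: number of points the tracker is (re)initialised
        with.
    min_track_frames
        Consecutive valid frames a point needs before its acceleration is
        eligible (3 frames = the minimum for a second difference).
    cv_folds, cv_reps
        Fold count and repetition count for threshold cross-validation.
    rng_seed
        Seed for every stochastic step (fold assignment).
    """

    startle_window_s: float = 0.7
    min_freeze_s: float = 0.4
    record_window_s: float = 30.0
    top_k: int = 50
    n_init_points: int = 150
    min_track_frames: int = 3
    cv_folds: int = 10
    cv_reps: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.startle_window_s > 0 and self.min_freeze_s > 0
                and self.record_window_s > 0):
            raise ValueError("durations must be positive")
        if not self.min_freeze_s < self.record_window_s:
            raise ValueError("min_freeze_s must be < record_window_s")
        if not 1 <= self.top_k <= self.n_init_points:
            raise ValueError("need 1 <= top_k <= n_init_points")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


def window_frames(duration_s: float, rate_hz: float) -> int:
    """Window length in frames: ``round(duration_s * rate_hz)``.

    Half-open frame windows ``[t0, t0 + n)`` with 0-based indexing are used
    throughout, so a 0.7 s window is 140 frames at 200 Hz, 21 at 30 Hz and
    280 at 400 Hz.
    """
    return int(round(duration_s * rate_hz))


@dataclass
class MotionSeries:
    """A per-frame nonnegative motion statistic at a known rate.

    ``values`` are magnitudes in the native units of the modality
    (pixels/frame, pixels/frame^2, g, mm/frame, mm/frame^2 — see
    ``units_tag``); no cross-modality unit conversion is attempted, series
    are compared only through ranks and thresholds.  ``valid`` flags frames
    where the statistic is defined (e.g. enough consecutively tracked
    points); invalid frames hold NaN-safe zeros but are never interpreted.
    """

    values: np.ndarray
    rate_hz: float
    t0_index: int
    units_tag: str
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    source: str = ""  # producing modality, e.g. "klt", "load", "depth"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.ndim != 1 or self.values.shape != self.valid.shape:
            raise ValueError("values/valid must be matching 1-D arrays")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not 0 <= self.t0_index < len(self.values):
            raise ValueError("t0_index outside series")
        v = self.values[self.valid]
        if v.size and (not np.all(np.isfinite(v)) or np.any(v < 0)):
            raise ValueError("valid values must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class StartleResult:
    """Peak motion statistic in the post-stimulus startle window."""

    magnitude: float
    peak_frame: int
    window_frames: tuple[int, int]  # [start, end)


@dataclass(frozen=True)
class FreezeResult:
    """Sub-threshold runs surviving the minimum-duration rule."""

    intervals: tuple[tuple[int, int], ...]  # [start, end) frame runs
    total_duration_s: float
    threshold: float


@dataclass(frozen=True)
class ThresholdCalibration:
    """Outcome of repeated k-fold threshold cross-validation.

    ``threshold`` is the mean of the per-fold selected thresholds;
    ``per_fold_errors`` are the held-out mean absolute duration errors,
    one per (repetition, fold).
    """

    threshold: float
    per_fold_errors: tuple[float, ...]
    per_fold_thresholds: tuple[float, ...]
    folds: int
    reps: int
    seed: int


# ---------------------------------------------------------------------------
# kinematic differencing

def diff_kinematics(
    positions: np.ndarray,
    validity: np.ndarray | None = None,
    *,
    rate_hz: float,
    t0_index: int = 0,
    units: str = "units/frame",
) -> tuple[MotionSeries, MotionSeries]:
    """First- and second-difference magnitudes of a position track.

    ``positions`` is ``(T,)`` for a scalar coordinate (e.g. vertical
    height) or ``(T, d)`` for pixel/world coordinates.  Per frame ``t``::

        speed[t] = ||p[t] - p[t-1]||
        accel[t] = ||p[t] - 2 p[t-1] + p[t-2]||

    A frame's speed requires 2 consecutive valid positions ending at ``t``,
    its acceleration 3; frames without them are flagged invalid.
    """
    p = np.asarray(positions, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
    if p.ndim != 2:
        raise ValueError("positions must be (T,) or (T, d)")
    T = p.shape[0]
    if T < 3:
        raise ValueError("need at least 3 frames")
    if validity is None:
        valid = np.ones(T, dtype=bool)
    else:
        valid = np.asarray(validity, dtype=bool)
        if valid.shape != (T,):
            raise ValueError("validity must be (T,)")
    if not np.all(np.isfinite(p[valid])):
        raise ValueError("valid positions must be finite")

    pf = np.where(valid[:, None], p, 0.0)  # masked copy; invalid never read
    speed = np.zeros(T)
    accel = np.zeros(T)
    sv = np.zeros(T, dtype=bool)
    av = np.zeros(T, dtype=bool)
    sv[1:] = valid[1:] & valid[:-1]
    av[2:] = valid[2:] & valid[1:-1] & valid[:-2]
    d1 = np.linalg.norm(pf[1:] - pf[:-1], axis=1)
    d2 = np.linalg.norm(pf[2:] - 2 * pf[1:-1] + pf[:-2], axis=1)
    speed[1:][sv[1:]] = d1[sv[1:]]
    accel[2:][av[2:]] = d2[av[2:]]

    sp = MotionSeries(speed, rate_hz, t0_index, units, sv)
    ac = MotionSeries(accel, rate_hz, t0_index, units + "2"
                      if units.endswith("/frame") else units, av)
    return sp, ac


# ---------------------------------------------------------------------------
# startle magnitude

def startle_magnitude(series: MotionSeries,
                      config: AnalysisConfig | None = None) -> StartleResult:
    """Peak of the series in the post-stimulus startle window.

    The window is ``[t0, t0 + round(startle_window_s * rate_hz))``.  Only
    valid frames compete; ties resolve to the earliest frame.  A series too
    short to contain the full window is refused rather than silently
    truncated.
    """
    config = config or AnalysisConfig()
    n = window_frames(config.startle_window_s, series.rate_hz)
    start, end = series.t0_index, series.t0_index + n
    if end > len(series):
        raise ValueError(
            f"series ends at frame {len(series)} but the startle window "
            f"needs frames [{start}, {end})")
    vals = series.values[start:end]
    ok = series.valid[start:end]
    if not ok.any():
        raise ValueError("no valid frame in the startle window")
    masked = np.where(ok, vals, -np.inf)
    peak = int(np.argmax(masked))  # first occurrence on ties
    return StartleResult(float(masked[peak]), start + peak, (start, end))


# ---------------------------------------------------------------------------
# freeze detection

def detect_freezes(series: MotionSeries, threshold: float,
                   config: AnalysisConfig | None = None) -> FreezeResult:
    """Sub-threshold runs of at least ``min_freeze_s`` after the stimulus.

    A frame is frozen when its value is strictly below ``threshold``.
    Invalid frames break a run (immobility cannot be asserted without a
    measurement).  Runs are evaluated in the window
    ``[t0, t0 + round(record_window_s * rate_hz))``; a run truncated by the
    end of the window still counts if its observed duration qualifies.
    """
    config = config or AnalysisConfig()
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = window_frames(config.record_window_s, series.rate_hz)
    start = series.t0_index
    end = min(start + n, len(series))
    frozen = (series.values[start:end] < threshold) & series.valid[start:end]

    min_frames = window_frames(config.min_freeze_s, series.rate_hz)
    intervals: list[tuple[int, int]] = []
    total_frames = 0
    edges = np.flatnonzero(np.diff(np.r_[False, frozen, False]))
    for run_start, run_end in zip(edges[::2], edges[1::2]):
        if run_end - run_start >= min_frames:
            intervals.append((start + int(run_start), start + int(run_end)))
            total_frames += int(run_end - run_start)
    return FreezeResult(tuple(intervals), total_frames / series.rate_hz,
                        float(threshold))


# ---------------------------------------------------------------------------
# threshold calibration

def _candidate_grid(series_set: Sequence[MotionSeries],
                    n_candidates: int = 200) -> np.ndarray:
    """Log-spaced candidate thresholds spanning the pooled value range."""
    pooled = np.concatenate([s.values[s.valid] for s in series_set])
    pos = pooled[pooled > 0]
    if pos.size == 0:
        return np.array([1.0])
    lo, hi = pos.min(), pooled.max()
    if hi <= lo:
        return np.array([float(hi)])
    # slightly above the smallest positive value so a strict '<' can bite
    return np.geomspace(lo * 1.001, hi, n_candidates)


def calibrate_threshold(
    series_set: Sequence[MotionSeries],
    observer_durations: Sequence[float],
    config: AnalysisConfig | None = None,
) -> ThresholdCalibration:
    """Cross-validated freeze threshold against observer durations.

    For each of ``cv_reps`` repetitions the tests are shuffled (seeded) into
    ``cv_folds`` folds.  For every fold, a grid of 200 log-spaced candidate
    thresholds spanning the pooled value range is searched on the training
    90%: the candidate minimising the mean absolute error between the
    detected total freeze duration and the observer duration is selected,
    and its error on the held-out 10% is recorded.  The final threshold is
    the mean of the fold-selected thresholds.

    The training error is typically flat over a plateau of candidate
    thresholds (the band separating immobility from baseline motion);
    the median candidate of the minimising set is selected so the
    threshold sits mid-band rather than at its edge, where measurement
    noise would make run boundaries fragile.
    """
    config = config or AnalysisConfig()
    series_set = list(series_set)
    obs = np.asarray(observer_durations, dtype=float)
    if len(series_set) != len(obs):
        raise ValueError("series and observer durations must align")
    if len(series_set) < config.cv_folds:
        raise ValueError(
            f"{len(series_set)} tests < cv_folds={config.cv_folds}")

    grid = _candidate_grid(series_set)
    # duration matrix: durations[i, j] = detected duration of test i at grid j
    durations = np.empty((len(series_set), grid.size))
    for i, s in enumerate(series_set):
        for j, thr in enumerate(grid):
            durations[i, j] = detect_freezes(s, thr, config).total_duration_s

    fold_errors: list[float] = []
    fold_thresholds: list[float] = []
    for rep in range(config.cv_reps):
        kf = KFold(n_splits=config.cv_folds, shuffle=True,
                   random_state=(config.rng_seed + 1000003 * rep) % (2**31))
        for train_idx, test_idx in kf.split(durations):
            train_mae = np.mean(
                np.abs(durations[train_idx] - obs[train_idx, None]), axis=0)
            minimisers = np.flatnonzero(train_mae == train_mae.min())
            j = int(minimisers[len(minimisers) // 2])  # mid-plateau
            fold_thresholds.append(float(grid[j]))
            fold_errors.append(float(np.mean(
                np.abs(durations[test_idx, j] - obs[test_idx]))))

    return ThresholdCalibration(
        threshold=float(np.mean(fold_thresholds)),
        per_fold_errors=tuple(fold_errors),
        per_fold_thresholds=tuple(fold_thresholds),
        folds=config.cv_folds,
        reps=config.cv_reps,
        seed=config.rng_seed,
    )
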