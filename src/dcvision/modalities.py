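"""Load-platform, depth-camera and marker-kinematic streams as MotionSeries.

Each modality is reduced to the same per-frame scalar currency so the
startle and freeze computations in :mod:`dcvision.core_metrics` apply
uniformly:

* **load platform** — the four load-cell channels are summed to total
  instantaneous vertical force; subtracting and dividing by the pig's
  weight (mean pre-stimulus force) gives vertical acceleration in
  gravities (g = 9.8 m/s^2);
* **depth camera** — the animal is segmented by background subtraction and
  its centroid vertical height differenced to speed (mm/frame) and
  acceleration (mm/frame^2);
* **marker kinematics** — vertical first/second difference magnitudes of
  six reflective markers, averaged over the markers valid at each frame.

Marker records are short (15 s) and are therefore used only for startle
magnitudes, never for freeze durations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_metrics import (AnalysisConfig, FreezeResult, MotionSeries,
                           detect_freezes, diff_kinematics, window_frames)

__all__ = ["LoadRecord", "DepthSequence", "MarkerSet",
           "load_to_acceleration", "depth_centroid_series",
           "marker_motion_series", "freeze_from_modality",
           "G_CONST", "MARKER_NAMES"]

G_CONST = 9.8  # m/s^2, one gravity
MARKER_NAMES = ("head", "spine1", "spine2", "spine3",
                "sacroiliac_l", "sacroiliac_r")

# depth pixels further than this from the background model are foreground
DEPTH_FOREGROUND_MARGIN_MM = 30.0
# marker occlusion gaps up to this many frames are linearly interpolated
MARKER_MAX_INTERP_GAP = 2


@dataclass
class LoadRecord:
    """Four load-cell force channels sampled at 400 Hz."""

    channels: np.ndarray        # (4, T) force readings
    rate_hz: float = 400.0
    t0_index: int = 0

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != 4:
            raise ValueError("channels must be (4, T)")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")


@dataclass
class DepthSequence:
    """Per-frame depth maps (mm) plus a static background model."""

    frames: np.ndarray          # (T, H, W) depth in mm
    background: np.ndarray      # (H, W) empty-pen reference depth
    rate_hz: float = 30.0
    t0_index: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if self.background.shape != self.frames.shape[1:]:
            raise ValueError("background must match frame dimensions")


@dataclass
class MarkerSet:
    """Six marker trajectories of (x, y, z) mm positions; z is vertical.

    NaN marks occlusion.  Native capture is 200 Hz; analysis expects the
    30 Hz sub-sampled record (see :func:`subsample_markers`).
    """

    positions: np.ndarray       # (6, T, 3) mm, NaN = occluded
    rate_hz: float = 30.0
    t0_index: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[0] != 6 \
                or self.positions.shape[2] != 3:
            raise ValueError("positions must be (6, T, 3)")


def subsample_markers(positions: np.ndarray, native_hz: float = 200.0,
                      target_hz: float = 30.0, t0_index: int = 0
                      ) -> MarkerSet:
    """Decimate native-rate marker data to the analysis rate.

    Nearest-frame decimation on a common clock: target frame ``i`` takes
    the native frame closest to ``i / target_hz``.
    """
    positions = np.asarray(positions, dtype=float)
    T = positions.shape[1]
    n_out = int(np.floor((T - 1) * target_hz / native_hz)) + 1
    idx = np.round(np.arange(n_out) * native_hz / target_hz).astype(int)
    idx = np.clip(idx, 0, T - 1)
    new_t0 = int(round(t0_index * target_hz / native_hz))
    return MarkerSet(positions[:, idx, :], target_hz, new_t0)


# ---------------------------------------------------------------------------

def load_to_acceleration(record: LoadRecord,
                         baseline_window_s: float = 1.0) -> MotionSeries:
    """Whole-body vertical acceleration in gravities from the load platform.

    Total force ``F(t)`` is the sum of the four channels; the pig's weight
    ``W`` is the mean of ``F`` over the ``baseline_window_s`` immediately
    before stimulus onset.  The series value is ``|F(t) - W| / W`` — the
    absolute value makes downstream peak extraction the peak *absolute*
    acceleration, and freezes are detected on the same absolute series.
    """
    F = record.channels.sum(axis=0)
    n_base = window_frames(baseline_window_s, record.rate_hz)
    if n_base < 1 or record.t0_index - n_base < 0:
        raise ValueError("baseline window must lie wholly before stimulus "
                         "onset")
    W = float(F[record.t0_index - n_base:record.t0_index].mean())
    if W <= 0:
        raise ValueError("non-positive baseline weight: pig absent from "
                         "platform?")
    values = np.abs(F - W) / W
    return MotionSeries(values, record.rate_hz, record.t0_index, "g",
                        source="load")


def depth_centroid_series(seq: DepthSequence,
                          foreground_margin_mm: float =
                          DEPTH_FOREGROUND_MARGIN_MM,
                          max_empty_fraction: float = 0.10
                          ) -> tuple[np.ndarray, MotionSeries, MotionSeries]:
    """Vertical centroid displacement, speed and acceleration from depth.

    A pixel is foreground when its depth differs from the background model
    by more than ``foreground_margin_mm``; the centroid height of a frame
    is the mean of (background - depth) over the foreground mask.  Frames
    with an empty mask are invalid; more than ``max_empty_fraction`` of
    them is a data-quality error.

    Returns ``(displacement_mm, speed, accel)`` with kinematics in
    mm/frame and mm/frame^2 at the depth-camera rate.
    """
    T = len(seq.frames)
    heights = np.full(T, np.nan)
    valid = np.zeros(T, dtype=bool)
    for i, frame in enumerate(seq.frames):
        mask = np.abs(frame - seq.background) > foreground_margin_mm
        if mask.any():
            heights[i] = float((seq.background[mask] - frame[mask]).mean())
            valid[i] = True
    if (~valid).mean() > max_empty_fraction:
        raise ValueError(
            f"empty foreground in {(~valid).mean():.0%} of frames")
    speed, accel = diff_kinematics(heights, valid, rate_hz=seq.rate_hz,
                                   t0_index=seq.t0_index, units="mm/frame")
    speed.source = accel.source = "depth"
    return heights, speed, accel


def _interpolate_short_gaps(z: np.ndarray,
                            max_gap: int = MARKER_MAX_INTERP_GAP
                            ) -> np.ndarray:
    """Linearly fill NaN runs of length <= max_gap (longer gaps stay NaN)."""
    z = z.copy()
    isnan = np.isnan(z)
    if not isnan.any():
        return z
    edges = np.flatnonzero(np.diff(np.r_[False, isnan, False]))
    for a, b in zip(edges[::2], edges[1::2]):
        if b - a <= max_gap and a > 0 and b < len(z):
            z[a:b] = np.interp(np.arange(a, b), [a - 1, b],
                               [z[a - 1], z[b]])
    return z


def marker_motion_series(markers: MarkerSet
                         ) -> tuple[MotionSeries, MotionSeries]:
    """Mean vertical velocity / acceleration magnitude over markers.

    Per marker, vertical (z) first- and second-difference magnitudes are
    taken at the analysis rate; per frame, the series value is the mean
    over the markers valid at that frame.  Occlusion gaps of at most
    two frames are linearly interpolated first; frames where every marker
    is occluded are flagged invalid.
    """
    T = markers.positions.shape[1]
    if T < 3:
        raise ValueError("need at least 3 frames")
    speeds = np.zeros((6, T))
    accels = np.zeros((6, T))
    sp_valid = np.zeros((6, T), dtype=bool)
    ac_valid = np.zeros((6, T), dtype=bool)
    any_track = False
    for m in range(6):
        z = _interpolate_short_gaps(markers.positions[m, :, 2])
        ok = np.isfinite(z)
        if ok.sum() < 3:
            continue
        any_track = True
        sp, ac = diff_kinematics(z, ok, rate_hz=markers.rate_hz,
                                 t0_index=markers.t0_index,
                                 units="mm/frame")
        speeds[m], sp_valid[m] = sp.values, sp.valid
        accels[m], ac_valid[m] = ac.values, ac.valid
    if not any_track:
        raise ValueError("no marker with 3 consecutive valid frames")

    def mean_over_valid(vals, ok):
        n = ok.sum(axis=0)
        out = np.zeros(T)
        np.divide((vals * ok).sum(axis=0), n, out=out, where=n > 0)
        return MotionSeries(out, markers.rate_hz, markers.t0_index,
                            "mm/frame", n > 0)

    vel = mean_over_valid(speeds, sp_valid)
    acc = mean_over_valid(accels, ac_valid)
    acc.units_tag = "mm/frame2"
    vel.source = acc.source = "markers"
    return vel, acc


def freeze_from_modality(series: MotionSeries, threshold: float,
                         config: AnalysisConfig | None = None
                         ) -> FreezeResult:
    """Freeze detection for non-video modalities.

    Delegates to :func:`dcvision.core_metrics.detect_freezes`.  Marker
    kinematics are refused: their 15 s records are too short to capture
    longer freezes, so no freeze duration is defined for that modality.
    """
    if series.source == "markers":
        raise ValueError("marker-kinematic records (15 s) are too short "
                         "for freeze duration estimation")
    if series.units_tag not in ("g", "mm/frame", "mm/frame2"):
        raise ValueError(f"unsupported units for modality freeze "
                         f"detection: {series.units_tag!r}")
    return detect_freezes(series, threshold, config)
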