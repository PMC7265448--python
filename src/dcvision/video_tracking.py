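"""Sparse feature tracking of overhead video (pyramidal Lucas-Kanade).

The overhead fast-capture view of the pig is reduced to per-frame motion
statistics by tracking corner-like image features from frame to frame.
Up to ``n_init_points`` points are maintained (default 150); points lost by
the tracker are terminated and replaced with fresh detections.  Per frame,
the mean speed / acceleration magnitude of the ``top_k`` fastest points
(default 50) gives the :class:`~dcvision.core_metrics.MotionSeries` that
the startle and freeze computations consume.

Feature detection uses the Shi-Tomasi minimum-eigenvalue cornerness score;
tracking is iterative Lucas-Kanade on an image pyramid with bilinear
sub-pixel sampling.  Pixel coordinates are (x right, y down), origin at the
top-left corner, sub-pixel positions allowed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.feature import corner_peaks, corner_shi_tomasi

from .core_metrics import AnalysisConfig, MotionSeries

__all__ = ["FrameSource", "Track", "PointTrackSet", "detect_features",
           "track", "topk_motion_series"]

# LK solver constants
_WIN_HALF = 7            # 15x15 interrogation window
_PYR_LEVELS = 3
_MAX_ITERS = 15
_CONV_EPS = 0.01         # px, per-level convergence
_MIN_EIG = 1e-5          # Gram-matrix conditioning floor (unit-intensity imgs)
_MAX_RESIDUAL = 0.12     # mean abs intensity error after convergence
_REDETECT_RADIUS = 5.0   # px exclusion around live tracks
_SPAWN_INTERVAL = 5      # frames between routine re-detection attempts


@dataclass
class FrameSource:
    """Ordered grayscale frames with a sampling rate.

    ``frames`` is ``(T, H, W)`` float in [0, 1] (integer input is
    rescaled).  ``t0_index`` marks stimulus onset on the video clock.
    """

    frames: np.ndarray
    rate_hz: float
    t0_index: int = 0
    #: optional 3x3 planar homography normalising the overhead view from
    #: the four pen corners; identity (None) if absent
    homography: np.ndarray | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if np.issubdtype(f.dtype, np.integer):
            f = f.astype(np.float32) / np.iinfo(f.dtype).max
        self.frames = np.asarray(f, dtype=np.float32)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.homography is not None:
            self.homography = np.asarray(self.homography, dtype=float)
            if self.homography.shape != (3, 3):
                raise ValueError("homography must be 3x3")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @classmethod
    def from_directory(cls, path: str | Path) -> "FrameSource":
        """Load numbered PNG/TIFF frames plus a ``meta.json`` sidecar.

        If the sidecar carries ``corners`` — the (x, y) image positions
        of the four pen corners, in order top-left, top-right,
        bottom-right, bottom-left — a normalising homography onto a
        square of equal average side length is estimated and attached.
        """
        import imageio.v3 as iio

        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no frames in {path}")
        frames = []
        for i, p in enumerate(files):
            try:
                img = iio.imread(p)
            except Exception as exc:  # pragma: no cover - corrupt input
                raise IOError(f"unreadable frame index {i}: {p}") from exc
            if img.ndim == 3:
                img = img.mean(axis=2)
            frames.append(img)
        H = None
        if "corners" in meta:
            H = corner_homography(np.asarray(meta["corners"], dtype=float))
        return cls(np.stack(frames), float(meta["rate_hz"]),
                   int(meta.get("t0_index", 0)), homography=H)


@dataclass
class Track:
    """One tracked point: spawn frame and its per-frame positions."""

    spawn_frame: int
    positions: list  # of (x, y); index i is frame spawn_frame + i

    @property
    def loss_frame(self) -> int:
        """First frame at which the point is no longer tracked."""
        return self.spawn_frame + len(self.positions)


@dataclass
class PointTrackSet:
    """All tracks produced from one clip."""

    tracks: list[Track]
    frame_count: int
    rate_hz: float
    t0_index: int = 0

    def active_count(self, frame: int) -> int:
        return sum(1 for t in self.tracks
                   if t.spawn_frame <= frame < t.loss_frame)

    def to_dataframe(self):
        """Long-format (frame, point_id, x, y, valid) table."""
        import pandas as pd

        rows = []
        for pid, t in enumerate(self.tracks):
            for i, (x, y) in enumerate(t.positions):
                rows.append((t.spawn_frame + i, pid, x, y, True))
        return pd.DataFrame(rows,
                            columns=["frame", "point_id", "x", "y", "valid"])


def corner_homography(corners: np.ndarray) -> np.ndarray:
    """Homography sending the four pen corners to an axis-aligned square.

    ``corners`` is (4, 2) in order top-left, top-right, bottom-right,
    bottom-left.  The target square keeps the mean observed side length,
    so transformed coordinates stay on the pixel scale.
    """
    from skimage.transform import ProjectiveTransform

    corners = np.asarray(corners, dtype=float)
    if corners.shape != (4, 2):
        raise ValueError("corners must be (4, 2)")
    sides = np.linalg.norm(np.roll(corners, -1, axis=0) - corners, axis=1)
    s = float(sides.mean())
    dst = np.array([[0, 0], [s, 0], [s, s], [0, s]], dtype=float)
    tf = ProjectiveTransform.from_estimate(corners, dst)
    if not tf:
        raise ValueError("degenerate corner configuration")
    return np.asarray(tf.params)


def _apply_homography(H: np.ndarray, xy: np.ndarray) -> np.ndarray:
    p = np.c_[xy, np.ones(len(xy))] @ H.T
    return p[:, :2] / p[:, 2:3]


# ---------------------------------------------------------------------------
# feature detection

def detect_features(frame: np.ndarray, n: int,
                    mask: np.ndarray | None = None,
                    min_distance: int = 5) -> np.ndarray:
    """Up to ``n`` corner points, strongest Shi-Tomasi response first.

    Returns an ``(m, 2)`` array of (x, y) positions, ``m <= n``; an
    untextured frame yields an empty array.  Deterministic for a fixed
    frame.
    """
    if frame.size == 0:
        raise ValueError("empty frame")
    if n < 1:
        raise ValueError("n must be >= 1")
    response = corner_shi_tomasi(frame.astype(np.float64))
    if mask is not None:
        response = np.where(mask, response, 0.0)
    peaks = corner_peaks(response, min_distance=min_distance,
                         threshold_abs=1e-8, threshold_rel=0.0,
                         num_peaks=n)
    if peaks.size == 0:
        return np.empty((0, 2))
    # corner_peaks returns (row, col); order by descending response
    scores = response[peaks[:, 0], peaks[:, 1]]
    order = np.argsort(-scores, kind="stable")
    peaks = peaks[order]
    return peaks[:, ::-1].astype(float)  # -> (x, y)


# ---------------------------------------------------------------------------
# pyramidal Lucas-Kanade

def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [img.astype(np.float32)]
    for _ in range(1, levels):
        sm = ndimage.gaussian_filter(pyr[-1], 1.0, mode="nearest")
        pyr.append(sm[::2, ::2])
    return pyr


def _bilinear(img: np.ndarray, rows: np.ndarray,
              cols: np.ndarray) -> np.ndarray:
    """Vectorised bilinear sampling with edge clamping."""
    H, W = img.shape
    r = np.minimum(np.maximum(rows, 0.0), H - 1.000001)
    c = np.minimum(np.maximum(cols, 0.0), W - 1.000001)
    r0 = r.astype(np.intp)
    c0 = c.astype(np.intp)
    fr = (r - r0).astype(img.dtype)
    fc = (c - c0).astype(img.dtype)
    flat = img.ravel()
    idx = r0 * W + c0
    top = flat.take(idx) * (1 - fc) + flat.take(idx + 1) * fc
    bot = flat.take(idx + W) * (1 - fc) + flat.take(idx + W + 1) * fc
    return top * (1 - fr) + bot * fr


def _lk_pair(pyr_i: list[np.ndarray], pyr_j: list[np.ndarray],
             pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Track ``pts`` (n, 2 as x,y) from image I to J.

    Returns (new_pts, ok).  Coarse-to-fine iterative LK; a point fails on
    an ill-conditioned gradient matrix, a window leaving the image, or a
    large post-convergence residual.
    """
    n = len(pts)
    if n == 0:
        return pts.copy(), np.zeros(0, dtype=bool)
    w = _WIN_HALF
    oy, ox = np.mgrid[-w:w + 1, -w:w + 1]
    off_r = oy.ravel()[None, :]
    off_c = ox.ravel()[None, :]

    d = np.zeros((n, 2))  # displacement, (x, y) at full resolution
    ok = np.ones(n, dtype=bool)
    residual = np.zeros(n)

    for level in range(len(pyr_i) - 1, -1, -1):
        I, J = pyr_i[level], pyr_j[level]
        gy, gx = np.gradient(I)
        scale = 2.0 ** level
        p = pts / scale          # (n, 2) x,y at this level
        dl = d / scale
        # sample template windows + gradients once per level
        rows = p[:, 1:2] + off_r
        cols = p[:, 0:1] + off_c
        Iw = _bilinear(I, rows, cols)
        Gx = _bilinear(gx, rows, cols)
        Gy = _bilinear(gy, rows, cols)
        gxx = np.sum(Gx * Gx, axis=1)
        gxy = np.sum(Gx * Gy, axis=1)
        gyy = np.sum(Gy * Gy, axis=1)
        det = gxx * gyy - gxy * gxy
        tr = gxx + gyy
        min_eig = (tr - np.sqrt(np.maximum(tr * tr - 4 * det, 0.0))) / 2
        ok &= min_eig > _MIN_EIG * off_r.shape[1]

        for _ in range(_MAX_ITERS):
            Jw = _bilinear(J, rows + dl[:, 1:2], cols + dl[:, 0:1])
            e = Jw - Iw
            bx = np.sum(Gx * e, axis=1)
            by = np.sum(Gy * e, axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                inc_x = -(gyy * bx - gxy * by) / det
                inc_y = -(-gxy * bx + gxx * by) / det
            inc_x = np.where(ok & np.isfinite(inc_x), inc_x, 0.0)
            inc_y = np.where(ok & np.isfinite(inc_y), inc_y, 0.0)
            dl[:, 0] += inc_x
            dl[:, 1] += inc_y
            if np.max(np.hypot(inc_x, inc_y), initial=0.0) < _CONV_EPS:
                break
        residual = np.mean(np.abs(e), axis=1)
        d = dl * scale

    new = pts + d
    ok &= residual < _MAX_RESIDUAL
    H, W = pyr_i[0].shape
    ok &= ((new[:, 0] >= w) & (new[:, 0] <= W - 1 - w)
           & (new[:, 1] >= w) & (new[:, 1] <= H - 1 - w))
    return new, ok


def track(source: FrameSource,
          config: AnalysisConfig | None = None) -> PointTrackSet:
    """Track up to ``n_init_points`` features through the clip.

    The tracker is initialised on the first frame; after every frame
    transition, lost points (tracking failure or leaving the field of
    view) are terminated and replaced by fresh detections away from
    surviving tracks, keeping the live count near capacity.
    """
    config = config or AnalysisConfig()
    if len(source) < 3:
        raise ValueError("need at least 3 frames")
    frames = source.frames
    pyr_prev = _pyramid(frames[0], _PYR_LEVELS)

    tracks: list[Track] = []
    live_idx: list[int] = []     # indices into tracks of live points

    def spawn(frame_idx: int, img: np.ndarray) -> None:
        # losses of more than 10% of capacity trigger immediate
        # re-detection; smaller shortfalls (scenes that support fewer
        # corners than capacity) retry on a short fixed cadence
        need = config.n_init_points - len(live_idx)
        if need <= 0:
            return
        if (need < max(1, config.n_init_points // 10)
                and frame_idx % _SPAWN_INTERVAL != 0):
            return
        cand = detect_features(img, config.n_init_points,
                               min_distance=int(_REDETECT_RADIUS))
        if cand.size == 0:
            return
        if live_idx:
            cur = np.array([tracks[i].positions[-1] for i in live_idx])
            dist = np.min(np.linalg.norm(
                cand[:, None, :] - cur[None, :, :], axis=2), axis=1)
            cand = cand[dist > _REDETECT_RADIUS]
        for x, y in cand[:need]:
            tracks.append(Track(frame_idx, [(float(x), float(y))]))
            live_idx.append(len(tracks) - 1)

    spawn(0, frames[0])
    for f in range(1, len(frames)):
        pyr_cur = _pyramid(frames[f], _PYR_LEVELS)
        if live_idx:
            pts = np.array([tracks[i].positions[-1] for i in live_idx])
            new, ok = _lk_pair(pyr_prev, pyr_cur, pts)
            survivors = []
            for j, ti in enumerate(live_idx):
                if ok[j]:
                    tracks[ti].positions.append(
                        (float(new[j, 0]), float(new[j, 1])))
                    survivors.append(ti)
            live_idx = survivors
        spawn(f, frames[f])
        pyr_prev = pyr_cur

    if source.homography is not None:
        # normalise the overhead view: kinematics are then measured in
        # pen-plane coordinates
        for t in tracks:
            t.positions = [tuple(p) for p in _apply_homography(
                source.homography, np.asarray(t.positions))]
    return PointTrackSet(tracks, len(frames), source.rate_hz,
                         source.t0_index)


# ---------------------------------------------------------------------------
# reduction to a per-frame motion statistic

def topk_motion_series(tracks: PointTrackSet, k: int | None = None,
                       quantity: str = "accel",
                       config: AnalysisConfig | None = None,
                       aggregate: str = "mean") -> MotionSeries:
    """Per-frame statistic of the k fastest tracked points.

    For every frame, the chosen kinematic magnitude (first difference for
    ``"speed"``, second difference for ``"accel"``) is computed for each
    point tracked over the required consecutive frames (2 for speed, 3 for
    acceleration); the frame statistic is the mean of the ``k`` largest
    (``aggregate="max"`` gives the single-point maximum instead).  Frames
    with fewer than ``k`` eligible points use all eligible points; frames
    with none are flagged invalid.
    """
    config = config or AnalysisConfig()
    k = k if k is not None else config.top_k
    if k < 1:
        raise ValueError("k must be >= 1")
    if quantity not in ("speed", "accel"):
        raise ValueError("quantity must be 'speed' or 'accel'")
    if aggregate not in ("mean", "max"):
        raise ValueError("aggregate must be 'mean' or 'max'")
    if not tracks.tracks:
        raise ValueError("no tracks")

    T = tracks.frame_count
    per_frame: list[list[float]] = [[] for _ in range(T)]
    need = 2 if quantity == "speed" else max(3, config.min_track_frames)
    for t in tracks.tracks:
        L = len(t.positions)
        if L < need:
            continue
        p = np.asarray(t.positions)
        if quantity == "speed":
            mags = np.linalg.norm(p[1:] - p[:-1], axis=1)
            first = t.spawn_frame + 1
        else:
            mags = np.linalg.norm(p[2:] - 2 * p[1:-1] + p[:-2], axis=1)
            first = t.spawn_frame + 2
        for i, m in enumerate(mags):
            per_frame[first + i].append(float(m))

    values = np.zeros(T)
    valid = np.zeros(T, dtype=bool)
    for f, mags in enumerate(per_frame):
        if not mags:
            continue
        valid[f] = True
        arr = np.sort(np.asarray(mags))[::-1][:k]
        values[f] = arr.max() if aggregate == "max" else arr.mean()
    if not valid.any():
        raise ValueError("no frame with any eligible point")

    units = "px/frame" if quantity == "speed" else "px/frame2"
    return MotionSeries(values, tracks.rate_hz, tracks.t0_index, units,
                        valid)
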