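"""Synchronized multi-modal synthetic Defence Cascade recordings.

No public dataset of pig startle tests exists, so every stream the
pipeline ingests is emulated from a scripted ground-truth
:class:`Scenario`: a textured ellipse ("pig") over a textured floor
wanders with Gaussian jitter, performs a displacement impulse of scripted
amplitude at stimulus onset, and holds still during scripted freeze
intervals.  The same script drives

* rendered overhead grayscale video (default 160x160 at 50 Hz; the frame
  rate is a parameter, nothing in the metrics depends on resolution),
* four load-cell channels at 400 Hz (weight + impulse transient + noise),
* a depth-map sequence at 30 Hz (height field over a flat floor,
  including a vertical hop at onset),
* six marker trajectories riding the body (30 Hz, 15 s record), and
* an observer record whose events re-score to the intended 0-4 startle
  score and freeze duration exactly.

Every random draw flows from ``Scenario.rng_seed``; the same seed gives
bit-identical outputs.  The :class:`GroundTruthManifest` carries the
scripted event times, per-modality amplitudes and freeze durations that
recovery tests compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_metrics import window_frames
from .modalities import DepthSequence, LoadRecord, MarkerSet
from .observer_ground_truth import (BehaviourCode, BehaviourEvent,
                                    ObserverRecord)
from .video_tracking import FrameSource

__all__ = ["Scenario", "GroundTruthManifest", "SyntheticTest",
           "generate_test", "generate_corpus"]

# amplitude scaling between modalities: one unit of scripted amplitude is
# 1 px/frame of video displacement, LOAD_G_PER_UNIT gravities of platform
# acceleration, and MM_PER_UNIT mm/frame of vertical motion
LOAD_G_PER_UNIT = 0.05
MM_PER_UNIT = 3.0

_SCORE_CODE = {4: BehaviourCode.FLEE, 3: BehaviourCode.JUMP_AWAY,
               2: BehaviourCode.JUMP_ON_SPOT, 1: BehaviourCode.HEAD_UP}


@dataclass(frozen=True)
class Scenario:
    """Script of one synthetic startle test.

    ``freeze_intervals`` are absolute seconds on the test clock and must
    lie inside the post-stimulus record ``[t0_s, t0_s + record_s)``.
    ``startle_amplitude`` is in video pixels/frame; the load and
    depth/marker amplitudes are fixed multiples of it (LOAD_G_PER_UNIT g
    and MM_PER_UNIT mm per unit).  ``baseline_motion_sd`` is the
    per-frame positional jitter (px) of baseline wander; freeze-interval
    jitter is FREEZE_JITTER_FACTOR times smaller.
    """

    rng_seed: int = 0
    t0_s: float = 2.0
    startle_amplitude: float = 4.0
    startle_score_intent: int = 2
    freeze_intervals: tuple[tuple[float, float], ...] = ()
    baseline_motion_sd: float = 0.3
    pig_mass: float = 30.0
    record_s: float = 30.0
    video_hz: float = 50.0
    load_hz: float = 400.0
    depth_hz: float = 30.0
    marker_hz: float = 30.0
    marker_record_s: float = 15.0
    frame_size: int = 160
    load_noise_g: float = 0.02
    depth_noise_mm: float = 1.0
    marker_noise_mm: float = 0.3
    freeze_jitter_factor: float = 0.02

    def __post_init__(self) -> None:
        if self.startle_amplitude < 0 or self.baseline_motion_sd < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.startle_score_intent not in range(5):
            raise ValueError("startle_score_intent must be 0..4")
        prev_end = self.t0_s
        for a, b in self.freeze_intervals:
            if a < prev_end or b <= a or b > self.t0_s + self.record_s:
                raise ValueError(
                    "freeze intervals must be disjoint, ordered and inside "
                    "the post-stimulus record")
            prev_end = b


@dataclass(frozen=True)
class GroundTruthManifest:
    """Scripted truth the recovery tests measure against."""

    rng_seed: int
    t0_s: float
    record_s: float
    startle_amplitude_px: float
    startle_amplitude_g: float
    startle_amplitude_mm: float
    freeze_intervals_s: tuple[tuple[float, float], ...]  # stimulus-relative
    true_freeze_total_s: float
    startle_score: int
    observer_freeze_s: float


@dataclass
class SyntheticTest:
    """One generated test: whichever streams were requested, plus truth."""

    scenario: Scenario
    manifest: GroundTruthManifest
    video: FrameSource | None = None
    load: LoadRecord | None = None
    depth: DepthSequence | None = None
    markers: MarkerSet | None = None
    observer: ObserverRecord = field(default_factory=ObserverRecord)


# ---------------------------------------------------------------------------
# scripted kinematics

def _freeze_mask(sc: Scenario, rate_hz: float, n: int) -> np.ndarray:
    """Frames whose time falls inside a scripted freeze interval."""
    t = np.arange(n) / rate_hz
    mask = np.zeros(n, dtype=bool)
    for a, b in sc.freeze_intervals:
        mask |= (t >= a) & (t < b)
    return mask


def _wander(sc: Scenario, rng: np.random.Generator, rate_hz: float,
            n: int, sd: float, dims: int, pull: float = 0.02
            ) -> np.ndarray:
    """Mean-reverting jittered walk, frozen still inside freeze intervals.

    Noise-free scenarios (sd == 0) stay exactly at the origin outside the
    impulse, so scripted events are the only motion.
    """
    frozen = _freeze_mask(sc, rate_hz, n)
    steps = rng.normal(0.0, 1.0, size=(n, dims))
    p = np.zeros((n, dims))
    for i in range(1, n):
        if frozen[i]:  # scripted immobility: only residual tremor
            p[i] = p[i - 1] + steps[i] * (sc.freeze_jitter_factor * sd)
        else:
            p[i] = p[i - 1] * (1 - pull) + steps[i] * sd
    return p


def _impulse_frame(sc: Scenario, rate_hz: float) -> int:
    return window_frames(sc.t0_s, rate_hz)


# ---------------------------------------------------------------------------
# video rendering

def _textured_floor(size: int, rng: np.random.Generator) -> np.ndarray:
    base = rng.random((size, size))
    tex = ndimage.gaussian_filter(base, 1.5)
    tex = (tex - tex.min()) / (tex.max() - tex.min())
    return (0.35 + 0.15 * tex).astype(np.float32)


def _pig_sprite(rng: np.random.Generator, a: int = 42, b: int = 28
                ) -> tuple[np.ndarray, np.ndarray]:
    """High-contrast textured ellipse sprite and its soft mask."""
    h, w = 2 * b + 5, 2 * a + 5
    yy, xx = np.mgrid[:h, :w]
    r = (((xx - w / 2) / a) ** 2 + ((yy - h / 2) / b) ** 2)
    mask = np.clip((1.0 - r) * 8.0, 0.0, 1.0).astype(np.float32)
    tex = ndimage.gaussian_filter(rng.random((h, w)), 0.8)
    tex = (tex - tex.min()) / (tex.max() - tex.min())
    return (0.2 + 0.75 * tex).astype(np.float32), mask


def _render_video(sc: Scenario, rng: np.random.Generator) -> FrameSource:
    rate = sc.video_hz
    n = window_frames(sc.t0_s + sc.record_s, rate) + 1
    path = _wander(sc, rng, rate, n, sc.baseline_motion_sd, dims=2)
    jf = _impulse_frame(sc, rate)
    amp = sc.startle_amplitude / np.sqrt(2)
    path[jf:] += np.array([amp, amp])  # one-frame displacement burst

    floor = _textured_floor(sc.frame_size, rng)
    sprite, mask = _pig_sprite(rng)
    sh, sw = sprite.shape
    cy = cx = sc.frame_size / 2

    frames = np.empty((n, sc.frame_size, sc.frame_size), dtype=np.float32)
    for i in range(n):
        x = cx + path[i, 0] - sw / 2
        y = cy + path[i, 1] - sh / 2
        ix, iy = int(np.floor(x)), int(np.floor(y))
        fx, fy = x - ix, y - iy
        spr = ndimage.shift(sprite, (fy, fx), order=1, mode="nearest")
        msk = ndimage.shift(mask, (fy, fx), order=1, mode="constant")
        frame = floor.copy()
        y0, y1 = max(iy, 0), min(iy + sh, sc.frame_size)
        x0, x1 = max(ix, 0), min(ix + sw, sc.frame_size)
        sy0, sx0 = y0 - iy, x0 - ix
        m = msk[sy0:sy0 + (y1 - y0), sx0:sx0 + (x1 - x0)]
        s = spr[sy0:sy0 + (y1 - y0), sx0:sx0 + (x1 - x0)]
        frame[y0:y1, x0:x1] = frame[y0:y1, x0:x1] * (1 - m) + s * m
        frames[i] = frame
    return FrameSource(frames, rate, t0_index=jf)


# ---------------------------------------------------------------------------
# non-video streams

def _make_load(sc: Scenario, rng: np.random.Generator) -> LoadRecord:
    rate = sc.load_hz
    n = window_frames(sc.t0_s + sc.record_s, rate) + 1
    t = np.arange(n) / rate
    frozen = _freeze_mask(sc, rate, n)
    noise_sd = np.where(frozen, sc.load_noise_g * sc.freeze_jitter_factor,
                        sc.load_noise_g)
    accel_g = rng.normal(0.0, 1.0, n) * noise_sd
    jf = _impulse_frame(sc, rate)
    amp_g = LOAD_G_PER_UNIT * sc.startle_amplitude
    tail = t[jf:] - t[jf]
    accel_g[jf:] += amp_g * np.exp(-tail / 0.05)  # 50 ms decay transient
    F = sc.pig_mass * (1.0 + accel_g)
    shares = np.array([0.27, 0.24, 0.26, 0.23])
    channels = F[None, :] * shares[:, None]
    return LoadRecord(channels, rate, t0_index=jf)


def _vertical_height(sc: Scenario, rng: np.random.Generator,
                     rate_hz: float, n: int, noise_mm: float) -> np.ndarray:
    """Shared vertical body-height script (mm above standing height)."""
    h = _wander(sc, rng, rate_hz, n, noise_mm, dims=1)[:, 0]
    jf = _impulse_frame(sc, rate_hz)
    amp_mm = MM_PER_UNIT * sc.startle_amplitude
    # a brief hop: up for one frame, back down
    h[jf] += amp_mm
    return h


def _make_depth(sc: Scenario, rng: np.random.Generator) -> DepthSequence:
    rate = sc.depth_hz
    n = window_frames(sc.t0_s + sc.record_s, rate) + 1
    size = 80
    background = np.full((size, size), 2000.0)
    h = _vertical_height(sc, rng, rate, n, sc.baseline_motion_sd
                         * MM_PER_UNIT / 3.0)
    xy = _wander(sc, rng, rate, n, sc.baseline_motion_sd / 2.0, dims=2)

    yy, xx = np.mgrid[:size, :size]
    frames = np.empty((n, size, size))
    body = 300.0  # standing body height, mm
    for i in range(n):
        cx, cy = size / 2 + xy[i, 0], size / 2 + xy[i, 1]
        mask = (((xx - cx) / 21) ** 2 + ((yy - cy) / 14) ** 2) <= 1.0
        frame = background + rng.normal(0.0, sc.depth_noise_mm,
                                        (size, size))
        frame[mask] = 2000.0 - (body + h[i]) + rng.normal(
            0.0, sc.depth_noise_mm, int(mask.sum()))
        frames[i] = frame
    return DepthSequence(frames, background, rate,
                         t0_index=_impulse_frame(sc, rate))


def _make_markers(sc: Scenario, rng: np.random.Generator) -> MarkerSet:
    rate = sc.marker_hz
    n = window_frames(sc.t0_s + sc.marker_record_s, rate) + 1
    h = _vertical_height(sc, rng, rate, n, 0.0)
    offsets = np.array([[0, -180, 350], [0, -90, 360], [0, 0, 365],
                        [0, 90, 360], [-40, 160, 350], [40, 160, 350]],
                       dtype=float)
    pos = np.empty((6, n, 3))
    for m in range(6):
        pos[m] = offsets[m][None, :] + rng.normal(
            0.0, sc.marker_noise_mm, (n, 3))
        pos[m, :, 2] += h
    frozen = _freeze_mask(sc, rate, n)
    for m in range(6):  # freezes: markers exactly still (tense immobility)
        idx = np.flatnonzero(frozen)
        for i in idx:
            if i > 0 and frozen[i - 1]:
                pos[m, i] = pos[m, i - 1]
    return MarkerSet(pos, rate, t0_index=_impulse_frame(sc, rate))


def _make_observer(sc: Scenario) -> ObserverRecord:
    events: list[BehaviourEvent] = []
    if sc.startle_score_intent > 0:
        code = _SCORE_CODE[sc.startle_score_intent]
        events.append(BehaviourEvent(code, 0.0, min(0.5, 30.0)))
    for a, b in sc.freeze_intervals:
        events.append(BehaviourEvent(BehaviourCode.FREEZE,
                                     a - sc.t0_s, b - sc.t0_s))
    events.append(BehaviourEvent(BehaviourCode.RETURN_TO_NORMAL,
                                 min(sc.record_s, 30.0),
                                 min(sc.record_s, 30.0)))
    return ObserverRecord(events)


# ---------------------------------------------------------------------------

def generate_test(scenario: Scenario,
                  streams: tuple[str, ...] = ("video", "load", "depth",
                                              "markers")) -> SyntheticTest:
    """Generate one synchronized multi-modal test from a scenario.

    ``streams`` selects which raw streams to materialise (rendering video
    is the expensive part); the observer record and manifest are always
    produced.  Identical scenarios give bit-identical outputs.
    """
    sc = scenario
    root = np.random.SeedSequence(sc.rng_seed)
    kids = {name: np.random.default_rng(s) for name, s in
            zip(("video", "load", "depth", "markers"), root.spawn(4))}

    observer = _make_observer(sc)
    rel = tuple((a - sc.t0_s, b - sc.t0_s) for a, b in sc.freeze_intervals)
    true_total = sum(b - a for a, b in rel if (b - a) >= 0.4)
    manifest = GroundTruthManifest(
        rng_seed=sc.rng_seed, t0_s=sc.t0_s, record_s=sc.record_s,
        startle_amplitude_px=sc.startle_amplitude,
        startle_amplitude_g=LOAD_G_PER_UNIT * sc.startle_amplitude,
        startle_amplitude_mm=MM_PER_UNIT * sc.startle_amplitude,
        freeze_intervals_s=rel, true_freeze_total_s=true_total,
        startle_score=sc.startle_score_intent,
        observer_freeze_s=observer.freeze_duration_s)

    test = SyntheticTest(sc, manifest, observer=observer)
    if "video" in streams:
        test.video = _render_video(sc, kids["video"])
    if "load" in streams:
        test.load = _make_load(sc, kids["load"])
    if "depth" in streams:
        test.depth = _make_depth(sc, kids["depth"])
    if "markers" in streams:
        test.markers = _make_markers(sc, kids["markers"])
    return test


def generate_corpus(n: int, amplitude_grid, freeze_grid=None,
                    seed: int = 0,
                    streams: tuple[str, ...] = ("load", "depth"),
                    **scenario_kw) -> list[SyntheticTest]:
    """A corpus of ``n`` tests spanning amplitude and freeze-script grids.

    Scenario ``i`` takes ``amplitude_grid[i % len]`` and, when
    ``freeze_grid`` is given, ``freeze_grid[i % len]`` (a tuple of
    stimulus-relative ``(start, end)`` freeze intervals).  Per-test seeds
    are spawned from ``seed``; intended observer scores are assigned by
    amplitude quartile within the grid.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    amplitude_grid = list(amplitude_grid)
    freeze_grid = list(freeze_grid) if freeze_grid is not None else [()]
    amax = max(max(amplitude_grid), 1e-12)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(seed).spawn(n)]
    tests = []
    for i in range(n):
        amp = amplitude_grid[i % len(amplitude_grid)]
        rel_intervals = freeze_grid[i % len(freeze_grid)]
        t0 = scenario_kw.get("t0_s", Scenario.t0_s)
        sc = Scenario(
            rng_seed=seeds[i],
            startle_amplitude=amp,
            startle_score_intent=(0 if amp == 0
                                  else min(4, 1 + int(3.999 * amp / amax))),
            freeze_intervals=tuple((t0 + a, t0 + b)
                                   for a, b in rel_intervals),
            **scenario_kw)
        tests.append(generate_test(sc, streams))
    return tests
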