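"""On-disk formats for every stream the pipeline reads and writes.

All tabular data are UTF-8 comma-separated files with a header row and
``.`` decimal; per-file acquisition metadata (sampling rate, stimulus
onset index, units) lives in a JSON sidecar next to the CSV.  Depth maps
and video frames are directories of numbered 16-bit / 8-bit PNGs with a
``meta.json`` sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core_metrics import MotionSeries
from .modalities import DepthSequence, LoadRecord, MarkerSet, MARKER_NAMES
from .observer_ground_truth import (BehaviourCode, BehaviourEvent,
                                    ObserverRecord)
from .video_tracking import FrameSource

__all__ = [
    "write_motion_series", "read_motion_series",
    "write_load_record", "read_load_record",
    "write_markers", "read_markers",
    "write_depth_sequence", "read_depth_sequence",
    "write_frames", "read_frames",
    "write_observer_events", "read_observer_events",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_motion_series(series: MotionSeries, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    n = len(series)
    pd.DataFrame({
        "frame": np.arange(n),
        "time_s": np.arange(n) / series.rate_hz,
        "value": series.values,
        "valid": series.valid.astype(int),
    }).to_csv(csv_path, index=False)
    _sidecar(csv_path).write_text(json.dumps({
        "rate_hz": series.rate_hz, "t0_index": series.t0_index,
        "units_tag": series.units_tag, "source": series.source}))


def read_motion_series(csv_path: str | Path) -> MotionSeries:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(_sidecar(csv_path).read_text())
    return MotionSeries(df["value"].to_numpy(), meta["rate_hz"],
                        meta["t0_index"], meta["units_tag"],
                        df["valid"].to_numpy().astype(bool),
                        meta.get("source", ""))


def write_load_record(record: LoadRecord, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    T = record.channels.shape[1]
    cols = {"time_s": np.arange(T) / record.rate_hz}
    for i in range(4):
        cols[f"ch{i + 1}"] = record.channels[i]
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    _sidecar(csv_path).write_text(json.dumps(
        {"rate_hz": record.rate_hz, "t0_index": record.t0_index}))


def read_load_record(csv_path: str | Path) -> LoadRecord:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(_sidecar(csv_path).read_text())
    channels = np.stack([df[f"ch{i + 1}"].to_numpy() for i in range(4)])
    return LoadRecord(channels, meta["rate_hz"], meta["t0_index"])


def write_markers(markers: MarkerSet, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    T = markers.positions.shape[1]
    rows = []
    for m, name in enumerate(MARKER_NAMES):
        for t in range(T):
            x, y, z = markers.positions[m, t]
            rows.append((t / markers.rate_hz, name, x, y, z))
    pd.DataFrame(rows, columns=["time_s", "marker_id", "x", "y", "z"]
                 ).to_csv(csv_path, index=False)
    _sidecar(csv_path).write_text(json.dumps(
        {"rate_hz": markers.rate_hz, "t0_index": markers.t0_index}))


def read_markers(csv_path: str | Path) -> MarkerSet:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(_sidecar(csv_path).read_text())
    T = df["time_s"].nunique()
    pos = np.full((6, T, 3), np.nan)
    for m, name in enumerate(MARKER_NAMES):
        sub = df[df["marker_id"] == name].sort_values("time_s")
        pos[m, :len(sub)] = sub[["x", "y", "z"]].to_numpy()
    return MarkerSet(pos, meta["rate_hz"], meta["t0_index"])


def write_depth_sequence(seq: DepthSequence, directory: str | Path) -> None:
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        iio.imwrite(directory / f"depth_{i:06d}.png",
                    np.clip(frame, 0, 65535).astype(np.uint16))
    iio.imwrite(directory / "background.png",
                np.clip(seq.background, 0, 65535).astype(np.uint16))
    (directory / "meta.json").write_text(json.dumps(
        {"rate_hz": seq.rate_hz, "t0_index": seq.t0_index}))


def read_depth_sequence(directory: str | Path) -> DepthSequence:
    import imageio.v3 as iio

    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    files = sorted(directory.glob("depth_*.png"))
    frames = np.stack([iio.imread(p).astype(float) for p in files])
    background = iio.imread(directory / "background.png").astype(float)
    return DepthSequence(frames, background, meta["rate_hz"],
                         meta["t0_index"])


def write_frames(source: FrameSource, directory: str | Path) -> None:
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(source.frames):
        iio.imwrite(directory / f"frame_{i:06d}.png",
                    np.clip(frame * 255, 0, 255).astype(np.uint8))
    (directory / "meta.json").write_text(json.dumps(
        {"rate_hz": source.rate_hz, "t0_index": source.t0_index}))


def read_frames(directory: str | Path) -> FrameSource:
    return FrameSource.from_directory(directory)


def write_observer_events(records: dict[str, ObserverRecord],
                          csv_path: str | Path) -> None:
    rows = []
    for test_id, rec in records.items():
        for e in rec.events:
            rows.append((test_id, e.code.value, e.start_s, e.end_s))
    pd.DataFrame(rows, columns=["test_id", "code", "start_s", "end_s"]
                 ).to_csv(csv_path, index=False)


def read_observer_events(csv_path: str | Path) -> dict[str, ObserverRecord]:
    df = pd.read_csv(csv_path)
    records: dict[str, ObserverRecord] = {}
    for test_id, sub in df.groupby("test_id", sort=False):
        events = [BehaviourEvent(BehaviourCode(r.code), r.start_s, r.end_s)
                  for r in sub.itertuples()]
        records[str(test_id)] = ObserverRecord(events, str(test_id))
    return records
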