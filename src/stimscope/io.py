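"""Readers and writers for the pipeline's on-disk artifacts.

Conventions, fixed package-wide: frames and pixels are 0-based, epoch
intervals are half-open ``[start, stop)``, pixel order is (row, col).
Movies are multi-page 32-bit float grayscale TIFF; behavior and schedules
are CSV with a ``# key: value`` comment header; ground truth and extraction
results are HDF5.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .extract import ExtractionResult
from .sim import (
    BehaviorTrace,
    FootprintSet,
    GroundTruth,
    StimEpoch,
    StimSchedule,
)

__all__ = [
    "Movie",
    "read_movie",
    "write_movie",
    "read_behavior",
    "write_behavior",
    "read_schedule",
    "write_schedule",
    "read_ground_truth",
    "write_ground_truth",
    "read_extraction",
    "write_extraction",
]


@dataclass
class Movie:
    data: np.ndarray          # (T, H, W) float32
    frame_rate_hz: float


def write_movie(movie: Movie | np.ndarray, path, frame_rate_hz: float | None = None) -> None:
    if isinstance(movie, Movie):
        data, fr = movie.data, movie.frame_rate_hz
    else:
        data, fr = movie, frame_rate_hz
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError("movie must be (T, H, W) grayscale")
    meta = {"frame_rate_hz": fr} if fr is not None else {}
    tifffile.imwrite(path, data, metadata=meta)


def read_movie(path) -> Movie:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a grayscale stack, got shape {data.shape}")
    if data.shape[0] == 0:
        raise ValueError(f"{path}: empty stack")
    fr = float(meta.get("frame_rate_hz", 0.0)) or None
    return Movie(data=np.asarray(data, dtype=np.float32), frame_rate_hz=fr)


# --------------------------------------------------------------------------
# CSV tables

def _write_csv_with_header(df: pd.DataFrame, path, header: dict) -> None:
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def _read_csv_with_header(path) -> tuple[pd.DataFrame, dict]:
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            header[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, header


def write_behavior(behavior: BehaviorTrace, path) -> None:
    df = pd.DataFrame({
        "frame": np.arange(len(behavior)),
        "velocity_cmps": behavior.velocity_cmps,
    })
    _write_csv_with_header(df, path, {"frame_rate_hz": behavior.frame_rate_hz})


def read_behavior(path) -> BehaviorTrace:
    df, header = _read_csv_with_header(path)
    if "velocity_cmps" not in df.columns:
        raise ValueError(f"{path}: missing velocity_cmps column")
    v = df["velocity_cmps"].to_numpy(dtype=float)
    bad = np.flatnonzero(v < 0)
    if bad.size:
        raise ValueError(f"{path}: negative velocity at frames {bad[:5].tolist()}")
    return BehaviorTrace(v, float(header.get("frame_rate_hz", 0)) or None)


def write_schedule(schedule: StimSchedule, path) -> None:
    df = pd.DataFrame(
        [{"start_frame": ep.start, "end_frame": ep.stop,
          "frequency_hz": ep.frequency_hz, "amplitude_ua": ep.amplitude_ua,
          "pulse_width_us": ep.pulse_width_us} for ep in schedule.epochs]
    )
    if df.empty:
        df = pd.DataFrame(columns=["start_frame", "end_frame", "frequency_hz",
                                   "amplitude_ua", "pulse_width_us"])
    _write_csv_with_header(df, path, {"paradigm": schedule.paradigm})


def read_schedule(path) -> StimSchedule:
    df, header = _read_csv_with_header(path)
    epochs = []
    prev = None
    offenders = []
    for _, row in df.iterrows():
        ep = StimEpoch(int(row.start_frame), int(row.end_frame),
                       float(row.frequency_hz), float(row.amplitude_ua),
                       float(row.pulse_width_us))
        if prev is not None and ep.start < prev.stop:
            offenders.append((prev, ep))
        epochs.append(ep)
        prev = ep
    if offenders:
        raise ValueError(
            f"{path}: overlapping/unsorted epochs: "
            + "; ".join(f"[{a.start},{a.stop}) vs [{b.start},{b.stop})"
                        for a, b in offenders)
        )
    return StimSchedule(epochs=epochs, paradigm=header.get("paradigm", "unknown"))


# --------------------------------------------------------------------------
# HDF5

def write_ground_truth(truth: GroundTruth, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("footprints", data=truth.footprints.footprints)
        f.create_dataset("centers", data=truth.footprints.centers)
        f.create_dataset("sigmas", data=truth.footprints.sigmas)
        f.create_dataset("traces", data=truth.traces)
        f.create_dataset("events", data=truth.events)
        f.create_dataset("baseline", data=truth.baseline_image)
        f.create_dataset("contamination_spatial", data=truth.contamination_spatial)
        f.create_dataset("contamination_temporal", data=truth.contamination_temporal)
        f.create_dataset("velocity_cmps", data=truth.behavior.velocity_cmps)
        f.attrs["frame_rate_hz"] = truth.behavior.frame_rate_hz
        f.attrs["paradigm"] = truth.schedule.paradigm
        sched = np.array([[ep.start, ep.stop, ep.frequency_hz, ep.amplitude_ua,
                           ep.pulse_width_us] for ep in truth.schedule.epochs],
                         dtype=float).reshape(-1, 5)
        f.create_dataset("schedule", data=sched)


def read_ground_truth(path) -> GroundTruth:
    with h5py.File(path, "r") as f:
        fr = float(f.attrs["frame_rate_hz"])
        epochs = [StimEpoch(int(r[0]), int(r[1]), r[2], r[3], r[4])
                  for r in f["schedule"][()]]
        return GroundTruth(
            footprints=FootprintSet(f["footprints"][()], f["centers"][()],
                                    f["sigmas"][()]),
            traces=f["traces"][()],
            events=f["events"][()],
            baseline_image=f["baseline"][()],
            contamination_spatial=f["contamination_spatial"][()],
            contamination_temporal=f["contamination_temporal"][()],
            behavior=BehaviorTrace(f["velocity_cmps"][()], fr),
            schedule=StimSchedule(epochs, str(f.attrs["paradigm"])),
        )


def write_label_image(result: ExtractionResult, path,
                      threshold: float = 0.2) -> None:
    """Export footprint outlines as a label-image TIFF.

    Each pixel holds 1 + the index of the strongest footprint covering it
    (above ``threshold`` x that footprint's peak), or 0 for background.
    """
    fps = np.asarray(result.footprints)
    if fps.ndim != 3:
        raise ValueError("footprints must be (n, H, W)")
    labels = np.zeros(fps.shape[1:], dtype=np.int32)
    if fps.shape[0]:
        peak = fps.max(axis=(1, 2), keepdims=True)
        masked = np.where(fps >= threshold * np.maximum(peak, 1e-12), fps, 0.0)
        best = masked.argmax(axis=0)
        labels = np.where(masked.max(axis=0) > 0, best + 1, 0).astype(np.int32)
    tifffile.imwrite(path, labels)


def write_extraction(result: ExtractionResult, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("footprints", data=result.footprints)
        f.create_dataset("traces", data=result.traces)
        f.attrs["method"] = result.method_label
        for k, v in result.diagnostics.items():
            if isinstance(v, (int, float, bool, str)):
                f.attrs[f"diag_{k}"] = v


def read_extraction(path) -> ExtractionResult:
    with h5py.File(path, "r") as f:
        diag = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("diag_")}
        return ExtractionResult(
            footprints=f["footprints"][()],
            traces=f["traces"][()],
            method_label=str(f.attrs["method"]),
            diagnostics=diag,
        )
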