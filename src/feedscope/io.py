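"""Readers and writers for the tabular text formats the pipeline consumes.

All formats are plain comma-separated tables with one header row:

* pose: ``time_s`` then ``<part>_x``/``<part>_y`` per body part (an optional
  ``<part>_likelihood`` column flags low-confidence samples), plus
  ``target_x``/``target_y`` when a food target was tracked;
* epochs: ``label,start_s,end_s``;
* traces: one row per cell, ``cell_id`` then the sample values;
* co-registration: ``cell_id_a,cell_id_b``;
* photometry: ``time_s,sig470,ref405``.

A session ``manifest.txt`` (``key: value`` lines) records sampling rates and
the generator seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import Arena, BehaviorEpochs, CoRegistrationMap, PhotometryRecording, PoseTrack, TraceMatrix

LIKELIHOOD_THRESHOLD = 0.9


# ---------------------------------------------------------------------------
# pose
# ---------------------------------------------------------------------------


def write_pose(pose: PoseTrack, path: str | Path) -> None:
    data = {"time_s": pose.time}
    for part, xy in pose.parts.items():
        data[f"{part}_x"] = xy[:, 0]
        data[f"{part}_y"] = xy[:, 1]
    if pose.target is not None:
        data["target_x"] = pose.target[:, 0]
        data["target_y"] = pose.target[:, 1]
    pd.DataFrame(data).to_csv(path, index=False)


def read_pose(path: str | Path, arena: Arena | None = None) -> PoseTrack:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("pose table needs a time_s column")
    parts: dict[str, np.ndarray] = {}
    missing: dict[str, np.ndarray] = {}
    names = {
        c[:-2] for c in df.columns if c.endswith("_x") and c != "target_x"
    }
    for name in sorted(names):
        if f"{name}_y" not in df.columns:
            raise ValueError(f"part {name!r} lacks a _y column")
        parts[name] = df[[f"{name}_x", f"{name}_y"]].to_numpy(float)
        lk = f"{name}_likelihood"
        if lk in df.columns:
            missing[name] = df[lk].to_numpy(float) < LIKELIHOOD_THRESHOLD
    target = None
    if "target_x" in df.columns and "target_y" in df.columns:
        target = df[["target_x", "target_y"]].to_numpy(float)
    return PoseTrack(
        time=df["time_s"].to_numpy(float),
        parts=parts,
        target=target,
        arena=arena,
        missing=missing,
    )


# ---------------------------------------------------------------------------
# epochs
# ---------------------------------------------------------------------------


def write_epochs(epochs: BehaviorEpochs, path: str | Path) -> None:
    pd.DataFrame(
        epochs.entries, columns=["label", "start_s", "end_s"]
    ).to_csv(path, index=False)


def read_epochs(path: str | Path) -> BehaviorEpochs:
    df = pd.read_csv(path)
    required = {"label", "start_s", "end_s"}
    if not required <= set(df.columns):
        raise ValueError(f"epoch table needs columns {sorted(required)}")
    return BehaviorEpochs(
        [
            (str(r.label), float(r.start_s), float(r.end_s))
            for r in df.itertuples()
        ]
    )


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


def write_traces(traces: TraceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(traces.values)
    df.insert(0, "cell_id", traces.cell_ids)
    df.to_csv(path, index=False)


def read_traces(path: str | Path, rate: float) -> TraceMatrix:
    df = pd.read_csv(path)
    if "cell_id" not in df.columns:
        raise ValueError("trace table needs a cell_id column")
    cell_ids = df["cell_id"].astype(str).tolist()
    values = df.drop(columns="cell_id").to_numpy(float)
    return TraceMatrix(cell_ids, rate, values)


# ---------------------------------------------------------------------------
# co-registration, photometry, manifest
# ---------------------------------------------------------------------------


def write_coregistration(coreg: CoRegistrationMap, path: str | Path) -> None:
    pd.DataFrame(coreg.pairs, columns=["cell_id_a", "cell_id_b"]).to_csv(
        path, index=False
    )


def read_coregistration(path: str | Path) -> CoRegistrationMap:
    df = pd.read_csv(path)
    return CoRegistrationMap(
        [(str(a), str(b)) for a, b in zip(df["cell_id_a"], df["cell_id_b"])]
    )


def write_photometry(rec: PhotometryRecording, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": rec.time, "sig470": rec.sig470, "ref405": rec.ref405}
    ).to_csv(path, index=False)


def read_photometry(path: str | Path, rate: float | None = None) -> PhotometryRecording:
    df = pd.read_csv(path)
    time = df["time_s"].to_numpy(float)
    if rate is None:
        rate = 1.0 / float(np.mean(np.diff(time)))
    return PhotometryRecording(
        time=time,
        sig470=df["sig470"].to_numpy(float),
        ref405=df["ref405"].to_numpy(float),
        rate=rate,
    )


def write_manifest(entries: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key in sorted(entries):
            fh.write(f"{key}: {entries[key]}\n")


def read_manifest(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if ":" in line:
                key, value = line.split(":", 1)
                out[key.strip()] = value.strip()
    return out


def write_session(bundle, out_dir: str | Path) -> None:
    """Write a synthetic session bundle as its five tabular files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pose(bundle.pose, out / "pose.csv")
    write_epochs(bundle.epochs, out / "epochs.csv")
    write_traces(bundle.traces, out / "traces.csv")
    write_manifest(
        {
            "behavior_rate_hz": bundle.pose.rate,
            "trace_rate_hz": bundle.traces.rate,
            "seed": bundle.truth.seed,
            "n_cells": bundle.traces.n_cells,
        },
        out / "manifest.txt",
    )
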