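"""Shared file I/O: pose-trace CSV, calibration JSON, correspondence CSV,
frame directories, and reproducibility manifests.

All text schemas carry a version stamp; round trips are lossless.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .geometry import RigidTransform
from .pose import CameraIntrinsics, PoseTrace, StereoRig, TRACE_COLUMNS
from .crosscal import PointCorrespondences
from .detection import Frame

__all__ = [
    "write_trace", "read_trace",
    "write_rig", "read_rig",
    "write_transform", "read_transform",
    "write_correspondences", "read_correspondences",
    "read_frame_dir", "write_frames",
    "write_manifest",
]

TRACE_SCHEMA = "moiretrack-trace-v1"


class ParseError(ValueError):
    """Malformed input file; message carries file and field context."""


def write_trace(trace: PoseTrace, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# schema={TRACE_SCHEMA}\n")
        trace.data.to_csv(fh, index=False, float_format="%.9g")


def read_trace(path) -> PoseTrace:
    path = Path(path)
    try:
        with path.open() as fh:
            header = fh.readline()
            if TRACE_SCHEMA not in header:
                raise ParseError(f"{path}: missing '# schema={TRACE_SCHEMA}' header line")
            df = pd.read_csv(fh)
    except pd.errors.EmptyDataError as e:
        raise ParseError(f"{path}: empty trace file") from e
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ParseError(f"{path}: trace contains no frames")
    df["methods"] = df["methods"].fillna("")
    return PoseTrace(df)


def write_rig(rig: StereoRig, path, reports: dict | None = None) -> None:
    d = {
        "schema": "moiretrack-rig-v1",
        "left": rig.left.to_dict(),
        "right": rig.right.to_dict(),
        "extrinsic_right_to_left": rig.extrinsic.matrix().tolist(),
    }
    if reports:
        d["reports"] = reports
    Path(path).write_text(json.dumps(d, indent=1))


def read_rig(path) -> StereoRig:
    path = Path(path)
    try:
        d = json.loads(path.read_text())
        return StereoRig(
            left=CameraIntrinsics.from_dict(d["left"]),
            right=CameraIntrinsics.from_dict(d["right"]),
            extrinsic=RigidTransform.from_matrix(np.asarray(d["extrinsic_right_to_left"])),
        )
    except (KeyError, json.JSONDecodeError) as e:
        raise ParseError(f"{path}: not a valid rig file ({e})") from e


def write_transform(T: RigidTransform, path, fre_mm: float | None = None) -> None:
    pose = T.to_pose()
    d = {
        "schema": "moiretrack-transform-v1",
        "matrix": T.matrix().tolist(),  # 4x4 row-major
        "dof": {"x_mm": pose.tx, "y_mm": pose.ty, "z_mm": pose.tz,
                "pitch_deg": pose.pitch, "yaw_deg": pose.yaw, "roll_deg": pose.roll},
    }
    if fre_mm is not None:
        d["fre_mm"] = fre_mm
    Path(path).write_text(json.dumps(d, indent=1))


def read_transform(path) -> RigidTransform:
    path = Path(path)
    try:
        d = json.loads(path.read_text())
        return RigidTransform.from_matrix(np.asarray(d["matrix"]))
    except (KeyError, json.JSONDecodeError) as e:
        raise ParseError(f"{path}: not a valid transform file ({e})") from e


def write_correspondences(corr: PointCorrespondences, path) -> None:
    df = pd.DataFrame({
        "label": corr.labels,
        "xs": corr.source[:, 0], "ys": corr.source[:, 1], "zs": corr.source[:, 2],
        "xt": corr.target[:, 0], "yt": corr.target[:, 1], "zt": corr.target[:, 2],
    })
    df.to_csv(path, index=False, float_format="%.9g")


def read_correspondences(path) -> PointCorrespondences:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise ParseError(f"{path}: empty correspondences file") from e
    required = ["label", "xs", "ys", "zs", "xt", "yt", "zt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return PointCorrespondences(
        source=df[["xs", "ys", "zs"]].to_numpy(),
        target=df[["xt", "yt", "zt"]].to_numpy(),
        labels=df["label"].tolist(),
    )


def read_frame_dir(directory, camera_id: str = "cam", fps: float = 30.0) -> list[Frame]:
    """Load a directory of PNG frames (sorted by filename) as a frame stream."""
    import imageio.v3 as iio

    directory = Path(directory)
    paths = sorted(directory.glob("*.png"))
    if not paths:
        raise ParseError(f"{directory}: no PNG frames found")
    return [Frame(pixels=iio.imread(p), timestamp=i / fps, camera_id=camera_id)
            for i, p in enumerate(paths)]


def write_frames(frames, directory) -> list[Path]:
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for i, f in enumerate(frames):
        p = directory / f"frame_{i:05d}.png"
        iio.imwrite(p, np.asarray(f.pixels, dtype=np.uint8))
        out.append(p)
    return out


def write_manifest(path, config: dict, seed: int | None = None) -> None:
    """Reproducibility manifest: config hash, seed, package version."""
    blob = json.dumps(config, sort_keys=True, default=str)
    d = {
        "schema": "moiretrack-manifest-v1",
        "version": _version,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    Path(path).write_text(json.dumps(d, indent=1, default=str))
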