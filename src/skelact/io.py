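"""On-disk containers for skeleton sequences and heatmap volumes.

A dataset is a single HDF5 file with one group per clip plus a sidecar
JSON manifest (``<stem>.manifest.json``) listing subject / action /
repetition for quick inspection without opening the HDF5 file.

Group layout, 3D container::

    /seq_0000042/positions   float64 (frames, joints, 3)   attrs: frame_rate,
                             subject_id, action_label, repetition

2D containers store ``pixels (frames, joints, 2)`` with ``viewpoint_deg``,
``image_size`` and ``source`` attributes; volume containers store
``values (T, H, W)`` with ``map_type``, ``action_label``, ``viewpoint_deg``
and ``subject_id``.

Externally estimated keypoints can also be imported from CSV with columns
``frame, joint_index, x, y, confidence``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .skeleton import Skeleton2DSequence, Skeleton3DSequence, ValidationError

_FORMAT_VERSION = 1


def _manifest_path(path: Path) -> Path:
    return path.with_name(path.stem + ".manifest.json")


def write_dataset(sequences: Sequence[Skeleton3DSequence], path: str | Path) -> None:
    """Write 3D sequences to an HDF5 container, replacing any existing file."""
    path = Path(path)
    manifest: list[dict] = []
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["kind"] = "skeleton3d"
        for i, seq in enumerate(sequences):
            g = f.create_group(f"seq_{i:07d}")
            g.create_dataset("positions", data=seq.positions)
            g.attrs["frame_rate"] = seq.frame_rate
            g.attrs["subject_id"] = seq.subject_id
            g.attrs["action_label"] = seq.action_label
            g.attrs["repetition"] = seq.repetition
            manifest.append(
                {
                    "record": f"seq_{i:07d}",
                    "subject_id": seq.subject_id,
                    "action_label": int(seq.action_label),
                    "repetition": int(seq.repetition),
                    "frames": int(seq.num_frames),
                }
            )
    _manifest_path(path).write_text(json.dumps(manifest, indent=1))


def read_dataset(
    path: str | Path, expected_joints: int = 16
) -> list[Skeleton3DSequence]:
    """Read all 3D sequences from a container written by :func:`write_dataset`.

    Raises
    ------
    FileNotFoundError
        If the container does not exist.
    ValidationError
        Naming the offending record, if a record has the wrong joint count
        or non-finite coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[Skeleton3DSequence] = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            pos = np.asarray(g["positions"])
            if pos.ndim != 3 or pos.shape[1] != expected_joints or pos.shape[2] != 3:
                raise ValidationError(
                    f"record {name}: expected (frames, {expected_joints}, 3) "
                    f"positions, got {pos.shape}"
                )
            if not np.all(np.isfinite(pos)):
                raise ValidationError(f"record {name}: non-finite coordinates")
            out.append(
                Skeleton3DSequence(
                    positions=pos,
                    frame_rate=float(g.attrs["frame_rate"]),
                    subject_id=str(g.attrs["subject_id"]),
                    action_label=int(g.attrs["action_label"]),
                    repetition=int(g.attrs["repetition"]),
                )
            )
    return out


def write_dataset_2d(sequences: Sequence[Skeleton2DSequence], path: str | Path) -> None:
    """Write 2D sequences (one group per clip-viewpoint) to an HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["kind"] = "skeleton2d"
        for i, seq in enumerate(sequences):
            g = f.create_group(f"seq_{i:07d}")
            g.create_dataset("pixels", data=seq.pixels)
            g.attrs["viewpoint_deg"] = seq.viewpoint_deg
            g.attrs["image_size"] = seq.image_size
            g.attrs["source"] = seq.source
            g.attrs["subject_id"] = seq.subject_id
            g.attrs["action_label"] = seq.action_label
            g.attrs["repetition"] = seq.repetition


def read_dataset_2d(path: str | Path) -> list[Skeleton2DSequence]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[Skeleton2DSequence] = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            h, w = (int(v) for v in g.attrs["image_size"])
            out.append(
                Skeleton2DSequence(
                    pixels=np.asarray(g["pixels"]),
                    viewpoint_deg=float(g.attrs["viewpoint_deg"]),
                    image_size=(h, w),
                    source=str(g.attrs["source"]),
                    subject_id=str(g.attrs["subject_id"]),
                    action_label=int(g.attrs["action_label"]),
                    repetition=int(g.attrs["repetition"]),
                )
            )
    return out


def write_volumes(
    volumes: Iterable["object"], path: str | Path
) -> None:  # HeatmapVolume; avoids a circular import
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["kind"] = "heatmap_volumes"
        for i, vol in enumerate(volumes):
            g = f.create_group(f"vol_{i:07d}")
            g.create_dataset("values", data=vol.values, dtype=np.float32)
            g.attrs["map_type"] = vol.map_type
            g.attrs["action_label"] = vol.action_label
            g.attrs["viewpoint_deg"] = vol.viewpoint_deg
            g.attrs["subject_id"] = vol.subject_id


def read_volumes(path: str | Path):
    from .heatmap import HeatmapVolume

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            out.append(
                HeatmapVolume(
                    values=np.asarray(g["values"], dtype=np.float64),
                    map_type=str(g.attrs["map_type"]),
                    action_label=int(g.attrs["action_label"]),
                    viewpoint_deg=float(g.attrs["viewpoint_deg"]),
                    subject_id=str(g.attrs["subject_id"]),
                )
            )
    return out


def read_keypoints_csv(
    path: str | Path,
    image_size: tuple[int, int],
    num_joints: int = 16,
) -> Skeleton2DSequence:
    """Import an externally estimated 2D keypoint sequence.

    Expects columns ``frame, joint_index, x, y, confidence`` with one row
    per (frame, joint).  Every frame must provide all ``num_joints``
    joints.  The result carries ``source="estimated"`` and can be fed
    straight to the heatmap stage.
    """
    df = pd.read_csv(path)
    required = {"frame", "joint_index", "x", "y", "confidence"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"keypoint CSV missing columns: {sorted(missing)}")
    frames = np.sort(df["frame"].unique())
    pixels = np.full((len(frames), num_joints, 2), np.nan)
    conf = np.zeros((len(frames), num_joints))
    frame_pos = {f: i for i, f in enumerate(frames)}
    for row in df.itertuples(index=False):
        j = int(row.joint_index)
        if not 0 <= j < num_joints:
            raise ValidationError(f"joint_index {j} out of range [0, {num_joints})")
        t = frame_pos[row.frame]
        pixels[t, j] = (row.x, row.y)
        conf[t, j] = row.confidence
    if np.isnan(pixels).any():
        t, j = np.argwhere(np.isnan(pixels[..., 0]))[0]
        raise ValidationError(f"frame {frames[t]} missing joint {j}")
    return Skeleton2DSequence(
        pixels=pixels,
        viewpoint_deg=0.0,
        image_size=image_size,
        source="estimated",
        confidence=conf,
    )
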