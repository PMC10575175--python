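"""Gaussian joint/bone heatmap volumes from 2D skeleton sequences.

Each clip becomes a T x H x W single-channel pseudo-video: frames are
cropped to the minimal bounding box enclosing the subject across the
whole clip, T frames are sampled uniformly along the clip, and each
sampled frame is rendered as either

* a joint map - every pixel sums, over joints k, exp(-D(px, u_k)^2 / sigma^2)
  with D the Euclidean distance to joint k, or
* a bone map - the same kernel applied to the shortest distance from the
  pixel to each bone segment.

The kernel denominator is sigma^2 (not 2 sigma^2) and overlapping
contributions are summed, not maxed; both choices are switchable via
:class:`HeatmapConfig` (``accumulate``, ``denominator``) since related
pipelines differ here.  Pixel centers sit at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .skeleton import JointTopology, Skeleton2DSequence, ValidationError


class HeatmapConfig(BaseModel):
    """Rendering parameters.

    ``sigma`` is in output-grid pixels; ``padding_fraction`` expands the
    subject bounding box by that fraction of its size on every side
    before it is mapped to the output grid.
    """

    model_config = ConfigDict(extra="forbid")

    sigma: float = 1.5
    out_height: int = 64
    out_width: int = 64
    num_frames_out: int = 12
    padding_fraction: float = 0.1
    sampling_mode: str = "center"  # or "random"
    map_type: str = "joint"  # or "bone"
    accumulate: str = "sum"  # or "max"
    denominator: str = "sigma2"  # or "2sigma2"

    @model_validator(mode="after")
    def _check(self) -> "HeatmapConfig":
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if min(self.out_height, self.out_width, self.num_frames_out) < 1:
            raise ValueError("output dimensions must be >= 1")
        if self.padding_fraction < 0:
            raise ValueError("padding_fraction must be >= 0")
        if self.sampling_mode not in ("center", "random"):
            raise ValueError(f"unknown sampling_mode {self.sampling_mode!r}")
        if self.map_type not in ("joint", "bone"):
            raise ValueError(f"unknown map_type {self.map_type!r}")
        if self.accumulate not in ("sum", "max"):
            raise ValueError(f"unknown accumulate {self.accumulate!r}")
        if self.denominator not in ("sigma2", "2sigma2"):
            raise ValueError(f"unknown denominator {self.denominator!r}")
        return self

    @property
    def denom_value(self) -> float:
        return self.sigma**2 if self.denominator == "sigma2" else 2 * self.sigma**2


@dataclass
class HeatmapVolume:
    """A T x H x W non-negative stack of per-frame heatmaps with its label
    and originating viewpoint."""

    values: np.ndarray
    map_type: str
    action_label: int
    viewpoint_deg: float = 0.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError(f"values must be (T, H, W), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError("heatmap values must be finite and >= 0")


def point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance from point p to the closed segment [a, b]
    (distance to the point when a == b)."""
    p, a, b = (np.asarray(v, float) for v in (p, a, b))
    if not all(np.all(np.isfinite(v)) for v in (p, a, b)):
        raise ValidationError("non-finite input to point_segment_distance")
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.linalg.norm(p - a))
    t = np.clip(float((p - a) @ ab) / denom, 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def _grid(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    ys, xs = np.mgrid[0:h, 0:w]
    return xs.astype(float), ys.astype(float)


def joint_heatmap_frame(
    joints2d: np.ndarray, grid: tuple[int, int], sigma: float,
    denom: float | None = None, accumulate: str = "sum",
) -> np.ndarray:
    """Render one frame of the joint map on an H x W grid.

    ``joints2d`` is (N, 2) as (x, y) pixel coordinates.
    """
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    h, w = grid
    xs, ys = _grid(h, w)
    pts = np.asarray(joints2d, float)
    d2 = (xs[..., None] - pts[:, 0]) ** 2 + (ys[..., None] - pts[:, 1]) ** 2
    contrib = np.exp(-d2 / (denom if denom is not None else sigma**2))
    return contrib.max(axis=-1) if accumulate == "max" else contrib.sum(axis=-1)


def bone_heatmap_frame(
    joints2d: np.ndarray, topology: JointTopology, grid: tuple[int, int],
    sigma: float, denom: float | None = None, accumulate: str = "sum",
) -> np.ndarray:
    """Render one frame of the bone map: per pixel, sum over bone segments
    of the Gaussian of the shortest pixel-to-segment distance."""
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    h, w = grid
    xs, ys = _grid(h, w)
    pts = np.asarray(joints2d, float)
    a = pts[[i for i, _ in topology.bones]]  # (B, 2)
    b = pts[[j for _, j in topology.bones]]
    ab = b - a
    den = np.einsum("bi,bi->b", ab, ab)  # (B,)
    px = np.stack([xs, ys], axis=-1)  # (H, W, 2)
    rel = px[:, :, None, :] - a  # (H, W, B, 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.einsum("hwbi,bi->hwb", rel, ab) / den
    t = np.where(den > 0, np.clip(t, 0.0, 1.0), 0.0)
    nearest = a + t[..., None] * ab  # (H, W, B, 2)
    d2 = np.sum((px[:, :, None, :] - nearest) ** 2, axis=-1)
    contrib = np.exp(-d2 / (denom if denom is not None else sigma**2))
    return contrib.max(axis=-1) if accumulate == "max" else contrib.sum(axis=-1)


@dataclass(frozen=True)
class CropBox:
    """The padded subject bounding box (input-pixel units) and the affine
    map (uniform scale + offset) taking input pixels to output-grid pixels."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    scale: float
    offset: tuple[float, float]


def subject_centered_crop(
    seq2d: Skeleton2DSequence,
    padding_fraction: float,
    out_size: tuple[int, int],
) -> tuple[Skeleton2DSequence, CropBox]:
    """Crop to the minimal box enclosing all joints over all frames, expand
    by ``padding_fraction`` per side, and map keypoints affinely so the box
    fills the output grid (uniform scale, centered: letterboxing).

    Translation-invariant: shifting every input keypoint leaves the output
    unchanged.
    """
    h_out, w_out = out_size
    pts = seq2d.pixels
    x_min, y_min = pts[..., 0].min(), pts[..., 1].min()
    x_max, y_max = pts[..., 0].max(), pts[..., 1].max()
    wbox, hbox = x_max - x_min, y_max - y_min
    if wbox == 0.0 and hbox == 0.0:
        raise ValidationError("degenerate clip: all keypoints at one point")
    x_min -= padding_fraction * wbox
    x_max += padding_fraction * wbox
    y_min -= padding_fraction * hbox
    y_max += padding_fraction * hbox
    wbox, hbox = x_max - x_min, y_max - y_min
    tiny = 1e-12 * max(wbox, hbox)
    scale = min((w_out - 1) / max(wbox, tiny), (h_out - 1) / max(hbox, tiny))
    # center the scaled box in the output grid
    ox = (w_out - 1 - scale * wbox) / 2.0 - scale * x_min
    oy = (h_out - 1 - scale * hbox) / 2.0 - scale * y_min
    mapped = pts * scale + np.array([ox, oy])
    out = Skeleton2DSequence(
        pixels=mapped,
        viewpoint_deg=seq2d.viewpoint_deg,
        image_size=(h_out, w_out),
        source=seq2d.source,
        subject_id=seq2d.subject_id,
        action_label=seq2d.action_label,
        repetition=seq2d.repetition,
    )
    return out, CropBox(x_min, y_min, x_max, y_max, scale, (ox, oy))


def uniform_sample(
    num_frames_in: int,
    num_frames_out: int,
    mode: str = "center",
    seed: int | None = None,
) -> list[int]:
    """Pick one frame index per equal contiguous bin of [0, T_in).

    ``center`` takes each bin's central index (deterministic); ``random``
    draws one index per bin from ``seed``.  Indices are non-decreasing and
    repeat when T_in < T_out.
    """
    if num_frames_in < 1 or num_frames_out < 1:
        raise ValidationError("frame counts must be >= 1")
    r = num_frames_in / num_frames_out
    if mode == "center":
        return [int(np.floor((b + 0.5) * r)) for b in range(num_frames_out)]
    if mode != "random":
        raise ValidationError(f"unknown sampling mode {mode!r}")
    rng = np.random.default_rng(seed)
    idx = []
    for b in range(num_frames_out):
        lo = int(np.floor(b * r))
        hi = max(lo, int(np.ceil((b + 1) * r)) - 1)
        hi = min(hi, num_frames_in - 1)
        idx.append(int(rng.integers(lo, hi + 1)))
    return idx


def build_volume(
    seq2d: Skeleton2DSequence,
    topology: JointTopology,
    config: HeatmapConfig,
    seed: int | None = None,
) -> HeatmapVolume:
    """Crop, sample T frames, and render per-frame joint or bone maps."""
    cropped, _ = subject_centered_crop(
        seq2d, config.padding_fraction, (config.out_height, config.out_width)
    )
    idx = uniform_sample(
        cropped.num_frames, config.num_frames_out, config.sampling_mode, seed
    )
    grid = (config.out_height, config.out_width)
    frames = []
    for t in idx:
        if config.map_type == "joint":
            frames.append(
                joint_heatmap_frame(
                    cropped.pixels[t], grid, config.sigma,
                    config.denom_value, config.accumulate,
                )
            )
        else:
            frames.append(
                bone_heatmap_frame(
                    cropped.pixels[t], topology, grid, config.sigma,
                    config.denom_value, config.accumulate,
                )
            )
    return HeatmapVolume(
        values=np.stack(frames),
        map_type=config.map_type,
        action_label=seq2d.action_label,
        viewpoint_deg=seq2d.viewpoint_deg,
        subject_id=seq2d.subject_id,
    )
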