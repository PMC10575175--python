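"""Pinhole camera orbit and 3D-to-2D skeleton projection.

A virtual camera orbits the subject on a circle about the vertical (z)
axis: its position at angle theta is the initial position rotated by
R_z(theta) about the vertical axis through the orbit center.  Each 3D
skeleton frame is mapped to pixel coordinates with the standard
homogeneous projection  s2D ~ K [R | t] s3D  followed by perspective
division.  Rotating the camera by theta is exactly equivalent to rotating
the skeleton by -theta about the orbit axis and keeping the theta = 0
camera; the test suite verifies this duality numerically.

Pixel convention: origin top-left, x right, y down, continuous 0-based
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .skeleton import Skeleton2DSequence, Skeleton3DSequence, ValidationError


class ProjectionError(ValueError):
    """A skeleton point is at or behind the camera plane."""


class CameraIntrinsics(BaseModel):
    """Optical parameters: single focal length (square pixels, zero skew),
    principal point, and image size (height, width) in pixels.

    The default focal length is chosen so a ~2.2 m standing figure at the
    default 3 m orbit radius fills about 80% of the image height.
    """

    model_config = ConfigDict(extra="forbid")

    focal_px: float = 280.0
    principal_point: tuple[float, float] = (128.0, 128.0)  # (cx, cy)
    image_size: tuple[int, int] = (256, 256)  # (H, W)

    @model_validator(mode="after")
    def _check(self) -> "CameraIntrinsics":
        if self.focal_px <= 0:
            raise ValueError("focal_px must be positive")
        if min(self.image_size) < 1:
            raise ValueError("image_size components must be >= 1")
        return self

    @property
    def matrix(self) -> np.ndarray:
        cx, cy = self.principal_point
        return np.array(
            [[self.focal_px, 0.0, cx], [0.0, self.focal_px, cy], [0.0, 0.0, 1.0]]
        )


@dataclass(frozen=True)
class CameraPose:
    """Extrinsic pose: camera position, fixation point, and up direction."""

    position: np.ndarray
    look_at: np.ndarray
    up: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, float))
        object.__setattr__(self, "look_at", np.asarray(self.look_at, float))
        up = np.array([0.0, 0.0, 1.0]) if self.up is None else np.asarray(self.up, float)
        object.__setattr__(self, "up", up / np.linalg.norm(up))
        gaze = self.look_at - self.position
        norm = np.linalg.norm(gaze)
        if norm < 1e-12:
            raise ValidationError("camera position coincides with look_at")
        if np.linalg.norm(np.cross(gaze / norm, self.up)) < 1e-9:
            raise ValidationError("up vector parallel to viewing direction")


@dataclass(frozen=True)
class ProjectionMatrix:
    """3x4 matrix P = K [R | t] mapping world points to homogeneous pixels."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.shape != (3, 4):
            raise ValidationError(f"projection matrix must be 3x4, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValidationError("non-finite projection matrix")
        if abs(np.linalg.det(m[:, :3])) < 1e-12:
            raise ValidationError("singular left 3x3 block")
        object.__setattr__(self, "matrix", m)


class OrbitConfig(BaseModel):
    """Camera orbit: radius and absolute camera height in metres, and how
    the orbit center is chosen (median pelvis of the clip, or the world
    origin)."""

    model_config = ConfigDict(extra="forbid")

    radius: float = 3.0
    height: float = 1.0
    center_mode: str = "sequence_centroid"  # or "fixed_origin"

    @model_validator(mode="after")
    def _check(self) -> "OrbitConfig":
        if self.radius <= 0:
            raise ValueError("orbit radius must be positive")
        if self.center_mode not in ("sequence_centroid", "fixed_origin"):
            raise ValueError(f"unknown center_mode {self.center_mode!r}")
        return self


def rotate_about_z(p0: np.ndarray, theta_deg: float) -> np.ndarray:
    """Right-handed rotation of a 3-vector about the world z axis."""
    p0 = np.asarray(p0, float)
    if p0.shape[-1] != 3 or not np.all(np.isfinite(p0)):
        raise ValidationError("rotate_about_z needs finite 3-vectors")
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return p0 @ rz.T


def viewpoint_angles(spacing_deg: float) -> list[float]:
    """Evenly spaced orbit angles {0, s, 2s, ...} in [0, 360)."""
    if spacing_deg <= 0:
        raise ValidationError("spacing must be positive")
    n = 360.0 / spacing_deg
    if abs(n - round(n)) > 1e-9:
        raise ValidationError(f"spacing {spacing_deg} does not divide 360 evenly")
    return [i * spacing_deg for i in range(int(round(n)))]


def build_projection(intrinsics: CameraIntrinsics, pose: CameraPose) -> ProjectionMatrix:
    """P = K [R | t] for a look-at pose.

    Camera frame: x right, y down, z forward (along the gaze), so that the
    world up direction maps to decreasing pixel y.
    """
    fwd = pose.look_at - pose.position
    fwd = fwd / np.linalg.norm(fwd)
    right = np.cross(fwd, pose.up)
    right = right / np.linalg.norm(right)
    down = np.cross(fwd, right)  # = -true_up
    rot = np.stack([right, down, fwd])
    t = -rot @ pose.position
    return ProjectionMatrix(intrinsics.matrix @ np.hstack([rot, t[:, None]]))


def project_points(
    points: np.ndarray, proj: ProjectionMatrix, min_depth: float = 1e-6
) -> np.ndarray:
    """Project (..., 3) world points to (..., 2) pixels with perspective
    division; raises :class:`ProjectionError` if any point is at or behind
    the camera plane."""
    pts = np.asarray(points, float)
    homog = np.concatenate([pts, np.ones(pts.shape[:-1] + (1,))], axis=-1)
    uvw = homog @ proj.matrix.T
    depth = uvw[..., 2]
    if np.any(depth <= min_depth):
        idx = np.unravel_index(int(np.argmin(depth)), depth.shape)
        raise ProjectionError(
            f"point at index {idx} has depth {depth[idx]:.4g} <= {min_depth}"
        )
    return uvw[..., :2] / depth[..., None]


def orbit_center(seq3d: Skeleton3DSequence, orbit: OrbitConfig, pelvis_index: int = 0
                 ) -> np.ndarray:
    if orbit.center_mode == "fixed_origin":
        return np.zeros(3)
    return np.median(seq3d.positions[:, pelvis_index, :], axis=0)


def orbit_pose(orbit: OrbitConfig, center: np.ndarray, theta_deg: float) -> CameraPose:
    """Camera pose at orbit angle theta: the initial position (radius south
    of the center, at the configured height) rotated about the vertical
    axis through the center."""
    p0 = np.array([0.0, -orbit.radius, orbit.height - center[2]])
    offset = rotate_about_z(p0, theta_deg)
    return CameraPose(position=center + offset, look_at=center)


def project_sequence(
    seq3d: Skeleton3DSequence,
    intrinsics: CameraIntrinsics,
    orbit: OrbitConfig,
    theta_deg: float,
    pelvis_index: int = 0,
) -> Skeleton2DSequence:
    """Project every frame of a 3D clip from the orbit viewpoint theta."""
    center = orbit_center(seq3d, orbit, pelvis_index)
    proj = build_projection(intrinsics, orbit_pose(orbit, center, theta_deg))
    try:
        pixels = project_points(seq3d.positions, proj)
    except ProjectionError as err:
        raise ProjectionError(
            f"clip subject={seq3d.subject_id} action={seq3d.action_label} "
            f"rep={seq3d.repetition} theta={theta_deg}: {err}"
        ) from err
    return Skeleton2DSequence(
        pixels=pixels,
        viewpoint_deg=float(theta_deg) % 360.0,
        image_size=intrinsics.image_size,
        source="projected",
        subject_id=seq3d.subject_id,
        action_label=seq3d.action_label,
        repetition=seq3d.repetition,
    )
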