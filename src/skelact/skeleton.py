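"""Skeleton data model: joint topology and labelled 2D/3D motion sequences.

The native representation throughout the package is a 16-joint human
skeleton: per-frame 3D joint positions in metres (world frame, z up) or,
after camera projection, per-frame 2D pixel coordinates.  The topology is
configurable so alternative joint sets can be supplied, but every default
path assumes the canonical 16-joint body below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass(frozen=True)
class JointTopology:
    """An ordered joint set plus the bone tree connecting it.

    Parameters
    ----------
    joint_names
        Ordered joint identifiers; the position arrays of every sequence
        follow this order.
    bones
        ``(parent_index, child_index)`` pairs.  Must form a spanning tree
        over the joints (``n_joints - 1`` undirected edges, connected).
    root_index
        Index of the kinematic root (pelvis for the default body).
    """

    joint_names: tuple[str, ...]
    bones: tuple[tuple[int, int], ...]
    root_index: int = 0

    def __post_init__(self) -> None:
        n = len(self.joint_names)
        if n < 2:
            raise ValidationError("topology needs at least two joints")
        if len(set(self.joint_names)) != n:
            raise ValidationError("duplicate joint names")
        if not 0 <= self.root_index < n:
            raise ValidationError(f"root_index {self.root_index} out of range")
        if len(self.bones) != n - 1:
            raise ValidationError(
                f"a tree on {n} joints has {n - 1} bones, got {len(self.bones)}"
            )
        seen: set[frozenset[int]] = set()
        adj: dict[int, list[int]] = {i: [] for i in range(n)}
        for a, b in self.bones:
            if not (0 <= a < n and 0 <= b < n):
                raise ValidationError(f"bone ({a}, {b}) references a missing joint")
            if a == b:
                raise ValidationError(f"self-loop bone at joint {a}")
            key = frozenset((a, b))
            if key in seen:
                raise ValidationError(f"duplicate bone ({a}, {b})")
            seen.add(key)
            adj[a].append(b)
            adj[b].append(a)
        # n-1 distinct edges + connectivity <=> spanning tree
        stack, reached = [self.root_index], {self.root_index}
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in reached:
                    reached.add(nb)
                    stack.append(nb)
        if len(reached) != n:
            raise ValidationError("bone list does not connect all joints")

    @property
    def num_joints(self) -> int:
        return len(self.joint_names)

    def index(self, name: str) -> int:
        return self.joint_names.index(name)


_DEFAULT_JOINTS = (
    "pelvis",
    "spine",
    "neck",
    "head",
    "l_shoulder",
    "l_elbow",
    "l_wrist",
    "r_shoulder",
    "r_elbow",
    "r_wrist",
    "l_hip",
    "l_knee",
    "l_ankle",
    "r_hip",
    "r_knee",
    "r_ankle",
)

_DEFAULT_BONES = (
    (0, 1),   # pelvis  -> spine
    (1, 2),   # spine   -> neck
    (2, 3),   # neck    -> head
    (2, 4),   # neck    -> l_shoulder
    (4, 5),   # l_shoulder -> l_elbow
    (5, 6),   # l_elbow -> l_wrist
    (2, 7),   # neck    -> r_shoulder
    (7, 8),   # r_shoulder -> r_elbow
    (8, 9),   # r_elbow -> r_wrist
    (0, 10),  # pelvis  -> l_hip
    (10, 11),  # l_hip  -> l_knee
    (11, 12),  # l_knee -> l_ankle
    (0, 13),  # pelvis  -> r_hip
    (13, 14),  # r_hip  -> r_knee
    (14, 15),  # r_knee -> r_ankle
)


def default_topology() -> JointTopology:
    """The canonical 16-joint body: head/neck/spine/pelvis plus two
    three-joint arms and legs; pelvis is the root; 15 bones."""
    return JointTopology(_DEFAULT_JOINTS, _DEFAULT_BONES, root_index=0)


@dataclass
class Skeleton3DSequence:
    """A labelled 3D motion clip.

    ``positions`` is ``(frames, n_joints, 3)`` in metres, world frame with
    z vertical, origin near the subject's initial pelvis position.
    """

    positions: np.ndarray
    frame_rate: float
    subject_id: str
    action_label: int
    repetition: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValidationError(
                f"positions must be (frames, joints, 3), got {self.positions.shape}"
            )
        if self.positions.shape[0] < 1:
            raise ValidationError("sequence needs at least one frame")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("non-finite 3D coordinates")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        if self.action_label < 0:
            raise ValidationError("action_label must be non-negative")

    @property
    def num_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def num_joints(self) -> int:
        return self.positions.shape[1]


@dataclass
class Skeleton2DSequence:
    """Per-frame 2D joint pixel coordinates for one viewpoint.

    ``pixels`` is ``(frames, n_joints, 2)`` as continuous (x, y) pixel
    coordinates, origin top-left, x right, y down, 0-based.  ``source``
    records whether the keypoints came from camera projection of a 3D clip
    or from an external pose estimator.
    """

    pixels: np.ndarray
    viewpoint_deg: float
    image_size: tuple[int, int]  # (height, width)
    source: str = "projected"
    subject_id: str = ""
    action_label: int = 0
    repetition: int = 0
    confidence: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 2:
            raise ValidationError(
                f"pixels must be (frames, joints, 2), got {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1:
            raise ValidationError("sequence needs at least one frame")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("non-finite pixel coordinates")
        if self.source not in ("projected", "estimated"):
            raise ValidationError(f"unknown source {self.source!r}")
        h, w = self.image_size
        if h < 1 or w < 1:
            raise ValidationError("image_size components must be >= 1")
        self.image_size = (int(h), int(w))

    @property
    def num_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def num_joints(self) -> int:
        return self.pixels.shape[1]
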