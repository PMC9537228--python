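"""Skeleton definition: joint names, tree topology, and a reference rest pose."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Canonical 20-joint skeleton (end effectors such as toe tips removed).
#: Convention: x = walking direction, y = up, z = lateral (left side at z > 0).
DEFAULT_JOINT_NAMES: tuple[str, ...] = (
    "pelvis",
    "spine",
    "neck",
    "head",
    "l_shoulder",
    "l_elbow",
    "l_wrist",
    "l_hand",
    "r_shoulder",
    "r_elbow",
    "r_wrist",
    "r_hand",
    "l_hip",
    "l_knee",
    "l_ankle",
    "l_foot",
    "r_hip",
    "r_knee",
    "r_ankle",
    "r_foot",
)

DEFAULT_PARENT_INDEX: tuple[int, ...] = (
    -1,  # pelvis
    0,   # spine -> pelvis
    1,   # neck -> spine
    2,   # head -> neck
    2,   # l_shoulder -> neck
    4,   # l_elbow
    5,   # l_wrist
    6,   # l_hand
    2,   # r_shoulder -> neck
    8,   # r_elbow
    9,   # r_wrist
    10,  # r_hand
    0,   # l_hip -> pelvis
    12,  # l_knee
    13,  # l_ankle
    14,  # l_foot
    0,   # r_hip -> pelvis
    16,  # r_knee
    17,  # r_ankle
    18,  # r_foot
)

#: Reference standing pose in meters (x forward, y up, z lateral-left).
DEFAULT_REST_POSE: dict[str, tuple[float, float, float]] = {
    "pelvis": (0.0, 1.00, 0.0),
    "spine": (0.0, 1.25, 0.0),
    "neck": (0.0, 1.50, 0.0),
    "head": (0.0, 1.65, 0.0),
    "l_shoulder": (0.0, 1.45, 0.20),
    "l_elbow": (0.0, 1.20, 0.25),
    "l_wrist": (0.0, 1.00, 0.27),
    "l_hand": (0.0, 0.90, 0.28),
    "r_shoulder": (0.0, 1.45, -0.20),
    "r_elbow": (0.0, 1.20, -0.25),
    "r_wrist": (0.0, 1.00, -0.27),
    "r_hand": (0.0, 0.90, -0.28),
    "l_hip": (0.0, 0.95, 0.10),
    "l_knee": (0.0, 0.50, 0.10),
    "l_ankle": (0.0, 0.10, 0.10),
    "l_foot": (0.10, 0.05, 0.10),
    "r_hip": (0.0, 0.95, -0.10),
    "r_knee": (0.0, 0.50, -0.10),
    "r_ankle": (0.0, 0.10, -0.10),
    "r_foot": (0.10, 0.05, -0.10),
}


@dataclass(frozen=True)
class SkeletonDef:
    """Ordered joint list with a parent index per joint (-1 marks the root).

    The parent indices must form a tree rooted at the single joint whose
    parent is -1.
    """

    joint_names: tuple[str, ...] = DEFAULT_JOINT_NAMES
    parent_index: tuple[int, ...] = DEFAULT_PARENT_INDEX

    def __post_init__(self) -> None:
        if len(self.joint_names) != len(self.parent_index):
            raise ValueError(
                f"joint_names has {len(self.joint_names)} entries but "
                f"parent_index has {len(self.parent_index)}"
            )
        if len(set(self.joint_names)) != len(self.joint_names):
            raise ValueError("duplicate joint names")
        roots = [i for i, p in enumerate(self.parent_index) if p == -1]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root joint, found {len(roots)}")
        for i, p in enumerate(self.parent_index):
            if p != -1 and not (0 <= p < len(self.joint_names)):
                raise ValueError(f"parent index {p} of joint {i} out of range")

    @property
    def J(self) -> int:
        return len(self.joint_names)

    @property
    def root_index(self) -> int:
        return self.parent_index.index(-1)

    def index(self, name: str) -> int:
        try:
            return self.joint_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown joint {name!r}; known joints: {', '.join(self.joint_names)}"
            ) from None

    def subset(self, keep: list[str] | tuple[str, ...]) -> "SkeletonDef":
        """Restrict to ``keep`` (in that order), re-rooting parents by walking
        up the original tree until a kept ancestor (or the root) is found."""
        kept_idx = [self.index(name) for name in keep]
        old_to_new = {old: new for new, old in enumerate(kept_idx)}
        parents = []
        for old in kept_idx:
            p = self.parent_index[old]
            while p != -1 and p not in old_to_new:
                p = self.parent_index[p]
            parents.append(old_to_new.get(p, -1) if p != -1 else -1)
        # ensure a single root survives the subsetting
        if parents.count(-1) != 1:
            # promote the first joint to root if the original root was dropped
            first_root = parents.index(-1) if -1 in parents else 0
            parents = [p if (p != -1 or i == first_root) else -1 for i, p in enumerate(parents)]
            if -1 not in parents:
                parents[0] = -1
        return SkeletonDef(tuple(keep), tuple(parents))


def default_skeleton() -> SkeletonDef:
    """The canonical 20-joint skeleton used throughout the package."""
    return SkeletonDef()


def rest_pose(skeleton: SkeletonDef | None = None) -> np.ndarray:
    """Reference standing pose, shape (J, 3), for the default joint names."""
    skeleton = skeleton or default_skeleton()
    try:
        return np.array([DEFAULT_REST_POSE[n] for n in skeleton.joint_names], dtype=float)
    except KeyError as exc:
        raise KeyError(f"no rest-pose entry for joint {exc.args[0]!r}") from None
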