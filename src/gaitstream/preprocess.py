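"""Temporal and spatial normalization of walking cycles.

Every cycle is rescaled to a fixed frame count by per-channel linear
interpolation, rigidly rotated about the vertical axis and translated so all
motions start at the origin and progress along a common heading, and
restricted to the canonical joint set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from gaitstream.io import MotionSample
from gaitstream.skeleton import SkeletonDef

VERTICAL_AXIS = 1  # y is up; heading rotations are about this axis


class AlignmentError(ValueError):
    """Raised when the walking heading is undefined (no horizontal motion)."""


@dataclass
class NormalizationConfig:
    """Settings of the normalization pipeline.

    ``t_target`` must be at least 3 so the temporal convolution kernel fits.
    """

    t_target: int = 100
    keep_joints: tuple[str, ...] | None = None
    heading_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.t_target < 3:
            raise ValueError(f"t_target must be >= 3, got {self.t_target}")
        h = np.asarray(self.heading_axis, dtype=float)
        if abs(h[VERTICAL_AXIS]) > 1e-12:
            raise ValueError("heading_axis must be horizontal (zero vertical component)")
        norm = np.linalg.norm(h)
        if norm == 0:
            raise ValueError("heading_axis must be nonzero")
        self.heading_axis = tuple(h / norm)


def resample_linear(sample: MotionSample, t_target: int) -> MotionSample:
    """Rescale to ``t_target`` frames by piecewise-linear interpolation.

    Each coordinate channel is sampled at ``t_target`` equally spaced
    parameter values spanning the original first and last frames, which are
    preserved exactly.
    """
    if t_target < 3:
        raise ValueError(f"t_target must be >= 3, got {t_target}")
    T = sample.n_frames
    old = np.arange(T, dtype=float)
    new = np.linspace(0.0, T - 1.0, t_target)
    flat = sample.positions.reshape(T, -1)
    out = np.empty((t_target, flat.shape[1]))
    for c in range(flat.shape[1]):
        out[:, c] = np.interp(new, old, flat[:, c])
    # endpoints are exact by construction of np.linspace/np.interp
    out[0] = flat[0]
    out[-1] = flat[-1]
    new_rate = sample.frame_rate * (t_target - 1) / max(T - 1, 1)
    return sample.with_positions(
        out.reshape(t_target, sample.skeleton.J, 3), frame_rate=new_rate
    )


def _heading_angle(v: np.ndarray) -> float:
    """Angle of the horizontal (x, z) components of ``v`` about the y axis."""
    return float(np.arctan2(v[2], v[0]))


def spatial_align(
    sample: MotionSample, config: NormalizationConfig | None = None
) -> MotionSample:
    """Translate and rotate so the cycle starts at the origin heading along
    ``config.heading_axis``.

    A single rigid rotation about the vertical axis plus a translation is
    applied to every joint of every frame; the rotation maps the horizontal
    root displacement (first to last frame) onto the heading axis.
    """
    config = config or NormalizationConfig()
    root = sample.skeleton.root_index
    start = sample.positions[0, root].copy()
    disp = sample.positions[-1, root] - start
    horiz = np.array([disp[0], 0.0, disp[2]])
    if np.linalg.norm(horiz) < 1e-12:
        raise AlignmentError(
            "zero horizontal root displacement: walking heading is undefined"
        )
    theta = _heading_angle(disp) - _heading_angle(np.asarray(config.heading_axis))
    c, s = np.cos(theta), np.sin(theta)
    # rotation about y by -theta brings the heading onto heading_axis
    rot = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    shifted = sample.positions - start[None, None, :]
    aligned = shifted @ rot.T
    return sample.with_positions(aligned)


def select_joints(sample: MotionSample, keep: list[str] | tuple[str, ...]) -> MotionSample:
    """Restrict and reorder joints to ``keep``; frames are unchanged."""
    for name in keep:
        if name not in sample.skeleton.joint_names:
            raise KeyError(
                f"unknown joint {name!r}; sample joints: "
                f"{', '.join(sample.skeleton.joint_names)}"
            )
    idx = [sample.skeleton.index(n) for n in keep]
    sub = sample.skeleton.subset(keep)
    return MotionSample(
        positions=sample.positions[:, idx, :],
        frame_rate=sample.frame_rate,
        label=sample.label,
        sample_id=sample.sample_id,
        skeleton=sub,
        synthetic=sample.synthetic,
    )


def normalize(sample: MotionSample, config: NormalizationConfig | None = None) -> MotionSample:
    """Full pipeline: joint selection, heading alignment, temporal resampling."""
    config = config or NormalizationConfig()
    out = sample
    if config.keep_joints is not None:
        out = select_joints(out, config.keep_joints)
    out = spatial_align(out, config)
    out = resample_linear(out, config.t_target)
    return out
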