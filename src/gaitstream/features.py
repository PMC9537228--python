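"""Stream inputs: joint-position and relative-joint-displacement tensors.

The position stream consumes ``S`` of shape (T, J, 3). The displacement
stream consumes ``S'`` of shape (T, J*(J-1), 3) holding the coordinate-wise
difference between every ordered joint pair (i, j), i != j, laid out in
grouped-by-first-joint lexicographic order so that a spatial filter of width
J-1 with stride J-1 covers exactly one joint's correlation block per
placement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gaitstream.io import MotionSample


@dataclass(frozen=True)
class JointPositionTensor:
    """Tensor ``S`` of shape (T, J, 3): position of joint i at frame t."""

    S: np.ndarray
    sample_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        if self.S.ndim != 3 or self.S.shape[2] != 3:
            raise ValueError(f"S must have shape (T, J, 3), got {self.S.shape}")
        if not np.all(np.isfinite(self.S)):
            raise ValueError("S contains non-finite values")

    @property
    def T(self) -> int:
        return self.S.shape[0]

    @property
    def J(self) -> int:
        return self.S.shape[1]


@dataclass(frozen=True)
class RelativeDisplacementTensor:
    """Tensor ``S'`` of shape (T, J*(J-1), 3) over all ordered joint pairs.

    ``pair_order[d]`` gives the 0-based (i, j) pair stored at column d;
    antisymmetry ``S'[t, index(i, j)] == -S'[t, index(j, i)]`` holds exactly.
    """

    S_prime: np.ndarray
    pair_order: tuple[tuple[int, int], ...]
    sample_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        if self.S_prime.ndim != 3 or self.S_prime.shape[2] != 3:
            raise ValueError(f"S' must have shape (T, D, 3), got {self.S_prime.shape}")
        if len(self.pair_order) != self.S_prime.shape[1]:
            raise ValueError("pair_order length must equal the number of columns")

    @property
    def T(self) -> int:
        return self.S_prime.shape[0]

    @property
    def D(self) -> int:
        return self.S_prime.shape[1]


def pair_index(i: int, j: int, J: int) -> int:
    """Column of ordered pair (i, j) in the grouped-by-first-joint layout.

    Indices are 0-based. All pairs (0, j) come first in ascending j, then
    (1, j), and so on; columns [i*(J-1), (i+1)*(J-1)) are exactly joint i's
    correlations to all other joints.
    """
    if not (0 <= i < J and 0 <= j < J):
        raise IndexError(f"joint indices must be in [0, {J}), got ({i}, {j})")
    if i == j:
        raise ValueError(f"self-pairs are excluded, got (i, j) = ({i}, {j})")
    return i * (J - 1) + (j if j < i else j - 1)


def pair_order(J: int) -> tuple[tuple[int, int], ...]:
    """All ordered pairs (i, j), i != j, in ``pair_index`` column order."""
    return tuple((i, j) for i in range(J) for j in range(J) if j != i)


def build_jp(sample: MotionSample) -> JointPositionTensor:
    """Copy a normalized motion into the position-stream tensor ``S``."""
    return JointPositionTensor(
        S=sample.positions.copy(), sample_id=sample.sample_id, label=sample.label
    )


def build_rjdp(sample: MotionSample) -> RelativeDisplacementTensor:
    """Build the displacement-stream tensor ``S'`` from a normalized motion."""
    pos = sample.positions
    order = pair_order(sample.skeleton.J)
    idx_i = np.array([p[0] for p in order])
    idx_j = np.array([p[1] for p in order])
    s_prime = pos[:, idx_i, :] - pos[:, idx_j, :]
    return RelativeDisplacementTensor(
        S_prime=s_prime,
        pair_order=order,
        sample_id=sample.sample_id,
        label=sample.label,
    )
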