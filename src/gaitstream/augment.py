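"""Mixup augmentation and per-class balancing.

A synthetic sample is the convex combination ``lam * X_a + (1 - lam) * X_b``
of two real samples from different classes and carries the label of the
dominant anchor ``X_a``. Balancing fills every class up to a common target
count; real samples are always retained and synthetic ones are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gaitstream.io import CLASSES, MotionSample


@dataclass(frozen=True)
class MixupSpec:
    """Interpolation weight and per-class balancing target."""

    lam: float = 0.9
    target_per_class: int = 45
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")
        if self.target_per_class < 1:
            raise ValueError(f"target_per_class must be >= 1, got {self.target_per_class}")


def mixup(x_a: np.ndarray, x_b: np.ndarray, lam: float) -> np.ndarray:
    """Elementwise ``lam * x_a + (1 - lam) * x_b``."""
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.shape != x_b.shape:
        raise ValueError(f"shape mismatch: {x_a.shape} vs {x_b.shape}")
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lam must be in [0, 1], got {lam}")
    return lam * x_a + (1.0 - lam) * x_b


def mixup_samples(
    anchor: MotionSample, donor: MotionSample, lam: float, sample_id: str
) -> MotionSample:
    """Mix two motions; the result carries the anchor's label and is flagged
    as synthetic."""
    if anchor.positions.shape != donor.positions.shape:
        raise ValueError(
            f"anchor/donor shape mismatch: {anchor.positions.shape} vs "
            f"{donor.positions.shape} (normalize to a common frame count first)"
        )
    return MotionSample(
        positions=mixup(anchor.positions, donor.positions, lam),
        frame_rate=anchor.frame_rate,
        label=anchor.label,
        sample_id=sample_id,
        skeleton=anchor.skeleton,
        synthetic=True,
    )


def balance_by_mixup(
    samples: list[MotionSample],
    spec: MixupSpec,
    classes: tuple[str, ...] = CLASSES,
) -> list[MotionSample]:
    """Fill every class up to ``spec.target_per_class`` with mixup samples.

    For each deficit class ``a``, the anchor ``X_a`` is drawn uniformly from
    the real samples of ``a`` and the donor ``X_b`` uniformly from a
    different class (chosen uniformly among the other non-empty classes).
    Deterministic given ``spec.seed``.
    """
    by_class: dict[str, list[MotionSample]] = {c: [] for c in classes}
    for s in samples:
        if s.label not in by_class:
            raise ValueError(f"sample {s.sample_id!r} has label {s.label!r} not in {classes}")
        by_class[s.label].append(s)
    empty = [c for c in classes if not by_class[c]]
    if empty:
        raise ValueError(
            f"cannot synthesize classes with no real anchor sample: {', '.join(empty)}"
        )
    over = [c for c in classes if len(by_class[c]) > spec.target_per_class]
    if over:
        raise ValueError(
            f"classes exceed target_per_class={spec.target_per_class}: {', '.join(over)}"
        )
    rng = np.random.default_rng(spec.seed)
    out = list(samples)
    for cls in classes:
        real = by_class[cls]
        donors_pool = [c for c in classes if c != cls and by_class[c]]
        for k in range(spec.target_per_class - len(real)):
            anchor = real[rng.integers(len(real))]
            donor_cls = donors_pool[rng.integers(len(donors_pool))]
            donor_list = by_class[donor_cls]
            donor = donor_list[rng.integers(len(donor_list))]
            out.append(
                mixup_samples(anchor, donor, spec.lam, sample_id=f"{cls}_mix{k:03d}")
            )
    return out
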