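"""Class-structured synthetic walking-motion generator.

Joints oscillate as phase-offset sinusoids (left/right limbs in antiphase)
around a reference standing pose, superimposed on a constant forward root
translation. Disorder classes perturb the kinematics through four knobs:

* ``asymmetry_ratio`` — scales the oscillation amplitude of the affected
  (right-leg) joints relative to the left side;
* ``rom_scale`` — additional range-of-motion reduction on a focal joint set
  (right knee and hip by default);
* ``tremor_sd`` — high-frequency additive noise on the affected joints;
* ``phase_jitter_sd`` — per-sample random phase offsets (gait irregularity).

The generator is deterministic given (params, class label, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gaitstream.io import CLASSES, MotionSample
from gaitstream.skeleton import SkeletonDef, default_skeleton, rest_pose


@dataclass(frozen=True)
class ClassEffect:
    """Kinematic perturbation applied to one disorder class."""

    asymmetry_ratio: float = 1.0  # in (0, 1]; 1 = symmetric
    rom_scale: float = 1.0        # in (0, 1]; multiplier on focal joints
    tremor_sd: float = 0.0        # meters
    phase_jitter_sd: float = 0.0  # radians

    def __post_init__(self) -> None:
        if not (0.0 < self.asymmetry_ratio <= 1.0):
            raise ValueError(f"asymmetry_ratio must be in (0, 1], got {self.asymmetry_ratio}")
        if not (0.0 < self.rom_scale <= 1.0):
            raise ValueError(f"rom_scale must be in (0, 1], got {self.rom_scale}")
        if self.tremor_sd < 0 or self.phase_jitter_sd < 0:
            raise ValueError("tremor_sd and phase_jitter_sd must be >= 0")


def _default_class_effects() -> dict[str, ClassEffect]:
    return {
        "healthy": ClassEffect(phase_jitter_sd=0.02),
        "joint_problem": ClassEffect(rom_scale=0.35, phase_jitter_sd=0.02),
        "muscle_weakness": ClassEffect(asymmetry_ratio=0.45, phase_jitter_sd=0.02),
        "neurological_defect": ClassEffect(
            asymmetry_ratio=0.75, rom_scale=0.7, tremor_sd=0.02, phase_jitter_sd=0.15
        ),
    }


def _default_amplitudes(skeleton: SkeletonDef) -> np.ndarray:
    base = {
        "pelvis": 0.03,
        "spine": 0.02,
        "neck": 0.02,
        "head": 0.02,
        "shoulder": 0.05,
        "elbow": 0.10,
        "wrist": 0.15,
        "hand": 0.15,
        "hip": 0.10,
        "knee": 0.25,
        "ankle": 0.30,
        "foot": 0.30,
    }
    amps = np.zeros(skeleton.J)
    for i, name in enumerate(skeleton.joint_names):
        key = name.split("_", 1)[-1]
        amps[i] = base.get(key, 0.05)
    return amps


@dataclass
class GaitSimParams:
    """Parameters of the synthetic gait simulator.

    ``affected_joints`` is the joint set perturbed by asymmetry and tremor;
    ``rom_joints`` is the focal subset further scaled by ``rom_scale``.
    """

    n_frames_raw: int = 120
    frame_rate: float = 100.0      # Hz, matching optical capture hardware
    stride_period: float = 1.2     # seconds per gait cycle
    walking_speed: float = 1.2     # m/s forward root translation
    base_amplitudes: np.ndarray | None = None
    class_effects: dict[str, ClassEffect] = field(default_factory=_default_class_effects)
    affected_joints: tuple[str, ...] = ("r_hip", "r_knee", "r_ankle", "r_foot")
    rom_joints: tuple[str, ...] = ("r_knee", "r_hip")
    noise_sd: float = 0.0          # meters, sensor noise on all joints
    seed: int = 0
    skeleton: SkeletonDef = field(default_factory=default_skeleton)

    def __post_init__(self) -> None:
        if self.n_frames_raw < 10:
            raise ValueError(f"n_frames_raw must be >= 10, got {self.n_frames_raw}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.base_amplitudes is None:
            self.base_amplitudes = _default_amplitudes(self.skeleton)
        else:
            self.base_amplitudes = np.asarray(self.base_amplitudes, dtype=float)
            if self.base_amplitudes.shape != (self.skeleton.J,):
                raise ValueError(
                    f"base_amplitudes must have shape ({self.skeleton.J},), "
                    f"got {self.base_amplitudes.shape}"
                )
            if np.any(self.base_amplitudes < 0):
                raise ValueError("base_amplitudes must be >= 0")


def _joint_phases(skeleton: SkeletonDef) -> np.ndarray:
    """Left leg / right arm at phase 0; right leg / left arm in antiphase."""
    phases = np.zeros(skeleton.J)
    for i, name in enumerate(skeleton.joint_names):
        if name.startswith("r_"):
            side = "right"
        elif name.startswith("l_"):
            side = "left"
        else:
            side = "center"
        is_arm = any(part in name for part in ("shoulder", "elbow", "wrist", "hand"))
        if side == "right":
            phases[i] = 0.0 if is_arm else np.pi
        elif side == "left":
            phases[i] = np.pi if is_arm else 0.0
        else:
            phases[i] = np.pi / 2  # trunk sway between the two
    return phases


def simulate_walk(params: GaitSimParams, class_label: str, seed: int) -> MotionSample:
    """Generate one synthetic walking cycle for the given disorder class."""
    if class_label not in CLASSES:
        raise ValueError(
            f"unknown class {class_label!r}; valid classes: {', '.join(CLASSES)}"
        )
    effect = params.class_effects.get(class_label, ClassEffect())
    skeleton = params.skeleton
    rng = np.random.default_rng(seed)

    T = params.n_frames_raw
    t = np.arange(T) / params.frame_rate                      # seconds
    omega = 2.0 * np.pi / params.stride_period                # rad/s

    amps = params.base_amplitudes.copy()
    affected = np.array([skeleton.index(n) for n in params.affected_joints], dtype=int)
    focal = np.array([skeleton.index(n) for n in params.rom_joints], dtype=int)
    amps[affected] *= effect.asymmetry_ratio
    amps[focal] *= effect.rom_scale

    phases = _joint_phases(skeleton)
    jitter = rng.normal(0.0, effect.phase_jitter_sd, size=skeleton.J)

    pose = rest_pose(skeleton)                                # (J, 3)
    positions = np.broadcast_to(pose, (T, skeleton.J, 3)).copy()

    phase_t = omega * t[:, None] + phases[None, :] + jitter[None, :]   # (T, J)
    # sagittal swing (x) with a smaller vertical component (y)
    positions[:, :, 0] += amps[None, :] * np.sin(phase_t)
    positions[:, :, 1] += 0.25 * amps[None, :] * np.cos(2.0 * phase_t)
    # forward root translation shared by the whole body
    positions[:, :, 0] += params.walking_speed * t[:, None]

    if effect.tremor_sd > 0:
        positions[:, affected, :] += rng.normal(
            0.0, effect.tremor_sd, size=(T, len(affected), 3)
        )
    if params.noise_sd > 0:
        positions += rng.normal(0.0, params.noise_sd, size=positions.shape)

    return MotionSample(
        positions=positions,
        frame_rate=params.frame_rate,
        label=class_label,
        sample_id=f"{class_label}_s{seed}",
        skeleton=skeleton,
    )


def generate_cohort(
    params: GaitSimParams, counts: dict[str, int], seed: int
) -> list[MotionSample]:
    """Generate a labelled cohort with the requested per-class counts.

    Per-sample seeds are spawned deterministically from the master seed, so
    the same (params, counts, seed) always yields an identical cohort.
    """
    for cls, n in counts.items():
        if cls not in CLASSES:
            raise ValueError(
                f"unknown class {cls!r}; valid classes: {', '.join(CLASSES)}"
            )
        if n < 0:
            raise ValueError(f"count for {cls!r} must be >= 0, got {n}")
    total = sum(counts.values())
    child_seeds = np.random.SeedSequence(seed).generate_state(max(total, 1))
    samples: list[MotionSample] = []
    k = 0
    for cls in CLASSES:
        for i in range(counts.get(cls, 0)):
            sample = simulate_walk(params, cls, int(child_seeds[k]))
            sample.sample_id = f"{cls}_{i:03d}"
            samples.append(sample)
            k += 1
    return samples
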