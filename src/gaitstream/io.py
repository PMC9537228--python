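"""Motion samples and their on-disk interchange formats.

Canonical formats:

* Motion CSV — header ``frame,<joint>_x,<joint>_y,<joint>_z`` for every joint,
  one row per frame, UTF-8, '.' decimal separator, coordinates in meters.
* Manifest CSV — header ``sample_id,path,label`` with label drawn from the
  four canonical disorder classes or ``unlabelled``.
* TRC — best-effort reader for optical motion-capture exports; the
  header-declared unit is honored (millimeters are converted to meters).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from gaitstream.skeleton import SkeletonDef, default_skeleton

#: Canonical disorder classes, in fixed order.
CLASSES: tuple[str, ...] = (
    "healthy",
    "joint_problem",
    "muscle_weakness",
    "neurological_defect",
)

UNLABELLED = "unlabelled"

_VALID_LABELS = frozenset(CLASSES) | {UNLABELLED}


class MotionParseError(ValueError):
    """Raised when a motion or manifest file violates its dialect."""


@dataclass
class MotionSample:
    """One subject's walking cycle: frames x joints x 3 coordinates plus label.

    Invariants enforced on construction: at least 2 frames, a (T, J, 3)
    position array matching the skeleton's joint count, and finite values.
    """

    positions: np.ndarray
    frame_rate: float = 100.0
    label: str | None = None
    sample_id: str = ""
    skeleton: SkeletonDef = field(default_factory=default_skeleton)
    synthetic: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError(
                f"positions must have shape (frames, joints, 3), got {self.positions.shape}"
            )
        if self.positions.shape[0] < 2:
            raise ValueError(f"a motion needs at least 2 frames, got {self.positions.shape[0]}")
        if self.positions.shape[1] != self.skeleton.J:
            raise ValueError(
                f"positions has {self.positions.shape[1]} joints but the skeleton "
                f"defines {self.skeleton.J}"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")
        if self.label is not None and self.label not in _VALID_LABELS:
            raise ValueError(
                f"unknown label {self.label!r}; valid labels: {sorted(_VALID_LABELS)}"
            )

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def with_positions(self, positions: np.ndarray, **kwargs) -> "MotionSample":
        return replace(self, positions=positions, **kwargs)


class ManifestEntry(NamedTuple):
    sample_id: str
    path: str
    label: str


def _motion_columns(skeleton: SkeletonDef) -> list[str]:
    cols = []
    for name in skeleton.joint_names:
        cols.extend([f"{name}_x", f"{name}_y", f"{name}_z"])
    return cols


def write_motion_csv(sample: MotionSample, path: str | Path) -> Path:
    """Write a motion sample; lossless for finite doubles (%.17g)."""
    path = Path(path)
    cols = _motion_columns(sample.skeleton)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", *cols])
        for t in range(sample.n_frames):
            row = [str(t)] + [format(v, ".17g") for v in sample.positions[t].ravel()]
            writer.writerow(row)
    return path


def read_motion_csv(
    path: str | Path,
    skeleton: SkeletonDef | None = None,
    frame_rate: float = 100.0,
    label: str | None = None,
    sample_id: str | None = None,
) -> MotionSample:
    """Read a motion CSV; tolerant of column order, strict about schema."""
    path = Path(path)
    skeleton = skeleton or default_skeleton()
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MotionParseError(f"{path}: cannot parse CSV: {exc}") from exc
    if "frame" not in df.columns:
        raise MotionParseError(f"{path}: missing required column 'frame'")
    missing = [c for c in _motion_columns(skeleton) if c not in df.columns]
    if missing:
        raise MotionParseError(
            f"{path}: missing joint columns: {', '.join(missing[:6])}"
            + ("..." if len(missing) > 6 else "")
        )
    if df["frame"].duplicated().any():
        dup = int(df["frame"][df["frame"].duplicated()].iloc[0])
        raise MotionParseError(f"{path}: duplicate frame index {dup}")
    df = df.sort_values("frame").reset_index(drop=True)
    cols = _motion_columns(skeleton)
    block = df[cols]
    bad = block.map(lambda v: not isinstance(v, (int, float, np.integer, np.floating)))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise MotionParseError(
            f"{path}: non-numeric cell at row {int(df['frame'].iloc[r])}, column {cols[c]!r}"
        )
    values = block.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise MotionParseError(
            f"{path}: non-finite value at row {int(df['frame'].iloc[r])}, column {cols[c]!r}"
        )
    positions = values.reshape(len(df), skeleton.J, 3)
    return MotionSample(
        positions=positions,
        frame_rate=frame_rate,
        label=label,
        sample_id=sample_id if sample_id is not None else path.stem,
        skeleton=skeleton,
    )


def write_manifest(entries: list[ManifestEntry] | list[tuple], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "path", "label"])
        for entry in entries:
            writer.writerow(list(entry))
    return path


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read a dataset manifest, enforcing the canonical label vocabulary."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    expected = ["sample_id", "path", "label"]
    if list(df.columns) != expected and not set(expected).issubset(df.columns):
        raise MotionParseError(
            f"{path}: manifest header must contain {expected}, got {list(df.columns)}"
        )
    entries = []
    for _, row in df.iterrows():
        label = row["label"]
        if label not in _VALID_LABELS:
            raise MotionParseError(
                f"{path}: unknown label {label!r} for sample {row['sample_id']!r}; "
                f"valid labels: {sorted(_VALID_LABELS)}"
            )
        entries.append(ManifestEntry(row["sample_id"], row["path"], label))
    return entries


def load_dataset(
    manifest_path: str | Path,
    skeleton: SkeletonDef | None = None,
    frame_rate: float = 100.0,
) -> list[MotionSample]:
    """Read every motion listed in a manifest (paths relative to the manifest)."""
    manifest_path = Path(manifest_path)
    samples = []
    for entry in read_manifest(manifest_path):
        motion_path = Path(entry.path)
        if not motion_path.is_absolute():
            motion_path = manifest_path.parent / motion_path
        samples.append(
            read_motion_csv(
                motion_path,
                skeleton=skeleton,
                frame_rate=frame_rate,
                label=entry.label if entry.label != UNLABELLED else None,
                sample_id=entry.sample_id,
            )
        )
    return samples


def read_trc(
    path: str | Path,
    skeleton: SkeletonDef | None = None,
    marker_map: dict[str, str] | None = None,
    label: str | None = None,
) -> MotionSample:
    """Best-effort TRC (Track Row Column) mocap reader.

    Markers are matched to skeleton joints by name (case-insensitive), or via
    ``marker_map`` (marker name -> joint name). The header-declared unit is
    honored: millimeters are divided by 1000.
    """
    path = Path(path)
    skeleton = skeleton or default_skeleton()
    lines = path.read_text(encoding="utf-8").splitlines()
    if len(lines) < 6:
        raise MotionParseError(f"{path}: too short to be a TRC file")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    meta = dict(zip(header_keys, header_vals))
    units = meta.get("Units", "m").strip().lower()
    scale = 1.0 if units == "m" else (0.001 if units == "mm" else None)
    if scale is None:
        raise MotionParseError(f"{path}: unsupported TRC unit {units!r}")
    frame_rate = float(meta.get("DataRate", 100.0))
    marker_row = lines[3].split("\t")
    # row 3: Frame#, Time, then marker names each followed by two blanks
    markers = [m.strip() for m in marker_row[2:] if m.strip()]
    marker_map = {k.lower(): v for k, v in (marker_map or {}).items()}
    joint_for_marker: dict[str, int] = {}
    lowered = {n.lower(): i for i, n in enumerate(skeleton.joint_names)}
    for m in markers:
        target = marker_map.get(m.lower(), m.lower())
        if target in lowered:
            joint_for_marker[m] = lowered[target]
    missing = [n for i, n in enumerate(skeleton.joint_names) if i not in joint_for_marker.values()]
    if missing:
        raise MotionParseError(
            f"{path}: no marker found for joints: {', '.join(missing)}"
        )
    rows = []
    for line in lines[5:]:
        if not line.strip():
            continue
        rows.append(line.split("\t"))
    n_frames = len(rows)
    positions = np.full((n_frames, skeleton.J, 3), np.nan)
    for t, row in enumerate(rows):
        data = row[2:]
        for k, m in enumerate(markers):
            if m not in joint_for_marker:
                continue
            j = joint_for_marker[m]
            try:
                xyz = [float(data[3 * k + a]) for a in range(3)]
            except (ValueError, IndexError) as exc:
                raise MotionParseError(
                    f"{path}: bad coordinate for marker {m!r} at data row {t}"
                ) from exc
            positions[t, j] = xyz
    positions *= scale
    return MotionSample(
        positions=positions,
        frame_rate=frame_rate,
        label=label,
        sample_id=path.stem,
        skeleton=skeleton,
    )
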