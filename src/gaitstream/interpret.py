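"""Attention-based importance of joints and joint pairs.

A sigmoid-bounded gate over the spatial columns of each stream's input is
trained jointly with the network; its weights are read out as importance
scores. Pair importances are aggregated onto joints (each pair contributes
to both of its endpoints) for reporting and visualization.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from gaitstream.features import pair_order
from gaitstream.model import FusionNet
from gaitstream.skeleton import SkeletonDef, default_skeleton, rest_pose


@dataclass
class AttentionReport:
    """Per-joint and per-pair importance weights, all non-negative.

    ``aggregated_joint_interaction[j]`` is the sum of ``pair_importance``
    over every pair containing joint j (as either endpoint).
    """

    joint_importance: np.ndarray        # (J,)
    pair_importance: np.ndarray         # (D,)
    aggregated_joint_interaction: np.ndarray  # (J,)
    pair_order: tuple[tuple[int, int], ...]
    fold_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if np.any(self.joint_importance < 0) or np.any(self.pair_importance < 0):
            raise ValueError("importance weights must be non-negative")


def attach_attention(model: FusionNet) -> FusionNet:
    """Return an attention-augmented copy of a model.

    Gates are inserted over the spatial axis of each stream input; all other
    weights are copied, so a gate fixed at 1 recovers the original model.
    """
    if model.config.attention:
        return model
    gated = FusionNet(replace(model.config, attention=True), seed=model.seed)
    for (src, _), (dst, _) in zip(model.core_parameters(), gated.core_parameters()):
        dst[...] = src
    return gated


def aggregate_pairs(
    pair_importance: np.ndarray, order: tuple[tuple[int, int], ...], n_joints: int
) -> np.ndarray:
    """Sum pair weights onto each joint they touch."""
    agg = np.zeros(n_joints)
    for weight, (i, j) in zip(pair_importance, order):
        agg[i] += weight
        agg[j] += weight
    return agg


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < 1e-12:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def extract_importance(
    models: list[FusionNet], rescale: bool = True
) -> AttentionReport:
    """Mean gate weights across trained folds, min-max rescaled per stream."""
    if not models:
        raise ValueError("no trained fold models supplied")
    for m in models:
        if m.gate_jp is None or m.gate_rjdp is None:
            raise ValueError("models must be attention-augmented (see attach_attention)")
    joint = np.mean([m.gate_jp.weights() for m in models], axis=0)
    pair = np.mean([m.gate_rjdp.weights() for m in models], axis=0)
    if rescale:
        joint = _minmax(joint)
        pair = _minmax(pair)
    J = models[0].config.n_joints
    order = pair_order(J)
    return AttentionReport(
        joint_importance=joint,
        pair_importance=pair,
        aggregated_joint_interaction=aggregate_pairs(pair, order, J),
        pair_order=order,
        fold_ids=tuple(range(len(models))),
    )


def export_importance(
    report: AttentionReport,
    out_dir: str | Path,
    skeleton: SkeletonDef | None = None,
) -> dict[str, Path]:
    """Write joint/pair importance CSVs and a skeleton figure.

    The figure shows the skeleton in the frontal plane with marker size
    proportional to joint importance and marker color encoding the
    aggregated pair interaction.
    """
    skeleton = skeleton or default_skeleton()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    joints_csv = out_dir / "joint_importance.csv"
    with open(joints_csv, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["joint", "importance", "aggregated_interaction"])
        for j, name in enumerate(skeleton.joint_names):
            writer.writerow([
                name,
                format(report.joint_importance[j], ".10g"),
                format(report.aggregated_joint_interaction[j], ".10g"),
            ])

    pairs_csv = out_dir / "pair_importance.csv"
    with open(pairs_csv, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["joint_i", "joint_j", "importance"])
        for weight, (i, j) in zip(report.pair_importance, report.pair_order):
            writer.writerow([
                skeleton.joint_names[i],
                skeleton.joint_names[j],
                format(weight, ".10g"),
            ])

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pose = rest_pose(skeleton)
    fig, ax = plt.subplots(figsize=(5, 7))
    for j, p in enumerate(skeleton.parent_index):
        if p >= 0:
            ax.plot(
                [pose[j, 2], pose[p, 2]], [pose[j, 1], pose[p, 1]],
                color="0.7", lw=1, zorder=1,
            )
    sizes = 40 + 360 * report.joint_importance
    sc = ax.scatter(
        pose[:, 2], pose[:, 1],
        s=sizes,
        c=report.aggregated_joint_interaction,
        cmap="summer_r",
        edgecolors="black",
        zorder=2,
    )
    fig.colorbar(sc, ax=ax, label="aggregated pair interaction")
    ax.set_xlabel("lateral (m)")
    ax.set_ylabel("height (m)")
    ax.set_title("Joint importance (size) and interaction (color)")
    ax.set_aspect("equal")
    ax.invert_xaxis()  # subject faces the viewer: left side on the right
    fig_path = out_dir / "importance.png"
    fig.savefig(fig_path, dpi=150, bbox_inches="tight")
    plt.close(fig)

    return {"joints": joints_csv, "pairs": pairs_csv, "figure": fig_path}
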