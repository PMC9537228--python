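"""The two convolutional streams, mid-layer fusion head, and ablation variants.

Stream 1 convolves the joint-position tensor ``S`` (T, J, 3) with a 3x1
kernel, stride 1; stream 2 convolves the displacement tensor ``S'``
(T, J*(J-1), 3) with a 3x(J-1) kernel and spatial stride J-1, so each filter
placement covers exactly one joint's correlation block and both streams emit
feature maps of identical spatial size (T-2, J). The maps are concatenated
along the channel axis and classified by a small convolutional head.

Ablation variants of the post-fusion head:

* ``full``    — two convs, adaptive max pool, fully connected layer;
* ``sin_cnn`` — one conv, pool, fully connected;
* ``no_cnn``  — pool, fully connected;
* ``no_maxp`` — two convs, flatten, fully connected.

``streams`` selects which stream(s) feed the head, giving the two
single-stream baselines alongside the fused network.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from gaitstream import nn
from gaitstream.features import JointPositionTensor, RelativeDisplacementTensor

VARIANTS = ("full", "no_cnn", "sin_cnn", "no_maxp")
STREAM_CHOICES = ("both", "jp", "rjdp")


@dataclass(frozen=True)
class StreamConfig:
    """Kernel geometry of one input stream."""

    f_t: int = 3
    f_spatial: int = 1
    stride_t: int = 1
    stride_spatial: int = 1
    out_channels: int = 3

    @staticmethod
    def jp(out_channels: int = 3) -> "StreamConfig":
        return StreamConfig(f_t=3, f_spatial=1, stride_t=1, stride_spatial=1,
                            out_channels=out_channels)

    @staticmethod
    def rjdp(n_joints: int, out_channels: int = 3) -> "StreamConfig":
        return StreamConfig(f_t=3, f_spatial=n_joints - 1, stride_t=1,
                            stride_spatial=n_joints - 1, out_channels=out_channels)


@dataclass(frozen=True)
class FusionNetConfig:
    """Architecture settings of the fusion network and its variants."""

    variant: str = "full"
    streams: str = "both"
    n_joints: int = 20
    t_frames: int = 100
    in_channels: int = 3
    stream_out_channels: int = 3
    post_fusion_channels: tuple[int, int] = (32, 64)
    pool_output: tuple[int, int] = (1, 1)
    n_classes: int = 4
    attention: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; valid variants: {', '.join(VARIANTS)}"
            )
        if self.streams not in STREAM_CHOICES:
            raise ValueError(
                f"unknown streams {self.streams!r}; valid choices: {', '.join(STREAM_CHOICES)}"
            )
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.t_frames < 3:
            raise ValueError("t_frames must be >= 3 for the temporal kernel to fit")

    @property
    def n_pairs(self) -> int:
        return self.n_joints * (self.n_joints - 1)

    @property
    def t2(self) -> int:
        # no temporal padding in the stream convolutions
        return self.t_frames - self.f_t + 1

    @property
    def f_t(self) -> int:
        return 3

    @property
    def fused_channels(self) -> int:
        if self.streams == "both":
            return 2 * self.stream_out_channels
        return self.stream_out_channels


class FusionNet:
    """Two-stream convolutional classifier with mid-layer channel fusion."""

    def __init__(self, config: FusionNetConfig, seed: int = 0) -> None:
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        J = config.n_joints
        oc = config.stream_out_channels

        self.gate_jp = nn.ColumnGate(J) if config.attention else None
        self.gate_rjdp = nn.ColumnGate(config.n_pairs) if config.attention else None

        self.conv_jp = nn.Conv2d(config.in_channels, oc, kernel=(3, 1), rng=rng)
        self.conv_rjdp = nn.Conv2d(
            config.in_channels, oc, kernel=(3, J - 1), stride=(1, J - 1), rng=rng
        )
        self.head = self._build_head(rng)

    def _build_head(self, rng: np.random.Generator) -> nn.Sequential:
        cfg = self.config
        c1, c2 = cfg.post_fusion_channels
        fc = cfg.fused_channels
        ph, pw = cfg.pool_output
        layers: list[nn.Layer] = []
        if cfg.variant in ("full", "no_maxp"):
            layers += [
                nn.Conv2d(fc, c1, kernel=(3, 1), padding=(1, 0), rng=rng),
                nn.ReLU(),
                nn.Conv2d(c1, c2, kernel=(3, 1), padding=(1, 0), rng=rng),
                nn.ReLU(),
            ]
            last = c2
        elif cfg.variant == "sin_cnn":
            layers += [
                nn.Conv2d(fc, c1, kernel=(3, 1), padding=(1, 0), rng=rng),
                nn.ReLU(),
            ]
            last = c1
        else:  # no_cnn
            last = fc
        if cfg.variant == "no_maxp":
            layers += [nn.Flatten()]
            in_features = last * cfg.t2 * cfg.n_joints
        else:
            layers += [nn.AdaptiveMaxPool2d((ph, pw)), nn.Flatten()]
            in_features = last * ph * pw
        layers += [nn.Linear(in_features, cfg.n_classes, rng=rng)]
        return nn.Sequential(*layers)

    # ------------------------------------------------------------------ params

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        params: list[tuple[np.ndarray, np.ndarray]] = []
        if self.gate_jp is not None and self.config.streams in ("both", "jp"):
            params += self.gate_jp.parameters()
        if self.gate_rjdp is not None and self.config.streams in ("both", "rjdp"):
            params += self.gate_rjdp.parameters()
        if self.config.streams in ("both", "jp"):
            params += self.conv_jp.parameters()
        if self.config.streams in ("both", "rjdp"):
            params += self.conv_rjdp.parameters()
        params += self.head.parameters()
        return params

    def core_parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Parameters excluding attention gates (for weight transfer)."""
        params: list[tuple[np.ndarray, np.ndarray]] = []
        if self.config.streams in ("both", "jp"):
            params += self.conv_jp.parameters()
        if self.config.streams in ("both", "rjdp"):
            params += self.conv_rjdp.parameters()
        params += self.head.parameters()
        return params

    @property
    def n_params(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def zero_grad(self) -> None:
        for _, g in self.parameters():
            g[...] = 0.0

    # ----------------------------------------------------------------- streams

    @staticmethod
    def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
        """Feature tensors (T, W, 3) are already NHWC; just add the batch axis."""
        x = np.asarray(x, dtype=nn.DTYPE)
        single = x.ndim == 3
        return (x[None] if single else x), single

    def stream_jp(self, S: np.ndarray | JointPositionTensor) -> np.ndarray:
        """Position-stream convolution: (T, J, 3) -> (T-2, J, out_channels)."""
        if isinstance(S, JointPositionTensor):
            S = S.S
        x, single = self._as_batch(S)
        if x.shape[2] != self.config.n_joints:
            raise ValueError(
                f"expected {self.config.n_joints} joints, got {x.shape[2]}"
            )
        if self.gate_jp is not None:
            x = self.gate_jp.forward(x)
        out = self.conv_jp.forward(x)
        return out[0] if single else out

    def stream_rjdp(self, S_prime: np.ndarray | RelativeDisplacementTensor) -> np.ndarray:
        """Displacement-stream convolution: (T, J(J-1), 3) -> (T-2, J, out_channels)."""
        if isinstance(S_prime, RelativeDisplacementTensor):
            S_prime = S_prime.S_prime
        x, single = self._as_batch(S_prime)
        J = self.config.n_joints
        if x.shape[2] != J * (J - 1):
            raise ValueError(
                f"expected spatial width J(J-1) = {J * (J - 1)}, got {x.shape[2]} "
                "(pair columns must be grouped by first joint)"
            )
        if self.gate_rjdp is not None:
            x = self.gate_rjdp.forward(x)
        out = self.conv_rjdp.forward(x)
        return out[0] if single else out

    # ----------------------------------------------------------------- forward

    def forward_logits(self, S: np.ndarray | None, S_prime: np.ndarray | None) -> np.ndarray:
        """Batch forward pass; inputs shaped (N, T, W, 3). Returns logits (N, E)."""
        streams = self.config.streams
        feats = []
        if streams in ("both", "jp"):
            if S is None:
                raise ValueError("position stream requires S")
            x, _ = self._as_batch(S)
            if self.gate_jp is not None:
                x = self.gate_jp.forward(x)
            feats.append(self.conv_jp.forward(x))
        if streams in ("both", "rjdp"):
            if S_prime is None:
                raise ValueError("displacement stream requires S'")
            x, _ = self._as_batch(S_prime)
            if self.gate_rjdp is not None:
                x = self.gate_rjdp.forward(x)
            feats.append(self.conv_rjdp.forward(x))
        if len(feats) == 2 and feats[0].shape[:3] != feats[1].shape[:3]:
            raise ValueError(
                f"stream output shapes disagree: {feats[0].shape} vs {feats[1].shape}"
            )
        self._split = feats[0].shape[-1] if len(feats) == 2 else None
        fused = np.concatenate(feats, axis=-1) if len(feats) == 2 else feats[0]
        logits = self.head.forward(fused)
        if not np.all(np.isfinite(logits)):
            raise FloatingPointError("non-finite activations in the classification head")
        return logits

    def backward(self, grad_logits: np.ndarray) -> None:
        grad_fused = self.head.backward(grad_logits)
        streams = self.config.streams
        if streams == "both":
            g_jp, g_rjdp = np.split(grad_fused, [self._split], axis=-1)
        elif streams == "jp":
            g_jp, g_rjdp = grad_fused, None
        else:
            g_jp, g_rjdp = None, grad_fused
        if g_jp is not None:
            gx = self.conv_jp.backward(g_jp)
            if self.gate_jp is not None:
                self.gate_jp.backward(gx)
        if g_rjdp is not None:
            gx = self.conv_rjdp.backward(g_rjdp)
            if self.gate_rjdp is not None:
                self.gate_rjdp.backward(gx)

    def predict_proba(self, S: np.ndarray | None, S_prime: np.ndarray | None) -> np.ndarray:
        """Softmax class probabilities, shape (N, E)."""
        return nn.softmax(self.forward_logits(S, S_prime).astype(np.float64))

    # -------------------------------------------------------------- checkpoint

    def state_arrays(self) -> list[np.ndarray]:
        return [p for p, _ in self.parameters()]

    def save(self, path: str | Path) -> Path:
        """Serialize weights (npz) with a JSON sidecar recording the config."""
        path = Path(path)
        arrays = {f"param_{i}": p for i, p in enumerate(self.state_arrays())}
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {"config": asdict(self.config), "seed": self.seed,
                   "n_arrays": len(arrays)}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path: str | Path) -> "FusionNet":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg_dict = sidecar["config"]
        cfg_dict["post_fusion_channels"] = tuple(cfg_dict["post_fusion_channels"])
        cfg_dict["pool_output"] = tuple(cfg_dict["pool_output"])
        model = cls(FusionNetConfig(**cfg_dict), seed=sidecar["seed"])
        data = np.load(path.with_suffix(".npz"))
        arrays = model.state_arrays()
        if len(arrays) != sidecar["n_arrays"]:
            raise ValueError("checkpoint/config mismatch: wrong parameter count")
        for i, p in enumerate(arrays):
            stored = data[f"param_{i}"]
            if stored.shape != p.shape:
                raise ValueError(
                    f"checkpoint/config mismatch: parameter {i} has shape "
                    f"{stored.shape}, expected {p.shape}"
                )
            p[...] = stored
        return model


# ------------------------------------------------------------------ functional


def fuse(f_jp: np.ndarray, f_rjdp: np.ndarray) -> np.ndarray:
    """Channel concatenation of the two stream outputs, position stream first."""
    f_jp = np.asarray(f_jp)
    f_rjdp = np.asarray(f_rjdp)
    if f_jp.shape[:-1] != f_rjdp.shape[:-1]:
        raise ValueError(
            f"stream outputs disagree on (T2, J): {f_jp.shape} vs {f_rjdp.shape}"
        )
    return np.concatenate([f_jp, f_rjdp], axis=-1)


def classify(f: np.ndarray, model: FusionNet) -> np.ndarray:
    """Apply the post-fusion head to a fused feature map (T2, J, 2C)."""
    x = np.asarray(f, dtype=nn.DTYPE)
    single = x.ndim == 3
    if single:
        x = x[None]
    logits = model.head.forward(x)
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite activations in the classification head")
    p = nn.softmax(logits.astype(np.float64))
    return p[0] if single else p


def cross_entropy(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    """Cross-entropy in nats: ``-sum_i y_i log p_i`` with p clamped at eps."""
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    return float(-np.sum(y * np.log(np.clip(p, eps, None))))


def build_variant(name: str, config: FusionNetConfig | None = None, seed: int = 0) -> FusionNet:
    """Build one of the ablation variants: full, no_cnn, sin_cnn, no_maxp."""
    if name not in VARIANTS:
        raise ValueError(
            f"unknown variant {name!r}; valid variants: {', '.join(VARIANTS)}"
        )
    config = config or FusionNetConfig()
    return FusionNet(replace(config, variant=name), seed=seed)
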