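"""The attention-augmented multi-branch 1D convolutional classifier.

Each modality (gene expression, domain embedding, subcellular localization,
orthology expansion) is read by its own small 1D convolutional branch; the
branch outputs are concatenated channel-wise into one multi-channel map of a
common length, batch-normalized, convolved once more, refined by a
channel-then-spatial attention block (CBAM), max-pooled, flattened, joined
with the per-protein modality-availability flags (and optional topology
descriptors), and classified by three fully connected layers into a
2-vector of class scores.

Default architecture (lengths for the default feature widths):

* expression branch: 36 -> conv(6,k5,s1) -> conv(10,k4,s2) -> maxpool(k4,s1) -> 10 x 12
* domain branch:     36 -> same stack -> 10 x 12
* subcellular branch: 11 zero-padded to 12 -> conv(20,k1,s1) -> 20 x 12
* orthology branch:  12 -> conv(20,k1,s1) -> 20 x 12
* head: 60 x 12 -> batchnorm -> conv(30,k2,s2) -> CBAM -> maxpool(k2,s2)
  -> flatten (90) [+ flags] -> FC 75 (dropout 0.3) -> FC 35 -> 2
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor, concat
from ._nn import BatchNorm1d, Conv1d, Dropout, Linear, Module
from .data_io import MODALITIES

__all__ = [
    "BranchConfig",
    "ModelConfig",
    "Branch",
    "Cbam",
    "DlamModel",
    "fuse_maps",
    "softmax",
    "softmax_cross_entropy",
    "default_branch_configs",
]

LEAKY_SLOPE = 0.01


@dataclass
class BranchConfig:
    """One modality branch: conv stack, optional max pool, input padding."""

    name: str
    in_length: int
    convs: list[tuple[int, int, int]]  # (out_channels, kernel, stride)
    pool: tuple[int, int] | None = None  # (kernel, stride)
    pad_to: int | None = None  # zero-pad input on the right to this length

    def out_length(self) -> int:
        L = self.pad_to if self.pad_to else self.in_length
        for _, k, s in self.convs:
            L = (L - k) // s + 1
        if self.pool:
            k, s = self.pool
            L = (L - k) // s + 1
        return L

    def out_channels(self) -> int:
        return self.convs[-1][0]


def default_branch_configs(
    expression_len: int = 36,
    domain_len: int = 36,
    subcellular_len: int = 11,
    orthology_len: int = 12,
) -> dict[str, BranchConfig]:
    two_conv = [(6, 5, 1), (10, 4, 2)]
    one_conv = [(20, 1, 1)]
    return {
        "expression": BranchConfig("expression", expression_len, list(two_conv), pool=(4, 1)),
        "domain": BranchConfig("domain", domain_len, list(two_conv), pool=(4, 1)),
        "subcellular": BranchConfig(
            "subcellular", subcellular_len, list(one_conv), pad_to=subcellular_len + 1
        ),
        "orthology": BranchConfig("orthology", orthology_len, list(one_conv)),
    }


@dataclass
class ModelConfig:
    """Hyperparameters of the full network."""

    modalities: tuple[str, ...] = MODALITIES
    branch_configs: dict[str, BranchConfig] = field(default_factory=default_branch_configs)
    attention: bool = True
    cnnam_channels: int = 30
    cnnam_kernel: int = 2
    cnnam_stride: int = 2
    pool_kernel: int = 2
    pool_stride: int = 2
    cbam_reduction: int = 2
    cbam_spatial_kernel: int = 3
    fc1: int = 75
    fc2: int = 35
    n_classes: int = 2
    dropout: float = 0.3
    n_extra: int = 0  # topology descriptors appended with the flags
    leaky_slope: float = LEAKY_SLOPE


class Branch(Module):
    def __init__(self, cfg: BranchConfig, *, rng: np.random.Generator,
                 slope: float = LEAKY_SLOPE):
        self.cfg = cfg
        self.slope = slope
        self.convs = []
        in_ch = 1
        for out_ch, k, s in cfg.convs:
            self.convs.append(Conv1d(in_ch, out_ch, k, stride=s, rng=rng))
            in_ch = out_ch

    def __call__(self, x: Tensor) -> Tensor:
        expected = self.cfg.in_length
        if x.shape[2] != expected:
            raise ValueError(
                f"branch {self.cfg.name!r} expects input length {expected}, got {x.shape[2]}"
            )
        if self.cfg.pad_to and self.cfg.pad_to > expected:
            pad = np.zeros((x.shape[0], x.shape[1], self.cfg.pad_to - expected))
            x = concat([x, Tensor(pad)], axis=2)
        for conv in self.convs:
            x = conv(x).leaky_relu(self.slope)
        if self.cfg.pool:
            k, s = self.cfg.pool
            x = x.maxpool1d(k, s)
        return x


def fuse_maps(maps: dict[str, Tensor], order: tuple[str, ...]) -> Tensor:
    """Channel-axis concatenation of branch maps in the fixed modality order."""
    ms = [maps[name] for name in order]
    lengths = {m.shape[2] for m in ms}
    if len(lengths) != 1:
        raise ValueError(f"branch map lengths differ: { {n: maps[n].shape[2] for n in order} }")
    return concat(ms, axis=1)


class Cbam(Module):
    """Channel-then-spatial attention on (B, C, L) maps.

    Channel attention squeezes the length axis by average and max pooling,
    passes both C-vectors through a shared two-layer 1x1-conv bottleneck
    (reduction ratio r, ReLU between), sums, and squashes with a sigmoid.
    Spatial attention pools the channel axis of the refined map by mean and
    max, stacks the two length-profiles, and convolves them to a single
    sigmoid-gated profile. Both gates are strictly inside (0, 1).
    """

    def __init__(self, channels: int, reduction: int = 2, spatial_kernel: int = 3,
                 *, rng: np.random.Generator):
        hidden = max(channels // reduction, 1)
        self.fc1 = Conv1d(channels, hidden, 1, rng=rng)
        self.fc2 = Conv1d(hidden, channels, 1, rng=rng)
        if spatial_kernel % 2 != 1:
            raise ValueError("spatial kernel must be odd for symmetric padding")
        self.spatial = Conv1d(2, 1, spatial_kernel, padding=spatial_kernel // 2, rng=rng)

    def _shared(self, pooled: Tensor) -> Tensor:
        return self.fc2(self.fc1(pooled).relu())

    def channel_attention(self, x: Tensor) -> Tensor:
        """Per-channel gate (B, C, 1)."""
        avg = x.mean(axis=2, keepdims=True)
        mx = x.max_reduce(axis=2, keepdims=True)
        return (self._shared(avg) + self._shared(mx)).sigmoid()

    def spatial_attention(self, refined: Tensor) -> Tensor:
        """Per-position gate (B, 1, L) from the channel-refined map."""
        avg = refined.mean(axis=1, keepdims=True)
        mx = refined.max_reduce(axis=1, keepdims=True)
        return self.spatial(concat([avg, mx], axis=1)).sigmoid()

    def __call__(self, x: Tensor) -> Tensor:
        refined = self.channel_attention(x) * x
        return refined * self.spatial_attention(refined)


class DlamModel(Module):
    """Full network; ``forward`` maps feature blocks to 2-class logits."""

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0):
        self.cfg = cfg or ModelConfig()
        cfg = self.cfg
        rng = np.random.default_rng(seed)
        self.branches = {
            name: Branch(cfg.branch_configs[name], rng=rng, slope=cfg.leaky_slope)
            for name in cfg.modalities
        }
        lengths = {cfg.branch_configs[n].out_length() for n in cfg.modalities}
        if len(lengths) != 1:
            raise ValueError(f"branch output lengths must agree, got {lengths}")
        self.map_length = lengths.pop()
        self.fused_channels = sum(cfg.branch_configs[n].out_channels() for n in cfg.modalities)
        self.bn = BatchNorm1d(self.fused_channels)
        self.cnnam_conv = Conv1d(
            self.fused_channels, cfg.cnnam_channels, cfg.cnnam_kernel,
            stride=cfg.cnnam_stride, rng=rng,
        )
        L1 = (self.map_length - cfg.cnnam_kernel) // cfg.cnnam_stride + 1
        self.attn_length = L1
        self.cbam = (
            Cbam(cfg.cnnam_channels, cfg.cbam_reduction, cfg.cbam_spatial_kernel, rng=rng)
            if cfg.attention
            else None
        )
        L2 = (L1 - cfg.pool_kernel) // cfg.pool_stride + 1
        self.flat_width = cfg.cnnam_channels * L2
        self.n_flags = len(cfg.modalities)
        fc_in = self.flat_width + self.n_flags + cfg.n_extra
        self.fc1 = Linear(fc_in, cfg.fc1, rng=rng)
        self.drop = Dropout(cfg.dropout)
        self.fc2 = Linear(cfg.fc1, cfg.fc2, rng=rng)
        self.out = Linear(cfg.fc2, cfg.n_classes, rng=rng)

    def parameters(self):
        params = []
        for b in self.branches.values():
            params.extend(b.parameters())
        params.extend(self.bn.parameters())
        params.extend(self.cnnam_conv.parameters())
        if self.cbam is not None:
            params.extend(self.cbam.parameters())
        params.extend(self.fc1.parameters())
        params.extend(self.fc2.parameters())
        params.extend(self.out.parameters())
        return params

    def forward(
        self,
        blocks: dict[str, np.ndarray],
        flags: np.ndarray,
        extra: np.ndarray | None = None,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Class logits (B, 2) for a batch of per-protein feature blocks.

        ``blocks[name]`` is (B, width) for each configured modality; missing
        modalities must already be zero-filled. ``flags`` is (B, n_modalities)
        in the configured modality order.
        """
        slope = self.cfg.leaky_slope
        maps = {}
        for name in self.cfg.modalities:
            x = np.asarray(blocks[name], dtype=float)
            maps[name] = self.branches[name](Tensor(x[:, None, :]))
        fused = fuse_maps(maps, self.cfg.modalities)
        h = self.bn(fused, training=training)
        h = self.cnnam_conv(h).leaky_relu(slope)
        if self.cbam is not None:
            h = self.cbam(h)
        h = h.maxpool1d(self.cfg.pool_kernel, self.cfg.pool_stride)
        h = h.reshape(h.shape[0], -1)
        side = [np.asarray(flags, dtype=float)]
        if extra is not None:
            side.append(np.asarray(extra, dtype=float))
        h = concat([h, Tensor(np.column_stack(side))], axis=1)
        h = self.drop(self.fc1(h).leaky_relu(slope), training=training, rng=rng)
        h = self.fc2(h).leaky_relu(slope)
        logits = self.out(h)
        if not np.all(np.isfinite(logits.data)):
            raise FloatingPointError("non-finite activations at output layer")
        return logits

    def predict_proba(
        self,
        blocks: dict[str, np.ndarray],
        flags: np.ndarray,
        extra: np.ndarray | None = None,
    ) -> np.ndarray:
        """Eval-mode class probabilities (B, 2)."""
        logits = self.forward(blocks, flags, extra=extra, training=False)
        return softmax(logits.data)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under softmax of the logits."""
    labels = np.asarray(labels, dtype=int)
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    z = logits - shift
    log_probs = z - z.exp().sum(axis=1, keepdims=True).log()
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    return -(log_probs * Tensor(onehot)).sum() * (1.0 / len(labels))
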