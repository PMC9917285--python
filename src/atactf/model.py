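"""The dilated convolutional TFBS model and its analytic companions.

The network maps a (1,024 bp x 5 channel) input — 4 one-hot DNA channels
plus 1 normalized ATAC-seq signal channel — to 32 sigmoid scores, one per
32 bp bin of the input window. It stacks 5 convolutional blocks, each of
two ReLU-activated same-padded convolutions (kernel width 7) followed by
batch normalization and width-2 max pooling; filter counts grow by a factor
of 1.5 per block from 15 to 75 (truncated to integer). The dilation rate
schedule is 1, 1, 2, 4, 8 across the blocks with a final dilation-16
two-layer stage before the sigmoid-activated output convolution, so the
receptive field of the ultimate hidden layer spans +/-512 bp — the whole
input — while the prediction resolution stays at 32 bp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import nn


@dataclass
class ArchitectureSpec:
    """Every architectural hyperparameter of the model."""

    input_length: int = 1024
    input_channels: int = 5  # 4 one-hot DNA + 1 accessibility signal
    n_blocks: int = 5
    layers_per_block: int = 2
    kernel_width: int = 7
    base_filters: int = 15
    filter_growth: float = 1.5
    dilation_schedule: Sequence[int] = field(default_factory=lambda: [1, 1, 2, 4, 8, 16])
    pool_width: int = 2
    output_bins: int = 32
    output_activation: str = "sigmoid"

    def __post_init__(self):
        self.dilation_schedule = list(self.dilation_schedule)
        if self.input_length % self.output_bins:
            raise ValueError("input_length must be a multiple of output_bins")
        if len(self.dilation_schedule) < self.n_blocks:
            raise ValueError("dilation_schedule shorter than n_blocks")
        for v in (self.n_blocks, self.layers_per_block, self.kernel_width,
                  self.base_filters, self.pool_width, self.output_bins):
            if v < 1:
                raise ValueError("all architecture counts must be >= 1")

    @property
    def n_extra_stages(self) -> int:
        """Dilation entries beyond the blocks form extra two-layer stages
        at the deepest spatial resolution (before the output layer)."""
        return len(self.dilation_schedule) - self.n_blocks

    @property
    def n_pools(self) -> int:
        """Pooling stages required so output length equals output_bins."""
        ratio = self.input_length // self.output_bins
        n = round(np.log(ratio) / np.log(self.pool_width))
        if self.pool_width ** n != ratio:
            raise ValueError(
                f"input_length/output_bins = {ratio} is not a power of "
                f"pool_width {self.pool_width}"
            )
        return n

    def validate_shapes(self) -> None:
        n_stages = self.n_blocks + self.n_extra_stages
        if self.n_pools > n_stages:
            implied = self.input_length // self.pool_width ** n_stages
            raise ValueError(
                f"cannot reach {self.output_bins} output bins with "
                f"{n_stages} stages; implied output length is {implied}"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ArchitectureSpec":
        return cls(**json.loads(s))


def block_filters(spec: ArchitectureSpec, k: int) -> int:
    """Filter count of block k (1-based): truncate(base * growth^(k-1)).

    Defaults give 15, 22, 33, 50, 75 across the five blocks.
    """
    if not 1 <= k <= spec.n_blocks + spec.n_extra_stages:
        raise ValueError(f"block index {k} out of range")
    k_eff = min(k, spec.n_blocks)  # extra stages keep the last block's width
    return int(spec.base_filters * spec.filter_growth ** (k_eff - 1))


def _stage_plan(spec: ArchitectureSpec):
    """Yield (dilation, n_filters, pooled) per convolutional stage."""
    spec.validate_shapes()
    n_stages = spec.n_blocks + spec.n_extra_stages
    for s in range(1, n_stages + 1):
        yield (
            spec.dilation_schedule[s - 1],
            block_filters(spec, s),
            s <= spec.n_pools,
        )


def build_network(spec: ArchitectureSpec, rng: np.random.Generator) -> nn.Sequential:
    layers: List[nn.Layer] = []
    in_ch = spec.input_channels
    for dilation, n_filters, pooled in _stage_plan(spec):
        for _ in range(spec.layers_per_block):
            layers.append(nn.Conv1d(in_ch, n_filters, spec.kernel_width, dilation, rng))
            layers.append(nn.ReLU())
            in_ch = n_filters
        layers.append(nn.BatchNorm1d(in_ch))
        if pooled:
            layers.append(nn.MaxPool1d(spec.pool_width))
    # single sigmoid-activated output convolution (sigmoid applied by the
    # handle so training can use the numerically stable logits form)
    layers.append(nn.Conv1d(in_ch, 1, spec.kernel_width, 1, rng))
    return nn.Sequential(layers)


@dataclass
class ModelHandle:
    """A (possibly trained) network together with its spec and seed."""

    spec: ArchitectureSpec
    net: nn.Sequential
    seed: int

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """(N, channels, input_length) -> (N, output_bins) logits."""
        out = self.net.forward(x.astype(np.float32), training)
        return out[:, 0, :]

    def predict(self, x: np.ndarray) -> np.ndarray:
        """(N, channels, input_length) -> (N, output_bins) scores in [0, 1]."""
        return nn.sigmoid(self.forward_logits(x, training=False))

    def save(self, path) -> None:
        """Single-file checkpoint with the spec embedded (self-describing)."""
        state = self.net.state_arrays()
        np.savez(path, __spec__=np.array(self.spec.to_json()),
                 __seed__=np.array(self.seed), **state)

    @classmethod
    def load(cls, path) -> "ModelHandle":
        data = np.load(path, allow_pickle=False)
        spec = ArchitectureSpec.from_json(str(data["__spec__"]))
        seed = int(data["__seed__"])
        handle = build_model(spec, seed)
        handle.net.load_state({k: data[k] for k in data.files
                               if not k.startswith("__")})
        return handle


def build_model(spec: ArchitectureSpec, seed: int = 0) -> ModelHandle:
    """Build a Glorot-initialized model; deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    return ModelHandle(spec=spec, net=build_network(spec, rng), seed=seed)


# ---------------------------------------------------------------------------
# Analytic companions
# ---------------------------------------------------------------------------

def receptive_field_untruncated(spec: ArchitectureSpec) -> int:
    """One-sided receptive-field extent (input bp) of the ultimate hidden
    layer, not truncated: sum over conv layers of (k-1)/2 * dilation *
    cumulative stride at that layer."""
    extent = 0
    stride = 1
    half = (spec.kernel_width - 1) // 2
    for dilation, _, pooled in _stage_plan(spec):
        extent += spec.layers_per_block * half * dilation * stride
        if pooled:
            stride *= spec.pool_width
    return extent


def receptive_field(spec: ArchitectureSpec) -> int:
    """One-sided receptive-field extent, truncated at the input boundary
    (a unit cannot see beyond the input window)."""
    return min(receptive_field_untruncated(spec), spec.input_length // 2)


def final_stride(spec: ArchitectureSpec) -> int:
    return spec.pool_width ** spec.n_pools


def empirical_receptive_span(spec: ArchitectureSpec) -> int:
    """Measure, by input perturbation on a ones-weight network (batch norm
    omitted so signs propagate), how many input positions influence the
    center unit of the ultimate hidden layer.

    For same-padded stride-1 convolutions over pooling of total stride s the
    span equals 2 * receptive_field_untruncated + s when no boundary
    truncation occurs.
    """
    layers: List[nn.Layer] = []
    rng = np.random.default_rng(0)
    in_ch = spec.input_channels
    for dilation, n_filters, pooled in _stage_plan(spec):
        for _ in range(spec.layers_per_block):
            conv = nn.Conv1d(in_ch, n_filters, spec.kernel_width, dilation, rng)
            conv.params["W"][:] = 0.01
            conv.params["b"][:] = 0.0
            layers.append(conv)
            layers.append(nn.ReLU())
            in_ch = n_filters
        if pooled:
            layers.append(nn.MaxPool1d(spec.pool_width))
    net = nn.Sequential(layers)
    length = spec.input_length
    base = net.forward(np.zeros((1, spec.input_channels, length), dtype=np.float32))
    center = base.shape[2] // 2
    affected = []
    for p in range(length):
        x = np.zeros((1, spec.input_channels, length), dtype=np.float32)
        x[0, 0, p] = 1.0
        out = net.forward(x)
        if abs(out[0, 0, center] - base[0, 0, center]) > 1e-12:
            affected.append(p)
    return len(affected)


def dice_coefficient(pred: np.ndarray, target: np.ndarray, epsilon: float = 1e-7) -> float:
    """Soft dice overlap 2*sum(p*t)/(sum p + sum t), smoothed by epsilon."""
    pred = np.asarray(pred, dtype=np.float64).ravel()
    target = np.asarray(target, dtype=np.float64).ravel()
    if pred.shape != target.shape:
        raise ValueError("pred and target must have the same length")
    num = 2.0 * float(np.sum(pred * target)) + epsilon
    den = float(np.sum(pred) + np.sum(target)) + epsilon
    return num / den


def bce_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean binary cross-entropy on probabilities (clamped at 1e-7)."""
    pred = np.clip(np.asarray(pred, dtype=np.float64).ravel(), 1e-7, 1 - 1e-7)
    target = np.asarray(target, dtype=np.float64).ravel()
    if pred.shape != target.shape:
        raise ValueError("pred and target must have the same length")
    return float(
        -np.mean(target * np.log(pred) + (1 - target) * np.log(1 - pred))
    )
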