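"""The siamese quality-pairing network and its contrastive loss.

Architecture (a SimSiam-style siamese net adapted to 1-D signals):

* **encoder E** — a 1-D residual convolutional network (ResNet translated
  to time series: length-7 stem convolution with stride 2, max pooling,
  residual blocks, global average pooling) mapping a normalized segment
  ``x`` to a representation ``h = E(x)``;
* **projector P** — three fully-connected layers mapping ``h`` to the
  contrastive space, ``z = P(h)``;
* **predictor D** — three fully-connected layers with equal input and
  output dimension, ``p = D(z)``.

Both members of a quality pair pass through the *same* weights.  The
loss is the symmetric negative cosine similarity between each branch's
prediction and the *other* branch's projection, with a stop-gradient on
the projection argument (the SimSiam collapse-avoidance contract, exposed
as a config flag):

    L = scale * [ -cos(p_good, sg(z_bad)) - cos(p_bad, sg(z_good)) ]

``scale`` defaults to 1; ``scale=0.5`` gives the averaged two-term form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "ModelConfig",
    "SiamOutputs",
    "SiamQualityNet",
    "negative_cosine",
    "pair_loss",
    "save_checkpoint",
    "load_checkpoint",
]

# (block type, stem channels, per-stage (channels, blocks, stride))
_VARIANTS = {
    "tiny_1d": ("basic", 16, [(16, 1, 1), (32, 1, 2), (64, 2, 2)]),
    "resnet50_1d": ("bottleneck", 64,
                    [(64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)]),
    "resnet101_1d": ("bottleneck", 64,
                     [(64, 3, 1), (128, 4, 2), (256, 23, 2), (512, 3, 2)]),
    "resnet152_1d": ("bottleneck", 64,
                     [(64, 3, 1), (128, 8, 2), (256, 36, 2), (512, 3, 2)]),
}
_EXPANSION = {"basic": 1, "bottleneck": 4}


@dataclass(frozen=True)
class ModelConfig:
    """Dimensions and switches of the siamese network.

    ``feature_dim`` is fixed by the encoder variant (last stage channels x
    block expansion) and filled in automatically when left at 0.  The
    predictor's input and output dimensions both equal
    ``projection_dim``; ``predictor_hidden`` is a bottleneck (smaller than
    ``projection_dim`` in the reference design).
    """

    encoder_variant: str = "tiny_1d"
    input_length: int = 1200
    feature_dim: int = 0
    projection_dim: int = 32
    projector_hidden: int = 64
    predictor_hidden: int = 16
    stop_gradient: bool = True

    def __post_init__(self):
        if self.encoder_variant not in _VARIANTS:
            raise ValueError(f"unknown encoder variant {self.encoder_variant!r}")
        block, _, stages = _VARIANTS[self.encoder_variant]
        derived = stages[-1][0] * _EXPANSION[block]
        if self.feature_dim == 0:
            object.__setattr__(self, "feature_dim", derived)
        elif self.feature_dim != derived:
            raise ValueError(
                f"feature_dim {self.feature_dim} incompatible with "
                f"{self.encoder_variant} (expected {derived})")
        for name in ("input_length", "projection_dim", "projector_hidden",
                     "predictor_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(eq=False)
class SiamOutputs:
    """Per-branch outputs: representation h, projection z, prediction p."""

    h: Tensor
    z: Tensor
    p: Tensor


class _BasicBlock(nn.Module):
    def __init__(self, in_ch, out_ch, stride, rng):
        self.conv1 = nn.Conv1d(in_ch, out_ch, 3, rng, stride=stride, padding=1)
        self.bn1 = nn.BatchNorm1d(out_ch)
        self.conv2 = nn.Conv1d(out_ch, out_ch, 3, rng, padding=1)
        self.bn2 = nn.BatchNorm1d(out_ch)
        self.down = None
        if stride != 1 or in_ch != out_ch:
            self.down = nn.Sequential(
                nn.Conv1d(in_ch, out_ch, 1, rng, stride=stride),
                nn.BatchNorm1d(out_ch))

    def forward(self, x):
        identity = x if self.down is None else self.down(x)
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        return (out + identity).relu()


class _Bottleneck(nn.Module):
    def __init__(self, in_ch, mid_ch, stride, rng):
        out_ch = mid_ch * 4
        self.conv1 = nn.Conv1d(in_ch, mid_ch, 1, rng)
        self.bn1 = nn.BatchNorm1d(mid_ch)
        self.conv2 = nn.Conv1d(mid_ch, mid_ch, 3, rng, stride=stride, padding=1)
        self.bn2 = nn.BatchNorm1d(mid_ch)
        self.conv3 = nn.Conv1d(mid_ch, out_ch, 1, rng)
        self.bn3 = nn.BatchNorm1d(out_ch)
        self.down = None
        if stride != 1 or in_ch != out_ch:
            self.down = nn.Sequential(
                nn.Conv1d(in_ch, out_ch, 1, rng, stride=stride),
                nn.BatchNorm1d(out_ch))

    def forward(self, x):
        identity = x if self.down is None else self.down(x)
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        return (out + identity).relu()


class _Encoder(nn.Module):
    """1-D residual encoder: stem, residual stages, global average pool."""

    def __init__(self, variant: str, rng: np.random.Generator):
        block, stem_ch, stages = _VARIANTS[variant]
        self.stem = nn.Conv1d(1, stem_ch, 7, rng, stride=2, padding=3)
        self.stem_bn = nn.BatchNorm1d(stem_ch)
        self.pool = nn.MaxPool1d(3, 2, 1)
        blocks = []
        in_ch = stem_ch
        for ch, n_blocks, stride in stages:
            for b in range(n_blocks):
                s = stride if b == 0 else 1
                if block == "basic":
                    blocks.append(_BasicBlock(in_ch, ch, s, rng))
                    in_ch = ch
                else:
                    blocks.append(_Bottleneck(in_ch, ch, s, rng))
                    in_ch = ch * 4
        self.blocks = blocks
        self.out_dim = in_ch

    def forward(self, x):
        out = self.pool(self.stem_bn(self.stem(x)).relu())
        for b in self.blocks:
            out = b(out)
        return nn.global_avg_pool(out)


class _MLP3(nn.Module):
    """Three fully-connected layers with BN+ReLU hidden activations."""

    def __init__(self, in_dim, hidden, out_dim, rng, final_bn: bool):
        self.fc1 = nn.Linear(in_dim, hidden, rng)
        self.bn1 = nn.BatchNorm1d(hidden)
        self.fc2 = nn.Linear(hidden, hidden, rng)
        self.bn2 = nn.BatchNorm1d(hidden)
        self.fc3 = nn.Linear(hidden, out_dim, rng)
        self.bn3 = nn.BatchNorm1d(out_dim) if final_bn else None

    def forward(self, x):
        out = self.bn1(self.fc1(x)).relu()
        out = self.bn2(self.fc2(out)).relu()
        out = self.fc3(out)
        if self.bn3 is not None:
            out = self.bn3(out)
        return out


class SiamQualityNet(nn.Module):
    """Shared-weight encoder + projector + predictor."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        self.encoder = _Encoder(self.config.encoder_variant, rng)
        assert self.encoder.out_dim == self.config.feature_dim
        self.projector = _MLP3(self.config.feature_dim,
                               self.config.projector_hidden,
                               self.config.projection_dim, rng, final_bn=True)
        self.predictor = _MLP3(self.config.projection_dim,
                               self.config.predictor_hidden,
                               self.config.projection_dim, rng, final_bn=False)

    def _as_batch(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        data = x.data
        if data.ndim == 1:
            x = x.reshape(1, 1, data.size)
        elif data.ndim == 2:
            x = x.reshape(data.shape[0], 1, data.shape[1])
        if x.shape[2] != self.config.input_length:
            raise ValueError(
                f"input length {x.shape[2]} != configured "
                f"{self.config.input_length}")
        return x

    def encode(self, x) -> Tensor:
        """h = E(x); accepts a segment (L,) or a batch (N, L)."""
        return self.encoder(self._as_batch(x))

    def project(self, h: Tensor) -> Tensor:
        return self.projector(h)

    def predict(self, z: Tensor) -> Tensor:
        return self.predictor(z)

    def forward(self, x) -> SiamOutputs:
        h = self.encode(x)
        z = self.project(h)
        p = self.predict(z)
        return SiamOutputs(h=h, z=z, p=p)

    def forward_pair(self, x_good, x_bad) -> tuple[SiamOutputs, SiamOutputs]:
        return self.forward(x_good), self.forward(x_bad)


def _cos_tensor(p: Tensor, z: Tensor) -> Tensor:
    """Mean cosine similarity along the last axis (batched or single)."""
    if p.ndim == 1:
        p = p.reshape(1, -1)
    if z.ndim == 1:
        z = z.reshape(1, -1)
    pn = ((p * p).sum(axis=1)) ** 0.5
    zn = ((z * z).sum(axis=1)) ** 0.5
    if np.any(pn.data == 0) or np.any(zn.data == 0):
        raise ValueError("cosine similarity undefined for zero vectors")
    cos = (p * z).sum(axis=1) / (pn * zn)
    return cos.mean()


def negative_cosine(p, z) -> Tensor:
    """Negative cosine similarity -p.z / (||p|| ||z||), in [-1, 1].

    For batched inputs the mean over the batch is returned.  No gradient
    flows through ``z``: it is detached (the stop-gradient contract).
    """
    p = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=np.float64))
    z = z if isinstance(z, Tensor) else Tensor(np.asarray(z, dtype=np.float64))
    return -_cos_tensor(p, z.detach())


def pair_loss(out_good: SiamOutputs, out_bad: SiamOutputs,
              scale: float = 1.0, stop_gradient: bool = True) -> Tensor:
    """Symmetric contrastive loss of one quality pair.

    ``scale x [-cos(p_good, z_bad) - cos(p_bad, z_good)]``; bounded by
    ``[-2, 2] x scale``.  ``stop_gradient=False`` disables the detach on
    the projection arguments (ablation only; risks representational
    collapse).
    """
    zb = out_bad.z.detach() if stop_gradient else out_bad.z
    zg = out_good.z.detach() if stop_gradient else out_good.z
    loss = -_cos_tensor(out_good.p, zb) - _cos_tensor(out_bad.p, zg)
    return loss * scale


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(model: SiamQualityNet, path) -> None:
    """Archive parameters, batch-norm running stats and the full config."""
    arrays = {}
    for i, p in enumerate(model.parameters()):
        arrays[f"param_{i:04d}"] = p.data
    bns = [m for m in model.modules() if isinstance(m, nn.BatchNorm1d)]
    for i, bn in enumerate(bns):
        arrays[f"bn_mean_{i:04d}"] = bn.running_mean
        arrays[f"bn_var_{i:04d}"] = bn.running_var
    meta = {"config": asdict(model.config), "numpy_version": np.__version__,
            "format_version": 1}
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path, expect_config: ModelConfig | None = None) -> SiamQualityNet:
    """Rebuild a model from an archive, verifying config compatibility."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
        config = ModelConfig(**meta["config"])
        if expect_config is not None and config != expect_config:
            raise ValueError(
                f"checkpoint config {config} != expected {expect_config}")
        model = SiamQualityNet(config, seed=0)
        params = model.parameters()
        for i, p in enumerate(params):
            stored = data[f"param_{i:04d}"]
            if stored.shape != p.data.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = stored.copy()
        bns = [m for m in model.modules() if isinstance(m, nn.BatchNorm1d)]
        for i, bn in enumerate(bns):
            bn.running_mean = data[f"bn_mean_{i:04d}"].copy()
            bn.running_var = data[f"bn_var_{i:04d}"].copy()
    return model
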