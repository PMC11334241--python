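"""Self-supervised pretraining on quality pairs and downstream fine-tuning.

Pretraining consumes quality pairs in curriculum order (easiest first),
passing both members through one shared-weight network and minimizing the
symmetric negative-cosine loss.  The optimizer is SGD with momentum and
an optional cosine learning-rate decay, following the SimSiam reference
recipe; all sources of randomness derive from a single seed, and
identical seeds give bit-identical traces.

Three fine-tuning strategies are supported:

* ``fine_tune_all`` — update encoder and task head jointly;
* ``fine_tune_last`` — freeze the encoder, train only a newly
  initialized linear head on the representation ``h``;
* ``in_domain_pretrain_then_last`` — run quality-pair pretraining on the
  target dataset's own (unlabeled) pairs, then fine-tune the head only.

A collapse diagnostic (mean per-dimension standard deviation of
length-normalized embeddings) is tracked per epoch: values near zero mean
all embeddings have collapsed to one point, the classic failure mode of
negative-pair-free contrastive learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import ModelConfig, SiamQualityNet, pair_loss
from .pairing import QualityPair, curriculum_order

__all__ = [
    "PretrainConfig",
    "FinetuneConfig",
    "TrainingTrace",
    "TaskModel",
    "pretrain",
    "collapse_diagnostic",
    "embed_segments",
    "finetune",
]


@dataclass(frozen=True)
class PretrainConfig:
    epochs: int = 5
    batch_size: int = 8
    learning_rate: float = 0.02
    optimizer_name: str = "adam"
    momentum: float = 0.9
    weight_decay: float = 0.0
    curriculum_mode: str = "staged_buckets"   # strict_sort | staged_buckets | shuffled_control
    n_buckets: int = 5
    replay_each_epoch: bool = True
    cosine_decay: bool = False
    loss_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer_name not in ("sgd", "adam"):
            raise ValueError("optimizer_name must be 'sgd' or 'adam'")


@dataclass(frozen=True)
class FinetuneConfig:
    strategy: str = "fine_tune_all"
    task_kind: str = "regression"             # regression | classification
    head_dim: int = 1
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in ("fine_tune_all", "fine_tune_last",
                                 "in_domain_pretrain_then_last"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.task_kind not in ("regression", "classification"):
            raise ValueError(f"unknown task kind {self.task_kind!r}")


@dataclass
class TrainingTrace:
    step_losses: list[float] = field(default_factory=list)
    epoch_mean_loss: list[float] = field(default_factory=list)
    epoch_dispersion: list[float] = field(default_factory=list)
    batch_mean_c: list[float] = field(default_factory=list)


def collapse_diagnostic(embeddings: np.ndarray) -> float:
    """Mean per-dimension std of L2-normalized embeddings.

    Near zero indicates representational collapse; independent random
    unit vectors in dimension d give roughly 1/sqrt(d).
    """
    embeddings = np.asarray(embeddings, dtype=np.float64)
    if embeddings.ndim != 2 or embeddings.shape[0] < 2:
        raise ValueError("need at least 2 embedding vectors")
    norms = np.linalg.norm(embeddings, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return float((embeddings / norms).std(axis=0).mean())


def embed_segments(model: SiamQualityNet, X: np.ndarray,
                   batch_size: int = 64, space: str = "h") -> np.ndarray:
    """Evaluation-mode embeddings of segments (rows of X): h or z space."""
    model.eval()
    outs = []
    for i in range(0, len(X), batch_size):
        h = model.encode(X[i:i + batch_size])
        if space == "z":
            h = model.project(h)
        outs.append(h.data)
    return np.concatenate(outs, axis=0)


def _pair_arrays(pairs: list[QualityPair]):
    xg = np.stack([p.good.samples for p in pairs])
    xb = np.stack([p.bad.samples for p in pairs])
    c = np.array([p.c for p in pairs])
    return xg, xb, c


def pretrain(pairs: list[QualityPair],
             model_config: ModelConfig | None = None,
             config: PretrainConfig | None = None,
             model: SiamQualityNet | None = None
             ) -> tuple[SiamQualityNet, TrainingTrace]:
    """Curriculum-ordered self-supervised pretraining.

    Returns the trained network (shared weights across both branches) and
    a trace of per-step losses, per-epoch mean loss and per-epoch
    embedding dispersion.  Raises on empty pairs and aborts on a
    non-finite loss.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    config = config or PretrainConfig()
    if model is None:
        model = SiamQualityNet(model_config or ModelConfig(), seed=config.seed)
    model.train()
    if config.optimizer_name == "adam":
        opt = nn.Adam(model.parameters(), lr=config.learning_rate,
                      weight_decay=config.weight_decay)
    else:
        opt = nn.SGD(model.parameters(), lr=config.learning_rate,
                     momentum=config.momentum, weight_decay=config.weight_decay)
    trace = TrainingTrace()

    n = len(pairs)
    steps_per_epoch = int(np.ceil(n / config.batch_size))
    total_steps = config.epochs * steps_per_epoch
    step = 0
    probe = _pair_arrays(pairs[: min(n, 64)])

    for epoch in range(config.epochs):
        order_seed = config.seed + epoch if config.replay_each_epoch else config.seed
        ordered = curriculum_order(pairs, mode=config.curriculum_mode,
                                   n_buckets=config.n_buckets, seed=order_seed)
        xg, xb, c = _pair_arrays(ordered)
        epoch_losses = []
        for i in range(0, n, config.batch_size):
            if config.cosine_decay:
                opt.lr = config.learning_rate * 0.5 * (
                    1.0 + np.cos(np.pi * step / max(total_steps, 1)))
            bg, bb = xg[i:i + config.batch_size], xb[i:i + config.batch_size]
            out_g, out_b = model.forward_pair(bg, bb)
            loss = pair_loss(out_g, out_b, scale=config.loss_scale,
                             stop_gradient=model.config.stop_gradient)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"non-finite loss {lval} at epoch {epoch} step {step}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            trace.step_losses.append(lval)
            trace.batch_mean_c.append(float(c[i:i + config.batch_size].mean()))
            epoch_losses.append(lval)
            step += 1
        trace.epoch_mean_loss.append(float(np.mean(epoch_losses)))
        z = embed_segments(model, np.concatenate([probe[0], probe[1]]), space="z")
        trace.epoch_dispersion.append(collapse_diagnostic(z))
        model.train()
    model.eval()
    return model, trace


# ---------------------------------------------------------------------------
# Fine-tuning
# ---------------------------------------------------------------------------


@dataclass
class TaskModel:
    """A fine-tuned task model: encoder + linear head on h."""

    encoder_model: SiamQualityNet
    head: nn.Linear
    task_kind: str
    target_mean: float = 0.0
    target_scale: float = 1.0

    def predict(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Predicted targets (regression) or class labels (classification)."""
        self.encoder_model.eval()
        preds = []
        for i in range(0, len(X), batch_size):
            h = self.encoder_model.encode(X[i:i + batch_size])
            out = self.head(h).data
            preds.append(out)
        out = np.concatenate(preds, axis=0)
        if self.task_kind == "regression":
            return out[:, 0] * self.target_scale + self.target_mean
        return out.argmax(axis=1)


def _softmax_xent(logits: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
    m = logits.data.max(axis=1, keepdims=True)     # constant shift for stability
    shifted = logits - m
    logsum = shifted.exp().sum(axis=1, keepdims=True).log()
    logsm = shifted - logsum
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(labels)), labels.astype(int)] = 1.0
    return -(logsm * onehot).sum(axis=1).mean()


def finetune(model: SiamQualityNet, X: np.ndarray, targets: np.ndarray,
             config: FinetuneConfig | None = None,
             X_val: np.ndarray | None = None,
             y_val: np.ndarray | None = None,
             pretrain_pairs: list[QualityPair] | None = None,
             pretrain_config: PretrainConfig | None = None
             ) -> tuple[TaskModel, float | None]:
    """Adapt a pretrained encoder to a labelled task.

    Returns the task model and the validation metric (MAE for regression,
    F1 for binary classification) on ``(X_val, y_val)`` if provided.  The
    input ``model`` is not modified: fine-tuning operates on a copy of
    its parameters.
    """
    config = config or FinetuneConfig()
    targets = np.asarray(targets)
    if config.task_kind == "regression":
        if targets.dtype.kind not in "fi":
            raise ValueError("regression targets must be numeric")
        targets = targets.astype(np.float64)
    else:
        if not np.issubdtype(targets.dtype, np.integer):
            raise ValueError("classification targets must be integer labels")
        if config.head_dim < 2:
            raise ValueError("classification needs head_dim >= 2 classes")

    # work on a copy so the caller's pretrained weights stay intact
    work = SiamQualityNet(model.config, seed=0)
    for dst, src in zip(work.parameters(), model.parameters()):
        dst.data = src.data.copy()
    for dst, src in zip(
            (m for m in work.modules() if isinstance(m, nn.BatchNorm1d)),
            (m for m in model.modules() if isinstance(m, nn.BatchNorm1d))):
        dst.running_mean = src.running_mean.copy()
        dst.running_var = src.running_var.copy()

    if config.strategy == "in_domain_pretrain_then_last":
        if not pretrain_pairs:
            raise ValueError(
                "in_domain_pretrain_then_last requires pretrain_pairs")
        work, _ = pretrain(pretrain_pairs, config=pretrain_config, model=work)

    rng = np.random.default_rng(config.seed)
    head_out = 1 if config.task_kind == "regression" else config.head_dim
    head = nn.Linear(model.config.feature_dim, head_out, rng)

    t_mean, t_scale = 0.0, 1.0
    if config.task_kind == "regression":
        t_mean = float(targets.mean())
        t_scale = float(targets.std()) or 1.0
        y_train = (targets - t_mean) / t_scale
    else:
        y_train = targets

    freeze = config.strategy in ("fine_tune_last", "in_domain_pretrain_then_last")
    if freeze:
        work.eval()
        feats = embed_segments(work, X)           # encoder is a fixed featurizer
        params = head.parameters()
    else:
        work.train()
        params = work.encoder.parameters() + head.parameters()
    if config.optimizer_name == "adam":
        opt = nn.Adam(params, lr=config.learning_rate)
    else:
        opt = nn.SGD(params, lr=config.learning_rate, momentum=config.momentum)

    n = len(X)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            if freeze:
                h = nn.Tensor(feats[idx])
            else:
                h = work.encode(X[idx])
            out = head(h)
            if config.task_kind == "regression":
                resid = out.reshape(-1) - y_train[idx]
                loss = (resid * resid).mean()
            else:
                loss = _softmax_xent(out, y_train[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()

    task = TaskModel(encoder_model=work, head=head, task_kind=config.task_kind,
                     target_mean=t_mean, target_scale=t_scale)
    metric = None
    if X_val is not None and y_val is not None:
        pred = task.predict(X_val)
        if config.task_kind == "regression":
            metric = float(np.mean(np.abs(np.asarray(y_val) - pred)))
        else:
            from .evaluate import ConfusionCounts, f1
            yv = np.asarray(y_val).astype(int)
            tp = int(np.sum((pred == 1) & (yv == 1)))
            fp = int(np.sum((pred == 1) & (yv == 0)))
            fn = int(np.sum((pred == 0) & (yv == 1)))
            tn = int(np.sum((pred == 0) & (yv == 0)))
            metric = f1(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))[0]
    return task, metric
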