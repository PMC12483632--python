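"""Training loops: supervised few-shot (FSSL) and model-agnostic
meta-learning (MAML), with the three optimizers, early stopping on
validation loss (patience 15, best weights restored) and step-wise
learning-rate decay (factor 0.1 at predefined epochs).

Both regimes train only the classification head; the backbone stays
frozen throughout.  The MAML inner loop is a pure functional update —
``inner_adapt`` returns a fresh parameter dictionary and never mutates
its input — and the outer loop differentiates the query loss through the
inner gradient steps (second-order by default; a ``first_order`` flag
switches to the FOMAML approximation).

When augmentation is disabled, backbone features are precomputed once per
bank (the backbone is frozen, so features are constants); with
augmentation enabled, images are re-augmented and re-extracted per batch.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import autodiff as ad
from .architectures import FewShotClassifier
from .autodiff import Tensor
from .data import (
    BackboneInputSpec,
    GeometricAugConfig,
    HsvAugConfig,
    ImageBank,
    augment_geometric,
    augment_hsv,
    load_image,
    resize_normalize,
)
from .episodes import Episode, ShotTaskConfig, sample_episode, sample_fssl_epoch

logger = logging.getLogger("toothmark")

__all__ = [
    "OptimizerSpec",
    "EarlyStopSpec",
    "LrScheduleSpec",
    "MamlConfig",
    "TrainHistory",
    "make_optimizer",
    "bank_tensors",
    "train_fssl",
    "inner_adapt",
    "meta_gradients",
    "meta_step",
    "train_maml",
    "finalize_maml",
    "evaluate_model",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

_OPTIMIZERS = ("adam", "adagrad", "sgd")


@dataclass(frozen=True)
class OptimizerSpec:
    kind: str = "adam"
    learning_rate: float = 1e-3
    momentum: float = 0.9  # sgd only

    def __post_init__(self):
        if self.kind not in _OPTIMIZERS:
            raise ValueError(
                f"unknown optimizer {self.kind!r}; valid options: {', '.join(_OPTIMIZERS)}"
            )
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must lie in [0, 1)")


@dataclass(frozen=True)
class EarlyStopSpec:
    """Stop when validation loss fails to improve for ``patience`` epochs."""

    patience: int = 15
    restore_best: bool = True

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be positive")


@dataclass(frozen=True)
class LrScheduleSpec:
    """Multiply the learning rate by ``factor`` at each milestone epoch."""

    factor: float = 0.1
    milestones: tuple[int, ...] = (40, 70)

    def __post_init__(self):
        if not (0.0 < self.factor < 1.0):
            raise ValueError("factor must lie in (0, 1)")
        if list(self.milestones) != sorted(set(self.milestones)):
            raise ValueError("milestones must be strictly increasing")

    def lr_at(self, base_lr: float, epoch: int) -> float:
        """Learning rate in effect during ``epoch`` (0-based)."""
        return base_lr * self.factor ** sum(1 for m in self.milestones if epoch >= m)


@dataclass(frozen=True)
class MamlConfig:
    inner_lr: float = 0.01
    inner_steps: int = 1
    meta_optimizer: OptimizerSpec = field(
        default_factory=lambda: OptimizerSpec("adam", 1e-4)
    )
    first_order: bool = False
    shot_task: ShotTaskConfig = field(
        default_factory=lambda: ShotTaskConfig.preset("maml-low")
    )

    def __post_init__(self):
        if self.inner_lr < 0 or self.inner_steps < 0:
            raise ValueError("inner_lr and inner_steps must be nonnegative")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_rows(self) -> list[dict]:
        return [
            {
                "epoch": i,
                "train_loss": self.train_loss[i],
                "train_acc": self.train_acc[i],
                "val_loss": self.val_loss[i],
                "val_acc": self.val_acc[i],
                "lr": self.lr[i],
                "best": i == self.best_epoch,
            }
            for i in range(len(self))
        ]


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class _Optimizer:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        raise NotImplementedError


class _SGD(_Optimizer):
    def __init__(self, lr: float, momentum: float):
        super().__init__(lr)
        self.momentum = momentum
        self.vel: dict[str, np.ndarray] = {}

    def step(self, params, grads):
        for k, g in grads.items():
            v = self.vel.get(k)
            v = g if v is None else self.momentum * v + g
            self.vel[k] = v
            params[k] -= self.lr * v


class _Adagrad(_Optimizer):
    def __init__(self, lr: float, eps: float = 1e-10):
        super().__init__(lr)
        self.eps = eps
        self.accum: dict[str, np.ndarray] = {}

    def step(self, params, grads):
        for k, g in grads.items():
            a = self.accum.get(k, 0.0) + g * g
            self.accum[k] = a
            params[k] -= self.lr * g / (np.sqrt(a) + self.eps)


class _Adam(_Optimizer):
    def __init__(self, lr: float, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        super().__init__(lr)
        self.b1, self.b2, self.eps = b1, b2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k, g in grads.items():
            m = self.b1 * self.m.get(k, 0.0) + (1 - self.b1) * g
            v = self.b2 * self.v.get(k, 0.0) + (1 - self.b2) * g * g
            self.m[k], self.v[k] = m, v
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


def make_optimizer(spec: OptimizerSpec) -> _Optimizer:
    if spec.kind == "sgd":
        return _SGD(spec.learning_rate, spec.momentum)
    if spec.kind == "adagrad":
        return _Adagrad(spec.learning_rate)
    return _Adam(spec.learning_rate)


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def bank_tensors(
    bank: ImageBank, spec: BackboneInputSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Load, resize and normalize a bank: (n, 3, side, side) floats + labels."""
    if len(bank) == 0:
        raise ValueError("empty bank")
    xs = [
        resize_normalize(load_image(r.path), spec).transpose(2, 0, 1)
        for r in bank.records
    ]
    return np.stack(xs), bank.labels()


class _FeatureSource:
    """Per-batch features: cached when augmentation is off, recomputed
    from freshly augmented raw images otherwise."""

    def __init__(
        self,
        model: FewShotClassifier,
        bank: ImageBank,
        spec: BackboneInputSpec,
        geo: GeometricAugConfig | None,
        hsv: HsvAugConfig | None,
        rng: np.random.Generator,
    ):
        self.model = model
        self.spec = spec
        self.geo, self.hsv, self.rng = geo, hsv, rng
        self.labels = bank.labels()
        self.augmented = geo is not None or hsv is not None
        if self.augmented:
            self.raw = [load_image(r.path) for r in bank.records]
            self.feats = None
        else:
            x, _ = bank_tensors(bank, spec)
            self.feats = model.features(x)

    def batch(self, indices: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
        idx = np.asarray(indices, dtype=int)
        if not self.augmented:
            return self.feats[idx], self.labels[idx]
        imgs = []
        for i in idx:
            img = self.raw[i]
            if self.geo is not None:
                img = augment_geometric(img, self.geo, self.rng)
            if self.hsv is not None:
                img = augment_hsv(img, self.hsv, self.rng)
            imgs.append(resize_normalize(img, self.spec).transpose(2, 0, 1))
        return self.model.features(np.stack(imgs)), self.labels[idx]


def _grads_to_np(params_t: dict[str, Tensor], grads: list[Tensor]) -> dict[str, np.ndarray]:
    return {k: g.data for k, g in zip(params_t, grads)}


def _accuracy(probs: np.ndarray, labels: np.ndarray) -> float:
    return float((probs.argmax(axis=1) == labels).mean())


# ---------------------------------------------------------------------------
# FSSL training
# ---------------------------------------------------------------------------

def train_fssl(
    model: FewShotClassifier,
    train_bank: ImageBank,
    val_bank: ImageBank,
    shot_task: ShotTaskConfig,
    opt: OptimizerSpec = OptimizerSpec(),
    stops: EarlyStopSpec = EarlyStopSpec(),
    sched: LrScheduleSpec = LrScheduleSpec(),
    geo_aug: GeometricAugConfig | None = None,
    hsv_aug: HsvAugConfig | None = None,
    rng: np.random.Generator | None = None,
    max_epochs: int = 100,
) -> TrainHistory:
    """Supervised few-shot training of the head on class-balanced batches.

    Each epoch consumes ``n_tasks`` class-balanced k-shot batches with
    online augmentation (training images only), minimizing cross-entropy.
    Validation loss drives early stopping; the best-epoch weights (and
    batch-norm running statistics) are restored on exit.
    """
    if len(train_bank) == 0:
        raise ValueError("empty train bank")
    rng = rng or np.random.default_rng(0)
    spec = BackboneInputSpec.for_backbone(
        model.backbone.spec.name, model.backbone.spec.input_side
    )
    source = _FeatureSource(model, train_bank, spec, geo_aug, hsv_aug, rng)
    val_x, val_y = bank_tensors(val_bank, spec)
    val_feats = model.features(val_x)

    optimizer = make_optimizer(opt)
    history = TrainHistory()
    best = {"loss": np.inf, "params": None, "running": None, "epoch": -1}
    for epoch in range(max_epochs):
        optimizer.lr = sched.lr_at(opt.learning_rate, epoch)
        batches = sample_fssl_epoch(train_bank, shot_task, rng)
        ep_loss, ep_acc = [], []
        for batch in batches:
            feats, labels = source.batch(batch.indices)
            params_t = model._wrap()
            loss, logits = model.loss(params_t, feats, labels, training=True, rng=rng)
            grads = ad.grad(loss, list(params_t.values()))
            optimizer.step(model.params, _grads_to_np(params_t, grads))
            ep_loss.append(loss.item())
            ep_acc.append(_accuracy(logits.data, labels))
        with ad.no_grad():
            vp = {k: Tensor(v) for k, v in model.params.items()}
            vloss, vlogits = model.loss(vp, val_feats, val_y, training=False)
        history.train_loss.append(float(np.mean(ep_loss)))
        history.train_acc.append(float(np.mean(ep_acc)))
        history.val_loss.append(vloss.item())
        history.val_acc.append(_accuracy(vlogits.data, val_y))
        history.lr.append(optimizer.lr)
        logger.info(
            "fssl epoch=%d train_loss=%.4f train_acc=%.3f val_loss=%.4f val_acc=%.3f lr=%.2e",
            epoch, history.train_loss[-1], history.train_acc[-1],
            history.val_loss[-1], history.val_acc[-1], optimizer.lr,
        )
        if vloss.item() < best["loss"]:
            best.update(
                loss=vloss.item(),
                params=copy.deepcopy(model.params),
                running=copy.deepcopy(model.running),
                epoch=epoch,
            )
        elif epoch - best["epoch"] >= stops.patience:
            break
    if stops.restore_best and best["params"] is not None:
        model.params = best["params"]
        model.running = best["running"]
    history.best_epoch = best["epoch"]
    return history


# ---------------------------------------------------------------------------
# MAML
# ---------------------------------------------------------------------------

def inner_adapt(
    params: dict[str, Tensor],
    loss_fn: Callable[[dict[str, Tensor]], Tensor],
    inner_lr: float,
    inner_steps: int,
    create_graph: bool = False,
) -> dict[str, Tensor]:
    """``inner_steps`` plain gradient-descent updates on the support loss.

    A purely functional update: the input dictionary is never mutated, and
    with ``create_graph=True`` the returned parameters remain
    differentiable w.r.t. the originals (enabling the meta-gradient).
    """
    cur = dict(params)
    for _ in range(inner_steps):
        loss = loss_fn(cur)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite inner loss: {loss.data}")
        grads = ad.grad(loss, list(cur.values()), create_graph=create_graph)
        lr = Tensor(inner_lr)
        cur = {
            k: ad.sub(v, ad.mul(lr, g))
            for (k, v), g in zip(cur.items(), grads)
        }
    return cur


def meta_gradients(
    params: dict[str, np.ndarray],
    episodes: Sequence,
    support_loss_fn: Callable[[dict[str, Tensor], object], Tensor],
    query_loss_fn: Callable[[dict[str, Tensor], object], Tensor],
    config: MamlConfig,
    aux_out: list | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Meta-gradient of the mean query loss over a batch of episodes.

    For each episode the parameters are adapted on its support set via
    :func:`inner_adapt` and the query loss is evaluated at the adapted
    parameters.  By default the gradient flows through the inner steps
    (second order); with ``first_order`` the adapted parameters are
    treated as fresh leaves and the query gradients are applied to the
    meta-parameters directly (FOMAML).

    ``query_loss_fn`` may return either a scalar loss or a
    ``(loss, aux)`` pair; auxiliary values are appended to ``aux_out``.
    """
    wrapped = {k: Tensor(v, track=True) for k, v in params.items()}
    total_loss = 0.0
    acc: dict[str, np.ndarray] = {k: np.zeros_like(v) for k, v in params.items()}
    n = len(episodes)
    for i, ep in enumerate(episodes):
        if config.first_order:
            adapted = inner_adapt(
                wrapped, lambda p: support_loss_fn(p, ep),
                config.inner_lr, config.inner_steps, create_graph=False,
            )
            leaves = {k: Tensor(v.data, track=True) for k, v in adapted.items()}
            qloss = query_loss_fn(leaves, ep)
            grad_wrt = leaves
        else:
            adapted = inner_adapt(
                wrapped, lambda p: support_loss_fn(p, ep),
                config.inner_lr, config.inner_steps, create_graph=True,
            )
            qloss = query_loss_fn(adapted, ep)
            grad_wrt = wrapped
        if isinstance(qloss, tuple):
            qloss, aux = qloss
            if aux_out is not None:
                aux_out.append(aux)
        grads = ad.grad(qloss, list(grad_wrt.values()))
        if not np.isfinite(qloss.data):
            raise FloatingPointError(f"non-finite meta loss at episode {i}")
        total_loss += qloss.item()
        for k, g in zip(params, grads):
            acc[k] += g.data / n
    return total_loss / n, acc


def meta_step(
    params: dict[str, np.ndarray],
    episodes: Sequence,
    support_loss_fn,
    query_loss_fn,
    config: MamlConfig,
    optimizer: _Optimizer,
    aux_out: list | None = None,
) -> float:
    """One outer-loop update; mutates ``params`` in place, returns meta loss."""
    loss, grads = meta_gradients(
        params, episodes, support_loss_fn, query_loss_fn, config, aux_out
    )
    optimizer.step(params, grads)
    return loss


def _episode_feats(source: _FeatureSource, ep: Episode):
    xs, ys = source.batch(ep.support_indices)
    xq, yq = source.batch(ep.query_indices)
    return xs, ys, xq, yq


def train_maml(
    model: FewShotClassifier,
    train_bank: ImageBank,
    val_bank: ImageBank,
    config: MamlConfig = MamlConfig(),
    stops: EarlyStopSpec = EarlyStopSpec(),
    sched: LrScheduleSpec = LrScheduleSpec(),
    geo_aug: GeometricAugConfig | None = None,
    hsv_aug: HsvAugConfig | None = None,
    rng: np.random.Generator | None = None,
    max_epochs: int = 100,
    val_episodes: int = 4,
) -> TrainHistory:
    """Episodic meta-training of the head (backbone frozen).

    Each epoch processes ``n_tasks`` support/query episodes through
    :func:`meta_step`.  Validation is episodic to match the
    meta-objective: adapt on a validation support set, score the
    validation query set; early stopping monitors that loss.  Inner loops
    use current-batch batch-norm statistics and never update the running
    estimates; dropout is disabled inside the inner/outer episode passes.
    """
    if len(train_bank) == 0:
        raise ValueError("empty train bank")
    rng = rng or np.random.default_rng(0)
    spec = BackboneInputSpec.for_backbone(
        model.backbone.spec.name, model.backbone.spec.input_side
    )
    source = _FeatureSource(model, train_bank, spec, geo_aug, hsv_aug, rng)
    val_source = _FeatureSource(model, val_bank, spec, None, None, rng)

    def support_loss(params_t, ep_data):
        xs, ys, _, _ = ep_data
        loss, _ = model.loss(
            params_t, xs, ys, training=False, bn_batch=True, update_running=False
        )
        return loss

    def query_loss(params_t, ep_data):
        _, _, xq, yq = ep_data
        loss, logits = model.loss(
            params_t, xq, yq, training=False, bn_batch=True, update_running=False
        )
        return loss, _accuracy(logits.data, yq)

    optimizer = make_optimizer(config.meta_optimizer)
    history = TrainHistory()
    best = {"loss": np.inf, "params": None, "running": None, "epoch": -1}
    for epoch in range(max_epochs):
        optimizer.lr = sched.lr_at(config.meta_optimizer.learning_rate, epoch)
        ep_loss, ep_acc = [], []
        for _ in range(config.shot_task.n_tasks):
            ep = sample_episode(train_bank, config.shot_task, rng)
            data = _episode_feats(source, ep)
            aux: list = []
            loss = meta_step(
                model.params, [data], support_loss, query_loss, config, optimizer, aux
            )
            ep_loss.append(loss)
            ep_acc.extend(aux)
        # episodic validation: adapt on val support, score val query
        vl, va = [], []
        for _ in range(val_episodes):
            vep = sample_episode(val_bank, config.shot_task, rng)
            vdata = _episode_feats(val_source, vep)
            with ad.no_grad():
                wrapped = {k: Tensor(v) for k, v in model.params.items()}
                adapted = inner_adapt(
                    wrapped, lambda p: support_loss(p, vdata),
                    config.inner_lr, config.inner_steps,
                )
                vloss, vlogits = model.loss(
                    adapted, vdata[2], vdata[3],
                    training=False, bn_batch=True, update_running=False,
                )
            vl.append(vloss.item())
            va.append(_accuracy(vlogits.data, vdata[3]))
        history.train_loss.append(float(np.mean(ep_loss)))
        history.train_acc.append(float(np.mean(ep_acc)))
        history.val_loss.append(float(np.mean(vl)))
        history.val_acc.append(float(np.mean(va)))
        history.lr.append(optimizer.lr)
        logger.info(
            "maml epoch=%d meta_loss=%.4f query_acc=%.3f val_loss=%.4f val_acc=%.3f lr=%.2e",
            epoch, history.train_loss[-1], history.train_acc[-1],
            history.val_loss[-1], history.val_acc[-1], optimizer.lr,
        )
        if history.val_loss[-1] < best["loss"]:
            best.update(
                loss=history.val_loss[-1],
                params=copy.deepcopy(model.params),
                epoch=epoch,
            )
        elif epoch - best["epoch"] >= stops.patience:
            break
    if stops.restore_best and best["params"] is not None:
        model.params = best["params"]
    history.best_epoch = best["epoch"]

    finalize_maml(model, train_bank, config, rng)
    return history


def finalize_maml(
    model: FewShotClassifier,
    support_bank: ImageBank,
    config: MamlConfig,
    rng: np.random.Generator,
) -> None:
    """Bake a deployed MAML predictor: adapt the meta-parameters on one
    support episode drawn from ``support_bank`` and freeze the adapted
    weights plus the support-batch batch-norm statistics into the model,
    so that standard evaluation-mode prediction applies afterwards."""
    spec = BackboneInputSpec.for_backbone(
        model.backbone.spec.name, model.backbone.spec.input_side
    )
    ep = sample_episode(support_bank, config.shot_task, rng)
    source = _FeatureSource(model, support_bank, spec, None, None, rng)
    xs, ys = source.batch(ep.support_indices)
    with ad.no_grad():
        wrapped = {k: Tensor(v) for k, v in model.params.items()}

        def sloss(p):
            loss, _ = model.loss(
                p, xs, ys, training=False, bn_batch=True, update_running=False
            )
            return loss

        adapted = inner_adapt(wrapped, sloss, config.inner_lr, config.inner_steps)
        model.params = {k: v.data.copy() for k, v in adapted.items()}
        # capture support-batch statistics as the running estimates
        model.head.apply(
            {k: Tensor(v) for k, v in model.params.items()},
            Tensor(xs),
            training=True,
            running=model.running,
            bn_momentum=1.0,
            dropout_active=False,
        )


def evaluate_model(
    model: FewShotClassifier, bank: ImageBank
) -> tuple[float, np.ndarray, np.ndarray]:
    """Evaluation-mode accuracy, predictions and labels on a bank."""
    spec = BackboneInputSpec.for_backbone(
        model.backbone.spec.name, model.backbone.spec.input_side
    )
    x, y = bank_tensors(bank, spec)
    probs = model.predict_proba_features(model.features(x))
    return _accuracy(probs, y), probs.argmax(axis=1), y
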