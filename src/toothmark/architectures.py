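"""Backbones and classification heads.

Two head variants sit atop a frozen convolutional feature extractor:

* ``complex`` — two residual blocks of depthwise-separable convolutions
  (kernel 3, stride 1, 'same' padding), each with a squeeze-and-excitation
  gate, then GAP -> dense(512, ReLU) -> dropout -> batch-norm -> softmax(4).
* ``baseline`` — a single standard convolution (512 filters) -> GAP ->
  dense(512, ReLU) -> dropout -> batch-norm -> softmax(4).

Named ImageNet backbones (ResNet50/152, DenseNet201, Xception,
EfficientNetV2L) are declared with their input sides and normalization
contracts, but their pretrained weights are not shipped; requesting one
raises :class:`BackboneWeightsUnavailable` suggesting the ``standin``
backbone — a small randomly initialized, frozen convolutional stack that
runs comfortably on a CPU and is the default for tests and desk-scale
experiments.

Everything is functional: parameters live in ``dict[str, ndarray]`` and are
wrapped into tracked tensors per call, which is what makes the MAML inner
loop a pure dictionary transformation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from . import autodiff as ad
from . import layers as L
from .autodiff import Tensor
from .taxa import TAXA

__all__ = [
    "BackboneSpec",
    "BackboneWeightsUnavailable",
    "NAMED_BACKBONES",
    "StandinBackbone",
    "build_backbone",
    "HeadSpec",
    "Head",
    "build_head",
    "FewShotClassifier",
    "se_recalibrate",
]

se_recalibrate = L.se_recalibrate


class BackboneWeightsUnavailable(RuntimeError):
    pass


#: name -> (input side, normalization contract name)
NAMED_BACKBONES: dict[str, tuple[int, str]] = {
    "resnet50": (224, "imagenet_caffe"),
    "resnet152": (224, "imagenet_caffe"),
    "densenet201": (224, "imagenet_torch"),
    "xception": (299, "imagenet_tf"),
    "efficientnetv2l": (299, "imagenet_tf"),
}


@dataclass(frozen=True)
class BackboneSpec:
    name: str = "standin"
    input_side: int = 64
    feature_shape: tuple[int, int, int] = (8, 8, 32)  # (h', w', c)
    frozen: bool = True


class StandinBackbone:
    """Three conv/ReLU/avg-pool stages; random, frozen feature extractor.

    Maps (n, 3, side, side) inputs to (n, c, side/8, side/8) feature maps.
    Weights are drawn once from a seeded He-normal initialization and never
    updated.
    """

    CHANNELS = (8, 16, 32)
    KERNEL = 3

    def __init__(self, input_side: int = 64, seed: int = 0):
        if input_side % 8 != 0 or input_side < 32:
            raise ValueError("standin backbone needs input_side >= 32 divisible by 8")
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = 3
        k = self.KERNEL
        for i, c_out in enumerate(self.CHANNELS):
            self.params[f"w{i}"] = L.he_init(rng, c_in * k * k, (c_out, c_in, k, k))
            self.params[f"b{i}"] = np.zeros(c_out)
            c_in = c_out
        side = input_side // 8
        self.spec = BackboneSpec(
            name="standin",
            input_side=input_side,
            feature_shape=(side, side, self.CHANNELS[-1]),
            frozen=True,
        )

    def features(self, x: np.ndarray, chunk: int = 64) -> np.ndarray:
        """Frozen forward pass: (n, 3, s, s) float array -> (n, c, s/8, s/8)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != self.spec.input_side:
            raise ValueError(
                f"expected (n, 3, {self.spec.input_side}, {self.spec.input_side}) "
                f"input, got {x.shape}"
            )
        outs = []
        with ad.no_grad():
            for lo in range(0, x.shape[0], chunk):
                t = Tensor(x[lo : lo + chunk])
                for i in range(len(self.CHANNELS)):
                    t = L.conv2d(t, Tensor(self.params[f"w{i}"]), Tensor(self.params[f"b{i}"]))
                    t = ad.relu(t)
                    t = L.avg_pool2d(t, 2)
                outs.append(t.data)
        return np.concatenate(outs, axis=0)

    __call__ = features


def build_backbone(
    name: str = "standin", input_side: int | None = None, seed: int = 0
) -> StandinBackbone:
    """Instantiate a feature extractor.

    Only ``standin`` is runnable in this installation; the five named
    ImageNet backbones require pretrained weights that are not shipped.
    """
    name = name.lower()
    if name == "standin":
        return StandinBackbone(input_side=input_side or 64, seed=seed)
    if name in NAMED_BACKBONES:
        raise BackboneWeightsUnavailable(
            f"pretrained weights for {name!r} are not available in this "
            f"installation; use the 'standin' backbone instead"
        )
    valid = "standin, " + ", ".join(NAMED_BACKBONES)
    raise ValueError(f"unknown backbone {name!r}; expected one of: {valid}")


# ---------------------------------------------------------------------------
# heads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeadSpec:
    variant: str = "complex"  # or "baseline"
    n_classes: int = len(TAXA)
    dropout_p: float = 0.5
    se_reduction: int = 16
    dense_width: int = 512
    baseline_filters: int = 512
    kernel: int = 3

    def __post_init__(self):
        if self.variant not in ("complex", "baseline"):
            raise ValueError(
                f"unknown head variant {self.variant!r}; expected 'complex' or 'baseline'"
            )
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must lie in [0, 1)")


class Head:
    """A classification head with functional parameters.

    ``init_params`` returns the trainable dict; ``apply`` maps backbone
    features (n, c, h', w') to logits (n, n_classes).
    """

    def __init__(self, spec: HeadSpec, feature_shape: tuple[int, int, int]):
        self.spec = spec
        self.feature_shape = feature_shape  # (h', w', c)

    # -- initialization ------------------------------------------------
    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        h, w, c = self.feature_shape
        s = self.spec
        p: dict[str, np.ndarray] = {}
        if s.variant == "complex":
            for blk in range(2):
                k = s.kernel
                p[f"rb{blk}_dw_w"] = L.he_init(rng, k * k, (c, k, k))
                p[f"rb{blk}_dw_b"] = np.zeros(c)
                p[f"rb{blk}_pw_w"] = L.he_init(rng, c, (c, c))
                p[f"rb{blk}_pw_b"] = np.zeros(c)
                hidden = max(1, c // s.se_reduction)
                p[f"rb{blk}_se_w1"] = L.he_init(rng, c, (hidden, c))
                p[f"rb{blk}_se_b1"] = np.zeros(hidden)
                p[f"rb{blk}_se_w2"] = L.he_init(rng, hidden, (c, hidden))
                p[f"rb{blk}_se_b2"] = np.zeros(c)
            dense_in = c
        else:
            k = s.kernel
            p["conv_w"] = L.he_init(rng, c * k * k, (s.baseline_filters, c, k, k))
            p["conv_b"] = np.zeros(s.baseline_filters)
            dense_in = s.baseline_filters
        p["fc1_w"] = L.he_init(rng, dense_in, (s.dense_width, dense_in))
        p["fc1_b"] = np.zeros(s.dense_width)
        p["bn_gamma"] = np.ones(s.dense_width)
        p["bn_beta"] = np.zeros(s.dense_width)
        p["out_w"] = L.he_init(rng, s.dense_width, (s.n_classes, s.dense_width))
        p["out_b"] = np.zeros(s.n_classes)
        return p

    def init_running(self) -> dict[str, np.ndarray]:
        return {
            "mean": np.zeros(self.spec.dense_width),
            "var": np.ones(self.spec.dense_width),
        }

    # -- structure -----------------------------------------------------
    def layer_inventory(self) -> list[str]:
        s = self.spec
        if s.variant == "complex":
            block = f"resblock(sepconv k{s.kernel} s1 same + se)"
            return [
                block,
                block,
                "gap",
                f"dense({s.dense_width}, relu)",
                "dropout",
                "batchnorm",
                f"softmax({s.n_classes})",
            ]
        return [
            f"conv2d({s.baseline_filters})",
            "gap",
            f"dense({s.dense_width}, relu)",
            "dropout",
            "batchnorm",
            f"softmax({s.n_classes})",
        ]

    def param_count(self, params: dict[str, np.ndarray]) -> int:
        return int(sum(v.size for v in params.values()))

    # -- forward -------------------------------------------------------
    def apply(
        self,
        params: dict[str, Tensor],
        x: Tensor,
        *,
        training: bool,
        rng: np.random.Generator | None = None,
        running: dict | None = None,
        bn_batch: bool | None = None,
        update_running: bool = True,
        bn_momentum: float = 0.1,
        dropout_active: bool | None = None,
        skip_residual_transform: bool = False,
    ) -> Tensor:
        """Features -> logits.

        ``bn_batch`` forces batch statistics in batch-norm independently of
        dropout (the transductive convention used when scoring MAML query
        sets); it defaults to ``training``.  ``skip_residual_transform``
        zeroes the transform branch of the residual blocks (identity-path
        verification only).
        """
        s = self.spec
        if dropout_active is None:
            dropout_active = training
        if dropout_active and s.dropout_p > 0 and rng is None:
            raise ValueError("training-mode dropout needs an rng")
        if bn_batch is None:
            bn_batch = training
        if s.variant == "complex":
            for blk in range(2):
                if skip_residual_transform:
                    continue
                y = L.separable_conv2d(
                    x,
                    params[f"rb{blk}_dw_w"],
                    params[f"rb{blk}_dw_b"],
                    params[f"rb{blk}_pw_w"],
                    params[f"rb{blk}_pw_b"],
                )
                y = ad.relu(y)
                y = L.se_recalibrate(
                    y,
                    params[f"rb{blk}_se_w1"],
                    params[f"rb{blk}_se_b1"],
                    params[f"rb{blk}_se_w2"],
                    params[f"rb{blk}_se_b2"],
                )
                # channel counts match by construction: identity shortcut
                x = ad.add(y, x)
        else:
            x = ad.relu(L.conv2d(x, params["conv_w"], params["conv_b"]))
        x = L.global_avg_pool(x)
        x = ad.relu(L.dense(x, params["fc1_w"], params["fc1_b"]))
        x = L.dropout(x, s.dropout_p, dropout_active, rng)
        x = L.batch_norm(
            x,
            params["bn_gamma"],
            params["bn_beta"],
            running,
            training=bn_batch,
            update_running=training and update_running,
            momentum=bn_momentum,
        )
        return L.dense(x, params["out_w"], params["out_b"])


def build_head(feature_shape: tuple[int, int, int], spec: HeadSpec) -> Head:
    """Construct the head for a backbone's (h', w', c) feature shape."""
    return Head(spec, feature_shape)


# ---------------------------------------------------------------------------
# classifier = frozen backbone + trainable head
# ---------------------------------------------------------------------------

class FewShotClassifier:
    """Frozen backbone + trainable head with taxon-ordered probabilities."""

    def __init__(
        self,
        backbone: StandinBackbone,
        head_spec: HeadSpec = HeadSpec(),
        seed: int = 0,
    ):
        self.backbone = backbone
        self.head = build_head(backbone.spec.feature_shape, head_spec)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = self.head.init_params(rng)
        self.running: dict[str, np.ndarray] = self.head.init_running()
        self.taxa = tuple(t.value for t in TAXA)
        self.test_accuracy: float | None = None

    # feature extraction (frozen => plain ndarray path)
    def features(self, images: np.ndarray) -> np.ndarray:
        h, w, c = self.backbone.spec.feature_shape
        return self.backbone.features(images).reshape(-1, c, h, w)

    def _wrap(self, params: dict[str, np.ndarray] | None = None) -> dict[str, Tensor]:
        src = self.params if params is None else params
        return {k: Tensor(v, track=True) for k, v in src.items()}

    def loss(
        self,
        params_t: dict[str, Tensor],
        feats: np.ndarray,
        labels: np.ndarray,
        *,
        training: bool,
        rng: np.random.Generator | None = None,
        bn_batch: bool | None = None,
        update_running: bool = True,
    ) -> tuple[Tensor, Tensor]:
        logits = self.head.apply(
            params_t,
            Tensor(feats),
            training=training,
            rng=rng,
            running=self.running,
            bn_batch=bn_batch,
            update_running=update_running,
        )
        return ad.cross_entropy(logits, labels), logits

    def predict_proba_features(
        self, feats: np.ndarray, params: dict[str, np.ndarray] | None = None
    ) -> np.ndarray:
        """Evaluation-mode class probabilities from backbone features."""
        with ad.no_grad():
            logits = self.head.apply(
                {k: Tensor(v) for k, v in (params or self.params).items()},
                Tensor(feats),
                training=False,
                running=self.running,
            )
            return ad.softmax(logits, axis=1).data

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Evaluation-mode class probabilities from (n, 3, s, s) images."""
        return self.predict_proba_features(self.features(images))

    forward = predict_proba

    def predict_image(self, image: np.ndarray) -> np.ndarray:
        """Probability vector for one (h, w, 3) uint8 RGB image."""
        from .data import BackboneInputSpec, resize_normalize  # avoid import cycle

        spec = BackboneInputSpec.for_backbone(
            self.backbone.spec.name, self.backbone.spec.input_side
        )
        x = resize_normalize(image, spec).transpose(2, 0, 1)[None]
        return self.predict_proba(x)[0]

    # -- checkpointing ---------------------------------------------------
    def manifest(self) -> dict:
        return {
            "backbone": self.backbone.spec.name,
            "input_side": self.backbone.spec.input_side,
            "head_variant": self.head.spec.variant,
            "taxa": list(self.taxa),
            "test_accuracy": self.test_accuracy,
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"param_{k}": v for k, v in self.params.items()}
        arrays |= {f"running_{k}": v for k, v in self.running.items()}
        arrays |= {f"backbone_{k}": v for k, v in self.backbone.params.items()}
        np.savez(path, manifest=json.dumps(self.manifest()), **arrays)

    @classmethod
    def load(cls, path: str | Path, expect_taxa: tuple[str, ...] | None = None):
        with np.load(Path(path), allow_pickle=False) as z:
            manifest = json.loads(str(z["manifest"]))
            if expect_taxa is not None and tuple(manifest["taxa"]) != tuple(expect_taxa):
                raise ValueError(
                    f"checkpoint class order {manifest['taxa']} does not match "
                    f"expected {list(expect_taxa)}"
                )
            backbone = StandinBackbone(input_side=manifest["input_side"])
            model = cls(backbone, HeadSpec(variant=manifest["head_variant"]))
            for key in z.files:
                if key.startswith("param_"):
                    model.params[key[6:]] = z[key]
                elif key.startswith("running_"):
                    model.running[key[8:]] = z[key]
                elif key.startswith("backbone_"):
                    model.backbone.params[key[9:]] = z[key]
            model.test_accuracy = manifest["test_accuracy"]
            return model
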