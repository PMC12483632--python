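"""Image-bank loading, the stratified 70/15/15 split, per-backbone
resizing/normalization, and the geometric + HSV augmentation protocols.

Augmentation conventions
------------------------
* Geometric: rotation uniform in ±20°, width/height shifts uniform in
  ±0.2 of the image side (independently per axis), horizontal flip with
  probability 0.5; exposed borders are filled nearest-edge.
* HSV: exactly one attribute is modified per augmented image, chosen
  uniformly among hue / saturation / value.  Hue lives on a circular
  0–180 scale and shifts wrap modulo 180; saturation and value are scaled
  by a factor in [0.8, 1.2] and clamped to the valid range.

Augmentation is applied online during training only, never to validation
or test images.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import color as skcolor

from .architectures import NAMED_BACKBONES
from .synthetic import MarkRecord
from .taxa import TAXA, TaxonLabel

__all__ = [
    "ImageBank",
    "SplitSpec",
    "BackboneInputSpec",
    "GeometricAugConfig",
    "HsvAugConfig",
    "load_bank",
    "load_image",
    "stratified_split",
    "largest_remainder_allocation",
    "resize_normalize",
    "augment_geometric",
    "augment_hsv",
]


@dataclass(frozen=True)
class ImageBank:
    """An ordered collection of mark records with a per-taxon index."""

    records: tuple[MarkRecord, ...]

    def __post_init__(self):
        ids = [r.mark_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate mark_id in bank")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def class_index(self) -> dict[TaxonLabel, list[int]]:
        idx: dict[TaxonLabel, list[int]] = {t: [] for t in TAXA}
        for i, rec in enumerate(self.records):
            idx[rec.taxon].append(i)
        return idx

    def class_counts(self) -> dict[TaxonLabel, int]:
        return {t: len(ix) for t, ix in self.class_index.items()}

    def subset(self, indices) -> "ImageBank":
        return ImageBank(tuple(self.records[i] for i in indices))

    def labels(self) -> np.ndarray:
        """Integer labels in fixed taxon order."""
        from .taxa import TAXON_INDEX

        return np.array([TAXON_INDEX[r.taxon] for r in self.records], dtype=np.intp)


def load_image(path: str | Path) -> np.ndarray:
    """Decode an image file to (h, w, 3) uint8 RGB."""
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"))
    except Exception as exc:  # noqa: BLE001 - rewrap with the offending file
        raise IOError(f"cannot read image {path}: {exc}") from exc


def load_bank(source: str | Path, check_images: bool = False) -> ImageBank:
    """Load a bank from a directory-per-taxon tree or a manifest CSV.

    Records are enumerated deterministically (sorted by taxon, then
    mark_id).  Unknown taxon directories and unreadable manifests raise
    labelled errors; ``check_images`` additionally decodes every file.
    """
    source = Path(source)
    records: list[MarkRecord] = []
    if source.is_file():  # manifest CSV
        with open(source, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"mark_id", "taxon", "path", "height", "width"}
            if not required <= set(reader.fieldnames or ()):
                raise ValueError(
                    f"manifest {source} missing columns: {sorted(required - set(reader.fieldnames or ()))}"
                )
            for row in reader:
                records.append(
                    MarkRecord(
                        row["mark_id"],
                        TaxonLabel.from_name(row["taxon"]),
                        Path(row["path"]),
                        (int(row["height"]), int(row["width"])),
                    )
                )
    elif source.is_dir():
        subdirs = sorted(p for p in source.iterdir() if p.is_dir())
        if not subdirs:
            raise ValueError(f"no taxon subdirectories found under {source}")
        valid = {t.value for t in TAXA}
        unknown = [p.name for p in subdirs if p.name not in valid]
        if unknown:
            raise ValueError(
                f"unknown taxon director{'y' if len(unknown)==1 else 'ies'} "
                f"{unknown} under {source}; expected {sorted(valid)}"
            )
        for sub in subdirs:
            taxon = TaxonLabel.from_name(sub.name)
            for path in sorted(sub.glob("*")):
                if path.suffix.lower() not in (".png", ".jpg", ".jpeg", ".tif", ".tiff"):
                    continue
                with Image.open(path) as im:
                    w, h = im.size
                records.append(MarkRecord(path.stem, taxon, path, (h, w)))
    else:
        raise FileNotFoundError(f"bank source {source} does not exist")

    if not records:
        raise ValueError(f"bank source {source} contains no images")
    records.sort(key=lambda r: (r.taxon.value, r.mark_id))
    if check_images:
        for rec in records:
            load_image(rec.path)
    return ImageBank(tuple(records))


# ---------------------------------------------------------------------------
# stratified split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Fractions of the train/validation/test partition."""

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.fractions[0] <= 0 or any(f < 0 for f in self.fractions):
            raise ValueError("train fraction must be positive, none negative")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def largest_remainder_allocation(
    counts: dict[TaxonLabel, int], fraction: float, total_target: int
) -> dict[TaxonLabel, int]:
    """Allocate ``total_target`` across classes proportionally to
    ``fraction * count`` by the largest-remainder rule.

    Ties in fractional parts are broken by descending class size (then by
    taxon order, for full determinism).  Each class's allocation differs
    from ``fraction * count`` by at most 1.
    """
    quotas = {t: fraction * n for t, n in counts.items()}
    alloc = {t: int(np.floor(q)) for t, q in quotas.items()}
    residual = total_target - sum(alloc.values())
    if residual < 0:
        raise ValueError("total_target below sum of floors")
    # round the fractional parts so float noise cannot defeat the
    # descending-class-size tie-break
    order = sorted(
        counts,
        key=lambda t: (-round(quotas[t] - alloc[t], 9), -counts[t], TAXA.index(t)),
    )
    for t in order[:residual]:
        alloc[t] += 1
    return alloc


def stratified_split(
    bank: ImageBank, spec: SplitSpec = SplitSpec()
) -> tuple[ImageBank, ImageBank, ImageBank]:
    """Disjoint, jointly exhaustive train/validation/test banks.

    The global train size is round-half-up(f_train · N) and the validation
    size round-half-up(f_val · N); the test split takes the remainder (for
    the default 1296-record bank at 70/15/15 this yields 907/194/195).
    Per-class allocations use the largest-remainder rule, so every class's
    share of each split is within one record of its exact quota.
    Deterministic given the seed.
    """
    counts = {t: n for t, n in bank.class_counts().items() if n > 0}
    need_all = spec.fractions[1] > 0 and spec.fractions[2] > 0
    for t, n in counts.items():
        if need_all and n < 3:
            raise ValueError(
                f"class {t.value} has only {n} record(s); at least 3 are "
                f"needed to populate train/validation/test"
            )
    n_total = len(bank)
    n_train = _round_half_up(spec.fractions[0] * n_total)
    n_val = _round_half_up(spec.fractions[1] * n_total)
    n_train = min(n_train, n_total)
    n_val = min(n_val, n_total - n_train)

    train_alloc = largest_remainder_allocation(counts, spec.fractions[0], n_train)
    # validation quotas come from the original class sizes; cap at remaining
    val_alloc = largest_remainder_allocation(counts, spec.fractions[1], n_val)

    rng = np.random.default_rng(spec.seed)
    idx_tr: list[int] = []
    idx_va: list[int] = []
    idx_te: list[int] = []
    class_index = bank.class_index
    for t in TAXA:
        members = np.array(class_index[t], dtype=int)
        if members.size == 0:
            continue
        perm = rng.permutation(members)
        k_tr, k_va = train_alloc[t], val_alloc[t]
        if k_tr + k_va > members.size:
            k_va = members.size - k_tr
        idx_tr.extend(perm[:k_tr].tolist())
        idx_va.extend(perm[k_tr : k_tr + k_va].tolist())
        idx_te.extend(perm[k_tr + k_va :].tolist())
    return bank.subset(sorted(idx_tr)), bank.subset(sorted(idx_va)), bank.subset(sorted(idx_te))


# ---------------------------------------------------------------------------
# resize / normalize
# ---------------------------------------------------------------------------

_NORMALIZATIONS = {"unit", "imagenet_caffe", "imagenet_torch", "imagenet_tf"}


@dataclass(frozen=True)
class BackboneInputSpec:
    """Input-side and normalization contract of one backbone."""

    backbone_name: str = "standin"
    side: int = 64
    normalization: str = "unit"

    def __post_init__(self):
        if self.side <= 0:
            raise ValueError("side must be positive")
        if self.backbone_name in NAMED_BACKBONES:
            expected = NAMED_BACKBONES[self.backbone_name][0]
            if self.side != expected:
                raise ValueError(
                    f"{self.backbone_name} expects side {expected}, got {self.side}"
                )
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(
                f"unknown normalization {self.normalization!r}; "
                f"expected one of {sorted(_NORMALIZATIONS)}"
            )

    @classmethod
    def for_backbone(cls, name: str, side: int | None = None) -> "BackboneInputSpec":
        if name in NAMED_BACKBONES:
            default_side, norm = NAMED_BACKBONES[name]
            return cls(name, side or default_side, norm)
        return cls("standin", side or 64, "unit")


_IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
_IMAGENET_STD = np.array([0.229, 0.224, 0.225])
_CAFFE_MEAN = np.array([103.939, 116.779, 123.68])  # BGR order


def resize_normalize(image: np.ndarray, spec: BackboneInputSpec) -> np.ndarray:
    """Bilinear resize to side×side then apply the normalization contract.

    Returns a float64 (side, side, 3) array.  The ``unit`` contract is a
    plain division by 255 (invertible); the three ImageNet contracts are
    the per-channel affine transforms conventionally paired with the named
    backbones.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (h, w, 3) RGB image, got shape {image.shape}")
    if image.shape[0] != spec.side or image.shape[1] != spec.side:
        pil = Image.fromarray(image.astype(np.uint8))
        image = np.asarray(pil.resize((spec.side, spec.side), Image.BILINEAR))
    x = image.astype(np.float64)
    if spec.normalization == "unit":
        return x / 255.0
    if spec.normalization == "imagenet_torch":
        return (x / 255.0 - _IMAGENET_MEAN) / _IMAGENET_STD
    if spec.normalization == "imagenet_tf":
        return x / 127.5 - 1.0
    # caffe: RGB->BGR then subtract channel means
    return x[:, :, ::-1] - _CAFFE_MEAN


# ---------------------------------------------------------------------------
# geometric augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometricAugConfig:
    rotation_deg: float = 20.0
    shift_frac: float = 0.2
    hflip: bool = True


def augment_geometric(
    image: np.ndarray, config: GeometricAugConfig, rng: np.random.Generator
) -> np.ndarray:
    """Random rotation, width/height shift and horizontal flip.

    The rotation angle is uniform in ±rotation_deg, shifts are uniform in
    ±shift_frac of each side (independently), and the flip fires with
    probability 0.5.  Borders exposed by the transform are filled
    nearest-edge.  The output shape always equals the input shape.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (h, w, 3) RGB image, got shape {image.shape}")
    out = image.astype(np.float64)
    angle = rng.uniform(-config.rotation_deg, config.rotation_deg)
    dy = rng.uniform(-config.shift_frac, config.shift_frac) * image.shape[0]
    dx = rng.uniform(-config.shift_frac, config.shift_frac) * image.shape[1]
    flip = config.hflip and rng.random() < 0.5
    if angle != 0.0:
        out = ndimage.rotate(
            out, angle, axes=(1, 0), reshape=False, order=1, mode="nearest"
        )
    if dy != 0.0 or dx != 0.0:
        out = ndimage.shift(out, (dy, dx, 0.0), order=1, mode="nearest")
    if flip:
        out = out[:, ::-1]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# HSV augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HsvAugConfig:
    hue_shift_range: tuple[float, float] = (-10.0, 10.0)  # on the 0-180 scale
    sat_scale_range: tuple[float, float] = (0.8, 1.2)
    val_scale_range: tuple[float, float] = (0.8, 1.2)


def augment_hsv(
    image: np.ndarray,
    config: HsvAugConfig,
    rng: np.random.Generator,
    force_mode: str | None = None,
    return_mode: bool = False,
):
    """Modify exactly one HSV attribute of an 8-bit RGB image.

    One of hue / saturation / value is chosen uniformly (or forced).  Hue
    shifts are drawn on the circular 0–180 scale and wrap modulo 180;
    saturation and value scale factors are drawn from their ranges and the
    channels clamped to the valid range.  Conversion back to 8-bit rounds
    half-up.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValueError("expected (h, w, 3) uint8 RGB image")
    mode = force_mode or ("hue", "sat", "val")[rng.integers(0, 3)]
    hsv = skcolor.rgb2hsv(image / 255.0)  # h in [0,1] == 0-360 degrees
    if mode == "hue":
        shift = rng.uniform(*config.hue_shift_range)  # on the 0-180 scale
        h180 = (hsv[:, :, 0] * 180.0 + shift) % 180.0
        hsv[:, :, 0] = h180 / 180.0
        param = shift
    elif mode == "sat":
        factor = rng.uniform(*config.sat_scale_range)
        hsv[:, :, 1] = np.clip(hsv[:, :, 1] * factor, 0.0, 1.0)
        param = factor
    elif mode == "val":
        factor = rng.uniform(*config.val_scale_range)
        hsv[:, :, 2] = np.clip(hsv[:, :, 2] * factor, 0.0, 1.0)
        param = factor
    else:
        raise ValueError(f"unknown HSV mode {mode!r}")
    rgb = skcolor.hsv2rgb(hsv) * 255.0
    out = np.clip(np.floor(rgb + 0.5), 0, 255).astype(np.uint8)
    if return_mode:
        return out, mode, param
    return out
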