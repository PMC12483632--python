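"""Data pipeline: loading, stratified splitting, preprocessing, augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from toothmark.data import (
    BackboneInputSpec,
    GeometricAugConfig,
    HsvAugConfig,
    ImageBank,
    SplitSpec,
    augment_geometric,
    augment_hsv,
    largest_remainder_allocation,
    load_bank,
    resize_normalize,
    stratified_split,
)
from toothmark.taxa import TAXA


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def test_load_bank_from_directory_and_manifest_agree(small_sep1_root):
    from_dir = load_bank(small_sep1_root)
    from_manifest = load_bank(small_sep1_root / "manifest.csv")
    assert [r.mark_id for r in from_dir.records] == [
        r.mark_id for r in from_manifest.records
    ]
    assert [r.taxon for r in from_dir.records] == [
        r.taxon for r in from_manifest.records
    ]


def test_load_bank_records_sorted_by_taxon_then_id(small_sep1_root):
    bank = load_bank(small_sep1_root)
    keys = [(r.taxon.value, r.mark_id) for r in bank.records]
    assert keys == sorted(keys)


def test_empty_directory_is_an_error(tmp_path):
    with pytest.raises(ValueError, match="no taxon subdirectories"):
        load_bank(tmp_path)


def test_unknown_taxon_directory_is_named_in_error(tmp_path):
    (tmp_path / "wolf").mkdir()
    with pytest.raises(ValueError, match="wolf"):
        load_bank(tmp_path)


def test_duplicate_mark_ids_rejected(default_count_records):
    records = default_count_records.records
    with pytest.raises(ValueError, match="duplicate"):
        ImageBank(records + (records[0],))


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

def test_default_bank_split_sizes(default_count_records):
    train, val, test = stratified_split(default_count_records, SplitSpec(seed=0))
    assert (len(train), len(val), len(test)) == (907, 194, 195)


def test_split_partitions_are_disjoint_and_exhaustive(default_count_records):
    parts = stratified_split(default_count_records, SplitSpec(seed=3))
    ids = [r.mark_id for p in parts for r in p.records]
    assert len(ids) == len(default_count_records)
    assert len(set(ids)) == len(ids)


def test_split_is_deterministic_given_seed(default_count_records):
    a = stratified_split(default_count_records, SplitSpec(seed=7))
    b = stratified_split(default_count_records, SplitSpec(seed=7))
    for pa, pb in zip(a, b):
        assert [r.mark_id for r in pa.records] == [r.mark_id for r in pb.records]
    c = stratified_split(default_count_records, SplitSpec(seed=8))
    assert any(
        [r.mark_id for r in pa.records] != [r.mark_id for r in pc.records]
        for pa, pc in zip(a, c)
    )


def test_per_class_train_shares_within_one_of_quota(default_count_records):
    """Largest-remainder stratification: train counts sum to 907 and each
    class's train share is within one record of 0.70 x class size."""
    train, _, _ = stratified_split(default_count_records, SplitSpec(seed=0))
    counts = train.class_counts()
    assert sum(counts.values()) == 907
    full = default_count_records.class_counts()
    for taxon in TAXA:
        assert abs(counts[taxon] - 0.70 * full[taxon]) <= 1


def test_tiny_class_rejected(small_sep1_root):
    bank = load_bank(small_sep1_root)
    crocodile_only_two = ImageBank(
        tuple(
            r for r in bank.records
            if r.taxon.value != "crocodile" or r.mark_id.endswith(("0000", "0001"))
        )
    )
    with pytest.raises(ValueError, match="crocodile"):
        stratified_split(crocodile_only_two, SplitSpec(seed=0))


def test_train_only_split_variant(small_sep1_root):
    bank = load_bank(small_sep1_root)
    train, val, test = stratified_split(bank, SplitSpec(fractions=(1.0, 0.0, 0.0)))
    assert len(train) == len(bank) and len(val) == 0 and len(test) == 0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    counts=st.lists(st.integers(min_value=3, max_value=400), min_size=4, max_size=4),
    frac=st.floats(min_value=0.3, max_value=0.9),
)
def test_largest_remainder_allocation_properties(counts, frac):
    by_taxon = dict(zip(TAXA, counts))
    total_target = int(np.floor(frac * sum(counts) + 0.5))
    floors = sum(int(np.floor(frac * c)) for c in counts)
    if not floors <= total_target <= sum(counts):
        return  # infeasible target for this fraction
    alloc = largest_remainder_allocation(by_taxon, frac, total_target)
    assert sum(alloc.values()) == total_target
    for taxon in TAXA:
        assert abs(alloc[taxon] - frac * by_taxon[taxon]) <= 1


# ---------------------------------------------------------------------------
# resize / normalize
# ---------------------------------------------------------------------------

def test_resize_shape_contract():
    out = resize_normalize(
        np.zeros((448, 448, 3), np.uint8), BackboneInputSpec("standin", 224, "unit")
    )
    assert out.shape == (224, 224, 3)


def test_constant_image_unit_scaling():
    out = resize_normalize(
        np.full((64, 64, 3), 51, np.uint8), BackboneInputSpec("standin", 64, "unit")
    )
    assert np.allclose(out, 51 / 255)


def test_resize_at_target_side_is_identity():
    img = (np.arange(64 * 64 * 3) % 251).reshape(64, 64, 3).astype(np.uint8)
    out = resize_normalize(img, BackboneInputSpec("standin", 64, "unit"))
    assert np.array_equal(out, img / 255.0)


def test_unit_normalization_round_trip():
    img = np.random.default_rng(0).integers(0, 256, (32, 32, 3)).astype(np.uint8)
    out = resize_normalize(img, BackboneInputSpec("standin", 32, "unit"))
    assert np.array_equal(np.rint(out * 255).astype(np.uint8), img)


def test_non_rgb_input_rejected():
    with pytest.raises(ValueError, match="RGB"):
        resize_normalize(np.zeros((64, 64)), BackboneInputSpec())


def test_named_backbone_side_contract():
    with pytest.raises(ValueError, match="299"):
        BackboneInputSpec("xception", 224, "imagenet_tf")


# ---------------------------------------------------------------------------
# geometric augmentation
# ---------------------------------------------------------------------------

def test_zero_range_geometric_config_is_identity(rng):
    img = np.random.default_rng(1).integers(0, 256, (40, 40, 3)).astype(np.uint8)
    config = GeometricAugConfig(rotation_deg=0.0, shift_frac=0.0, hflip=False)
    assert np.array_equal(augment_geometric(img, config, rng), img)


def test_exact_fraction_shift_relocates_pixel():
    img = np.zeros((20, 20, 3), np.uint8)
    img[10, 5] = 255

    class _Stub:
        def __init__(self):
            self.uniform_calls = 0

        def uniform(self, lo, hi):
            self.uniform_calls += 1
            # angle, dy, dx are drawn in that order
            return 0.0 if self.uniform_calls == 1 else (0.2 if self.uniform_calls == 2 else 0.0)

        def random(self):
            return 1.0  # no flip

    out = augment_geometric(img, GeometricAugConfig(), _Stub())
    assert out[14, 5, 0] == 255 and out[10, 5, 0] == 0


def test_geometric_augmentation_preserves_shape(rng):
    img = np.random.default_rng(2).integers(0, 256, (33, 47, 3)).astype(np.uint8)
    for _ in range(5):
        assert augment_geometric(img, GeometricAugConfig(), rng).shape == img.shape


# ---------------------------------------------------------------------------
# HSV augmentation
# ---------------------------------------------------------------------------

def test_gray_image_hue_shift_is_bit_exact_identity(rng):
    gray = np.full((16, 16, 3), 77, np.uint8)
    for _ in range(10):
        assert np.array_equal(
            augment_hsv(gray, HsvAugConfig(), rng, force_mode="hue"), gray
        )


def test_forced_value_scale_on_constant_gray():
    class _Stub:
        def uniform(self, lo, hi):
            return 0.8

    out = augment_hsv(np.full((8, 8, 3), 100, np.uint8), HsvAugConfig(), _Stub(), force_mode="val")
    assert np.array_equal(out, np.full((8, 8, 3), 80, np.uint8))


def test_identity_parameters_round_trip_within_one_level(rng):
    img = np.random.default_rng(3).integers(0, 256, (24, 24, 3)).astype(np.uint8)

    class _Stub:
        def uniform(self, lo, hi):
            return 0.0

    out = augment_hsv(img, HsvAugConfig(), _Stub(), force_mode="hue")
    assert np.abs(out.astype(int) - img.astype(int)).max() <= 1


def test_exactly_one_attribute_modified_per_call(rng):
    """Saturated test image: each mode leaves the other two HSV channels
    within rounding distance while moving its own."""
    from skimage import color as skcolor

    img = np.zeros((12, 12, 3), np.uint8)
    img[:, :, 0] = 200
    img[:, :, 1] = 60
    img[:, :, 2] = 40
    base = skcolor.rgb2hsv(img / 255.0)
    for mode, channel in (("hue", 0), ("sat", 1), ("val", 2)):
        out, got_mode, param = augment_hsv(
            img, HsvAugConfig(), np.random.default_rng(5), force_mode=mode, return_mode=True
        )
        assert got_mode == mode
        hsv = skcolor.rgb2hsv(out / 255.0)
        for other in {0, 1, 2} - {channel}:
            assert np.abs(hsv[:, :, other] - base[:, :, other]).max() < 0.02


def test_hsv_parameters_stay_in_ranges(rng):
    img = np.random.default_rng(4).integers(0, 256, (8, 8, 3)).astype(np.uint8)
    for _ in range(300):
        _, mode, param = augment_hsv(img, HsvAugConfig(), rng, return_mode=True)
        if mode == "hue":
            assert -10.0 <= param <= 10.0
        else:
            assert 0.8 <= param <= 1.2


def test_hsv_rejects_non_uint8():
    with pytest.raises(ValueError, match="uint8"):
        augment_hsv(np.zeros((4, 4, 3)), HsvAugConfig(), np.random.default_rng(0))
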