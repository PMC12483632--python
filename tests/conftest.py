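"""Shared fixtures: small synthetic banks generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from toothmark.data import ImageBank, load_bank
from toothmark.synthetic import DEFAULT_COUNTS, BankConfig, MarkRecord, generate_bank
from toothmark.taxa import TAXA


@pytest.fixture(scope="session")
def small_sep1_bank(tmp_path_factory) -> ImageBank:
    """Separability-1 bank, 12 images per class, 64x64."""
    root = tmp_path_factory.mktemp("bank_sep1")
    generate_bank(
        BankConfig(
            per_class_counts={t: 12 for t in TAXA},
            size_range=(64, 64),
            separability=1.0,
            seed=11,
        ),
        root,
    )
    return load_bank(root)


@pytest.fixture(scope="session")
def small_sep1_root(tmp_path_factory):
    root = tmp_path_factory.mktemp("bank_sep1_b")
    generate_bank(
        BankConfig(
            per_class_counts={t: 6 for t in TAXA},
            size_range=(64, 96),
            separability=1.0,
            seed=13,
        ),
        root,
    )
    return root


@pytest.fixture()
def default_count_records() -> ImageBank:
    """In-memory bank with the reference per-class counts (no files)."""
    from pathlib import Path

    records = []
    for taxon in TAXA:
        for i in range(DEFAULT_COUNTS[taxon]):
            records.append(
                MarkRecord(
                    f"{taxon.value}_{i:04d}", taxon,
                    Path(f"virtual/{taxon.value}/{i:04d}.png"), (64, 64),
                )
            )
    return ImageBank(tuple(records))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
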