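"""Stratified 70/15/15 splitting and episodic sampling.

Shows the split arithmetic on the reference per-class counts
(124/364/544/264, total 1296) and the shape of few-shot batches and
support/query episodes under the named presets.
"""

from pathlib import Path

import numpy as np

from toothmark import (
    DEFAULT_COUNTS,
    ImageBank,
    MarkRecord,
    PRESETS,
    SplitSpec,
    TAXA,
    sample_episode,
    sample_fssl_epoch,
    stratified_split,
)

# An in-memory bank with the reference counts (no image files needed
# for split arithmetic).
records = tuple(
    MarkRecord(f"{t.value}_{i:04d}", t, Path(f"virtual/{t.value}/{i}.png"), (64, 64))
    for t in TAXA
    for i in range(DEFAULT_COUNTS[t])
)
bank = ImageBank(records)
train, val, test = stratified_split(bank, SplitSpec(seed=0))
print(f"bank of {len(bank)} -> train {len(train)} / val {len(val)} / test {len(test)}")
for taxon in TAXA:
    print(
        f"  {taxon.value:10s} train {train.class_counts()[taxon]:3d}"
        f"  (quota {0.70 * DEFAULT_COUNTS[taxon]:6.1f})"
    )

rng = np.random.default_rng(0)
batches = sample_fssl_epoch(train, PRESETS["fssl-low"], rng)
print(f"\nfssl-low epoch: {len(batches)} batches of {len(batches[0].records)} images")

episode = sample_episode(train, PRESETS["maml-low"], rng)
print(f"maml-low episode: support {len(episode.support)}, query {len(episode.query)}")

# Train count 907 matches round-half-up(0.70 * 1296); each class's train
# share is within one record of 70% of its size.  A 4-way 5-shot batch
# holds 20 images; a 3-query episode adds 12 query images.
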