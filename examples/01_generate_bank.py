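"""Generate a synthetic tooth-mark bank and inspect its structure.

Builds a small four-class bank (crocodile, hyena, leopard, lion) with
unbalanced counts, then loads it back and prints the per-class record
counts and a few native image sizes.
"""

import tempfile
from pathlib import Path

from toothmark import BankConfig, TAXA, TaxonLabel, generate_bank, load_bank

with tempfile.TemporaryDirectory() as tmp:
    config = BankConfig(
        per_class_counts={
            TaxonLabel.CROCODILE: 12,
            TaxonLabel.HYENA: 36,
            TaxonLabel.LEOPARD: 54,
            TaxonLabel.LION: 26,
        },
        size_range=(64, 128),
        separability=1.0,
        seed=0,
    )
    records = generate_bank(config, Path(tmp) / "bank")
    bank = load_bank(Path(tmp) / "bank")

    print(f"bank of {len(bank)} marks")
    for taxon, count in bank.class_counts().items():
        print(f"  {taxon.value:10s} {count:3d} records")
    sizes = sorted({r.native_size for r in records})
    print(f"native sizes span {sizes[0]} .. {sizes[-1]} (h, w) pixels")

# The per-class counts mirror the unbalanced structure of a real mark
# bank; native sizes vary, so every downstream model resizes its input.
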