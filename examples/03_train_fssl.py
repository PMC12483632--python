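"""Train a supervised few-shot (FSSL) classifier on a synthetic bank.

Generates a separable bank, trains the SE-residual head on a frozen
standin backbone under the 5-shot/40-task preset, and prints the test
classification report.
"""

import tempfile
from pathlib import Path

import numpy as np

from toothmark import (
    BankConfig,
    FewShotClassifier,
    HeadSpec,
    OptimizerSpec,
    ShotTaskConfig,
    SplitSpec,
    StandinBackbone,
    TAXA,
    confusion,
    evaluate_model,
    generate_bank,
    load_bank,
    render_report,
    report,
    stratified_split,
    train_fssl,
)

with tempfile.TemporaryDirectory() as tmp:
    generate_bank(
        BankConfig(
            per_class_counts={t: 40 for t in TAXA},
            size_range=(64, 64),
            separability=1.0,
            seed=0,
        ),
        Path(tmp) / "bank",
    )
    train_bank, val_bank, test_bank = stratified_split(
        load_bank(Path(tmp) / "bank"), SplitSpec(seed=1)
    )

    model = FewShotClassifier(
        StandinBackbone(64, seed=0), HeadSpec(variant="complex"), seed=1
    )
    history = train_fssl(
        model, train_bank, val_bank,
        ShotTaskConfig.preset("fssl-low"),
        OptimizerSpec("adam", 1e-3),
        rng=np.random.default_rng(42),
        max_epochs=10,
    )
    accuracy, preds, labels = evaluate_model(model, test_bank)
    print(f"trained {len(history)} epochs (best {history.best_epoch})")
    print(f"test accuracy {accuracy:.3f} on {len(test_bank)} held-out marks\n")
    print(render_report(report(confusion(labels, preds)), "text"))

# On a separability-1 bank the head separates the four synthetic classes
# essentially perfectly; per-class F1 near 1.00 shows each taxon's
# signature is being recovered, not just the majority class.
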