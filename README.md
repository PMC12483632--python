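# toothmark

Few-shot and meta-learning classification of carnivore tooth marks on
bone, for taphonomists who need to know *which* carnivore chewed a bone
— and how much to trust the answer.

Tooth pits and scores left by crocodiles, hyenas, leopards and lions
carry taxon-specific signatures, but reference image banks are small
and unbalanced (a 1296-mark bank splits 124/364/544/264 across the four
taxa), which starves conventional deep-learning classifiers. This
package implements a dual few-shot framework for that setting:

* **FSSL** — few-shot supervised learning: standard transfer-learning
  optimization over *n-way k-shot* class-balanced mini-batches (every
  batch holds `k` examples of each of the 4 taxa; an epoch is `n_tasks`
  such batches).
* **MAML** — model-agnostic meta-learning: episodic training with a
  support set for inner-loop adaptation and a query set for the outer
  meta-gradient,

  θ′ = θ − α ∇<sub>θ</sub> L<sub>support</sub>(θ),  θ ← θ − β ∇<sub>θ</sub> L<sub>query</sub>(θ′),

  where the outer gradient flows *through* the inner step (second
  order; a first-order switch is available).

Both regimes train the same classification head — two residual blocks
of depthwise-separable convolutions with squeeze-and-excitation channel
gates, then GAP → dense(512) → dropout → batch-norm → softmax(4) — on a
frozen convolutional feature extractor. A simpler baseline head (one
512-filter convolution) is also provided. Trained models combine into
per-regime soft-voting ensembles weighted by test accuracy
(w<sub>i</sub> = acc<sub>i</sub> / Σ acc), and a mark's attribution is
**reliable** only when the FSSL and MAML ensembles agree on the arg-max
taxon with both probabilities above 0.70 — otherwise it is flagged
*interpretation with caution*.

Because the real image bank is an external download, the package ships
a synthetic bank generator with the same statistical structure (four
classes with controllable signatures and separability, unbalanced
counts, variable native sizes), so the whole pipeline is testable
end-to-end offline. There is no deep-learning framework dependency: the
package includes a small numpy reverse-mode autodiff engine with
higher-order gradients (needed for the second-order meta-gradient).

## Worked example

```python
import numpy as np
from toothmark import (
    BankConfig, FewShotClassifier, HeadSpec, MamlConfig, SplitSpec,
    StandinBackbone, TAXA, evaluate_model, generate_bank, load_bank,
    stratified_split, train_maml,
)

generate_bank(
    BankConfig(per_class_counts={t: 40 for t in TAXA},
               size_range=(64, 64), separability=1.0, seed=0),
    "bank",
)
train_bank, val_bank, test_bank = stratified_split(load_bank("bank"), SplitSpec(seed=1))
model = FewShotClassifier(StandinBackbone(64, seed=0), HeadSpec("complex"), seed=1)
train_maml(model, train_bank, val_bank, MamlConfig(),
           rng=np.random.default_rng(42), max_epochs=8)
accuracy, _, _ = evaluate_model(model, test_bank)
print(f"post-adaptation test accuracy {accuracy:.3f}")
```

prints

```
post-adaptation test accuracy 1.000
```

— on a separability-1 synthetic bank the meta-learned head separates
the four signatures perfectly after a single support-episode
adaptation; on a separability-0 bank (identical class distributions)
the same run lands at chance (0.25).

Rebuilding a published-style report from printed per-class metrics:

```python
from toothmark import render_report, report_from_rates
rep = report_from_rates(precisions=[0.94, 0.85, 0.91, 0.74],
                        recalls=[0.71, 0.81, 0.85, 0.97],
                        supports=[21, 54, 82, 38])
print(render_report(rep, "text"))
```

```
                  precision  recall  F1 score  support
crocodile              0.94    0.71      0.81       21
hyena                  0.85    0.81      0.83       54
leopard                0.91    0.85      0.88       82
lion                   0.74    0.97      0.84       38
accuracy                                 0.85      195
macro-average          0.86    0.84      0.84      195
weighted average       0.86    0.85      0.85      195
```

Accuracy falls out of the identity *accuracy = support-weighted mean
recall*; the macro row is the unweighted per-class mean. The
`examples/` directory holds six short scripts, one per capability
(bank generation, splitting/episodes, FSSL, MAML with a
finite-difference meta-gradient check, reports, ensemble verdicts).

A thin CLI mirrors the library for shell use:

```sh
toothmark synth --out bank --counts 124,364,544,264 --separability 1.0 --seed 0
toothmark split bank --out splits.csv
toothmark train-fssl --bank bank --preset fssl-low --seed 1
toothmark train-maml --bank bank --preset maml-low --seed 1
toothmark evaluate runs/<run-id>/checkpoint.npz bank
toothmark grid --config template.yaml --optimizers adam,adagrad,sgd
```

## Layout

```
src/toothmark/      autodiff, layers, architectures, synthetic bank,
                    data pipeline, episodes, training, evaluation,
                    ensemble, config, cli
examples/           one narrative script per capability
tests/              pytest suite (unit, property and acceptance tests)
scripts/acceptance.py
docs/methods.md     model, conventions, parameter defaults, limitations
```
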