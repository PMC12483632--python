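"""Experiment configuration, run orchestration and the runs ledger.

``run_experiment`` ties the modules into one reproducible unit: load the
bank, split it 70/15/15, build the model, train under the requested
regime, evaluate on the test split, and write all artifacts under a run
directory named by the config hash and seed.  A machine-readable summary
row (model, architecture, optimizer, shot, task, accuracy, loss, F1) is
appended to a ledger CSV, mirroring the experiment-grid table shape.

A single global seed feeds every source of randomness through
independent derived streams (split, samplers, initialization,
augmentation), so partial reruns are reproducible.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .architectures import FewShotClassifier, HeadSpec, StandinBackbone, build_backbone
from .data import (
    GeometricAugConfig,
    HsvAugConfig,
    ImageBank,
    SplitSpec,
    load_bank,
    stratified_split,
)
from .episodes import PRESETS, ShotTaskConfig
from .evaluation import confusion, render_report, report
from .taxa import TAXA
from .training import (
    EarlyStopSpec,
    LrScheduleSpec,
    MamlConfig,
    OptimizerSpec,
    TrainHistory,
    evaluate_model,
    train_fssl,
    train_maml,
)

logger = logging.getLogger("toothmark")

__all__ = ["RunConfig", "run_experiment", "grid_run", "LEDGER_COLUMNS"]

LEDGER_COLUMNS = [
    "run_id",
    "model",
    "architecture",
    "optimizer",
    "shot",
    "task",
    "accuracy",
    "loss",
    "F1 score",
    "seed",
    "status",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one training run."""

    bank: str  # bank root directory or manifest CSV
    out_dir: str = "runs"
    regime: str = "fssl"  # "fssl" | "maml"
    backbone: str = "standin"
    head_variant: str = "complex"  # "complex" | "baseline"
    preset: str | None = None  # shot-task preset name; explicit values override
    k_shot: int | None = None
    n_tasks: int | None = None
    q_query: int | None = None
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    momentum: float = 0.9
    inner_lr: float = 0.01
    inner_steps: int = 1
    first_order: bool = False
    patience: int = 15
    lr_factor: float = 0.1
    lr_milestones: tuple[int, ...] = (40, 70)
    max_epochs: int = 100
    augment_geometric: bool = False
    augment_hsv: bool = False
    dropout_p: float = 0.5
    input_side: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.regime not in ("fssl", "maml"):
            raise ValueError(f"regime must be 'fssl' or 'maml', got {self.regime!r}")
        if self.head_variant not in ("complex", "baseline"):
            raise ValueError("head_variant must be 'complex' or 'baseline'")
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; valid: {sorted(PRESETS)}")
        OptimizerSpec(self.optimizer, self.learning_rate, self.momentum)  # validates

    # -- derived pieces -------------------------------------------------
    def shot_task(self) -> ShotTaskConfig:
        if self.preset is not None:
            base = PRESETS[self.preset]
        else:
            base = PRESETS["fssl-low" if self.regime == "fssl" else "maml-low"]
        return ShotTaskConfig(
            n_way=base.n_way,
            k_shot=self.k_shot if self.k_shot is not None else base.k_shot,
            n_tasks=self.n_tasks if self.n_tasks is not None else base.n_tasks,
            q_query=self.q_query if self.q_query is not None else base.q_query,
        )

    def optimizer_spec(self) -> OptimizerSpec:
        return OptimizerSpec(self.optimizer, self.learning_rate, self.momentum)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:10]

    def run_id(self) -> str:
        return f"{self.regime}-{self.backbone}-{self.config_hash()}-s{self.seed}"

    def run_dir(self) -> Path:
        return Path(self.out_dir) / self.run_id()

    # -- (de)serialization ----------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "lr_milestones" in data and data["lr_milestones"] is not None:
            data["lr_milestones"] = tuple(data["lr_milestones"])
        return cls(**data)


def _derive_seeds(seed: int) -> dict[str, int]:
    """Independent derived streams from one global seed."""
    ss = np.random.SeedSequence(seed)
    names = ("split", "backbone", "head", "sampler")
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def run_experiment(config: RunConfig) -> dict:
    """Split -> train -> evaluate; write checkpoint, history CSV and
    report TSV under the run directory; append a ledger row.

    Returns the ledger row as a dict (including test accuracy, final
    validation loss and macro F1).
    """
    seeds = _derive_seeds(config.seed)
    bank = load_bank(config.bank)
    train_bank, val_bank, test_bank = stratified_split(
        bank, SplitSpec(seed=seeds["split"])
    )
    backbone = build_backbone(config.backbone, config.input_side, seed=seeds["backbone"])
    model = FewShotClassifier(
        backbone,
        HeadSpec(variant=config.head_variant, dropout_p=config.dropout_p),
        seed=seeds["head"],
    )
    rng = np.random.default_rng(seeds["sampler"])
    stops = EarlyStopSpec(patience=config.patience)
    sched = LrScheduleSpec(factor=config.lr_factor, milestones=config.lr_milestones)
    geo = GeometricAugConfig() if config.augment_geometric else None
    hsv = HsvAugConfig() if config.augment_hsv else None
    shot_task = config.shot_task()

    if config.regime == "fssl":
        history = train_fssl(
            model, train_bank, val_bank, shot_task,
            config.optimizer_spec(), stops, sched, geo, hsv, rng,
            max_epochs=config.max_epochs,
        )
    else:
        maml = MamlConfig(
            inner_lr=config.inner_lr,
            inner_steps=config.inner_steps,
            meta_optimizer=config.optimizer_spec(),
            first_order=config.first_order,
            shot_task=shot_task,
        )
        history = train_maml(
            model, train_bank, val_bank, maml, stops, sched, geo, hsv, rng,
            max_epochs=config.max_epochs,
        )

    accuracy, preds, labels = evaluate_model(model, test_bank)
    model.test_accuracy = accuracy
    rep = report(confusion(labels, preds))
    best = history.best_epoch if history.best_epoch >= 0 else len(history) - 1
    val_loss = history.val_loss[best] if len(history) else float("nan")

    run_dir = config.run_dir()
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    model.save(run_dir / "checkpoint.npz")
    with open(run_dir / "history.csv", "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["epoch", "train_loss", "train_acc", "val_loss", "val_acc", "lr", "best"]
        )
        writer.writeheader()
        writer.writerows(history.to_rows())
    (run_dir / "report.tsv").write_text(render_report(rep, "tsv") + "\n")

    row = {
        "run_id": config.run_id(),
        "model": config.backbone,
        "architecture": "simple" if config.head_variant == "baseline" else "complex",
        "optimizer": config.optimizer,
        "shot": shot_task.k_shot,
        "task": shot_task.n_tasks,
        "accuracy": round(accuracy, 4),
        "loss": round(val_loss, 4),
        "F1 score": round(rep.macro[2], 4),
        "seed": config.seed,
        "status": "ok",
    }
    _append_ledger(Path(config.out_dir) / "ledger.csv", row)
    logger.info("run %s: accuracy=%.4f macro_f1=%.4f", row["run_id"], accuracy, rep.macro[2])
    return row


def _append_ledger(path: Path, row: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    new = not path.exists()
    with open(path, "a", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=LEDGER_COLUMNS)
        if new:
            writer.writeheader()
        writer.writerow(row)


def grid_run(
    template: RunConfig,
    axes: dict[str, list],
    resume: bool = True,
) -> list[dict]:
    """Cartesian product of config axes, executed sequentially.

    Per-run seeds derive from the template seed plus the run index.
    Completed runs (existing run directory with a report) are skipped
    when resuming; failures are recorded per row and the grid continues.
    """
    import itertools

    keys = sorted(axes)
    rows: list[dict] = []
    for index, combo in enumerate(itertools.product(*(axes[k] for k in keys))):
        config = dataclasses.replace(
            template, **dict(zip(keys, combo)), seed=template.seed + index
        )
        if resume and (config.run_dir() / "report.tsv").exists():
            logger.info("skipping completed run %s", config.run_id())
            with open(config.run_dir() / "ledger_row.json") as fh:
                rows.append(json.load(fh))
            continue
        try:
            row = run_experiment(config)
        except Exception as exc:  # noqa: BLE001 - record failure, continue grid
            row = {
                "run_id": config.run_id(),
                "model": config.backbone,
                "architecture": "simple" if config.head_variant == "baseline" else "complex",
                "optimizer": config.optimizer,
                "shot": config.shot_task().k_shot,
                "task": config.shot_task().n_tasks,
                "accuracy": "",
                "loss": "",
                "F1 score": "",
                "seed": config.seed,
                "status": f"error: {exc}",
            }
            _append_ledger(Path(config.out_dir) / "ledger.csv", row)
        config.run_dir().mkdir(parents=True, exist_ok=True)
        with open(config.run_dir() / "ledger_row.json", "w") as fh:
            json.dump(row, fh)
        rows.append(row)
    return rows
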