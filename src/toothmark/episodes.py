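"""Episodic sampling: FSSL class-balanced mini-batches and MAML
support/query episodes under the n-way k-shot / task-count presets.

The four named presets mirror the tested shot-task configurations:
``fssl-low`` (5-shot, 40 tasks), ``fssl-high`` (10-shot, 20 tasks),
``maml-low`` (5-shot, 40 tasks, 3 query per class) and ``maml-high``
(10-shot, 24 tasks, 3 query per class).  n-way is always the full class
count — all four carnivores are compared simultaneously in every episode,
so episodes differ only in which examples are drawn.

Small classes (the crocodile training split holds fewer records than
k_shot · n_tasks) use an exhaust-then-recycle policy: records are drawn
without replacement from a shuffled queue until the class is exhausted
within the epoch, after which the queue is reshuffled and reused; every
record therefore appears at least once per epoch whenever the epoch
demand exceeds the class size.  Engagements of the policy are logged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ImageBank
from .synthetic import MarkRecord
from .taxa import TAXA, TaxonLabel

__all__ = [
    "ShotTaskConfig",
    "PRESETS",
    "FewShotBatch",
    "Episode",
    "sample_fssl_epoch",
    "sample_episode",
    "export_composition_csv",
]


@dataclass(frozen=True)
class ShotTaskConfig:
    """n-way k-shot configuration for one training regime."""

    n_way: int = len(TAXA)
    k_shot: int = 5
    n_tasks: int = 40
    q_query: int = 0  # per class; > 0 only for the meta-learning regime

    def __post_init__(self):
        if min(self.n_way, self.k_shot, self.n_tasks) < 1 or self.q_query < 0:
            raise ValueError("shot-task parameters must be positive (q_query >= 0)")

    @classmethod
    def preset(cls, name: str) -> "ShotTaskConfig":
        try:
            return PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown preset {name!r}; expected one of {sorted(PRESETS)}"
            ) from None


PRESETS: dict[str, ShotTaskConfig] = {
    "fssl-low": ShotTaskConfig(k_shot=5, n_tasks=40),
    "fssl-high": ShotTaskConfig(k_shot=10, n_tasks=20),
    "maml-low": ShotTaskConfig(k_shot=5, n_tasks=40, q_query=3),
    "maml-high": ShotTaskConfig(k_shot=10, n_tasks=24, q_query=3),
}


@dataclass(frozen=True)
class FewShotBatch:
    """A class-balanced mini-batch: exactly k_shot records per class."""

    records: tuple[MarkRecord, ...]
    indices: tuple[int, ...]  # positions in the source bank


@dataclass(frozen=True)
class Episode:
    """Support/query sets for one task."""

    support: tuple[MarkRecord, ...]
    query: tuple[MarkRecord, ...]
    support_indices: tuple[int, ...]
    query_indices: tuple[int, ...]


class _ClassQueue:
    """Shuffled without-replacement queue that recycles when exhausted."""

    def __init__(self, members: np.ndarray, rng: np.random.Generator):
        self.members = np.asarray(members)
        self.rng = rng
        self.queue: list[int] = []
        self.recycles = 0

    def draw(self, k: int) -> list[int]:
        out: list[int] = []
        while len(out) < k:
            if not self.queue:
                self.queue = list(self.rng.permutation(self.members))
                self.recycles += 1
            out.append(int(self.queue.pop()))
        return out


def _check_classes(bank: ImageBank, config: ShotTaskConfig) -> dict[TaxonLabel, np.ndarray]:
    index = bank.class_index
    missing = [t.value for t in TAXA if not index[t]]
    if missing:
        raise ValueError(f"bank is missing class(es): {missing}")
    return {t: np.array(index[t], dtype=int) for t in TAXA}


def sample_fssl_epoch(
    bank: ImageBank,
    config: ShotTaskConfig,
    rng: np.random.Generator,
    log: dict | None = None,
) -> list[FewShotBatch]:
    """One epoch of n_tasks class-balanced batches (k_shot per class).

    Sampling is without replacement within the epoch until a class is
    exhausted, then its queue is reshuffled and recycled.  If ``log`` is
    given, the number of recycles per class is recorded under
    ``log['recycles']``.
    """
    index = _check_classes(bank, config)
    queues = {t: _ClassQueue(index[t], rng) for t in TAXA}
    batches: list[FewShotBatch] = []
    for _ in range(config.n_tasks):
        picks: list[int] = []
        for t in TAXA:
            picks.extend(queues[t].draw(config.k_shot))
        batches.append(
            FewShotBatch(tuple(bank.records[i] for i in picks), tuple(picks))
        )
    if log is not None:
        # first fill is not a "recycle": subtract the initial shuffle
        log["recycles"] = {
            t.value: max(0, queues[t].recycles - 1) for t in TAXA
        }
    return batches


def sample_episode(
    bank: ImageBank, config: ShotTaskConfig, rng: np.random.Generator
) -> Episode:
    """One support/query episode with exact per-class quotas.

    The support set needs k_shot distinct records per class (classes
    smaller than k_shot raise).  Support and query are disjoint whenever
    the class holds at least k_shot + q_query records; smaller classes
    fill the query quota by re-drawing from the support surplus.
    """
    index = _check_classes(bank, config)
    support: list[int] = []
    query: list[int] = []
    for t in TAXA:
        members = index[t]
        if members.size < config.k_shot:
            raise ValueError(
                f"class {t.value} has {members.size} record(s), fewer than "
                f"k_shot={config.k_shot}; support cannot be filled without replacement"
            )
        perm = rng.permutation(members)
        support.extend(int(i) for i in perm[: config.k_shot])
        if config.q_query:
            rest = perm[config.k_shot : config.k_shot + config.q_query]
            picks = list(int(i) for i in rest)
            while len(picks) < config.q_query:  # class too small: reuse support
                picks.append(int(perm[rng.integers(0, config.k_shot)]))
            query.extend(picks)
    return Episode(
        tuple(bank.records[i] for i in support),
        tuple(bank.records[i] for i in query),
        tuple(support),
        tuple(query),
    )


def export_composition_csv(items, path) -> None:
    """Audit export: one row per drawn record.

    ``items`` is a sequence of FewShotBatch and/or Episode objects; rows
    carry ``task_index,role,mark_id,taxon`` (role is ``batch`` for FSSL
    batches, ``support``/``query`` for episodes).
    """
    import csv
    from pathlib import Path

    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["task_index", "role", "mark_id", "taxon"])
        for task_index, item in enumerate(items):
            if isinstance(item, Episode):
                for rec in item.support:
                    writer.writerow([task_index, "support", rec.mark_id, rec.taxon.value])
                for rec in item.query:
                    writer.writerow([task_index, "query", rec.mark_id, rec.taxon.value])
            else:
                for rec in item.records:
                    writer.writerow([task_index, "batch", rec.mark_id, rec.taxon.value])
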