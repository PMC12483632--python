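"""Accuracy-weighted soft-voting ensembles and the dual-method
reliability rule for attributing marks on fossil specimens.

Each regime (FSSL, MAML) contributes one ensemble whose member weights
are proportional to the members' held-out test accuracies.  A mark's
attribution is *reliable* only when the two ensembles agree on the
arg-max taxon and both arg-max probabilities exceed the 0.70 threshold;
anything less is flagged *interpretation with caution* (the arg-max
taxon is still reported).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .taxa import TAXA, TaxonLabel

__all__ = [
    "MemberModel",
    "WeightedEnsemble",
    "ReliabilityVerdict",
    "RELIABILITY_THRESHOLD",
    "compute_weights",
    "ensemble_predict",
    "dual_verdict",
    "classify_marks",
    "render_mark_table",
]

RELIABILITY_THRESHOLD = 0.70


@dataclass(frozen=True)
class MemberModel:
    """One trained model contributing to a regime's ensemble.

    ``predictor`` maps a (h, w, 3) uint8 RGB image to a 4-probability
    vector in taxon order (any per-member preprocessing happens inside).
    """

    model_id: str
    regime: str  # "fssl" | "maml"
    test_accuracy: float
    predictor: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self):
        if self.regime not in ("fssl", "maml"):
            raise ValueError(f"regime must be 'fssl' or 'maml', got {self.regime!r}")
        if not (0.0 < self.test_accuracy <= 1.0):
            raise ValueError("test_accuracy must lie in (0, 1]")


def compute_weights(accuracies: Sequence[float]) -> np.ndarray:
    """Proportional (order-preserving) normalization of member accuracies."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size == 0:
        raise ValueError("at least one accuracy is required")
    if (acc <= 0).any():
        raise ValueError("accuracies must be positive")
    return acc / acc.sum()


@dataclass(frozen=True)
class WeightedEnsemble:
    members: tuple[MemberModel, ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        regimes = {m.regime for m in self.members}
        if len(regimes) != 1:
            raise ValueError(f"ensemble mixes regimes: {sorted(regimes)}")

    @property
    def regime(self) -> str:
        return self.members[0].regime

    @property
    def weights(self) -> np.ndarray:
        return compute_weights([m.test_accuracy for m in self.members])


def ensemble_predict(ensemble: WeightedEnsemble, image: np.ndarray) -> np.ndarray:
    """Accuracy-weighted soft vote: sum_i w_i · p_i(image), renormalized."""
    weights = ensemble.weights
    total = np.zeros(len(TAXA))
    for member, w in zip(ensemble.members, weights):
        try:
            p = np.asarray(member.predictor(image), dtype=float)
        except Exception as exc:  # noqa: BLE001 - name the failing member
            raise RuntimeError(
                f"member {member.model_id!r} failed to predict: {exc}"
            ) from exc
        if p.shape != (len(TAXA),) or not np.isclose(p.sum(), 1.0, atol=1e-6):
            raise ValueError(
                f"member {member.model_id!r} returned an invalid probability vector"
            )
        total += w * p
    return total / total.sum()


@dataclass(frozen=True)
class ReliabilityVerdict:
    best_taxon: TaxonLabel
    fssl_prob: float
    maml_prob: float
    status: str  # "reliable" | "caution"


def dual_verdict(
    fssl_probs: np.ndarray,
    maml_probs: np.ndarray,
    threshold: float = RELIABILITY_THRESHOLD,
) -> ReliabilityVerdict:
    """Reliable iff both ensembles pick the same taxon with probability
    strictly above the threshold; otherwise interpretation with caution.

    The FSSL arg-max taxon is reported as ``best_taxon`` even under
    caution (reliance is still placed on the ensemble classification).
    """
    f = np.asarray(fssl_probs, dtype=float)
    m = np.asarray(maml_probs, dtype=float)
    # tolerate rounded (printed) vectors whose entries sum near 1
    for name, v in (("fssl", f), ("maml", m)):
        if v.shape != (len(TAXA),) or (v < 0).any() or not np.isclose(v.sum(), 1.0, atol=0.02):
            raise ValueError(f"{name} probabilities are not a valid probability vector")
    fi, mi = int(f.argmax()), int(m.argmax())
    agree = fi == mi
    status = (
        "reliable"
        if agree and f[fi] > threshold and m[mi] > threshold
        else "caution"
    )
    return ReliabilityVerdict(TAXA[fi], float(f[fi]), float(m[mi]), status)


def classify_marks(
    marks: Sequence[tuple[str, np.ndarray]],
    fssl_ensemble: WeightedEnsemble,
    maml_ensemble: WeightedEnsemble,
    threshold: float = RELIABILITY_THRESHOLD,
) -> list[dict]:
    """Attribute a set of (mark_id, image) pairs with both ensembles.

    Returns one row per mark with the full probability vector per
    regime, the arg-max taxon, and the dual-method verdict.  A failing
    mark yields an ``error`` row; processing continues.
    """
    if fssl_ensemble.regime != "fssl" or maml_ensemble.regime != "maml":
        raise ValueError("pass the FSSL ensemble first and the MAML ensemble second")
    rows: list[dict] = []
    for mark_id, image in marks:
        try:
            pf = ensemble_predict(fssl_ensemble, image)
            pm = ensemble_predict(maml_ensemble, image)
            verdict = dual_verdict(pf, pm, threshold)
            rows.append(
                {
                    "mark_id": mark_id,
                    "fssl": pf,
                    "maml": pm,
                    "best_taxon": verdict.best_taxon.value,
                    "fssl_prob": verdict.fssl_prob,
                    "maml_prob": verdict.maml_prob,
                    "verdict": verdict.status,
                }
            )
        except Exception as exc:  # noqa: BLE001 - per-row error, keep going
            rows.append({"mark_id": mark_id, "error": str(exc)})
    return rows


def render_mark_table(rows: list[dict], path: str | Path | None = None) -> str:
    """TSV with columns mark_id, regime, the four taxa, argmax, verdict."""
    lines = [
        "\t".join(
            ["mark_id", "regime", *(t.value for t in TAXA), "argmax", "verdict"]
        )
    ]
    for row in rows:
        if "error" in row:
            lines.append(f"{row['mark_id']}\terror\t{row['error']}")
            continue
        for regime in ("fssl", "maml"):
            probs = row[regime]
            lines.append(
                "\t".join(
                    [
                        row["mark_id"],
                        regime,
                        *(f"{p:.3f}" for p in probs),
                        TAXA[int(np.argmax(probs))].value,
                        row["verdict"],
                    ]
                )
            )
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
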