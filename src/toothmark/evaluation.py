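"""Confusion matrices and per-class / macro / weighted
precision-recall-F1 classification reports.

Report layout mirrors the standard table shape: one row per taxon with
precision, recall, F1 and support, then accuracy, macro-average and
weighted-average rows.  All metrics are computed unrounded; two-decimal
rounding is applied only at rendering.

Zero-division convention: precision, recall or F1 is defined as 0 when
its denominator is 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from io import StringIO

import numpy as np

from .taxa import TAXA, TAXON_INDEX, TaxonLabel

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "ClassificationReport",
    "confusion",
    "report",
    "report_from_rates",
    "render_report",
]


def _as_index(labels) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, TaxonLabel):
            out.append(TAXON_INDEX[lab])
        elif isinstance(lab, str):
            out.append(TAXON_INDEX[TaxonLabel.from_name(lab)])
        else:
            i = int(lab)
            if not 0 <= i < len(TAXA):
                raise ValueError(f"label index {i} outside taxon range 0..{len(TAXA)-1}")
            out.append(i)
    return np.array(out, dtype=np.intp)


@dataclass(frozen=True)
class ConfusionMatrix:
    """counts[i, j] = records of true taxon i predicted as taxon j."""

    counts: np.ndarray  # (4, 4) nonnegative ints, axes in taxon order

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (len(TAXA), len(TAXA)) or (c < 0).any():
            raise ValueError("confusion matrix must be 4x4 with nonnegative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def support(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_csv(self, path) -> None:
        """True-taxon rows x predicted-taxon columns."""
        import csv
        from pathlib import Path

        with open(Path(path), "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["true\\pred", *(t.value for t in TAXA)])
            for taxon, row in zip(TAXA, np.asarray(self.counts)):
                writer.writerow([taxon.value, *(int(x) for x in row)])


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Tally a confusion matrix from paired label sequences.

    Labels may be TaxonLabel members, taxon names or integer indices in
    the fixed taxon order.
    """
    t = _as_index(true_labels)
    p = _as_index(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"label sequences differ in length: {t.size} vs {p.size}")
    k = len(TAXA)
    counts = np.bincount(t * k + p, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts)


@dataclass(frozen=True)
class ClassMetrics:
    taxon: TaxonLabel
    precision: float
    recall: float
    f1: float
    support: int


@dataclass(frozen=True)
class ClassificationReport:
    per_class: tuple[ClassMetrics, ...]
    accuracy: float
    macro: tuple[float, float, float]  # (precision, recall, f1)
    weighted: tuple[float, float, float]
    total_support: int


def _f1(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def _assemble(
    precisions: np.ndarray,
    recalls: np.ndarray,
    supports: np.ndarray,
    accuracy: float,
) -> ClassificationReport:
    f1s = np.array([_f1(p, r) for p, r in zip(precisions, recalls)])
    total = int(supports.sum())
    per_class = tuple(
        ClassMetrics(t, float(p), float(r), float(f), int(s))
        for t, p, r, f, s in zip(TAXA, precisions, recalls, f1s, supports)
    )
    macro = (float(precisions.mean()), float(recalls.mean()), float(f1s.mean()))
    w = supports / total
    weighted = (float(w @ precisions), float(w @ recalls), float(w @ f1s))
    return ClassificationReport(per_class, float(accuracy), macro, weighted, total)


def report(cm: ConfusionMatrix) -> ClassificationReport:
    """Full classification report from a confusion matrix."""
    counts = cm.counts.astype(float)
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    support = counts.sum(axis=1)
    predicted = counts.sum(axis=0)
    tp = np.diag(counts)
    precisions = np.divide(tp, predicted, out=np.zeros_like(tp), where=predicted > 0)
    recalls = np.divide(tp, support, out=np.zeros_like(tp), where=support > 0)
    accuracy = tp.sum() / counts.sum()
    return _assemble(precisions, recalls, support.astype(int), accuracy)


def report_from_rates(
    precisions, recalls, supports
) -> ClassificationReport:
    """Report reconstructed from printed per-class precision/recall/support.

    F1 follows from each precision/recall pair, and accuracy from the
    identity accuracy = support-weighted mean recall (the off-diagonal
    structure of the confusion matrix is not needed for any table row).
    """
    p = np.asarray(precisions, dtype=float)
    r = np.asarray(recalls, dtype=float)
    s = np.asarray(supports, dtype=int)
    if not (p.shape == r.shape == s.shape == (len(TAXA),)):
        raise ValueError(f"expected {len(TAXA)} per-class values")
    if s.sum() <= 0:
        raise ValueError("total support must be positive")
    accuracy = float((s * r).sum() / s.sum())
    return _assemble(p, r, s, accuracy)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    # two decimals, round half up (matches conventional table rendering,
    # e.g. a macro recall of 0.835 prints as 0.84)
    from decimal import ROUND_HALF_UP, Decimal

    return str(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def render_report(rep: ClassificationReport, fmt: str = "text") -> str:
    """Render a report as an aligned text table, TSV or JSON.

    Layout: per-class rows, then accuracy, macro-average and
    weighted-average rows; two-decimal rendering with trailing zeros.
    """
    if fmt == "json":
        payload = {
            "per_class": {
                m.taxon.value: {
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                    "support": m.support,
                }
                for m in rep.per_class
            },
            "accuracy": rep.accuracy,
            "macro": dict(zip(("precision", "recall", "f1"), rep.macro)),
            "weighted": dict(zip(("precision", "recall", "f1"), rep.weighted)),
            "total_support": rep.total_support,
        }
        return json.dumps(payload, indent=2)
    if fmt not in ("text", "tsv"):
        raise ValueError(f"unknown format {fmt!r}; expected 'text', 'tsv' or 'json'")

    rows: list[tuple[str, str, str, str, str]] = [
        ("", "precision", "recall", "F1 score", "support")
    ]
    for m in rep.per_class:
        rows.append(
            (m.taxon.value, _fmt(m.precision), _fmt(m.recall), _fmt(m.f1), str(m.support))
        )
    rows.append(("accuracy", "", "", _fmt(rep.accuracy), str(rep.total_support)))
    rows.append(("macro-average", *map(_fmt, rep.macro), str(rep.total_support)))
    rows.append(("weighted average", *map(_fmt, rep.weighted), str(rep.total_support)))

    if fmt == "tsv":
        return "\n".join("\t".join(r) for r in rows)
    widths = [max(len(r[i]) for r in rows) for i in range(5)]
    buf = StringIO()
    for r in rows:
        buf.write(
            "  ".join(
                (cell.ljust(widths[i]) if i == 0 else cell.rjust(widths[i]))
                for i, cell in enumerate(r)
            ).rstrip()
            + "\n"
        )
    return buf.getvalue()


def parse_tsv_report(text: str) -> ClassificationReport:
    """Re-parse a TSV rendering (round-trip at rendered precision)."""
    lines = [ln.split("\t") for ln in text.strip().split("\n")]
    per = {row[0]: row[1:] for row in lines[1:]}
    precisions = [float(per[t.value][0]) for t in TAXA]
    recalls = [float(per[t.value][1]) for t in TAXA]
    supports = [int(per[t.value][3]) for t in TAXA]
    rep = report_from_rates(precisions, recalls, supports)
    # keep the printed accuracy (computed from unrounded recalls upstream)
    return ClassificationReport(
        rep.per_class,
        float(per["accuracy"][2]),
        rep.macro,
        rep.weighted,
        rep.total_support,
    )
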