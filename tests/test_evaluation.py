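"""Classification reports: confusion arithmetic, averages, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from toothmark.evaluation import (
    ConfusionMatrix,
    confusion,
    parse_tsv_report,
    render_report,
    report,
    report_from_rates,
)
from toothmark.taxa import TAXA


# ---------------------------------------------------------------------------
# confusion
# ---------------------------------------------------------------------------

def test_perfect_predictions_give_diagonal_matrix(rng):
    labels = rng.integers(0, 4, 50)
    cm = confusion(labels, labels)
    assert np.array_equal(cm.counts, np.diag(np.bincount(labels, minlength=4)))


def test_single_predicted_class_gives_single_column(rng):
    labels = rng.integers(0, 4, 30)
    cm = confusion(labels, np.full(30, 2))
    assert cm.counts[:, [0, 1, 3]].sum() == 0
    assert cm.counts[:, 2].sum() == 30


def test_confusion_is_permutation_invariant(rng):
    t = rng.integers(0, 4, 40)
    p = rng.integers(0, 4, 40)
    perm = rng.permutation(40)
    assert np.array_equal(confusion(t, p).counts, confusion(t[perm], p[perm]).counts)


def test_confusion_accepts_taxon_names():
    cm = confusion(["lion", "hyena"], ["lion", "leopard"])
    assert cm.counts[3, 3] == 1 and cm.counts[1, 2] == 1


def test_out_of_range_label_rejected():
    with pytest.raises(ValueError, match="outside"):
        confusion([0, 5], [0, 1])
    with pytest.raises(ValueError, match="unknown taxon"):
        confusion(["wolf"], ["lion"])


def test_length_mismatch_rejected():
    with pytest.raises(ValueError, match="length"):
        confusion([0, 1], [0])


# ---------------------------------------------------------------------------
# report arithmetic
# ---------------------------------------------------------------------------

def test_empty_matrix_rejected():
    with pytest.raises(ValueError, match="empty"):
        report(ConfusionMatrix(np.zeros((4, 4), dtype=int)))


def test_zero_predicted_positives_precision_is_zero():
    counts = np.zeros((4, 4), dtype=int)
    counts[0, 1] = 5  # crocodiles all predicted hyena
    counts[1, 1] = 5
    counts[2, 2] = 5
    counts[3, 3] = 5
    rep = report(ConfusionMatrix(counts))
    assert rep.per_class[0].precision == 0.0
    assert rep.per_class[0].recall == 0.0
    assert rep.per_class[0].f1 == 0.0
    assert rep.accuracy == pytest.approx(0.75)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_report_identities_on_random_confusion_matrices(seed):
    gen = np.random.default_rng(seed)
    counts = gen.integers(0, 30, (4, 4))
    counts[np.arange(4), np.arange(4)] += 1  # nonempty rows
    rep = report(ConfusionMatrix(counts))
    support = counts.sum(axis=1)
    # accuracy equals the support-weighted mean recall
    recalls = np.array([m.recall for m in rep.per_class])
    assert rep.accuracy == pytest.approx((support * recalls).sum() / support.sum())
    assert rep.weighted[1] == pytest.approx(rep.accuracy)
    # macro F1 bounded by per-class extremes
    f1s = [m.f1 for m in rep.per_class]
    assert min(f1s) <= rep.macro[2] <= max(f1s)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_report_matches_sklearn_from_raw_labels(seed):
    """Brute-force oracle: metrics from raw label lists (via sklearn)
    equal metrics computed from the tallied confusion matrix."""
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    gen = np.random.default_rng(seed)
    t = gen.integers(0, 4, 120)
    p = gen.integers(0, 4, 120)
    rep = report(confusion(t, p))
    sk = sklearn_metrics.classification_report(
        t, p, labels=[0, 1, 2, 3], output_dict=True, zero_division=0
    )
    assert rep.accuracy == pytest.approx(sk["accuracy"])
    for i, taxon in enumerate(TAXA):
        assert rep.per_class[i].precision == pytest.approx(sk[str(i)]["precision"])
        assert rep.per_class[i].recall == pytest.approx(sk[str(i)]["recall"])
        assert rep.per_class[i].f1 == pytest.approx(sk[str(i)]["f1-score"])
    assert rep.macro[2] == pytest.approx(sk["macro avg"]["f1-score"])
    assert rep.weighted[0] == pytest.approx(sk["weighted avg"]["precision"])


def test_macro_f1_invariant_under_class_relabeling(rng):
    counts = rng.integers(1, 20, (4, 4))
    rep = report(ConfusionMatrix(counts))
    perm = rng.permutation(4)
    rep_perm = report(ConfusionMatrix(counts[np.ix_(perm, perm)]))
    assert rep.macro[2] == pytest.approx(rep_perm.macro[2])
    assert rep.accuracy == pytest.approx(rep_perm.accuracy)


def test_weighted_metrics_invariant_under_dataset_duplication(rng):
    counts = rng.integers(1, 20, (4, 4))
    rep = report(ConfusionMatrix(counts))
    rep2 = report(ConfusionMatrix(counts * 2))
    assert rep.weighted == pytest.approx(rep2.weighted)
    assert rep.macro == pytest.approx(rep2.macro)


# ---------------------------------------------------------------------------
# worked examples from the published per-class tables
# ---------------------------------------------------------------------------

FSSL_RESNET50 = dict(
    precisions=[0.85, 0.72, 0.94, 0.77],
    recalls=[0.52, 0.91, 0.82, 0.87],
    supports=[21, 54, 82, 38],
)
MAML_RESNET50 = dict(
    precisions=[0.94, 0.85, 0.91, 0.74],
    recalls=[0.71, 0.81, 0.85, 0.97],
    supports=[21, 54, 82, 38],
)


def test_fssl_worked_example_report_cells():
    rep = report_from_rates(**FSSL_RESNET50)
    text = render_report(rep, "tsv")
    rows = {line.split("\t")[0]: line.split("\t")[1:] for line in text.split("\n")[1:]}
    assert rows["crocodile"][2] == "0.65"
    assert rows["accuracy"][2] == "0.82"
    assert rows["macro-average"] == ["0.82", "0.78", "0.79", "195"]
    assert rows["weighted average"] == ["0.84", "0.82", "0.82", "195"]


def test_maml_worked_example_report_cells():
    rep = report_from_rates(**MAML_RESNET50)
    text = render_report(rep, "tsv")
    rows = {line.split("\t")[0]: line.split("\t")[1:] for line in text.split("\n")[1:]}
    assert rows["crocodile"][2] == "0.81"
    assert rows["leopard"][2] == "0.88"
    assert rows["accuracy"][2] == "0.85"
    assert rows["macro-average"][2] == "0.84"


def test_tsv_round_trip_preserves_rendered_values():
    rep = report_from_rates(**FSSL_RESNET50)
    parsed = parse_tsv_report(render_report(rep, "tsv"))
    assert render_report(parsed, "tsv") == render_report(rep, "tsv")


def test_json_rendering_covers_all_fields():
    import json

    rep = report_from_rates(**MAML_RESNET50)
    payload = json.loads(render_report(rep, "json"))
    assert set(payload) == {"per_class", "accuracy", "macro", "weighted", "total_support"}
    assert set(payload["per_class"]) == {t.value for t in TAXA}
    assert payload["total_support"] == 195


def test_unknown_render_format_rejected():
    rep = report_from_rates(**MAML_RESNET50)
    with pytest.raises(ValueError, match="format"):
        render_report(rep, "xml")


def test_confusion_csv_export(tmp_path, rng):
    cm = confusion(rng.integers(0, 4, 30), rng.integers(0, 4, 30))
    path = tmp_path / "cm.csv"
    cm.to_csv(path)
    lines = path.read_text().strip().split("\n")
    assert lines[0].endswith("crocodile,hyena,leopard,lion")
    parsed = np.array([[int(x) for x in line.split(",")[1:]] for line in lines[1:]])
    assert np.array_equal(parsed, cm.counts)
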