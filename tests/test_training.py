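"""Training loops: optimizers, schedules, inner/outer MAML updates."""

import numpy as np
import pytest

from toothmark import autodiff as ad
from toothmark.autodiff import Tensor
from toothmark.architectures import FewShotClassifier, HeadSpec, StandinBackbone
from toothmark.data import SplitSpec, stratified_split
from toothmark.episodes import ShotTaskConfig
from toothmark.training import (
    EarlyStopSpec,
    LrScheduleSpec,
    MamlConfig,
    OptimizerSpec,
    evaluate_model,
    inner_adapt,
    make_optimizer,
    meta_gradients,
    train_fssl,
    train_maml,
)


# ---------------------------------------------------------------------------
# specs and optimizers
# ---------------------------------------------------------------------------

def test_invalid_optimizer_kind_lists_valid_options():
    with pytest.raises(ValueError, match="adam, adagrad, sgd"):
        OptimizerSpec("rmsprop")


def test_lr_schedule_arithmetic():
    sched = LrScheduleSpec(factor=0.1, milestones=(5,))
    assert sched.lr_at(1e-3, 4) == pytest.approx(1e-3)
    assert sched.lr_at(1e-3, 5) == pytest.approx(1e-4)
    assert sched.lr_at(1e-3, 99) == pytest.approx(1e-4)
    two = LrScheduleSpec(factor=0.1, milestones=(2, 4))
    assert two.lr_at(1e-2, 4) == pytest.approx(1e-4)


@pytest.mark.parametrize(
    "kind,lr,steps",
    [("adam", 0.1, 150), ("adagrad", 0.5, 150), ("sgd", 0.05, 50)],
)
def test_each_optimizer_descends_a_quadratic(kind, lr, steps):
    spec = OptimizerSpec(kind, learning_rate=lr)
    opt = make_optimizer(spec)
    params = {"w": np.array([4.0, -3.0])}
    losses = []
    for _ in range(steps):
        grads = {"w": 2 * params["w"]}  # d/dw ||w||^2
        losses.append(float((params["w"] ** 2).sum()))
        opt.step(params, grads)
    assert losses[-1] < losses[0] * 0.1


# ---------------------------------------------------------------------------
# inner loop
# ---------------------------------------------------------------------------

def _quadratic_loss(target):
    return lambda p: ad.mul(
        ad.sum_(ad.pow_const(ad.sub(p["w"], Tensor(target)), 2)), Tensor(0.5)
    )


def test_inner_adapt_zero_lr_is_identity():
    p = {"w": Tensor(np.array([1.0, 2.0]), track=True)}
    adapted = inner_adapt(p, _quadratic_loss(np.zeros(2)), 0.0, 3)
    assert np.array_equal(adapted["w"].data, p["w"].data)


def test_inner_adapt_matches_closed_form_single_step():
    w0, wstar, lr = np.array([0.0, 0.0]), np.array([2.0, -1.0]), 0.1
    p = {"w": Tensor(w0, track=True)}
    adapted = inner_adapt(p, _quadratic_loss(wstar), lr, 1)
    assert np.allclose(adapted["w"].data, w0 + lr * (wstar - w0), atol=1e-12)


def test_inner_adapt_matches_closed_form_recursion_two_steps():
    w0, wstar, lr = np.array([0.3, -0.7]), np.array([2.0, -1.0]), 0.1
    p = {"w": Tensor(w0, track=True)}
    adapted = inner_adapt(p, _quadratic_loss(wstar), lr, 2)
    expected = wstar + (1 - lr) ** 2 * (w0 - wstar)
    assert np.allclose(adapted["w"].data, expected, atol=1e-12)


def test_inner_adapt_leaves_input_untouched():
    w0 = np.array([0.3, -0.7])
    p = {"w": Tensor(w0.copy(), track=True)}
    inner_adapt(p, _quadratic_loss(np.zeros(2)), 0.5, 4)
    assert np.array_equal(p["w"].data, w0)


def test_inner_adapt_raises_on_non_finite_loss():
    p = {"w": Tensor(np.array([1.0]), track=True)}
    bad = lambda q: ad.log(ad.sub(q["w"], Tensor(np.array([5.0]))))  # log(-4)
    with np.errstate(invalid="ignore"), pytest.raises(FloatingPointError):
        inner_adapt(p, lambda q: ad.sum_(bad(q)), 0.1, 1)


# ---------------------------------------------------------------------------
# meta gradients
# ---------------------------------------------------------------------------

def _logistic_toy():
    gen = np.random.default_rng(0)
    xs = gen.normal(size=(8,))
    ys = (xs * 1.5 - 0.3 > 0).astype(float)
    xq = gen.normal(size=(6,))
    yq = (xq * 1.5 - 0.3 > 0).astype(float)

    def nll(params_t, data):
        x, y = data
        z = ad.add(ad.mul(params_t["w"], Tensor(x)), params_t["b"])
        p = ad.sigmoid(z)
        eps = Tensor(1e-12)
        ll = ad.add(
            ad.mul(Tensor(y), ad.log(ad.add(p, eps))),
            ad.mul(Tensor(1 - y), ad.log(ad.add(ad.sub(Tensor(1.0), p), eps))),
        )
        return ad.neg(ad.mean_(ll))

    episode = ((xs, ys), (xq, yq))
    return nll, episode


def test_meta_gradient_matches_finite_differences():
    nll, episode = _logistic_toy()
    support = lambda p, ep: nll(p, ep[0])
    query = lambda p, ep: nll(p, ep[1])
    config = MamlConfig(inner_lr=0.05, inner_steps=2)
    theta = {"w": np.array(0.4), "b": np.array(-0.2)}
    _, grads = meta_gradients(theta, [episode], support, query, config)

    def query_loss_at(w, b):
        wrapped = {"w": Tensor(np.array(w), track=True), "b": Tensor(np.array(b), track=True)}
        adapted = inner_adapt(
            wrapped, lambda p: support(p, episode), config.inner_lr, config.inner_steps
        )
        return query(adapted, episode).item()

    h = 1e-6
    fd_w = (query_loss_at(0.4 + h, -0.2) - query_loss_at(0.4 - h, -0.2)) / (2 * h)
    fd_b = (query_loss_at(0.4, -0.2 + h) - query_loss_at(0.4, -0.2 - h)) / (2 * h)
    assert abs(grads["w"] - fd_w) / abs(fd_w) < 1e-4
    assert abs(grads["b"] - fd_b) / abs(fd_b) < 1e-4


def test_first_order_with_zero_inner_steps_is_plain_query_gradient():
    nll, episode = _logistic_toy()
    support = lambda p, ep: nll(p, ep[0])
    query = lambda p, ep: nll(p, ep[1])
    theta = {"w": np.array(0.4), "b": np.array(-0.2)}
    _, fo = meta_gradients(
        theta, [episode], support, query, MamlConfig(inner_steps=0, first_order=True)
    )
    wrapped = {k: Tensor(v, track=True) for k, v in theta.items()}
    plain = ad.grad(query(wrapped, episode), list(wrapped.values()))
    assert np.allclose(fo["w"], plain[0].data)
    assert np.allclose(fo["b"], plain[1].data)


def test_first_and_second_order_agree_for_tiny_inner_lr():
    nll, episode = _logistic_toy()
    support = lambda p, ep: nll(p, ep[0])
    query = lambda p, ep: nll(p, ep[1])
    theta = {"w": np.array(0.4), "b": np.array(-0.2)}
    _, so = meta_gradients(
        theta, [episode], support, query, MamlConfig(inner_lr=1e-6, inner_steps=1)
    )
    _, fo = meta_gradients(
        theta, [episode], support, query,
        MamlConfig(inner_lr=1e-6, inner_steps=1, first_order=True),
    )
    assert abs(fo["w"] - so["w"]) / abs(so["w"]) < 1e-3
    assert abs(fo["b"] - so["b"]) / abs(so["b"]) < 1e-3


def test_meta_gradients_are_deterministic():
    nll, episode = _logistic_toy()
    support = lambda p, ep: nll(p, ep[0])
    query = lambda p, ep: nll(p, ep[1])
    theta = {"w": np.array(0.4), "b": np.array(-0.2)}
    config = MamlConfig(inner_lr=0.05, inner_steps=1)
    l1, g1 = meta_gradients(theta, [episode], support, query, config)
    l2, g2 = meta_gradients(theta, [episode], support, query, config)
    assert l1 == l2
    assert np.array_equal(g1["w"], g2["w"])


# ---------------------------------------------------------------------------
# full loops on the small synthetic bank
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def split_small_bank(request):
    bank = request.getfixturevalue("small_sep1_bank")
    return stratified_split(bank, SplitSpec(seed=2))


def _fresh_model(seed=1):
    return FewShotClassifier(
        StandinBackbone(64, seed=0), HeadSpec(variant="complex"), seed=seed
    )


def test_fssl_short_run_learns_and_respects_patience(split_small_bank):
    train_bank, val_bank, test_bank = split_small_bank
    model = _fresh_model()
    history = train_fssl(
        model, train_bank, val_bank,
        ShotTaskConfig(k_shot=3, n_tasks=10),
        OptimizerSpec("adam", 1e-3),
        EarlyStopSpec(patience=5),
        LrScheduleSpec(milestones=(50,)),
        rng=np.random.default_rng(3),
        max_epochs=8,
    )
    assert len(history) <= 8
    assert history.best_epoch == int(np.argmin(history.val_loss))
    accuracy, _, _ = evaluate_model(model, test_bank)
    assert accuracy >= 0.5  # tiny bank, easy signal


def test_fssl_histories_reproducible_for_identical_seeds(split_small_bank):
    train_bank, val_bank, _ = split_small_bank
    histories = []
    for _ in range(2):
        model = _fresh_model(seed=7)
        histories.append(
            train_fssl(
                model, train_bank, val_bank,
                ShotTaskConfig(k_shot=3, n_tasks=5),
                OptimizerSpec("adam", 1e-3),
                rng=np.random.default_rng(11),
                max_epochs=3,
            )
        )
    assert histories[0].train_loss == histories[1].train_loss
    assert histories[0].val_loss == histories[1].val_loss


def test_fssl_recorded_lr_follows_schedule(split_small_bank):
    train_bank, val_bank, _ = split_small_bank
    model = _fresh_model()
    history = train_fssl(
        model, train_bank, val_bank,
        ShotTaskConfig(k_shot=3, n_tasks=5),
        OptimizerSpec("adam", 1e-3),
        EarlyStopSpec(patience=50),
        LrScheduleSpec(factor=0.1, milestones=(2,)),
        rng=np.random.default_rng(3),
        max_epochs=4,
    )
    assert history.lr[:2] == [1e-3, 1e-3]
    assert history.lr[2:] == [1e-4, 1e-4]


def test_fssl_empty_train_bank_rejected(split_small_bank):
    from toothmark.data import ImageBank

    _, val_bank, _ = split_small_bank
    with pytest.raises(ValueError, match="empty"):
        train_fssl(
            _fresh_model(), ImageBank(()), val_bank, ShotTaskConfig(), rng=np.random.default_rng(0)
        )


def test_maml_short_run_keeps_backbone_frozen_and_learns(split_small_bank):
    train_bank, val_bank, test_bank = split_small_bank
    model = _fresh_model()
    before = {k: v.copy() for k, v in model.backbone.params.items()}
    history = train_maml(
        model, train_bank, val_bank,
        # 1-shot keeps episodes valid in the 1-2 record validation classes
        MamlConfig(shot_task=ShotTaskConfig(k_shot=1, n_tasks=8, q_query=1)),
        rng=np.random.default_rng(5),
        max_epochs=6,
        val_episodes=2,
    )
    for key, value in before.items():
        assert np.array_equal(model.backbone.params[key], value)
    assert len(history) <= 6
    accuracy, _, _ = evaluate_model(model, test_bank)
    assert accuracy >= 0.5
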