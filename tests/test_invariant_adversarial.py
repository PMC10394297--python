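"""Gradient reversal, discriminators, center loss and their identities."""

import numpy as np
import pytest

from seizdg import autodiff as ad
from seizdg import (
    CategoryClassifier,
    ClassCenters,
    Discriminators,
    ValidationError,
    center_loss,
    gradient_reversal,
    one_hot_categories,
)
from seizdg.invariant_adversarial import (
    category_cls_loss_2,
    global_adversarial_loss,
    local_adversarial_loss,
)


# ---------------------------------------------------------------------------
# Gradient reversal
# ---------------------------------------------------------------------------


def test_grl_forward_is_identity(rng):
    x = rng.normal(size=(5, 4))
    assert np.array_equal(gradient_reversal(ad.Tensor(x), 0.3).data, x)


def test_grl_backward_scales_and_negates(rng):
    lam = 0.7
    w = rng.normal(size=(4, 2))
    x = ad.Tensor(rng.normal(size=(5, 4)), requires_grad=True)
    out = ad.matmul(gradient_reversal(x, lam), ad.Tensor(w)).sum()
    out.backward()
    plain = np.ones((5, 2)) @ w.T  # gradient without the reversal layer
    assert np.allclose(x.grad, -lam * plain, atol=1e-12)


def test_grl_zero_lambda_stops_upstream_gradients(rng):
    x = ad.Tensor(rng.normal(size=(3, 4)), requires_grad=True)
    out = (gradient_reversal(x, 0.0) * gradient_reversal(x, 0.0)).sum()
    out.backward()
    assert np.allclose(x.grad, 0.0)


# ---------------------------------------------------------------------------
# Adversarial losses
# ---------------------------------------------------------------------------


def _uniform_disc(dim, n_patients, rng):
    disc = Discriminators(dim, n_patients, rng)
    for p in disc.parameters():
        p.data[:] = 0.0
    return disc


def test_global_loss_uniform_and_perfect(rng):
    disc = _uniform_disc(4, 14, rng)
    f = ad.Tensor(rng.normal(size=(7, 4)))
    d = np.arange(7) % 14
    assert np.isclose(global_adversarial_loss(disc, f, d).item(), np.log(14), atol=1e-12)
    with pytest.raises(ValidationError):
        global_adversarial_loss(disc, f, np.array([0, 1, 2, 3, 4, 5, 14]))


def test_local_loss_uniform_is_twice_log_n_patients(rng):
    disc = _uniform_disc(4, 14, rng)
    f = ad.Tensor(rng.normal(size=(6, 4)))
    y = np.array([0, 1, 0, 1, 0, 1])
    d = np.arange(6) % 14
    val = local_adversarial_loss(disc, f, one_hot_categories(y), d).item()
    assert np.isclose(val, 2 * np.log(14), atol=1e-12)


def test_local_loss_single_class_batch_makes_other_branch_constant(rng):
    disc = Discriminators(4, 3, rng)
    y = np.zeros(5, dtype=int)  # everyone class 0 -> G_l2 sees zero vectors
    d = np.array([0, 1, 2, 0, 1])
    f1 = ad.Tensor(rng.normal(size=(5, 4)), requires_grad=True)
    f2 = ad.Tensor(rng.normal(size=(5, 4)), requires_grad=True)
    l1 = local_adversarial_loss(disc, f1, one_hot_categories(y), d)
    l2 = local_adversarial_loss(disc, f2, one_hot_categories(y), d)
    # G_l2's term is feature-independent (bias softmax only): the loss
    # difference comes from the G_l1 branch alone
    zero_in = ad.Tensor(np.zeros((5, 4)))
    bias_term = ad.softmax_cross_entropy(disc.g_l2(zero_in), d, reduction="sum").item() / 5
    direct1 = ad.softmax_cross_entropy(disc.g_l1(f1), d, reduction="sum").item() / 5
    assert np.isclose(l1.item(), direct1 + bias_term, atol=1e-10)
    assert not np.isclose(l1.item(), l2.item())


def test_true_vs_predicted_masks_differ_when_classifier_errs(rng):
    disc = Discriminators(4, 3, rng)
    f = ad.Tensor(rng.normal(size=(4, 4)))
    y = np.array([0, 0, 1, 1])
    d = np.array([0, 1, 2, 0])
    soft = np.array([[0.9, 0.1], [0.2, 0.8], [0.3, 0.7], [0.6, 0.4]])  # errs on 1 & 3
    hard_val = local_adversarial_loss(disc, f, one_hot_categories(y), d).item()
    soft_val = local_adversarial_loss(disc, f, soft, d).item()
    assert not np.isclose(hard_val, soft_val)


def test_local_loss_degenerates_to_twice_global_with_shared_discriminator(rng):
    """All-ones masks + G_l1 = G_l2 = G_g collapse the double sum to 2×global."""
    disc = Discriminators(4, 5, rng)
    state = disc.g_g.state_dict()
    disc.g_l1.load_state_dict(state)
    disc.g_l2.load_state_dict(state)
    f = ad.Tensor(rng.normal(size=(6, 4)))
    d = np.arange(6) % 5
    ones = np.ones((6, 2))
    val = local_adversarial_loss(disc, f, ones, d, normalized=False).item()
    assert np.isclose(val, 2 * global_adversarial_loss(disc, f, d).item(), atol=1e-10)


def test_one_hot_validation():
    oh = one_hot_categories(np.array([0, 1, 1]))
    assert oh.tolist() == [[1, 0], [0, 1], [0, 1]]
    with pytest.raises(ValidationError):
        one_hot_categories(np.array([0, 2]))


def test_adversarial_training_drives_discriminator_to_chance(rng):
    """Two linearly separable patient clusters: minimizing the GRL-coupled
    objective defeats the discriminator.  The dynamics use the standard
    stabilizers of adversarial alignment — batch-normalized features (so
    invariance is reached by nulling the between-cluster direction rather
    than by scale collapse) and a slower plain-SGD discriminator (a
    confident discriminator saturates the cross-entropy and freezes the
    feature gradient)."""
    final_accs = []
    for seed in range(5):
        srng = np.random.default_rng(seed)
        n = 400
        d = np.repeat([0, 1], n // 2)
        x = srng.normal(size=(n, 2)) + np.where(d[:, None] == 0, -2.0, 2.0)
        extractor = ad.Linear(2, 2, srng)
        bn = ad.BatchNorm(2)
        disc = ad.MLP([2, 8, 2], srng)
        opt_feat = ad.Adam([*extractor.parameters(), *bn.parameters()], lr=0.05)
        opt_disc = ad.SGD(disc.parameters(), lr=0.1)
        for _ in range(500):
            feats = bn(extractor(ad.Tensor(x)))
            ce = ad.softmax_cross_entropy(
                disc(gradient_reversal(feats, 1.0)), d, reduction="mean"
            )
            opt_feat.zero_grad()
            opt_disc.zero_grad()
            ce.backward()
            opt_feat.step()
            opt_disc.step()
        feats = bn(extractor(ad.Tensor(x)))
        acc = (np.argmax(disc(feats).data, axis=1) == d).mean()
        final_accs.append(acc)
    assert np.mean(final_accs) <= 0.65


# ---------------------------------------------------------------------------
# Center loss and the main classifier
# ---------------------------------------------------------------------------


def test_center_loss_values_and_sum_not_mean():
    centers = ClassCenters(2, 2)
    centers.centers[:] = 0.0
    y = np.array([0])
    at_center = center_loss(ad.Tensor(np.zeros((1, 2))), y, centers).item()
    assert at_center == 0.0
    # one sample at distance 2 -> 0.5 * 4 = 2
    one = center_loss(ad.Tensor(np.array([[2.0, 0.0]])), y, centers).item()
    assert one == 2.0
    # duplicating the sample doubles the loss (sum, no 1/M)
    two = center_loss(
        ad.Tensor(np.array([[2.0, 0.0], [2.0, 0.0]])), np.array([0, 0]), centers
    ).item()
    assert two == 4.0


def test_center_update_is_contractive(rng):
    centers = ClassCenters(2, 3)
    feats = rng.normal(loc=4.0, size=(50, 3))
    y = np.zeros(50, dtype=int)
    for _ in range(200):
        centers.update(feats, y, lr=0.05)
    assert np.allclose(centers.centers[0], feats.mean(axis=0), atol=0.2)
    assert np.allclose(centers.centers[1], 0.0)  # untouched class


def test_category_classifier_uniform_loss_and_tie_break(rng):
    clf = CategoryClassifier(6, rng)
    for p in clf.parameters():
        p.data[:] = 0.0
    f = ad.Tensor(rng.normal(size=(4, 6)))
    y = np.array([0, 1, 0, 1])
    feats, logits, loss = category_cls_loss_2(clf, f, y)
    assert np.isclose(loss.item(), np.log(2), atol=1e-12)
    # equal logits -> argmax resolves to class 0
    assert np.argmax(ad.softmax(logits), axis=1).tolist() == [0, 0, 0, 0]
    assert feats.shape == (4, clf.hidden_dim)
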