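"""The joint objective, the minimax realization, and the training loop."""

import dataclasses

import numpy as np
import pytest

from seizdg import autodiff as ad
from seizdg import (
    ConfigurationError,
    LossBreakdown,
    ModelConfig,
    FrontendConfig,
    SeizureDetector,
    TrainConfig,
    TrainedModel,
    TrainingDivergenceError,
    ValidationError,
    total_loss,
    train_model,
    grid_search,
    gradient_reversal,
)
from seizdg.training import _assemble


# ---------------------------------------------------------------------------
# Objective combination
# ---------------------------------------------------------------------------


def test_total_loss_hand_weighted_examples():
    zero = LossBreakdown(l_cls_2=0, l_cent=0, l_cls_1=0, l_p=0,
                         l_max_divergence=0, l_global=0, l_local=0)
    assert total_loss(zero) == 0.0
    only_cls2 = LossBreakdown(l_cls_2=1.0, l_cent=0, l_cls_1=0, l_p=0,
                              l_max_divergence=0, l_global=0, l_local=0)
    assert total_loss(only_cls2) == 1.0  # unit weight on the main classifier
    adv = LossBreakdown(l_cls_2=0, l_cent=0, l_cls_1=0, l_p=0,
                        l_max_divergence=0, l_global=1.0, l_local=0)
    assert np.isclose(total_loss(adv), -0.1)  # adversarial sign
    mixed = LossBreakdown(l_cls_2=2.0, l_cent=3.0, l_cls_1=1.0, l_p=0.5,
                          l_max_divergence=-2.0, l_global=1.5, l_local=0.5)
    assert np.isclose(total_loss(mixed), 2.0 + 0.1 * (3.0 + 1.0 + 0.5 - 2.0) - 0.1 * 2.0)


def test_total_loss_flags_nonfinite_terms():
    bad = LossBreakdown(l_cls_2=np.nan, l_cent=0.0)
    with pytest.raises(TrainingDivergenceError):
        total_loss(bad)


def test_absent_terms_drop_from_history_dict():
    parts = LossBreakdown(l_cls_2=1.0, l_cent=2.0, l_global=0.5)
    d = parts.as_dict()
    assert "l_local" not in d and "l_cls_1" not in d
    assert set(d) >= {"l_cls_2", "l_cent", "l_global", "l_sum"}


# ---------------------------------------------------------------------------
# Minimax realization
# ---------------------------------------------------------------------------


def test_grl_update_direction_equals_direct_maximization(rng):
    """On a toy linear discriminator, the GRL-trained discriminator update
    equals gradient descent on its own loss (= ascent on −λ·CE in the joint
    objective), while the feature parameters receive the −λ-scaled
    gradient."""
    x = rng.normal(size=(20, 3))
    d = (rng.uniform(size=20) > 0.5).astype(int)
    lam = 0.1

    w_feat = ad.Tensor(rng.normal(size=(3, 3)), requires_grad=True)
    w_disc = ad.Tensor(rng.normal(size=(3, 2)), requires_grad=True)
    feats = ad.matmul(ad.Tensor(x), w_feat)
    ce = ad.softmax_cross_entropy(ad.matmul(gradient_reversal(feats, lam), w_disc), d)
    ce.backward()
    grl_disc_grad = w_disc.grad.copy()
    grl_feat_grad = w_feat.grad.copy()

    w_feat2 = ad.Tensor(w_feat.data.copy(), requires_grad=True)
    w_disc2 = ad.Tensor(w_disc.data.copy(), requires_grad=True)
    feats2 = ad.matmul(ad.Tensor(x), w_feat2)
    ce2 = ad.softmax_cross_entropy(ad.matmul(feats2, w_disc2), d)
    ce2.backward()

    # discriminator: same descent direction on its cross-entropy
    assert np.allclose(grl_disc_grad, w_disc2.grad, atol=1e-12)
    # features: reversed and λ-scaled
    assert np.allclose(grl_feat_grad, -lam * w_feat2.grad, atol=1e-12)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


def test_single_patient_training_rejected(small_cohort, small_model_config):
    with pytest.raises(ConfigurationError):
        train_model(small_cohort[:1], TrainConfig(epochs=1), small_model_config)


def test_full_batch_one_step_per_epoch(trained_small):
    assert len(trained_small.history) == trained_small.train_config.epochs
    assert [row["epoch"] for row in trained_small.history] == list(
        range(trained_small.train_config.epochs)
    )
    # all seven loss terms present in the full variant
    assert {"l_cls_1", "l_p", "l_max_divergence", "l_cls_2", "l_cent",
            "l_global", "l_local", "l_sum"} <= set(trained_small.history[0])


def test_learning_happens_on_small_cohorts(small_model_config):
    """Final main-classifier loss below its initial value (majority of seeds)."""
    from seizdg import SyntheticCohortSpec, cohort_to_batches, generate_cohort

    wins = 0
    for seed in range(3):
        spec = SyntheticCohortSpec(
            n_patients=3, n_channels=3, seconds_per_class_per_patient=6, seed=seed
        )
        batches = cohort_to_batches(generate_cohort(spec))
        tm = train_model(batches, TrainConfig(epochs=25, seed=seed), small_model_config)
        wins += tm.history[-1]["l_cls_2"] < tm.history[0]["l_cls_2"]
    assert wins >= 2


def test_same_seed_reproduces_history_exactly(small_cohort, small_model_config):
    cfg = TrainConfig(epochs=5, seed=3)
    a = train_model(small_cohort[:2], cfg, small_model_config)
    b = train_model(small_cohort[:2], cfg, small_model_config)
    assert a.history[-1]["l_sum"] == b.history[-1]["l_sum"]
    x = small_cohort[2].samples[:10]
    assert np.array_equal(a.predict_proba(x), b.predict_proba(x))


def test_lambda_zero_reproduces_plain_classifier_training(small_cohort, small_model_config):
    """With λ = 0 the network parameters update exactly as in a run where
    only the main classification loss exists."""
    x, y, d, _ = _assemble(small_cohort[:2])
    x = x[:40]
    y = y[:40]
    d = d[:40]

    cfg = TrainConfig(epochs=1, seed=11, lambda_=0.0)
    model = SeizureDetector(small_model_config, 2, np.random.default_rng(5))
    ref = SeizureDetector(small_model_config, 2, np.random.default_rng(5))

    from seizdg.training import _combine_backward, _step_losses

    tensors, feats, _, _ = _step_losses(model, ad.Tensor(x), y, d, cfg)
    opt = ad.Adam(model.parameters(), lr=cfg.lr_network)
    opt.zero_grad()
    _combine_backward(tensors, 0.0, len(y)).backward()
    opt.step()

    from seizdg.invariant_adversarial import category_cls_loss_2
    from seizdg.feature_separation import recombine, split_features

    ref_params = [*ref.frontend.parameters(), *ref.classifier.parameters()]
    opt2 = ad.Adam(ref_params, lr=cfg.lr_network)
    f_all = ref.frontend(ad.Tensor(x))
    f_prime = recombine(split_features(f_all))
    _, _, loss = category_cls_loss_2(ref.classifier, f_prime, y)
    opt2.zero_grad()
    loss.backward()
    opt2.step()

    for p_model, p_ref in zip(
        [*model.frontend.parameters(), *model.classifier.parameters()], ref_params
    ):
        assert np.allclose(p_model.data, p_ref.data, atol=1e-6)

    # the discriminators still receive their own gradients under λ = 0
    tensors, _, _, _ = _step_losses(model, ad.Tensor(x), y, d, cfg)
    model.zero_grad()
    _combine_backward(tensors, 0.0, len(y)).backward()
    disc_grads = [p.grad for p in model.discriminators.parameters()]
    assert any(g is not None and np.abs(g).max() > 0 for g in disc_grads)


def test_variant_histories_contain_expected_terms(small_cohort, small_model_config):
    for variant, absent in [
        ("dann_only", "l_local"),
        ("mada_only", "l_global"),
        ("no_separation", "l_max_divergence"),
    ]:
        cfg = TrainConfig(epochs=2, seed=0, variant=variant)
        tm = train_model(small_cohort[:2], cfg, small_model_config)
        assert absent not in tm.history[0]


def test_save_load_round_trip_bit_identical(tmp_path, trained_small, small_cohort):
    trained_small.save(tmp_path / "model")
    back = TrainedModel.load(tmp_path / "model")
    x = small_cohort[2].samples[:16]
    assert np.array_equal(back.predict_proba(x), trained_small.predict_proba(x))
    assert back.history == trained_small.history


def test_grid_search_prefers_sane_learning_rate(small_model_config):
    from seizdg import SyntheticCohortSpec, cohort_to_batches, generate_cohort

    spec = SyntheticCohortSpec(
        n_patients=3, n_channels=3, seconds_per_class_per_patient=5,
        class_amplitude=4.0, background_rhythm_amp=0.5, patient_gain_sd=0.1,
        noise_level_spread=0.1, seizure_intensity_spread=0.1, seed=2,
    )
    batches = cohort_to_batches(generate_cohort(spec))
    base = TrainConfig(epochs=20, seed=0)
    best, table = grid_search(batches, {"lr_network": [0.005, 1000.0]}, base, small_model_config)
    assert len(table) == 2  # score table row count = grid cardinality
    assert best.lr_network == 0.005  # sabotaged configuration not selected

    single, table1 = grid_search(batches, {"lambda_": [0.1]}, base, small_model_config)
    assert single.lambda_ == 0.1 and len(table1) == 1
    with pytest.raises(ValidationError):
        grid_search(batches, {}, base, small_model_config)
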