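"""Class weights, weighted cross-entropy, augmentation, training contract."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from her2pss.classifier import (
    TrainConfig,
    augment,
    apply_dihedral,
    class_weights,
    forward,
    invert_dihedral,
    load_model,
    save_model,
    train,
    weighted_cross_entropy,
)
from her2pss.pyramid import PyramidConfig, sample_pss
from her2pss.synthetic import CoreSpec, generate_dataset


# -- class weights ---------------------------------------------------------


def test_equal_counts_give_unit_weights():
    np.testing.assert_allclose(class_weights([10, 10, 10, 10]), np.ones(4))


def test_weights_for_imbalanced_counts_match_direct_arithmetic():
    counts = np.array([242, 526, 314, 380])
    w = class_weights(counts)
    np.testing.assert_allclose(w, counts.sum() / (4 * counts), rtol=1e-12)
    np.testing.assert_allclose(
        w, [1.510330578512397, 0.6948669201520913, 1.1640127388535032,
            0.9618421052631578], rtol=1e-9,
    )
    assert (w * counts).sum() == pytest.approx(counts.sum(), rel=1e-12)


def test_weights_scale_invariant():
    np.testing.assert_allclose(
        class_weights([3, 5, 7, 9]), class_weights([6, 10, 14, 18])
    )


def test_empty_class_rejected_with_name():
    with pytest.raises(ValueError, match="2\\+"):
        class_weights([5, 5, 0, 5])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(1, 10_000), min_size=4, max_size=4))
def test_weight_count_identity(counts):
    """sum_c w_c n_c == M for the M/(C n_c) normalization."""
    counts = np.array(counts)
    assert float((class_weights(counts) * counts).sum()) == pytest.approx(
        counts.sum(), rel=1e-12
    )


# -- weighted cross-entropy ------------------------------------------------


def _one_hot(labels, n=4):
    eye = np.eye(n)
    return eye[np.asarray(labels)]


def test_uniform_prediction_loss_is_log4():
    probs = np.full((1, 4), 0.25)
    assert weighted_cross_entropy(probs, _one_hot([2]), np.ones(4)) == pytest.approx(
        np.log(4), rel=1e-12
    )


def test_hand_arithmetic_example():
    probs = np.array([[0.7, 0.1, 0.1, 0.1], [0.25, 0.25, 0.25, 0.25]])
    labels = _one_hot([0, 2])
    weights = np.array([2.0, 1.0, 1.0, 1.0])
    expected = -0.5 * (2 * np.log(0.7) + 1 * np.log(0.25))
    assert weighted_cross_entropy(probs, labels, weights) == pytest.approx(
        expected, rel=1e-12
    )


def test_perfect_one_hot_prediction_zero_loss():
    probs = _one_hot([1, 3])
    assert weighted_cross_entropy(probs, probs, np.ones(4)) == pytest.approx(0.0)


def test_unit_weights_equal_mean_nll_oracle(rng):
    """Against an independently coded mean negative log-likelihood."""
    for _ in range(100):
        m = int(rng.integers(1, 8))
        raw = rng.random((m, 4)) + 1e-3
        probs = raw / raw.sum(axis=1, keepdims=True)
        labels = rng.integers(0, 4, m)
        oracle = float(np.mean([-np.log(probs[i, labels[i]]) for i in range(m)]))
        assert weighted_cross_entropy(
            probs, _one_hot(labels), np.ones(4)
        ) == pytest.approx(oracle, abs=1e-12)


def test_zero_probability_clamped_with_warning():
    probs = np.array([[1.0, 0.0, 0.0, 0.0]])
    with pytest.warns(RuntimeWarning):
        loss = weighted_cross_entropy(probs, _one_hot([1]), np.ones(4))
    assert np.isfinite(loss)


def test_invalid_probability_rows_rejected():
    with pytest.raises(ValueError):
        weighted_cross_entropy(np.array([[0.5, 0.5, 0.5, 0.5]]), _one_hot([0]), np.ones(4))


# -- dihedral augmentation -------------------------------------------------


def test_dihedral_group_inverse_recovers_original(rng):
    patch = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
    for t in range(8):
        out = apply_dihedral(patch, t)
        back = apply_dihedral(out, invert_dihedral(t))
        assert np.array_equal(back, patch), f"transform {t}"


def test_dihedral_preserves_histogram(rng):
    patch = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
    ref = np.bincount(patch.reshape(-1), minlength=256)
    for t in range(8):
        out = apply_dihedral(patch, t)
        assert np.array_equal(np.bincount(out.reshape(-1), minlength=256), ref)


def test_augment_uniform_over_transforms():
    """Each of the 8 transforms appears 1000 +- 150 times in 8000 draws."""
    rng = np.random.default_rng(7)
    patch = np.arange(4 * 4 * 3, dtype=np.uint8).reshape(4, 4, 3)
    counts = np.zeros(8, dtype=int)
    for _ in range(8000):
        _, t = augment(patch, rng, return_transform=True)
        counts[t] += 1
    assert counts.min() >= 850 and counts.max() <= 1150


def test_augment_rejects_non_square(rng):
    with pytest.raises(ValueError):
        augment(np.zeros((4, 6, 3), dtype=np.uint8), rng)


# -- training --------------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_setup():
    cores, manifest = generate_dataset(3, CoreSpec(diameter_px=128), seed=5)
    manifest = manifest.copy()
    manifest["split"] = (["train"] * 2 + ["val"]) * 4
    images = {c.core_id: c for c, _ in cores}
    config = PyramidConfig(patch_size=32, levels=((1, 3), (2, 1)))
    return manifest, images, config


def test_training_reduces_loss_and_is_deterministic(tiny_setup):
    manifest, images, config = tiny_setup
    tc = TrainConfig(learning_rate=3e-3, max_epochs=15, seed=17)
    m1 = train(manifest, config, tc, images=images, channels=(4, 8))
    m2 = train(manifest, config, tc, images=images, channels=(4, 8))
    # stochastic PSS resampling makes per-epoch loss noisy; compare the
    # tail of the trajectory against its start
    assert m1.history["train_loss"].tail(3).mean() < m1.history["train_loss"].iloc[0]
    pd.testing.assert_frame_equal(m1.history, m2.history)


def test_training_requires_both_splits(tiny_setup):
    manifest, images, config = tiny_setup
    bad = manifest[manifest["split"] == "train"]
    with pytest.raises(ValueError, match="val"):
        train(bad, config, TrainConfig(max_epochs=1), images=images)


def test_forward_contract(trained_model, held_out_cores, small_config):
    core, _ = held_out_cores[0]
    pss = sample_pss(core, small_config, seed=0)
    p1 = forward(trained_model, pss)
    p2 = forward(trained_model, pss)
    assert p1.shape == (4,)
    assert np.all(p1 >= 0) and p1.sum() == pytest.approx(1.0, abs=1e-6)
    np.testing.assert_array_equal(p1, p2)


def test_forward_d_in_mismatch_raises(trained_model):
    wrong = PyramidConfig(patch_size=64, levels=((1, 2),), include_whole_core=False)
    core_img = np.zeros((64, 64, 3), dtype=np.uint8)
    pss = sample_pss(core_img, wrong, seed=0)
    with pytest.raises(ValueError, match="D_in"):
        forward(trained_model, pss)


def test_separable_classes_reach_high_validation_accuracy(trained_model):
    """On separable synthetic classes the best epoch's validation accuracy
    reaches at least 0.9 (the parameter-recovery contract)."""
    assert trained_model.history["val_acc"].max() >= 0.9


def test_trained_class3_core_argmax_is_3(trained_model, held_out_cores, small_config):
    """A 3+ core's PSS predicts 3+ in at least 9 of 10 sampled PSSs."""
    core = next(c for c, lab in held_out_cores if int(lab) == 3)
    hits = sum(
        int(np.argmax(forward(trained_model, sample_pss(core, small_config, seed=s))))
        == 3
        for s in range(10)
    )
    assert hits >= 9


def test_checkpoint_round_trip(tmp_path, trained_model, held_out_cores, small_config):
    path = tmp_path / "model.npz"
    save_model(path, trained_model)
    reloaded = load_model(path)
    assert reloaded.pyramid_config == trained_model.pyramid_config
    core, _ = held_out_cores[1]
    pss = sample_pss(core, small_config, seed=3)
    np.testing.assert_allclose(
        forward(reloaded, pss), forward(trained_model, pss), atol=1e-7
    )


def test_backbone_swap_changes_no_contract(random_model):
    """Any backbone honoring the contract plugs into forward unchanged."""
    config = random_model.pyramid_config
    pss = sample_pss(np.full((64, 64, 3), 200, dtype=np.uint8), config, seed=0)
    p = forward(random_model, pss)
    assert p.shape == (4,) and p.sum() == pytest.approx(1.0, abs=1e-6)
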