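import numpy as np
import pytest

from liverseg import nn
from liverseg.model import ModelConfig, build_model
from liverseg.phantom import BACKGROUND_INTENSITY, LIVER_INTENSITY
from liverseg.training import (PatchBatch, TrainConfig, augment,
                               draw_augmentation_params, jaccard,
                               sample_patch_batch, soft_dice_loss,
                               train_orientation_model)


@pytest.fixture(scope="module")
def sampler_setup(separable_cases, small_model):
    cfg = TrainConfig(patch_size=24, batch_size=8, seed=0)
    return separable_cases, cfg, small_model


def test_sampler_is_deterministic(sampler_setup):
    cases, cfg, model = sampler_setup
    a = sample_patch_batch(cases, "axial", cfg, model, np.random.default_rng(3))
    b = sample_patch_batch(cases, "axial", cfg, model, np.random.default_rng(3))
    assert np.array_equal(a.inputs, b.inputs)
    assert np.array_equal(a.labels, b.labels)


def test_sampler_alignment_on_separable_phantom(sampler_setup):
    """The label window must coincide with the center crop of the input:
    on a noiseless phantom, thresholding the input center must reproduce
    the label wherever the window stays inside the slice."""
    cases, cfg, model = sampler_setup
    rng = np.random.default_rng(1)
    batch = sample_patch_batch(cases, "axial", cfg, model, rng)
    pad = (model.receptive_field - 1) // 2
    thr = 0.5  # normalized phantom: liver ~1, background ~0
    center = batch.inputs[:, 0, pad:-pad, pad:-pad]
    agreement = ((center > thr) == batch.labels.astype(bool)).mean()
    assert agreement > 0.99  # reflect-padding can fold edge voxels


def test_sampler_rejects_empty_case_list(sampler_setup):
    _, cfg, model = sampler_setup
    with pytest.raises(ValueError):
        sample_patch_batch([], "axial", cfg, model, np.random.default_rng(0))


def test_background_patch_has_empty_label(separable_cases, small_model):
    from liverseg.imaging_io import ImageVolume, MaskVolume, VolumeGeometry
    geom = VolumeGeometry(spacing_mm=(2.0, 2.0, 2.0))
    img = ImageVolume(np.zeros((48, 48, 32), dtype=np.float32), geom)
    empty = MaskVolume(np.zeros((48, 48, 32)), geom)
    cfg = TrainConfig(patch_size=24, batch_size=4, seed=0)
    batch = sample_patch_batch([(img, empty)], "axial", cfg, small_model,
                               np.random.default_rng(0))
    assert batch.labels.sum() == 0


def test_degenerate_augmentation_is_identity(sampler_setup):
    cases, _, model = sampler_setup
    cfg = TrainConfig(patch_size=24, batch_size=4, rot_sigma_deg=0.0,
                      intensity_shift_sigma=0.0, seed=0)
    batch = sample_patch_batch(cases, "axial", cfg, model, np.random.default_rng(2))
    out = augment(batch, cfg, np.random.default_rng(5))
    assert np.array_equal(out.inputs, batch.inputs)
    assert np.array_equal(out.labels, batch.labels)


def test_augmented_labels_stay_binary(sampler_setup):
    cases, cfg, model = sampler_setup
    batch = sample_patch_batch(cases, "coronal", cfg, model, np.random.default_rng(4))
    out = augment(batch, cfg, np.random.default_rng(6))
    assert set(np.unique(out.labels)) <= {0, 1}


def test_augmentation_parameter_distributions():
    cfg = TrainConfig()
    angles, shifts = draw_augmentation_params(cfg, np.random.default_rng(123), 10_000)
    assert abs(angles.mean()) < 3 * angles.std(ddof=1) / 100
    assert 9.5 <= angles.std(ddof=1) <= 10.5
    assert 0.095 <= shifts.std(ddof=1) <= 0.105


def test_soft_dice_closed_forms():
    # perfect binary prediction
    labels = np.zeros((2, 4, 4))
    labels[:, :2] = 1
    assert soft_dice_loss(labels.copy(), labels) < 1e-4
    # all-ones prediction, half-foreground labels: 1 − 2(n/2)/(n + n/2) = 1/3
    pred = np.ones((1, 10, 10))
    half = np.zeros((1, 10, 10))
    half[0, :5] = 1
    assert abs(soft_dice_loss(pred, half) - 1.0 / 3.0) < 1e-4
    # empty-empty is perfect by the epsilon convention
    z = np.zeros((1, 5, 5))
    assert soft_dice_loss(z, z) == 0.0
    with pytest.raises(ValueError):
        soft_dice_loss(np.zeros((1, 4, 4)), np.zeros((1, 5, 5)))


def test_soft_dice_gradient_direction():
    """Increasing predicted probability inside the object lowers the loss."""
    labels = np.zeros((1, 6, 6))
    labels[0, 2:5, 2:5] = 1
    p = nn.Parameter(np.full((1, 6, 6), 0.5))
    loss = soft_dice_loss(p, labels)
    loss.backward()
    assert np.all(p.grad[labels.astype(bool)] < 0)
    assert np.all(p.grad[~labels.astype(bool)] > 0)


def test_jaccard_definition():
    a = np.zeros((2, 2, 2), dtype=bool)
    a[0] = True  # 4 voxels
    full = np.ones((2, 2, 2), dtype=bool)
    assert jaccard(a, full) == 0.5
    assert jaccard(a, a) == 1.0
    assert jaccard(a, ~a) == 0.0
    assert jaccard(np.zeros((3, 3)), np.zeros((3, 3))) == 1.0
    with pytest.raises(ValueError):
        jaccard(np.zeros((2, 2)), np.zeros((3, 3)))


def test_training_terminates_and_tracks_best(separable_cases):
    cfg = TrainConfig(patch_size=24, batch_size=4, learning_rate=1e-3,
                      val_interval=5, patience=1, max_iterations=30, seed=0)
    model, history = train_orientation_model(separable_cases, "axial",
                                             ModelConfig.small(base_features=4), cfg)
    assert len(history.val_jaccard) >= 1
    assert history.best_jaccard == max(history.val_jaccard)
    # loss stays in its theoretical range
    assert all(0.0 <= l <= 1.0 + 1e-9 for l in history.loss)


def test_training_is_reproducible(separable_cases):
    cfg = TrainConfig(patch_size=24, batch_size=4, learning_rate=1e-3,
                      val_interval=10, patience=1, max_iterations=20, seed=9)
    _, h1 = train_orientation_model(separable_cases, "axial",
                                    ModelConfig.small(base_features=4), cfg)
    _, h2 = train_orientation_model(separable_cases, "axial",
                                    ModelConfig.small(base_features=4), cfg)
    assert h1.loss == h2.loss
    assert h1.val_jaccard == h2.val_jaccard
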