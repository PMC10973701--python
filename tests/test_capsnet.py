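"""Capsule math (squash, predictions, routing), architecture shapes and
training behavior of the capsule autoencoder."""

import numpy as np
import pytest

from capspace import capsnet, stimuli
from capspace.capsnet import (
    EncoderConfig,
    capn,
    dynamic_routing,
    predict_vectors,
    squash,
    tiny_config,
)


# -- squash --------------------------------------------------------------


@pytest.mark.parametrize("norm,expected", [(0.0, 0.0), (1.0, 0.5), (3.0, 0.9)])
def test_squash_norms(norm, expected):
    """|squash(s)| = |s|^2 / (1 + |s|^2): 0 -> 0, 1 -> 0.5, 3 -> 0.9."""
    s = np.zeros(5)
    s[2] = norm
    out = squash(s)
    assert np.linalg.norm(out) == pytest.approx(expected, abs=1e-12)


def test_squash_direction_and_bound(rng):
    s = rng.standard_normal(8)
    out = squash(s)
    cos = out @ s / (np.linalg.norm(out) * np.linalg.norm(s))
    assert cos == pytest.approx(1.0)
    norms = [np.linalg.norm(squash(s * k)) for k in np.linspace(0.1, 50, 40)]
    assert all(n < 1.0 for n in norms)
    assert all(b > a for a, b in zip(norms, norms[1:]))


# -- predictions ---------------------------------------------------------


def test_predict_vectors_identity_and_zero(rng):
    u = rng.standard_normal((3, 4))
    W = np.broadcast_to(np.eye(4), (3, 2, 4, 4)).copy()
    u_hat = predict_vectors(u, W)
    for j in range(2):
        np.testing.assert_allclose(u_hat[:, j, :], u)
    assert predict_vectors(np.zeros((3, 4)), W).sum() == 0.0


def test_predict_vectors_matches_manual_matmul(rng):
    u = rng.standard_normal((2, 3))
    W = rng.standard_normal((2, 2, 5, 3))
    u_hat = predict_vectors(u, W)
    for i in range(2):
        for j in range(2):
            np.testing.assert_allclose(u_hat[i, j], W[i, j] @ u[i], rtol=1e-12)


def test_predict_vectors_shape_mismatch(rng):
    with pytest.raises(ValueError):
        predict_vectors(rng.standard_normal((3, 4)), rng.standard_normal((3, 1, 5, 6)))


# -- routing -------------------------------------------------------------


from oracles import routing_oracle


def test_routing_uniform_first_iteration(rng):
    """With b=0 and over-lower softmax, every coefficient is 1/I."""
    I = 3136
    u_hat = rng.standard_normal((I, 1, 4)) * 1e-3
    _, c, _ = dynamic_routing(u_hat, n_iters=1, normalization="over_lower")
    np.testing.assert_allclose(c, np.full((I, 1), 1.0 / I), rtol=1e-12)


def test_routing_over_higher_singleton_is_one(rng):
    """Classic softmax over a single higher capsule gives c = 1 always."""
    u_hat = rng.standard_normal((5, 1, 4))
    for iters in (1, 2, 3):
        _, c, _ = dynamic_routing(u_hat, iters, normalization="over_higher")
        np.testing.assert_allclose(c, np.ones((5, 1)), rtol=1e-12)


@pytest.mark.parametrize("normalization", ["over_lower", "over_higher"])
@pytest.mark.parametrize("shape,iters", [((2, 1, 3), 2), ((5, 3, 4), 3), ((4, 2, 6), 3)])
def test_routing_matches_oracle(normalization, shape, iters, rng):
    u_hat = rng.standard_normal(shape)
    v, c, _ = dynamic_routing(u_hat, iters, normalization)
    ve, ce = routing_oracle(u_hat, iters, normalization)
    np.testing.assert_allclose(v, ve, atol=1e-10)
    np.testing.assert_allclose(c, ce, atol=1e-10)


@pytest.mark.parametrize("normalization,axis", [("over_lower", 0), ("over_higher", 1)])
def test_routing_coefficients_normalized(normalization, axis, rng):
    u_hat = rng.standard_normal((6, 3, 4))
    for iters in (1, 2, 4):
        _, c, _ = dynamic_routing(u_hat, iters, normalization)
        np.testing.assert_allclose(c.sum(axis=axis), 1.0, rtol=1e-10)


def test_routing_b_log_length(rng):
    _, _, log = dynamic_routing(rng.standard_normal((3, 1, 2)), n_iters=4)
    assert len(log) == 4


def test_routing_rejects_bad_iters(rng):
    with pytest.raises(ValueError):
        dynamic_routing(rng.standard_normal((3, 1, 2)), n_iters=0)


# -- capn ----------------------------------------------------------------


def test_capn_pythagoras_and_zero():
    caps = np.zeros((1, 1, 1, 10))
    caps[0, 0, 0, :2] = (3.0, 4.0)
    assert capn(caps)[0, 0, 0] == pytest.approx(5.0)
    assert capn(np.zeros((2, 2, 2, 10))).sum() == 0.0


# -- architecture --------------------------------------------------------


def test_encoder_layer_shapes_full_config(full_model, stim_images):
    """The default architecture reproduces the published layer shapes."""
    maps = capsnet.encoder_forward(full_model, stim_images[0][:2])
    assert maps["L1"].shape == (2, 256, 22, 22)
    assert maps["L2"].shape == (2, 64, 7, 7, 10)
    assert maps["L2N"].shape == (2, 64, 7, 7)
    assert maps["L3"].shape == (2, 1, 40)
    cfg = EncoderConfig()
    assert cfg.n_primary_caps == 3136
    assert cfg.layer_shapes["L3"] == (1, 40)


def test_extract_feature_row_lengths(full_model, stim_images):
    feats = capsnet.extract_features(full_model, stim_images[0][:2])
    assert feats["L1"].shape[1] == 256 * 22 * 22
    assert feats["L2"].shape[1] == 31360
    assert feats["L2N"].shape[1] == 3136
    assert feats["L3"].shape[1] == 40


def test_zero_input_zero_biases_gives_zero_l1(full_model):
    x = np.zeros((1, 3, 30, 30), dtype=np.float32)
    maps = capsnet.encoder_forward(full_model, x)
    assert np.abs(maps["L1"]).max() == 0.0


def test_encoder_is_pure_function(tiny_trained, small_training_set):
    a = capsnet.encoder_forward(tiny_trained, small_training_set[:3])
    b = capsnet.encoder_forward(tiny_trained, small_training_set[:3])
    for k in a:
        np.testing.assert_array_equal(a[k], b[k])


def test_post_squash_capsule_norms_below_one(tiny_trained, small_training_set):
    maps = capsnet.encoder_forward(tiny_trained, small_training_set[:4])
    assert maps["L2N"].max() < 1.0
    assert np.linalg.norm(maps["L3"], axis=-1).max() < 1.0


def test_encoder_rejects_wrong_shape(tiny_trained):
    with pytest.raises(ValueError):
        capsnet.encoder_forward(tiny_trained, np.zeros((1, 3, 28, 28), dtype=np.float32))


def test_decoder_output_shape_and_range(tiny_trained, rng):
    v = rng.standard_normal((3, tiny_trained.config.higher_caps_dim)).astype(np.float32)
    out = capsnet.decoder_forward(tiny_trained, v)
    assert out.shape == (3, 3, 30, 30)
    assert out.min() >= 0.0 and out.max() <= 1.0


# -- training ------------------------------------------------------------


def test_train_one_epoch_smoke(small_training_set):
    m = capsnet.train(small_training_set[:4], epochs=1, seed=0, config=tiny_config())
    assert len(m.training_log) == 1
    assert np.isfinite(m.training_log[0])


def test_train_determinism(small_training_set):
    kw = dict(epochs=3, seed=5, config=tiny_config())
    a = capsnet.train(small_training_set[:8], **kw)
    b = capsnet.train(small_training_set[:8], **kw)
    assert a.training_log == b.training_log
    for k in a.params:
        np.testing.assert_array_equal(a.params[k].data, b.params[k].data)


def test_train_reduces_mae(tiny_trained):
    log = tiny_trained.training_log
    assert log[-1] < 0.5 * log[0]


def test_train_empty_raises():
    with pytest.raises(ValueError):
        capsnet.train([], epochs=1, seed=0, config=tiny_config())


def test_reconstruction_beats_mean_image(tiny_trained, small_training_set):
    """After training, reconstructions are closer to their inputs than the
    training-set mean image is."""
    x = stimuli.images_to_array(small_training_set)
    recon = capsnet.reconstruct(tiny_trained, small_training_set)
    mae_model = np.abs(recon - x).mean()
    mae_mean = np.abs(x.mean(axis=0, keepdims=True) - x).mean()
    assert mae_model < mae_mean


def test_reconstructions_match_own_input_best(tiny_trained, small_training_set):
    """Mean pixel correlation is higher for matched than mismatched pairs."""
    x = stimuli.images_to_array(small_training_set)
    recon = capsnet.reconstruct(tiny_trained, small_training_set)
    n = x.shape[0]
    flat_x = x.reshape(n, -1)
    flat_r = recon.reshape(n, -1)
    cors = np.corrcoef(flat_r, flat_x)[:n, n:]
    matched = np.diag(cors).mean()
    mismatched = (cors.sum() - np.trace(cors)) / (n * n - n)
    assert matched > mismatched


def test_save_load_roundtrip(tmp_path, tiny_trained, small_training_set):
    path = tmp_path / "model.npz"
    capsnet.save_model(tiny_trained, path)
    loaded = capsnet.load_model(path)
    assert loaded.config == tiny_trained.config
    a = capsnet.extract_features(tiny_trained, small_training_set[:2])
    b = capsnet.extract_features(loaded, small_training_set[:2])
    for k in a:
        np.testing.assert_array_equal(a[k], b[k])
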