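"""Control models the capsule autoencoder is compared against.

* PCA pixel baseline — a linear projection of the flattened images; fitted
  on the training set via :func:`capspace.spatial_features.fit_image_pca`.
* VAE — a variational autoencoder with a three-conv encoder, a 40-mean /
  40-log-variance latent, and a three-deconv decoder; the latent means are
  its feature set.
* SFF-CNN — a supervised feedforward CNN (three conv + two linear layers)
  trained with cross-entropy on the circle-count class (1/3/5/7); features
  come from the third convolution layer.
* S-CapsNet — the U-CapsNet encoder with two linear projection layers on
  top, trained with cross-entropy; the higher-capsule vector is its
  feature set.

All models consume the same 30x30x3 inputs, the same seeds and the same
optimizer protocol (Adam, lr 1e-4) as U-CapsNet, so comparisons differ
only in architecture and objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .capsnet import (
    EncoderConfig,
    TrainedModel,
    _as_batch,
    _conv_out,
    encoder_graph,
    init_params,
    tiny_config,
)
from .stimuli import RenderedImage

SET_SIZE_CLASSES = (1, 3, 5, 7)


def labels_from_set_sizes(set_sizes: Sequence[int]) -> np.ndarray:
    """Map circle counts {1,3,5,7} to class indices {0,1,2,3}."""
    lut = {s: i for i, s in enumerate(SET_SIZE_CLASSES)}
    try:
        return np.array([lut[int(s)] for s in set_sizes], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"set size {e.args[0]} outside classes {SET_SIZE_CLASSES}")


def labels_from_images(images: Sequence[RenderedImage]) -> np.ndarray:
    return labels_from_set_sizes([len(im.source) for im in images])


@dataclass(frozen=True)
class ConvStackConfig:
    """Shared three-conv encoder front end for VAE and SFF-CNN.

    Geometry mirrors U-CapsNet's front end (30 -> 22 -> 7 -> 5) so the
    models are comparable in depth and receptive field.
    """

    input_hw: int = 30
    in_channels: int = 3
    channels: tuple[int, int, int] = (32, 64, 64)
    kernels: tuple[int, int, int] = (9, 9, 3)
    strides: tuple[int, int, int] = (1, 2, 1)

    @property
    def out_hws(self) -> tuple[int, int, int]:
        hw = self.input_hw
        outs = []
        for k, s in zip(self.kernels, self.strides):
            hw = _conv_out(hw, k, s)
            outs.append(hw)
        return tuple(outs)

    @property
    def flat_dim(self) -> int:
        return self.channels[-1] * self.out_hws[-1] ** 2


def _init_conv_stack(
    rng: np.random.Generator, cfg: ConvStackConfig
) -> dict[str, Tensor]:
    p = {}
    cin = cfg.in_channels
    for i, (cout, k) in enumerate(zip(cfg.channels, cfg.kernels), 1):
        p[f"conv{i}_w"] = ad.parameter(rng, (cout, cin, k, k), cin * k * k)
        p[f"conv{i}_b"] = ad.zeros_parameter((cout,))
        cin = cout
    return p


def _conv_stack_forward(
    params: dict[str, Tensor], cfg: ConvStackConfig, x: Tensor
) -> list[Tensor]:
    h = x
    outs = []
    for i, s in enumerate(cfg.strides, 1):
        h = ad.relu(ad.conv2d(h, params[f"conv{i}_w"], params[f"conv{i}_b"], s))
        outs.append(h)
    return outs


# -- VAE -----------------------------------------------------------------


@dataclass(frozen=True)
class VAEConfig:
    conv: ConvStackConfig = field(default_factory=ConvStackConfig)
    latent_dim: int = 40
    decoder_fc_channels: int = 64
    decoder_channels: tuple[int, int] = (32, 16)
    decoder_hw: int = 7
    epochs: int = 3000
    lr: float = 1e-4
    #: weight of the KL term; the KL is averaged over batch and latent dims
    #: so it is on the same per-element scale as the MAE reconstruction term
    kl_weight: float = 1.0


def tiny_vae_config(**overrides) -> VAEConfig:
    defaults = dict(
        conv=ConvStackConfig(channels=(8, 8, 8)),
        decoder_fc_channels=8,
        decoder_channels=(8, 8),
    )
    defaults.update(overrides)
    return VAEConfig(**defaults)


@dataclass
class VAEModel:
    params: dict[str, Tensor]
    config: VAEConfig
    training_log: list[dict[str, float]] = field(default_factory=list)
    seed: int = 0

    def encode(self, images) -> tuple[np.ndarray, np.ndarray]:
        """Latent means and log-variances, [N, latent_dim] each."""
        x = Tensor(_as_batch(images))
        mu, logvar = _vae_encode(self.params, self.config, x)
        return mu.data.copy(), logvar.data.copy()

    def features(self, images) -> np.ndarray:
        """The latent means, used as the control feature set."""
        return self.encode(images)[0]


def _vae_decoder_graph(
    params: dict[str, Tensor], cfg: VAEConfig, z: Tensor
) -> Tensor:
    n = z.shape[0]
    h = ad.relu(ad.add(ad.matmul(z, params["fc_dec_w"]), params["fc_dec_b"]))
    h = ad.reshape(h, (n, cfg.decoder_fc_channels, cfg.decoder_hw, cfg.decoder_hw))
    h = ad.relu(
        ad.conv_transpose2d(h, params["dec1_w"], params["dec1_b"], stride=2, padding=1)
    )
    h = ad.relu(
        ad.conv_transpose2d(h, params["dec2_w"], params["dec2_b"], stride=2, padding=1)
    )
    return ad.sigmoid(
        ad.conv_transpose2d(h, params["dec3_w"], params["dec3_b"], stride=1, padding=0)
    )


def _vae_encode(
    params: dict[str, Tensor], cfg: VAEConfig, x: Tensor
) -> tuple[Tensor, Tensor]:
    """Conv stack -> linear head -> (means, log-variances), [N, d] each."""
    h = _conv_stack_forward(params, cfg.conv, x)[-1]
    n = x.shape[0]
    h = ad.reshape(h, (n, cfg.conv.flat_dim))
    stats = ad.add(ad.matmul(h, params["fc_mu_logvar_w"]), params["fc_mu_logvar_b"])
    d = cfg.latent_dim
    full = ad.reshape(stats, (n, 2, d))
    mu = _take_axis1(full, 0)
    logvar = _take_axis1(full, 1)
    return mu, logvar


def _take_axis1(t: Tensor, idx: int) -> Tensor:
    """Select index ``idx`` along axis 1 of a [N, 2, D] tensor."""
    _, two, _ = t.shape
    mask = np.zeros((1, two, 1), dtype=np.float32)
    mask[0, idx, 0] = 1.0
    return ad.tsum(ad.mul(t, Tensor(mask)), axis=1)


def train_vae(
    images,
    config: VAEConfig | None = None,
    seed: int = 0,
    epochs: int | None = None,
    batch_size: int | None = None,
) -> VAEModel:
    """Train the VAE (MAE reconstruction + KL to a standard normal prior)."""
    cfg = config or VAEConfig()
    n_epochs = cfg.epochs if epochs is None else epochs
    x = _as_batch(images)
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    p = _init_conv_stack(rng, cfg.conv)
    d = cfg.latent_dim
    fc_out = cfg.decoder_fc_channels * cfg.decoder_hw**2
    p["fc_mu_logvar_w"] = ad.parameter(rng, (cfg.conv.flat_dim, 2 * d), cfg.conv.flat_dim)
    p["fc_mu_logvar_b"] = ad.zeros_parameter((2 * d,))
    p["fc_dec_w"] = ad.parameter(rng, (d, fc_out), d)
    p["fc_dec_b"] = ad.zeros_parameter((fc_out,))
    d1, d2 = cfg.decoder_channels
    p["dec1_w"] = ad.parameter(rng, (cfg.decoder_fc_channels, d1, 4, 4), 16 * cfg.decoder_fc_channels)
    p["dec1_b"] = ad.zeros_parameter((d1,))
    p["dec2_w"] = ad.parameter(rng, (d1, d2, 4, 4), 16 * d1)
    p["dec2_b"] = ad.zeros_parameter((d2,))
    p["dec3_w"] = ad.parameter(rng, (d2, cfg.conv.in_channels, 3, 3), 9 * d2)
    p["dec3_b"] = ad.zeros_parameter((cfg.conv.in_channels,))

    opt = ad.Adam(p, lr=cfg.lr)
    noise_rng = np.random.default_rng(seed + 1)
    shuffle_rng = np.random.default_rng(seed + 2)
    n = x.shape[0]
    bs = n if batch_size is None else min(batch_size, n)
    model = VAEModel(params=p, config=cfg, seed=seed)
    for _ in range(n_epochs):
        order = shuffle_rng.permutation(n)
        ep = {"recon": 0.0, "kl": 0.0, "total": 0.0}
        for lo in range(0, n, bs):
            idx = order[lo : lo + bs]
            xb = Tensor(x[idx])
            mu, logvar = _vae_encode(p, cfg, xb)
            eps = Tensor(noise_rng.standard_normal((len(idx), d)).astype(np.float32))
            z = ad.add(mu, ad.mul(ad.exp(ad.mul(logvar, 0.5)), eps))
            recon = _vae_decoder_graph(p, cfg, z)
            recon_loss = ad.mean(ad.absolute(recon - xb))
            # KL(q || N(0,I)) averaged over batch and latent dimensions
            kl = ad.mean(
                ad.mul(
                    ad.add(
                        ad.add(ad.mul(mu, mu), ad.exp(logvar)),
                        ad.mul(ad.add(logvar, 1.0), -1.0),
                    ),
                    0.5,
                )
            )
            loss = ad.add(recon_loss, ad.mul(kl, cfg.kl_weight))
            val = float(loss.data)
            if not np.isfinite(val):
                raise FloatingPointError("VAE training diverged")
            opt.zero_grad()
            loss.backward()
            opt.step()
            w = len(idx) / n
            ep["recon"] += float(recon_loss.data) * w
            ep["kl"] += float(kl.data) * w
            ep["total"] += val * w
        model.training_log.append(ep)
    return model


# -- SFF-CNN -------------------------------------------------------------


@dataclass(frozen=True)
class SupervisedConfig:
    n_classes: int = 4
    hidden_dim: int = 64
    epochs: int = 3000
    lr: float = 1e-4


@dataclass
class SFFCNNModel:
    params: dict[str, Tensor]
    conv: ConvStackConfig
    config: SupervisedConfig
    training_log: list[float] = field(default_factory=list)
    seed: int = 0

    def logits(self, images) -> np.ndarray:
        x = Tensor(_as_batch(images))
        return _sff_forward(self.params, self.conv, x)[1].data.copy()

    def features(self, images) -> np.ndarray:
        """Flattened third-convolution-layer maps (pre-projection)."""
        x = Tensor(_as_batch(images))
        h3 = _sff_forward(self.params, self.conv, x)[0]
        return h3.data.reshape(x.shape[0], -1).copy()

    def predict(self, images) -> np.ndarray:
        return self.logits(images).argmax(axis=1)


def _sff_forward(
    params: dict[str, Tensor], conv_cfg: ConvStackConfig, x: Tensor
) -> tuple[Tensor, Tensor]:
    h3 = _conv_stack_forward(params, conv_cfg, x)[-1]
    n = x.shape[0]
    flat = ad.reshape(h3, (n, conv_cfg.flat_dim))
    h = ad.relu(ad.add(ad.matmul(flat, params["fc1_w"]), params["fc1_b"]))
    logits = ad.add(ad.matmul(h, params["fc2_w"]), params["fc2_b"])
    return h3, logits


def train_sff_cnn(
    images,
    labels: Sequence[int] | np.ndarray,
    config: SupervisedConfig | None = None,
    conv: ConvStackConfig | None = None,
    seed: int = 0,
    epochs: int | None = None,
    batch_size: int | None = None,
) -> SFFCNNModel:
    """Train the supervised feedforward CNN on circle-count classes."""
    cfg = config or SupervisedConfig()
    conv_cfg = conv or ConvStackConfig()
    n_epochs = cfg.epochs if epochs is None else epochs
    x = _as_batch(images)
    y = np.asarray(labels, dtype=np.int64)
    if y.min() < 0 or y.max() >= cfg.n_classes:
        raise ValueError("labels outside the class set")
    rng = np.random.default_rng(seed)
    p = _init_conv_stack(rng, conv_cfg)
    p["fc1_w"] = ad.parameter(rng, (conv_cfg.flat_dim, cfg.hidden_dim), conv_cfg.flat_dim)
    p["fc1_b"] = ad.zeros_parameter((cfg.hidden_dim,))
    p["fc2_w"] = ad.parameter(rng, (cfg.hidden_dim, cfg.n_classes), cfg.hidden_dim)
    p["fc2_b"] = ad.zeros_parameter((cfg.n_classes,))
    opt = ad.Adam(p, lr=cfg.lr)
    shuffle_rng = np.random.default_rng(seed + 2)
    n = x.shape[0]
    bs = n if batch_size is None else min(batch_size, n)
    model = SFFCNNModel(params=p, conv=conv_cfg, config=cfg, seed=seed)
    for _ in range(n_epochs):
        order = shuffle_rng.permutation(n)
        ep = 0.0
        for lo in range(0, n, bs):
            idx = order[lo : lo + bs]
            xb = Tensor(x[idx])
            _, logits = _sff_forward(p, conv_cfg, xb)
            loss = ad.cross_entropy(logits, y[idx])
            val = float(loss.data)
            if not np.isfinite(val):
                raise FloatingPointError("SFF-CNN training diverged")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep += val * len(idx) / n
        model.training_log.append(ep)
    return model


# -- S-CapsNet -----------------------------------------------------------


@dataclass
class SCapsNetModel:
    params: dict[str, Tensor]
    encoder_config: EncoderConfig
    config: SupervisedConfig
    training_log: list[float] = field(default_factory=list)
    seed: int = 0

    def _forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        g = encoder_graph(self.params, self.encoder_config, x)
        h = ad.relu(ad.add(ad.matmul(g["L3"], self.params["proj1_w"]), self.params["proj1_b"]))
        logits = ad.add(ad.matmul(h, self.params["proj2_w"]), self.params["proj2_b"])
        return g["L3"], logits

    def features(self, images) -> np.ndarray:
        """The higher-capsule vector (CAP), [N, higher_caps_dim]."""
        x = Tensor(_as_batch(images))
        return self._forward(x)[0].data.copy()

    def logits(self, images) -> np.ndarray:
        x = Tensor(_as_batch(images))
        return self._forward(x)[1].data.copy()

    def predict(self, images) -> np.ndarray:
        return self.logits(images).argmax(axis=1)


def train_s_capsnet(
    images,
    labels: Sequence[int] | np.ndarray,
    config: SupervisedConfig | None = None,
    encoder_config: EncoderConfig | None = None,
    seed: int = 0,
    epochs: int | None = None,
    batch_size: int | None = None,
) -> SCapsNetModel:
    """Train the supervised CapsNet: U-CapsNet encoder + two linear layers."""
    cfg = config or SupervisedConfig()
    enc_cfg = encoder_config or EncoderConfig()
    n_epochs = cfg.epochs if epochs is None else epochs
    x = _as_batch(images)
    y = np.asarray(labels, dtype=np.int64)
    if y.min() < 0 or y.max() >= cfg.n_classes:
        raise ValueError("labels outside the class set")
    p = init_params(enc_cfg, seed)
    # drop the decoder parameters: the supervised variant has no decoder
    for k in list(p):
        if k.startswith(("fc_", "dec")):
            del p[k]
    rng = np.random.default_rng(seed + 3)
    hid = max(cfg.hidden_dim // 2, cfg.n_classes)
    p["proj1_w"] = ad.parameter(rng, (enc_cfg.higher_caps_dim, hid), enc_cfg.higher_caps_dim)
    p["proj1_b"] = ad.zeros_parameter((hid,))
    p["proj2_w"] = ad.parameter(rng, (hid, cfg.n_classes), hid)
    p["proj2_b"] = ad.zeros_parameter((cfg.n_classes,))
    opt = ad.Adam(p, lr=cfg.lr)
    shuffle_rng = np.random.default_rng(seed + 2)
    n = x.shape[0]
    bs = n if batch_size is None else min(batch_size, n)
    model = SCapsNetModel(
        params=p, encoder_config=enc_cfg, config=cfg, seed=seed
    )
    for _ in range(n_epochs):
        order = shuffle_rng.permutation(n)
        ep = 0.0
        for lo in range(0, n, bs):
            idx = order[lo : lo + bs]
            xb = Tensor(x[idx])
            _, logits = model._forward(xb)
            loss = ad.cross_entropy(logits, y[idx])
            val = float(loss.data)
            if not np.isfinite(val):
                raise FloatingPointError("S-CapsNet training diverged")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep += val * len(idx) / n
        model.training_log.append(ep)
    return model
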