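"""U-CapsNet: an unsupervised capsule autoencoder for circle-array images.

Encoder: a convolutional layer (Layer 1), a primary capsule layer whose
units are vectors ("capsules", Layer 2), and a single higher capsule
(Layer 3) reached by dynamic routing.  A fully connected layer links the
encoder to a three-layer deconvolutional decoder that reconstructs the
input image.  Training minimizes the mean absolute error (MAE) between
input and reconstruction with Adam.

At the default configuration the layer shapes are
Layer 1 = 256x22x22, Layer 2 = 64x7x7 capsules of dimension 10 (3136
capsules), Layer 3 = 1 capsule of dimension 40.  The 30->22 and 22->7
spatial maps force kernel 9 / stride 1 and kernel 9 / stride 2
respectively; decoder widths invert that geometry (7->14->28->30).

The squashing nonlinearity maps a vector s to
``(|s|^2 / (1 + |s|^2)) * s / |s|``, so capsule norms lie in [0, 1).  The
routing softmax is normalized over the *lower* capsules by default (the
``over_lower`` convention); the classic convention (over higher capsules)
is available as ``over_higher`` and is degenerate when there is exactly
one higher capsule.
"""

from __future__ import annotations

import gc
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .stimuli import RenderedImage, images_to_array

Normalization = Literal["over_lower", "over_higher"]


def _conv_out(hw: int, k: int, s: int) -> int:
    return (hw - k) // s + 1


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters; defaults give the full-scale network."""

    input_hw: int = 30
    in_channels: int = 3
    conv1_filters: int = 256
    conv1_kernel: int = 9
    conv1_stride: int = 1
    primary_caps_channels: int = 64
    primary_caps_dim: int = 10
    primary_caps_kernel: int = 9
    primary_caps_stride: int = 2
    higher_caps_count: int = 1
    higher_caps_dim: int = 40
    routing_iters: int = 3
    routing_normalization: Normalization = "over_lower"
    #: decoder deconvolution channel widths (last layer always maps to RGB)
    decoder_channels: tuple[int, int] = (32, 16)
    decoder_fc_channels: int = 64

    @property
    def conv1_hw(self) -> int:
        return _conv_out(self.input_hw, self.conv1_kernel, self.conv1_stride)

    @property
    def primary_hw(self) -> int:
        return _conv_out(
            self.conv1_hw, self.primary_caps_kernel, self.primary_caps_stride
        )

    @property
    def n_primary_caps(self) -> int:
        return self.primary_caps_channels * self.primary_hw**2

    @property
    def layer_shapes(self) -> dict[str, tuple[int, ...]]:
        return {
            "L1": (self.conv1_filters, self.conv1_hw, self.conv1_hw),
            "L2": (
                self.primary_caps_channels,
                self.primary_hw,
                self.primary_hw,
                self.primary_caps_dim,
            ),
            "L2N": (
                self.primary_caps_channels,
                self.primary_hw,
                self.primary_hw,
            ),
            "L3": (self.higher_caps_count, self.higher_caps_dim),
        }


def tiny_config(**overrides) -> EncoderConfig:
    """A scaled-down configuration for fast tests; same layer geometry."""
    defaults = dict(
        conv1_filters=8,
        primary_caps_channels=4,
        primary_caps_dim=4,
        higher_caps_dim=8,
        decoder_channels=(8, 8),
        decoder_fc_channels=8,
    )
    defaults.update(overrides)
    return EncoderConfig(**defaults)


# -- core capsule math (plain numpy; inspectable) ------------------------


def squash(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """Squashing nonlinearity applied along ``axis``.

    ``|out| = |s|^2 / (1 + |s|^2)``, direction preserved; the zero vector
    maps to itself.
    """
    s = np.asarray(s, dtype=float)
    n2 = (s * s).sum(axis=axis, keepdims=True)
    norm = np.sqrt(n2)
    scale = np.where(norm > 0, n2 / (1.0 + n2) / np.where(norm > 0, norm, 1.0), 0.0)
    return s * scale


def predict_vectors(u: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Prediction vectors u_hat[i, j] = W[i, j] @ u[i].

    u: [I, Dl]; W: [I, J, Dh, Dl] -> u_hat: [I, J, Dh].
    """
    u = np.asarray(u, dtype=float)
    W = np.asarray(W, dtype=float)
    if u.shape[0] != W.shape[0] or u.shape[1] != W.shape[3]:
        raise ValueError(
            f"shape mismatch: u {u.shape} vs W {W.shape} (need [I,Dl] and [I,J,Dh,Dl])"
        )
    return np.einsum("ijab,ib->ija", W, u)


def dynamic_routing(
    u_hat: np.ndarray,
    n_iters: int = 3,
    normalization: Normalization = "over_lower",
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Routing-by-agreement between one lower and one higher capsule layer.

    u_hat: [I, J, Dh] prediction vectors.  Priors b start at 0.  Each round
    computes coupling coefficients c = softmax(b) (normalized over lower
    capsules i by default, or over higher capsules j), the weighted sums
    s_j, outputs v_j = squash(s_j), and the agreement update
    b_ij += u_hat_ij . v_j.

    Returns (v [J, Dh], c [I, J] from the final round's softmax, and the
    list of b matrices after each update).
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    u_hat = np.asarray(u_hat, dtype=float)
    I, J, _ = u_hat.shape
    axis = 0 if normalization == "over_lower" else 1
    b = np.zeros((I, J))
    b_log: list[np.ndarray] = []
    v = c = None
    for _ in range(n_iters):
        bz = b - b.max(axis=axis, keepdims=True)
        e = np.exp(bz)
        c = e / e.sum(axis=axis, keepdims=True)
        s = np.einsum("ij,ija->ja", c, u_hat)
        v = squash(s)
        if not np.all(np.isfinite(v)):
            raise FloatingPointError("non-finite routing intermediate")
        b = b + np.einsum("ija,ja->ij", u_hat, v)
        b_log.append(b.copy())
    return v, c, b_log


def capn(L2: np.ndarray) -> np.ndarray:
    """Capsule norms (CAPN): the L2 length of each capsule vector.

    Accepts a capsule grid [..., C, H, W, D] and returns [..., C, H, W].
    """
    return np.linalg.norm(np.asarray(L2, dtype=float), axis=-1)


# -- model ---------------------------------------------------------------


def _squash_t(s: Tensor, axis: int = -1, eps: float = 1e-9) -> Tensor:
    n2 = ad.tsum(ad.mul(s, s), axis=axis, keepdims=True)
    scale = ad.mul(
        ad.mul(n2, ad.power(ad.add(n2, 1.0), -1.0)),
        ad.power(ad.add(n2, eps), -0.5),
    )
    return ad.mul(s, scale)


def init_params(config: EncoderConfig, seed: int) -> dict[str, Tensor]:
    rng = np.random.default_rng(seed)
    c = config
    k1, kp = c.conv1_kernel, c.primary_caps_kernel
    pc_out = c.primary_caps_channels * c.primary_caps_dim
    hw = c.primary_hw
    fc_out = c.decoder_fc_channels * hw * hw
    d1, d2 = c.decoder_channels
    p = {
        "conv1_w": ad.parameter(
            rng, (c.conv1_filters, c.in_channels, k1, k1), c.in_channels * k1 * k1
        ),
        "conv1_b": ad.zeros_parameter((c.conv1_filters,)),
        "pc_w": ad.parameter(
            rng, (pc_out, c.conv1_filters, kp, kp), c.conv1_filters * kp * kp
        ),
        "pc_b": ad.zeros_parameter((pc_out,)),
        "route_w": ad.parameter(
            rng,
            (c.n_primary_caps, c.higher_caps_dim, c.primary_caps_dim),
            c.primary_caps_dim,
        ),
        "fc_w": ad.parameter(rng, (c.higher_caps_dim, fc_out), c.higher_caps_dim),
        "fc_b": ad.zeros_parameter((fc_out,)),
        "dec1_w": ad.parameter(
            rng, (c.decoder_fc_channels, d1, 4, 4), c.decoder_fc_channels * 16
        ),
        "dec1_b": ad.zeros_parameter((d1,)),
        "dec2_w": ad.parameter(rng, (d1, d2, 4, 4), d1 * 16),
        "dec2_b": ad.zeros_parameter((d2,)),
        "dec3_w": ad.parameter(rng, (d2, c.in_channels, 3, 3), d2 * 9),
        "dec3_b": ad.zeros_parameter((c.in_channels,)),
    }
    return p


@dataclass
class TrainedModel:
    """Parameters + config + the per-epoch MAE training log."""

    params: dict[str, Tensor]
    config: EncoderConfig
    training_log: list[float] = field(default_factory=list)
    seed: int = 0


def encoder_graph(
    params: dict[str, Tensor], config: EncoderConfig, x: Tensor
) -> dict[str, Tensor]:
    """Autodiff encoder pass.  x: [N, 3, H, W].  Returns L1, u (primary
    capsules, post-squash), L3 (higher capsule vector [N, Dh])."""
    c = config
    l1 = ad.relu(ad.conv2d(x, params["conv1_w"], params["conv1_b"], c.conv1_stride))
    pc = ad.conv2d(l1, params["pc_w"], params["pc_b"], c.primary_caps_stride)
    n = x.shape[0]
    # [N, C*D, h, w] -> capsules [N, C*h*w, D]: channel-major capsule order
    pc = ad.reshape(
        pc, (n, c.primary_caps_channels, c.primary_caps_dim, c.primary_hw, c.primary_hw)
    )
    pc = ad.transpose(pc, (0, 1, 3, 4, 2))  # [N, C, h, w, D]
    u = _squash_t(ad.reshape(pc, (n, c.n_primary_caps, c.primary_caps_dim)))
    u_hat = ad.caps_predict(u, params["route_w"])  # [N, I, Dh]
    b = Tensor(np.zeros((n, c.n_primary_caps, 1), dtype=np.float32))
    axis = 1 if c.routing_normalization == "over_lower" else 2
    v = None
    for it in range(c.routing_iters):
        cc = ad.softmax(b, axis=axis)
        s = ad.tsum(ad.mul(cc, u_hat), axis=1)  # [N, Dh]
        v = _squash_t(s)
        if it < c.routing_iters - 1:
            agree = ad.tsum(
                ad.mul(u_hat, ad.reshape(v, (n, 1, c.higher_caps_dim))),
                axis=2,
                keepdims=True,
            )
            b = ad.add(b, agree)
    return {"L1": l1, "u": u, "L3": v}


def decoder_graph(
    params: dict[str, Tensor], config: EncoderConfig, v: Tensor
) -> Tensor:
    """Autodiff decoder pass: higher capsule [N, Dh] -> image [N, 3, H, W]."""
    c = config
    n = v.shape[0]
    h = ad.relu(ad.add(ad.matmul(v, params["fc_w"]), params["fc_b"]))
    h = ad.reshape(h, (n, c.decoder_fc_channels, c.primary_hw, c.primary_hw))
    h = ad.relu(
        ad.conv_transpose2d(h, params["dec1_w"], params["dec1_b"], stride=2, padding=1)
    )
    h = ad.relu(
        ad.conv_transpose2d(h, params["dec2_w"], params["dec2_b"], stride=2, padding=1)
    )
    out = ad.sigmoid(
        ad.conv_transpose2d(h, params["dec3_w"], params["dec3_b"], stride=1, padding=0)
    )
    return out


def _as_batch(images) -> np.ndarray:
    if isinstance(images, np.ndarray):
        x = images.astype(np.float32)
        if x.ndim == 3:
            x = x[None]
        return x
    if isinstance(images, RenderedImage):
        images = [images]
    return images_to_array(images)


def encoder_forward(
    model: TrainedModel, images, batch_size: int = 64
) -> dict[str, np.ndarray]:
    """Run the trained encoder; returns numpy feature maps per layer.

    Output shapes (per image): L1 [F, h1, h1]; L2 [C, h2, h2, D] (post-
    squash capsule grid); L2N [C, h2, h2]; L3 [1, Dh].
    """
    c = model.config
    x = _as_batch(images)
    if x.shape[1:] != (c.in_channels, c.input_hw, c.input_hw):
        raise ValueError(
            f"expected input shape [N, {c.in_channels}, {c.input_hw}, "
            f"{c.input_hw}], got {x.shape}"
        )
    outs: dict[str, list[np.ndarray]] = {"L1": [], "L2": [], "L3": []}
    for lo in range(0, x.shape[0], batch_size):
        xb = Tensor(x[lo : lo + batch_size])
        g = encoder_graph(model.params, c, xb)
        nb = xb.shape[0]
        outs["L1"].append(g["L1"].data.copy())
        outs["L2"].append(
            g["u"].data.reshape(
                nb, c.primary_caps_channels, c.primary_hw, c.primary_hw,
                c.primary_caps_dim,
            ).copy()
        )
        outs["L3"].append(g["L3"].data.reshape(nb, 1, c.higher_caps_dim).copy())
    res = {k: np.concatenate(v) for k, v in outs.items()}
    res["L2N"] = capn(res["L2"])
    return res


def decoder_forward(model: TrainedModel, L3: np.ndarray) -> np.ndarray:
    """Reconstruct images from higher-capsule vectors [N, 1, Dh] or [N, Dh]."""
    c = model.config
    v = np.asarray(L3, dtype=np.float32)
    if v.ndim == 3:
        v = v.reshape(v.shape[0], -1)
    if v.ndim == 1:
        v = v[None]
    if v.shape[1] != c.higher_caps_dim:
        raise ValueError(f"L3 must have dimension {c.higher_caps_dim}")
    out = decoder_graph(model.params, c, Tensor(v))
    return out.data.copy()


def train(
    images,
    epochs: int,
    lr: float = 1e-4,
    seed: int = 0,
    config: EncoderConfig | None = None,
    batch_size: int | None = None,
) -> TrainedModel:
    """Train the autoencoder with Adam on MAE reconstruction loss.

    Fully seeded (parameter init and batch shuffling derive from ``seed``).
    ``batch_size=None`` trains full-batch.  Raises on non-finite loss.
    """
    x = _as_batch(images)
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    cfg = config or EncoderConfig()
    params = init_params(cfg, seed)
    opt = ad.Adam(params, lr=lr)
    shuffle_rng = np.random.default_rng(seed + 1)
    n = x.shape[0]
    bs = n if batch_size is None else min(batch_size, n)
    log: list[float] = []
    for _ in range(epochs):
        gc.collect()  # keep peak memory flat across epochs
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, bs):
            idx = order[lo : lo + bs]
            xb = Tensor(x[idx])
            enc = encoder_graph(params, cfg, xb)
            recon = decoder_graph(params, cfg, enc["L3"])
            loss = ad.mean(ad.absolute(recon - xb))
            val = float(loss.data)
            if not np.isfinite(val):
                raise FloatingPointError("training diverged: non-finite loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += val * len(idx)
        log.append(epoch_loss / n)
    return TrainedModel(params=params, config=cfg, training_log=log, seed=seed)


def extract_features(
    model: TrainedModel, images, batch_size: int = 64
) -> dict[str, np.ndarray]:
    """Flattened per-layer feature tables, one row per image.

    Row layouts (C-order of the per-image shapes): L1 [F*h1*h1], L2
    [C*h2*h2*D] (capsule-major, capsule components contiguous), L2N
    [C*h2*h2], L3 [Dh].
    """
    maps = encoder_forward(model, images, batch_size=batch_size)
    n = maps["L1"].shape[0]
    return {k: maps[k].reshape(n, -1) for k in ("L1", "L2", "L2N", "L3")}


def reconstruct(model: TrainedModel, images, batch_size: int = 64) -> np.ndarray:
    """End-to-end autoencoder output for the given images: [N, 3, H, W]."""
    maps = encoder_forward(model, images, batch_size=batch_size)
    return decoder_forward(model, maps["L3"])


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Save parameters, config, seed and training log in one .npz container."""
    arrays = {k: p.data for k, p in model.params.items()}
    meta = json.dumps(
        {
            "config": asdict(model.config),
            "seed": model.seed,
            "training_log": model.training_log,
        }
    )
    np.savez(path, __meta__=np.array(meta), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        cfg_d = meta["config"]
        cfg_d["decoder_channels"] = tuple(cfg_d["decoder_channels"])
        config = EncoderConfig(**cfg_d)
        params = {
            k: Tensor(z[k], requires_grad=True)
            for k in z.files
            if k != "__meta__"
        }
    return TrainedModel(
        params=params,
        config=config,
        training_log=list(meta["training_log"]),
        seed=meta["seed"],
    )
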