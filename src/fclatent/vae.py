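"""Convolutional beta-VAE over hemisphere image pairs.

The encoder turns a left/right pair of H x W connectivity images into the
mean and standard deviation of an N-dimensional diagonal-Gaussian posterior;
the decoder mirrors it exactly (transposed convolutions are the adjoints of
the encoder's convolutions).  Layer 1 convolves each hemisphere separately
with 8 x 8 kernels and combines the two streams (channel concatenation by
default); layers 2-5 use 4 x 4 kernels.  All convolutions stride by 2, pad
circularly along azimuth (width) and with zeros along elevation (height).

The training objective is

    L = ||x - x'||^2  +  beta * KL[ N(mu_z, sigma_z) || N(0, I) ]

with the squared error summed over valid pixels of both hemispheres, the KL
in closed form for diagonal Gaussians, per-sample terms averaged over the
mini-batch.  Optimization is Adam with a step-decayed learning rate
(divided by ``lr_decay_factor`` every ``lr_decay_every`` epochs).

Embeddings for analysis are the posterior means mu_z; sampling through the
reparameterization z = mu + sigma * eps is used during training only.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._nn import Adam, Conv2d, ConvTranspose2d, Linear, relu, relu_grad
from .fc import ProfileSet
from .reformat import GridImage, ResamplingMap, profiles_to_images

__all__ = [
    "VAEConfig",
    "PosteriorParams",
    "ConvVAE",
    "TrainedModel",
    "TrainingDivergenceError",
    "loss",
    "encode",
    "reparameterize",
    "decode",
    "train",
    "traverse_latent",
    "save_model",
    "load_model",
]

_N_LAYERS = 5
_LOGVAR_CLIP = 15.0


class TrainingDivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class VAEConfig:
    """Architecture and schedule of the embedding model.

    ``channels[0]`` is the per-hemisphere width of the first layer; kernels
    are fixed at 8 (layer 1) and 4 (layers 2-5), all with stride 2, so the
    grid must be divisible by 2**5 = 32.  The default schedule is batch 128,
    initial learning rate 1e-4, 50 epochs, rate divided by 10 every 20
    epochs; ``small()`` is a desk-scale preset for 32 x 32 grids.
    """

    zdim: int = 2
    beta: float = 2.0
    batch_size: int = 128
    lr: float = 1e-4
    epochs: int = 50
    lr_decay_factor: float = 10.0
    lr_decay_every: int = 20
    channels: tuple[int, ...] = (32, 64, 128, 256, 512)
    grid: tuple[int, int] = (192, 192)
    combine: str = "concat"          # "concat" | "sum" of hemisphere streams
    recon_valid_only: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "grid", tuple(self.grid))
        if self.zdim < 1 or self.beta < 0:
            raise ValueError("need zdim >= 1 and beta >= 0")
        if len(self.channels) != _N_LAYERS:
            raise ValueError(f"need {_N_LAYERS} channel widths")
        if self.grid[0] % 32 or self.grid[1] % 32:
            raise ValueError("grid sides must be divisible by 32")
        if self.combine not in ("concat", "sum"):
            raise ValueError("combine must be 'concat' or 'sum'")
        if self.lr_decay_every > self.epochs:
            raise ValueError("decay period must not exceed the epoch count")

    @classmethod
    def small(cls, **overrides) -> "VAEConfig":
        """Desk-scale preset: 32 x 32 grid, narrow layers, short schedule."""
        base = dict(
            zdim=2, beta=2.0, batch_size=32, lr=1e-3, epochs=10,
            lr_decay_every=10, channels=(8, 16, 16, 32, 32), grid=(32, 32),
        )
        base.update(overrides)
        if "lr_decay_every" not in overrides:
            base["lr_decay_every"] = min(base["lr_decay_every"], base["epochs"])
        return cls(**base)

    def learning_rate_at(self, epoch: int) -> float:
        """Learning rate in force during a given 0-based epoch."""
        return self.lr / self.lr_decay_factor ** (epoch // self.lr_decay_every)


@dataclass(frozen=True)
class PosteriorParams:
    """Per-sample latent posterior: mean and standard deviation (N each)."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma).all() and (self.sigma > 0).all()):
            raise ValueError("sigma must be finite and strictly positive")


class ConvVAE:
    """Encoder/decoder pair; see module docstring for the architecture."""

    def __init__(self, config: VAEConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed))
        c = config.channels
        c1c = 2 * c[0] if config.combine == "concat" else c[0]
        widths = [c1c, c[1], c[2], c[3], c[4]]
        self.enc1_l = Conv2d(1, c[0], 8, 2, rng)
        self.enc1_r = Conv2d(1, c[0], 8, 2, rng)
        self.enc = [Conv2d(widths[i - 1], widths[i], 4, 2, rng) for i in range(1, 5)]
        hf, wf = config.grid[0] // 32, config.grid[1] // 32
        self._feat_shape = (c[4], hf, wf)
        nfeat = c[4] * hf * wf
        self.fc_enc = Linear(nfeat, 2 * config.zdim, rng)
        self.fc_dec = Linear(config.zdim, nfeat, rng)
        self.dec = [ConvTranspose2d(widths[i], widths[i - 1], 4, 2, rng)
                    for i in range(4, 0, -1)]
        self.dec1_l = ConvTranspose2d(c[0], 1, 8, 2, rng)
        self.dec1_r = ConvTranspose2d(c[0], 1, 8, 2, rng)
        self._cache: dict = {}

    # ---- layers bookkeeping -------------------------------------------------
    def layers(self):
        return [self.enc1_l, self.enc1_r, *self.enc, self.fc_enc,
                self.fc_dec, *self.dec, self.dec1_l, self.dec1_r]

    # ---- encoder ------------------------------------------------------------
    def encode_images(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """x: (B, 2, H, W) -> (mu, logvar), each (B, zdim)."""
        if x.ndim != 4 or x.shape[1] != 2 or x.shape[2:] != self.config.grid:
            raise ValueError("input shape does not match the configured grid")
        hl = self.enc1_l.forward(x[:, :1])
        hr = self.enc1_r.forward(x[:, 1:])
        pre = np.concatenate([hl, hr], axis=1) if self.config.combine == "concat" else hl + hr
        pres = [pre]
        h = relu(pre)
        for layer in self.enc:
            pre = layer.forward(h)
            pres.append(pre)
            h = relu(pre)
        flat = h.reshape(h.shape[0], -1)
        out = self.fc_enc.forward(flat)
        n = self.config.zdim
        mu, logvar = out[:, :n], np.clip(out[:, n:], -_LOGVAR_CLIP, _LOGVAR_CLIP)
        self._cache["enc_pres"] = pres
        self._cache["enc_feat_shape"] = h.shape
        return mu, logvar

    def encoder_backward(self, dmu: np.ndarray, dlogvar: np.ndarray) -> None:
        dout = np.concatenate([dmu, dlogvar], axis=1)
        dflat = self.fc_enc.backward(dout)
        pres = self._cache["enc_pres"]
        dh = dflat.reshape(self._cache["enc_feat_shape"])
        for layer, pre in zip(reversed(self.enc), reversed(pres[1:])):
            dh = layer.backward(relu_grad(dh, pre))
        dpre = relu_grad(dh, pres[0])
        if self.config.combine == "concat":
            c0 = self.config.channels[0]
            self.enc1_l.backward(dpre[:, :c0])
            self.enc1_r.backward(dpre[:, c0:])
        else:
            self.enc1_l.backward(dpre)
            self.enc1_r.backward(dpre)

    # ---- decoder ------------------------------------------------------------
    def decode_z(self, z: np.ndarray) -> np.ndarray:
        """z: (B, zdim) -> images (B, 2, H, W)."""
        if z.ndim != 2 or z.shape[1] != self.config.zdim:
            raise ValueError("latent vector length does not match zdim")
        fpre = self.fc_dec.forward(z)
        h = relu(fpre).reshape(z.shape[0], *self._feat_shape)
        pres = [fpre]
        for layer in self.dec:
            pre = layer.forward(h)
            pres.append(pre)
            h = relu(pre)
        if self.config.combine == "concat":
            c0 = self.config.channels[0]
            xl = self.dec1_l.forward(h[:, :c0])
            xr = self.dec1_r.forward(h[:, c0:])
        else:
            xl = self.dec1_l.forward(h)
            xr = self.dec1_r.forward(h)
        self._cache["dec_pres"] = pres
        return np.concatenate([xl, xr], axis=1)

    def decoder_backward(self, dx: np.ndarray) -> np.ndarray:
        dl = self.dec1_l.backward(dx[:, :1])
        dr = self.dec1_r.backward(dx[:, 1:])
        dh = (np.concatenate([dl, dr], axis=1)
              if self.config.combine == "concat" else dl + dr)
        pres = self._cache["dec_pres"]
        for layer, pre in zip(reversed(self.dec), reversed(pres[1:])):
            dh = layer.backward(relu_grad(dh, pre))
        dflat = relu_grad(dh.reshape(dh.shape[0], -1), pres[0])
        return self.fc_dec.backward(dflat)


@dataclass
class TrainedModel:
    """A fitted model plus its config, pixel masks and per-epoch loss trace."""

    net: ConvVAE
    config: VAEConfig
    loss_trace: pd.DataFrame      # columns: epoch, recon, kl, lr
    mask: np.ndarray              # (2, H, W) bool valid-pixel mask

    def grid_image(self, arr: np.ndarray) -> GridImage:
        """Wrap a (2, H, W) array as a GridImage under the model's masks."""
        arr = arr * self.mask
        return GridImage(left=arr[0], right=arr[1],
                         mask_left=self.mask[0], mask_right=self.mask[1])


def _as_batch(images) -> np.ndarray:
    if isinstance(images, GridImage):
        return images.stack()[None]
    arr = np.asarray(images, dtype=float)
    if arr.ndim == 3:
        arr = arr[None]
    return arr


def loss(
    x,
    x_recon,
    post: PosteriorParams,
    beta: float,
    mask: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Total loss and its (reconstruction, KL) breakdown, averaged per sample.

    reconstruction = sum of squared differences over (valid) pixels of both
    hemispheres; KL = 0.5 * sum_d (mu_d^2 + sigma_d^2 - 1 - ln sigma_d^2).
    """
    x = _as_batch(x)
    xr = _as_batch(x_recon)
    if x.shape != xr.shape:
        raise ValueError("input and reconstruction shapes disagree")
    mu = np.atleast_2d(post.mu)
    sigma = np.atleast_2d(post.sigma)
    diff = xr - x
    if mask is not None:
        diff = diff * mask
    recon = float((diff ** 2).sum(axis=(1, 2, 3)).mean())
    var = sigma ** 2
    kl = float((0.5 * (mu ** 2 + var - 1.0 - np.log(var))).sum(axis=1).mean())
    return recon + beta * kl, recon, kl


def encode(model: TrainedModel, image) -> PosteriorParams:
    """Posterior parameters (mu_z, sigma_z) of one image or a batch."""
    x = _as_batch(image)
    mu, logvar = model.net.encode_images(x)
    post = PosteriorParams(mu=mu, sigma=np.exp(0.5 * logvar))
    return post


def reparameterize(post: PosteriorParams, seed: int = 0) -> np.ndarray:
    """z = mu + sigma * eps with eps ~ N(0, I) from the seeded stream."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mu = np.atleast_2d(post.mu)
    sigma = np.atleast_2d(post.sigma)
    return mu + sigma * rng.standard_normal(mu.shape)


def decode(model: TrainedModel, z: np.ndarray) -> GridImage | list[GridImage]:
    """Deterministic decode of latent point(s) into hemisphere image pairs."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    out = model.net.decode_z(z)
    images = [model.grid_image(out[i]) for i in range(out.shape[0])]
    return images[0] if len(images) == 1 else images


def embed_profiles(model: TrainedModel, profiles, rmap: ResamplingMap) -> PosteriorParams:
    """Convenience: reformat profile vectors and encode them (batched)."""
    mat = profiles.profiles if isinstance(profiles, ProfileSet) else np.atleast_2d(profiles)
    images = profiles_to_images(mat, rmap)
    mus, sigmas = [], []
    bs = max(model.config.batch_size, 64)
    for i in range(0, images.shape[0], bs):
        p = encode(model, images[i:i + bs])
        mus.append(p.mu)
        sigmas.append(p.sigma)
    return PosteriorParams(mu=np.vstack(mus), sigma=np.vstack(sigmas))


def train(profiles, rmap: ResamplingMap, config: VAEConfig) -> TrainedModel:
    """Fit the model on reformatted FC profiles.

    ``profiles`` may be a ProfileSet, a (n, n_cortex) profile matrix, or a
    prebuilt (n, 2, H, W) image stack.  Mini-batches are drawn by seeded
    shuffling each epoch; the run is reproducible given (config, data).
    """
    if isinstance(profiles, ProfileSet):
        images = profiles_to_images(profiles.profiles, rmap)
    else:
        arr = np.asarray(profiles, dtype=float)
        images = arr if arr.ndim == 4 else profiles_to_images(arr, rmap)
    n = images.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    mask = np.stack([rmap.mask_left, rmap.mask_right]).astype(float)
    loss_mask = mask if config.recon_valid_only else None

    ss = np.random.SeedSequence(config.seed).spawn(3)
    net = ConvVAE(config, np.random.default_rng(ss[0]))
    shuffle_rng = np.random.default_rng(ss[1])
    eps_rng = np.random.default_rng(ss[2])
    opt = Adam(net.layers(), lr=config.lr)

    trace = []
    for epoch in range(config.epochs):
        opt.lr = config.learning_rate_at(epoch)
        order = shuffle_rng.permutation(n)
        recon_sum = kl_sum = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            x = images[idx]
            b = x.shape[0]
            opt.zero_grad()
            mu, logvar = net.encode_images(x)
            sigma = np.exp(0.5 * logvar)
            eps = eps_rng.standard_normal(mu.shape)
            z = mu + sigma * eps
            xr = net.decode_z(z)
            diff = xr - x
            if loss_mask is not None:
                diff = diff * loss_mask
            recon = (diff ** 2).sum(axis=(1, 2, 3)).mean()
            kl = (0.5 * (mu ** 2 + sigma ** 2 - 1.0 - logvar)).sum(axis=1).mean()
            if not np.isfinite(recon + kl):
                raise TrainingDivergenceError(f"non-finite loss at epoch {epoch + 1}")
            # backward pass of  recon.mean + beta * kl.mean
            dxr = 2.0 * diff / b
            dz = net.decoder_backward(dxr)
            dmu = dz + config.beta * mu / b
            dlogvar = dz * eps * 0.5 * sigma + config.beta * 0.5 * (sigma ** 2 - 1.0) / b
            net.encoder_backward(dmu, dlogvar)
            opt.step()
            recon_sum += recon * b
            kl_sum += kl * b
        trace.append((epoch + 1, recon_sum / n, kl_sum / n, opt.lr))
    return TrainedModel(
        net=net,
        config=config,
        loss_trace=pd.DataFrame(trace, columns=["epoch", "recon", "kl", "lr"]),
        mask=mask.astype(bool),
    )


def traverse_latent(
    model: TrainedModel,
    dim: int,
    lo: float,
    hi: float,
    steps: int,
    others_at: float = 0.0,
) -> tuple[np.ndarray, list[GridImage]]:
    """Decode a sweep of one latent coordinate, the others held fixed.

    Returns the swept values and the decoded hemisphere image pairs; vertex
    maps follow via ``reformat.from_grid``.
    """
    if steps < 2:
        raise ValueError("need at least 2 steps")
    if not (0 <= dim < model.config.zdim):
        raise ValueError("latent dimension out of range")
    values = np.linspace(lo, hi, steps)
    z = np.full((steps, model.config.zdim), others_at, dtype=float)
    z[:, dim] = values
    images = decode(model, z)
    if isinstance(images, GridImage):
        images = [images]
    return values, images


# ---- serialization ----------------------------------------------------------

def save_model(model: TrainedModel, path) -> None:
    """Single-file .npz archive: JSON config + parameter tensors + trace."""
    payload = {"config": np.array(json.dumps(asdict(model.config))),
               "mask": model.mask,
               "trace": model.loss_trace.to_numpy(dtype=float).reshape(-1, 4)}
    for i, layer in enumerate(model.net.layers()):
        payload[f"w{i}"] = layer.weight
        payload[f"b{i}"] = layer.bias
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_model(path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["config"]))
        cfg_dict["channels"] = tuple(cfg_dict["channels"])
        cfg_dict["grid"] = tuple(cfg_dict["grid"])
        config = VAEConfig(**cfg_dict)
        net = ConvVAE(config)
        for i, layer in enumerate(net.layers()):
            layer.weight = data[f"w{i}"]
            layer.bias = data[f"b{i}"]
            layer.dweight = np.zeros_like(layer.weight)
            layer.dbias = np.zeros_like(layer.bias)
        trace = pd.DataFrame(data["trace"], columns=["epoch", "recon", "kl", "lr"])
        return TrainedModel(net=net, config=config, loss_trace=trace,
                            mask=data["mask"].astype(bool))
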