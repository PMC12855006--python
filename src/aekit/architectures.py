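"""The five autoencoder families as explicit computation graphs.

Hidden widths follow a geometric contraction controlled by the encoding
factor, clamped below at the latent width:

    h_i = max(floor(h_{i-1} / e), L_dim),  h_0 = input width.

Every fully connected block is linear → batch-norm → dropout → ReLU, with the
ReLU omitted on the last block before the latent layer; output layers are
plain linear (sigmoid under binary cross-entropy). Decoders mirror their
encoders. Downstream embeddings are always the posterior mean (ε = 0) with
batch-norm in inference mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import nn
from .datamodel import MultiModalDataset, OntologyMap, RunConfig

__all__ = [
    "build_hidden_dims", "reparameterize", "MaskSet", "StackixPlan",
    "Vanillix", "Varix", "Ontix", "Stackix", "ImageVAE", "XModalixPair",
    "LatentClassifier", "build_vanillix", "build_varix", "build_stackix",
    "build_ontix_masks", "build_ontix", "build_image_vae", "build_xmodalix",
    "translate", "n_parameters",
]


def build_hidden_dims(input_dim: int, e: float, latent_dim: int,
                      n_hidden: int) -> list[int]:
    """Hidden layer widths h_1..h_n by repeated division by ``e``."""
    if latent_dim < 1 or input_dim < latent_dim:
        raise ValueError("need input_dim >= latent_dim >= 1")
    if e <= 1:
        raise ValueError("encoding factor must exceed 1")
    dims, h = [], input_dim
    for _ in range(n_hidden):
        h = max(int(np.floor(h / e)), latent_dim)
        dims.append(h)
    return dims


def reparameterize(mu: np.ndarray, log_var: np.ndarray,
                   eps: np.ndarray) -> np.ndarray:
    """z = mu + eps * exp(log_var / 2)."""
    mu, log_var, eps = map(np.asarray, (mu, log_var, eps))
    if not (mu.shape == log_var.shape == eps.shape):
        raise ValueError("mu, log_var and eps must share a shape")
    return mu + eps * np.exp(0.5 * log_var)


@dataclass
class MaskSet:
    """Decoder masks ordered latent-side first; entries 1 iff an edge exists."""

    masks: list[np.ndarray]
    layer_names: list[str]

    def check(self, weights: list[np.ndarray]) -> bool:
        """True iff every masked position is exactly zero in ``weights``."""
        return all(np.all(w[m == 0] == 0.0)
                   for w, m in zip(weights, self.masks))


@dataclass
class StackixPlan:
    modality_names: list[str]
    modality_dims: list[int]  # k_input per modality
    latent_dims: list[int]    # d per modality
    top_latent_dim: int

    @property
    def top_input_dim(self) -> int:
        return sum(self.latent_dims)


# ---------------------------------------------------------------- MLP helpers

def _encoder_trunk(input_dim, hidden, dropout, rng):
    mods, prev = [], input_dim
    for i, h in enumerate(hidden):
        mods += [nn.Linear(prev, h, rng), nn.BatchNorm1d(h), nn.Dropout(dropout, rng)]
        if i < len(hidden) - 1:  # no ReLU on the last layer before the latent
            mods.append(nn.ReLU())
        prev = h
    return nn.Sequential(*mods), prev


def _decoder_trunk(latent_dim, hidden, output_dim, dropout, rng, sigmoid_out):
    mods, prev = [], latent_dim
    for h in reversed(hidden):
        mods += [nn.Linear(prev, h, rng), nn.BatchNorm1d(h),
                 nn.Dropout(dropout, rng), nn.ReLU()]
        prev = h
    mods.append(nn.Linear(prev, output_dim, rng))
    if sigmoid_out:
        mods.append(nn.Sigmoid())
    return nn.Sequential(*mods)


# --------------------------------------------------------------------- models

class _AEBase(nn.Module):
    is_variational = False

    def masked_layers(self) -> list[nn.MaskedLinear]:
        return [m for m in self.modules() if isinstance(m, nn.MaskedLinear)]

    def apply_masks(self) -> None:
        for m in self.masked_layers():
            m.apply_mask()

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Deterministic embedding (mu, eps=0, inference-mode batch norm)."""
        was_training = self.training
        self.eval()
        out = self.encode(nn.Tensor(np.asarray(x, dtype=np.float64))).data
        if was_training:
            self.train()
        return out

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        was_training = self.training
        self.eval()
        out = self.forward(nn.Tensor(np.asarray(x, dtype=np.float64)))[0].data
        if was_training:
            self.train()
        return out


class Vanillix(_AEBase):
    """Plain autoencoder with a deterministic linear bottleneck."""

    def __init__(self, input_dim: int, latent_dim: int, hidden: list[int],
                 dropout: float, rng: np.random.Generator,
                 sigmoid_out: bool = False):
        super().__init__()
        self.input_dim, self.latent_dim, self.hidden = input_dim, latent_dim, hidden
        self.encoder, trunk_out = _encoder_trunk(input_dim, hidden, dropout, rng)
        self.to_latent = nn.Linear(trunk_out, latent_dim, rng)
        self.decoder = _decoder_trunk(latent_dim, hidden, input_dim, dropout,
                                      rng, sigmoid_out)

    def encode(self, x):
        return self.to_latent(self.encoder(x))

    def decode(self, z):
        return self.decoder(z)

    def forward(self, x):
        z = self.encode(x)
        return self.decode(z), None, None, z

    def plan(self) -> dict:
        return {"architecture": "vanillix", "input_dim": self.input_dim,
                "hidden_dims": self.hidden, "latent_dim": self.latent_dim}


class Varix(_AEBase):
    """Variational autoencoder with a standard-normal prior."""

    is_variational = True

    def __init__(self, input_dim: int, latent_dim: int, hidden: list[int],
                 dropout: float, rng: np.random.Generator,
                 sigmoid_out: bool = False):
        super().__init__()
        self.input_dim, self.latent_dim, self.hidden = input_dim, latent_dim, hidden
        self.rng = rng
        self.encoder, trunk_out = _encoder_trunk(input_dim, hidden, dropout, rng)
        self.mu_head = nn.Linear(trunk_out, latent_dim, rng)
        self.logvar_head = nn.Linear(trunk_out, latent_dim, rng)
        self.decoder = _decoder_trunk(latent_dim, hidden, input_dim, dropout,
                                      rng, sigmoid_out)

    def encode_dist(self, x):
        h = self.encoder(x)
        return self.mu_head(h), self.logvar_head(h)

    def encode(self, x):
        return self.encode_dist(x)[0]

    def sample_z(self, mu, log_var):
        if self.training:
            eps = self.rng.standard_normal(mu.shape)
        else:
            eps = np.zeros(mu.shape)
        return mu + nn.Tensor(eps) * (log_var * 0.5).exp()

    def decode(self, z):
        return self.decoder(z)

    def forward(self, x):
        mu, log_var = self.encode_dist(x)
        z = self.sample_z(mu, log_var)
        return self.decode(z), mu, log_var, z

    def plan(self) -> dict:
        return {"architecture": "varix", "input_dim": self.input_dim,
                "hidden_dims": self.hidden, "latent_dim": self.latent_dim}


class Ontix(_AEBase):
    """Variational encoder with an ontology-masked decoder.

    The decoder stack runs latent → (optional dense widening when
    latent_dim < #top terms) → masked layers down to the features; masked
    weights are zeroed at construction and must be re-zeroed after every
    optimizer step (``apply_masks``).
    """

    is_variational = True

    def __init__(self, input_dim: int, latent_dim: int, hidden: list[int],
                 mask_set: MaskSet, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.input_dim, self.latent_dim, self.hidden = input_dim, latent_dim, hidden
        self.mask_set = mask_set
        self.rng = rng
        self.encoder, trunk_out = _encoder_trunk(input_dim, hidden, dropout, rng)
        self.mu_head = nn.Linear(trunk_out, latent_dim, rng)
        self.logvar_head = nn.Linear(trunk_out, latent_dim, rng)

        n_top = mask_set.masks[0].shape[0]
        mods: list[nn.Module] = []
        if latent_dim < n_top:
            mods += [nn.Linear(latent_dim, n_top, rng), nn.ReLU()]
        elif latent_dim > n_top:
            raise ValueError(f"latent_dim {latent_dim} exceeds {n_top} top-level terms")
        for i, mask in enumerate(mask_set.masks):
            mods.append(nn.MaskedLinear(mask.shape[0], mask.shape[1], mask, rng))
            if i < len(mask_set.masks) - 1:
                mods.append(nn.ReLU())
        self.decoder = nn.Sequential(*mods)

    def encode_dist(self, x):
        h = self.encoder(x)
        return self.mu_head(h), self.logvar_head(h)

    def encode(self, x):
        return self.encode_dist(x)[0]

    def sample_z(self, mu, log_var):
        eps = self.rng.standard_normal(mu.shape) if self.training else np.zeros(mu.shape)
        return mu + nn.Tensor(eps) * (log_var * 0.5).exp()

    def decode(self, z):
        return self.decoder(z)

    def forward(self, x):
        mu, log_var = self.encode_dist(x)
        z = self.sample_z(mu, log_var)
        return self.decode(z), mu, log_var, z

    def plan(self) -> dict:
        return {"architecture": "ontix", "input_dim": self.input_dim,
                "hidden_dims": self.hidden, "latent_dim": self.latent_dim,
                "mask_shapes": [list(m.shape) for m in self.mask_set.masks]}


class Stackix(nn.Module):
    """Per-modality VAEs plus a top VAE over their concatenated embeddings."""

    is_variational = True

    def __init__(self, plan: StackixPlan, config: RunConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.stack_plan = plan
        self.modality_vaes = [
            Varix(k, d, build_hidden_dims(k, config.encoding_factor, d,
                                          config.n_hidden),
                  config.dropout, rng)
            for k, d in zip(plan.modality_dims, plan.latent_dims)
        ]
        top_in = plan.top_input_dim
        self.top_vae = Varix(
            top_in, plan.top_latent_dim,
            build_hidden_dims(top_in, config.encoding_factor,
                              plan.top_latent_dim, config.n_hidden),
            config.dropout, rng)

    def concat_embeddings(self, blocks: list[np.ndarray]) -> np.ndarray:
        return np.concatenate(
            [vae.embed(x) for vae, x in zip(self.modality_vaes, blocks)], axis=1)

    def embed(self, blocks: list[np.ndarray]) -> np.ndarray:
        return self.top_vae.embed(self.concat_embeddings(blocks))

    def plan(self) -> dict:
        return {"architecture": "stackix",
                "modalities": self.stack_plan.modality_names,
                "modality_latent_dims": self.stack_plan.latent_dims,
                "latent_dim": self.stack_plan.top_latent_dim}


class ImageVAE(_AEBase):
    """Convolutional VAE: five stride-2 kernel-4 conv layers each side."""

    is_variational = True

    def __init__(self, channels: int, side: int, latent_dim: int,
                 rng: np.random.Generator, channel_base: int = 32,
                 sigmoid_out: bool = True):
        super().__init__()
        if side % 32 != 0:
            raise ValueError(f"image side {side} must be divisible by 32")
        self.channels, self.side, self.latent_dim = channels, side, latent_dim
        self.rng = rng
        widths = [channel_base * 2 ** i for i in range(5)]
        self.widths = widths
        enc: list[nn.Module] = []
        prev = channels
        for w in widths:
            enc += [nn.Conv2d(prev, w, rng), nn.BatchNorm2d(w), nn.ReLU()]
            prev = w
        self.encoder = nn.Sequential(*enc)
        self.post_side = side // 32
        flat = widths[-1] * self.post_side ** 2
        self.flatten = nn.Flatten()
        self.mu_head = nn.Linear(flat, latent_dim, rng)
        self.logvar_head = nn.Linear(flat, latent_dim, rng)
        self.from_latent = nn.Linear(latent_dim, flat, rng)
        dec: list[nn.Module] = []
        rev = list(reversed(widths))
        for i in range(4):
            dec += [nn.ConvTranspose2d(rev[i], rev[i + 1], rng),
                    nn.BatchNorm2d(rev[i + 1]), nn.ReLU()]
        dec.append(nn.ConvTranspose2d(rev[-1], channels, rng))
        if sigmoid_out:
            dec.append(nn.Sigmoid())
        self.decoder = nn.Sequential(*dec)

    def encode_dist(self, x):
        h = self.flatten(self.encoder(x))
        return self.mu_head(h), self.logvar_head(h)

    def encode(self, x):
        return self.encode_dist(x)[0]

    def sample_z(self, mu, log_var):
        eps = self.rng.standard_normal(mu.shape) if self.training else np.zeros(mu.shape)
        return mu + nn.Tensor(eps) * (log_var * 0.5).exp()

    def decode(self, z):
        h = self.from_latent(z)
        n = h.shape[0]
        h = h.reshape(n, self.widths[-1], self.post_side, self.post_side)
        return self.decoder(h)

    def forward(self, x):
        mu, log_var = self.encode_dist(x)
        z = self.sample_z(mu, log_var)
        return self.decode(z), mu, log_var, z

    def plan(self) -> dict:
        return {"architecture": "image_vae", "channels": self.channels,
                "side": self.side, "conv_widths": self.widths,
                "latent_dim": self.latent_dim,
                "kernel": 4, "stride": 2, "padding": 1}


class LatentClassifier(nn.Module):
    """Feed-forward modality discriminator: input, two hidden layers, output."""

    def __init__(self, latent_dim: int, rng: np.random.Generator,
                 hidden: int = 64, n_classes: int = 2):
        super().__init__()
        self.net = nn.Sequential(
            nn.Linear(latent_dim, hidden, rng), nn.ReLU(),
            nn.Linear(hidden, hidden, rng), nn.ReLU(),
            nn.Linear(hidden, n_classes, rng))

    def forward(self, z):
        return self.net(z)


@dataclass
class XModalixPair:
    """Two VAEs with a shared latent width plus the adversarial classifier."""

    vae_a: _AEBase
    vae_b: _AEBase
    classifier: LatentClassifier
    latent_dim: int = field(default=0)

    def __post_init__(self):
        if self.vae_a.latent_dim != self.vae_b.latent_dim:
            raise ValueError("both VAEs must share the latent dimension")
        self.latent_dim = self.vae_a.latent_dim

    def plan(self) -> dict:
        return {"architecture": "xmodalix", "latent_dim": self.latent_dim,
                "vae_a": self.vae_a.plan(), "vae_b": self.vae_b.plan()}


# ------------------------------------------------------------------- builders

def _mk_rng(config: RunConfig) -> np.random.Generator:
    return np.random.default_rng(config.seed)


def build_vanillix(input_dim: int, config: RunConfig,
                   rng: Optional[np.random.Generator] = None) -> Vanillix:
    rng = rng or _mk_rng(config)
    hidden = build_hidden_dims(input_dim, config.encoding_factor,
                               config.latent_dim, config.n_hidden)
    return Vanillix(input_dim, config.latent_dim, hidden, config.dropout, rng,
                    sigmoid_out=config.recon_loss == "bce")


def build_varix(input_dim: int, config: RunConfig,
                rng: Optional[np.random.Generator] = None) -> Varix:
    rng = rng or _mk_rng(config)
    hidden = build_hidden_dims(input_dim, config.encoding_factor,
                               config.latent_dim, config.n_hidden)
    return Varix(input_dim, config.latent_dim, hidden, config.dropout, rng,
                 sigmoid_out=config.recon_loss == "bce")


def stackix_latent_dim(k_input: int) -> int:
    """Per-modality embedding width d = max(2, round(k_input / 8))."""
    return max(2, round(k_input / 8))


def build_stackix(dataset: MultiModalDataset, config: RunConfig,
                  rng: Optional[np.random.Generator] = None) -> Stackix:
    rng = rng or _mk_rng(config)
    plan = StackixPlan(
        modality_names=[b.name for b in dataset.blocks],
        modality_dims=[b.n_features for b in dataset.blocks],
        latent_dims=[stackix_latent_dim(b.n_features) for b in dataset.blocks],
        top_latent_dim=config.latent_dim)
    return Stackix(plan, config, rng)


def build_ontix_masks(onto: OntologyMap, features: list[str],
                      latent_dim: int) -> MaskSet:
    """Masks from latent-side terms down to features.

    One ontology level: a single (terms × features) mask with the latent
    mapping one-to-one onto level-1 terms. Two levels: (super-terms ×
    terms) then (terms × features).
    """
    missing = [f for f in features if f not in set(onto.features)]
    if missing:
        raise ValueError(f"features absent from ontology: {missing[:5]}")
    t1 = onto.level1_terms
    t1_index = {t: i for i, t in enumerate(t1)}
    f_index = {f: i for i, f in enumerate(features)}
    m1 = np.zeros((len(t1), len(features)))
    for f, t in onto.level1_edges:
        if f in f_index:
            m1[t1_index[t], f_index[f]] = 1.0
    if onto.n_levels == 1:
        masks, names = [m1], ["latent_terms->features"]
        n_top = len(t1)
    else:
        t2 = onto.level2_terms
        t2_index = {t: i for i, t in enumerate(t2)}
        m2 = np.zeros((len(t2), len(t1)))
        for c, t in onto.level2_edges:
            m2[t2_index[t], t1_index[c]] = 1.0
        masks, names = [m2, m1], ["latent_superterms->terms", "terms->features"]
        n_top = len(t2)
    if latent_dim > n_top:
        raise ValueError(f"latent_dim {latent_dim} exceeds {n_top} top-level terms")
    return MaskSet(masks=masks, layer_names=names)


def build_ontix(onto: OntologyMap, features: list[str], config: RunConfig,
                rng: Optional[np.random.Generator] = None) -> Ontix:
    rng = rng or _mk_rng(config)
    mask_set = build_ontix_masks(onto, features, config.latent_dim)
    input_dim = len(features)
    hidden = build_hidden_dims(input_dim, config.encoding_factor,
                               config.latent_dim, config.n_hidden)
    return Ontix(input_dim, config.latent_dim, hidden, mask_set,
                 config.dropout, rng)


def build_image_vae(channels: int, side: int, config: RunConfig,
                    rng: Optional[np.random.Generator] = None) -> ImageVAE:
    rng = rng or _mk_rng(config)
    return ImageVAE(channels, side, config.latent_dim, rng,
                    channel_base=config.channel_base,
                    sigmoid_out=config.recon_loss == "bce")


def build_xmodalix(input_dim_a: int, image_shape: tuple[int, int, int],
                   config: RunConfig,
                   rng: Optional[np.random.Generator] = None) -> XModalixPair:
    rng = rng or _mk_rng(config)
    vae_a = Varix(input_dim_a, config.latent_dim,
                  build_hidden_dims(input_dim_a, config.encoding_factor,
                                    config.latent_dim, config.n_hidden),
                  config.dropout, rng)
    c, h, w = image_shape
    if h != w:
        raise ValueError("only quadratic images are supported")
    vae_b = ImageVAE(c, h, config.latent_dim, rng,
                     channel_base=config.channel_base,
                     sigmoid_out=config.recon_loss == "bce")
    classifier = LatentClassifier(config.latent_dim, rng)
    return XModalixPair(vae_a=vae_a, vae_b=vae_b, classifier=classifier)


def translate(pair: XModalixPair, x_a: np.ndarray) -> np.ndarray:
    """Deterministic modality translation: encode with A (z = mu), decode with B."""
    z = pair.vae_a.embed(x_a)
    pair.vae_b.eval()
    return pair.vae_b.decode(nn.Tensor(z)).data


def decode_class_centers(pair: XModalixPair, z_by_class: dict) -> dict:
    """Decode the per-class median embedding through the B-side decoder."""
    pair.vae_b.eval()
    out = {}
    for label, z in z_by_class.items():
        center = np.median(np.asarray(z), axis=0, keepdims=True)
        out[label] = pair.vae_b.decode(nn.Tensor(center)).data[0]
    return out


def n_parameters(model: nn.Module) -> int:
    return sum(p.data.size for p in model.parameters())
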