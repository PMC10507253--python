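"""Adversarially enhanced topological node embeddings, one GAN per graph
view.

The generator is a graph-convolutional autoencoder: an encoder stack maps
the Laplace-normalized adjacency and the node attribute matrix to a low
dimensional embedding ``H_en``, and a decoder stack (over the same
normalized adjacency) reconstructs the attribute matrix as ``H_hat``.  An
MLP discriminator receives individual node attribute rows (true samples)
or reconstructed rows (false samples) and outputs a softmax probability
pair ``(p_true, p_false)``.  Generator and discriminator are optimised
alternately with Adam; the generator loss adds a mean-squared
reconstruction term (weight ``gamma``) to the adversarial term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
import pandas as pd
from autograd import grad

from .graphs import HeteroGraph
from .nn import Adam, glorot, relu, softmax

__all__ = [
    "GanConfig",
    "GeneratorParams",
    "DiscriminatorParams",
    "TopologyEmbedding",
    "GanResult",
    "gcn_layer",
    "encode",
    "decode",
    "discriminate",
    "init_generator",
    "init_discriminator",
    "adversarial_train",
]

_EPS = 1e-12


@dataclass
class GanConfig:
    """Training hyperparameters for one view's GAN.

    ``encoder_dims`` are the per-layer output widths (the last is the
    embedding width N_f); a ``None`` in ``decoder_dims`` resolves to the
    node count N_v so the decoder reconstructs the attribute matrix.
    Defaults are fixture-scale; the full-scale analogue used
    (2500, 1500) / (2500, None) / (2500, 1200).
    """

    encoder_dims: tuple = (64, 32)
    decoder_dims: tuple = (64, None)
    disc_dims: tuple = (64, 32)
    epochs: int = 200
    lr: float = 1e-3
    d_lr: float = 1e-4
    gamma: float = 10.0
    seed: int = 0

    @property
    def n_f(self) -> int:
        return self.encoder_dims[-1]


@dataclass
class GeneratorParams:
    """Encoder/decoder weight stacks; layer i maps width ``dims[i]`` to
    ``dims[i+1]``."""

    encoder: list
    decoder: list

    def __post_init__(self):
        for lo, hi in zip(self.encoder[:-1], self.encoder[1:]):
            if lo.shape[1] != hi.shape[0]:
                raise ValueError("encoder weight chain dimension mismatch")
        if self.encoder[-1].shape[1] != self.decoder[0].shape[0]:
            raise ValueError("encoder output width != decoder input width")
        for lo, hi in zip(self.decoder[:-1], self.decoder[1:]):
            if lo.shape[1] != hi.shape[0]:
                raise ValueError("decoder weight chain dimension mismatch")

    @property
    def n_f(self) -> int:
        return self.encoder[-1].shape[1]

    def tree(self) -> dict:
        return {"encoder": list(self.encoder), "decoder": list(self.decoder)}


@dataclass
class DiscriminatorParams:
    """Hidden-layer weights/biases plus a 2-way softmax output head."""

    weights: list
    biases: list

    def __post_init__(self):
        if len(self.weights) != len(self.biases):
            raise ValueError("weights/biases length mismatch")
        if self.weights[-1].shape[0] != 2:
            raise ValueError("output head must produce 2 logits")

    def tree(self) -> dict:
        return {"weights": list(self.weights), "biases": list(self.biases)}


@dataclass
class TopologyEmbedding:
    """Final encoder output plus the decoder reconstruction for one view."""

    h_en: np.ndarray
    h_hat: np.ndarray
    view: str

    def __post_init__(self):
        if not (np.isfinite(self.h_en).all() and np.isfinite(self.h_hat).all()):
            raise ValueError("non-finite entries in topology embedding")


@dataclass
class GanResult:
    embedding: TopologyEmbedding
    generator: GeneratorParams
    discriminator: DiscriminatorParams
    history: pd.DataFrame = field(repr=False)


def gcn_layer(a_norm, h, w):
    """One graph-convolution layer: ``ReLU(A_norm @ H @ W)``."""
    if a_norm.shape[1] != h.shape[0] or h.shape[1] != w.shape[0]:
        raise ValueError(
            f"gcn_layer shape mismatch: A {a_norm.shape}, H {h.shape}, W {w.shape}")
    return relu(anp.matmul(anp.matmul(a_norm, h), w))


def _encode_tree(a_norm, h, encoder):
    for w in encoder:
        h = gcn_layer(a_norm, h, w)
    return h


def _decode_tree(a_norm, h_en, decoder):
    h = h_en
    for w in decoder:
        h = gcn_layer(a_norm, h, w)
    return h


def encode(graph: HeteroGraph, params: GeneratorParams) -> np.ndarray:
    """Chain the encoder layers over the graph; returns H_en (N_v x N_f)."""
    return _encode_tree(graph.normalized, graph.attributes, params.encoder)


def decode(graph: HeteroGraph, h_en, params: GeneratorParams) -> np.ndarray:
    """Chain the decoder layers; returns the reconstruction H_hat (N_v x N_v)."""
    return _decode_tree(graph.normalized, h_en, params.decoder)


def _discriminate_tree(x, weights, biases):
    h = x
    for w, b in zip(weights[:-1], biases[:-1]):
        h = relu(anp.matmul(h, w.T) + b)
    logits = anp.matmul(h, weights[-1].T) + biases[-1]
    return softmax(logits, axis=-1)


def discriminate(x, params: DiscriminatorParams) -> np.ndarray:
    """Probability pair(s) ``(p_true, p_false)`` for attribute row(s) ``x``."""
    if isinstance(x, (list, tuple)):
        x = np.asarray(x, dtype=float)
    if isinstance(x, np.ndarray) and not np.isfinite(x).all():
        raise ValueError("non-finite discriminator input")
    single = x.ndim == 1
    if single:
        x = x[None, :]
    probs = _discriminate_tree(x, params.weights, params.biases)
    return probs[0] if single else probs


def init_generator(rng: np.random.Generator, n_nodes: int,
                   encoder_dims, decoder_dims) -> GeneratorParams:
    dec = [n_nodes if d is None else d for d in decoder_dims]
    dims_enc = [n_nodes, *encoder_dims]
    dims_dec = [encoder_dims[-1], *dec]
    enc = [glorot(rng, (a, b)) for a, b in zip(dims_enc[:-1], dims_enc[1:])]
    decw = [glorot(rng, (a, b)) for a, b in zip(dims_dec[:-1], dims_dec[1:])]
    return GeneratorParams(encoder=enc, decoder=decw)


def init_discriminator(rng: np.random.Generator, n_in: int, dims) -> DiscriminatorParams:
    widths = [n_in, *dims, 2]
    weights = [glorot(rng, (b, a)) for a, b in zip(widths[:-1], widths[1:])]
    biases = [np.zeros(b) for b in widths[1:]]
    return DiscriminatorParams(weights=weights, biases=biases)


def adversarial_train(graph: HeteroGraph, config: GanConfig | None = None) -> GanResult:
    """Alternating min-G / max-D optimisation over full node batches.

    Per epoch: one discriminator ascent step on balanced true/false node
    rows (learning rate ``d_lr``), then one generator step minimising the
    adversarial term plus ``gamma`` times the mean-squared reconstruction
    error.  A slower discriminator keeps the game near its equilibrium at
    this scale (accuracy drifting to 0.5) while the reconstruction term
    steadily improves the embedding.  Deterministic for a fixed
    ``config.seed``.
    """
    config = config or GanConfig()
    rng = np.random.default_rng(config.seed)
    a_norm = graph.normalized
    h_true = graph.attributes

    gen = init_generator(rng, graph.n_nodes, config.encoder_dims,
                         config.decoder_dims).tree()
    disc = init_discriminator(rng, graph.n_nodes, config.disc_dims).tree()

    def reconstruct(gt):
        h_en = _encode_tree(a_norm, h_true, gt["encoder"])
        return h_en, _decode_tree(a_norm, h_en, gt["decoder"])

    def d_loss(dt, h_hat):
        p_true = _discriminate_tree(h_true, dt["weights"], dt["biases"])[:, 0]
        p_false = _discriminate_tree(h_hat, dt["weights"], dt["biases"])[:, 0]
        return -(anp.mean(anp.log(p_true + _EPS))
                 + anp.mean(anp.log(1.0 - p_false + _EPS)))

    def g_loss(gt, dt):
        _, h_hat = reconstruct(gt)
        p_false = _discriminate_tree(h_hat, dt["weights"], dt["biases"])[:, 0]
        adv = anp.mean(anp.log(1.0 - p_false + _EPS))
        recon = anp.mean((h_hat - h_true) ** 2)
        return adv + config.gamma * recon

    d_grad = grad(d_loss)
    g_grad = grad(g_loss)
    opt_d = Adam(lr=config.d_lr)
    opt_g = Adam(lr=config.lr)

    rows = []
    for epoch in range(config.epochs):
        _, h_hat = reconstruct(gen)
        dl = d_loss(disc, h_hat)
        disc = opt_d.step(disc, d_grad(disc, h_hat))
        gl = g_loss(gen, disc)
        gen = opt_g.step(gen, g_grad(gen, disc))
        h_en, h_hat = reconstruct(gen)
        recon = float(np.mean((h_hat - h_true) ** 2))
        p_t = _discriminate_tree(h_true, disc["weights"], disc["biases"])[:, 0]
        p_f = _discriminate_tree(h_hat, disc["weights"], disc["biases"])[:, 0]
        acc = 0.5 * (np.mean(p_t > 0.5) + np.mean(p_f <= 0.5))
        if not (np.isfinite(dl) and np.isfinite(gl)):
            raise RuntimeError(f"non-finite GAN loss at epoch {epoch} "
                               f"(D={dl}, G={gl})")
        rows.append({"epoch": epoch, "d_loss": float(dl), "g_loss": float(gl),
                     "recon_error": recon, "d_accuracy": float(acc)})

    gen_p = GeneratorParams(encoder=gen["encoder"], decoder=gen["decoder"])
    disc_p = DiscriminatorParams(weights=disc["weights"], biases=disc["biases"])
    h_en, h_hat = reconstruct(gen)
    emb = TopologyEmbedding(h_en=np.asarray(h_en), h_hat=np.asarray(h_hat),
                            view=graph.view)
    return GanResult(embedding=emb, generator=gen_p, discriminator=disc_p,
                     history=pd.DataFrame(rows))


def save_checkpoint(path, generator: GeneratorParams,
                    discriminator: DiscriminatorParams) -> None:
    """Persist GAN parameters in a portable array container (.npz)."""
    arrays = {}
    for i, w in enumerate(generator.encoder):
        arrays[f"enc_{i}"] = w
    for i, w in enumerate(generator.decoder):
        arrays[f"dec_{i}"] = w
    for i, (w, b) in enumerate(zip(discriminator.weights, discriminator.biases)):
        arrays[f"disc_w_{i}"] = w
        arrays[f"disc_b_{i}"] = b
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[GeneratorParams, DiscriminatorParams]:
    data = np.load(path)
    n_enc = sum(1 for k in data.files if k.startswith("enc_"))
    n_dec = sum(1 for k in data.files if k.startswith("dec_"))
    n_disc = sum(1 for k in data.files if k.startswith("disc_w_"))
    gen = GeneratorParams(encoder=[data[f"enc_{i}"] for i in range(n_enc)],
                          decoder=[data[f"dec_{i}"] for i in range(n_dec)])
    disc = DiscriminatorParams(weights=[data[f"disc_w_{i}"] for i in range(n_disc)],
                               biases=[data[f"disc_b_{i}"] for i in range(n_disc)])
    return gen, disc
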