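"""Branch scoring heads, cross-entropy losses, joint training and
lambda-weighted score fusion.

The model scores a drug/side-effect pair through two branches:

* topology branch - adversarially trained per-view GCN embeddings,
  attention-fused, stacked per pair and convolved (``score_topo``);
* attribute branch - the per-pair attribute tensor encoded by
  self-calibrated convolution (``score_att``).

Each branch ends in a dense softmax head giving ``(p0, p1)`` with ``p1``
the association probability; the final score is
``lambda * p1_topo + (1 - lambda) * p1_att``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import autograd.numpy as anp
import numpy as np
import pandas as pd
from autograd import grad

from . import fusion
from .attributes import build_pair_attr_batch, init_scc
from .gan import GanConfig, adversarial_train
from .graphs import build_hetero_graph
from .nn import Adam, dense, glorot, softmax
from .attributes import _scc_tree
from .fusion import _fuse_tree, _topo_conv_tree

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "score_head",
    "ce_loss",
    "fuse_scores",
    "train_model",
]

_EPS = 1e-12


def score_head(z, w, b):
    """Dense softmax head: probability pair(s) ``(p0, p1)``; ``p1`` is the
    association probability."""
    z_arr = z if not isinstance(z, (list, tuple)) else np.asarray(z, float)
    if isinstance(z_arr, np.ndarray) and not np.isfinite(z_arr).all():
        raise ValueError("non-finite features fed to score head")
    return softmax(dense(z_arr, w, b), axis=-1)


def ce_loss(probs, labels):
    """Summed binary cross entropy between association probabilities
    (column 1 of the softmax pairs) and binary labels."""
    labels = np.asarray(labels, dtype=float)
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    p1 = probs[..., 1] if probs.ndim > 1 else probs[1]
    p1 = anp.clip(p1, _EPS, 1.0 - _EPS)
    return -anp.sum(labels * anp.log(p1) + (1.0 - labels) * anp.log(1.0 - p1))


def fuse_scores(score_topo, score_att, lam: float):
    """Final association score: ``lam * topo + (1 - lam) * att`` applied to
    the association-probability components."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda={lam} outside [0, 1]")
    return lam * np.asarray(score_topo) + (1.0 - lam) * np.asarray(score_att)


@dataclass
class TrainConfig:
    """End-to-end training configuration (fixture-scale defaults).

    Ablation switches: ``use_tga=False`` scores with the attribute branch
    only (lambda forced to 0); ``use_scpa=False`` scores with the topology
    branch only (lambda forced to 1); ``use_rla=False`` replaces attention
    fusion by the plain residual sum.
    """

    gan: GanConfig = field(default_factory=GanConfig)
    head_epochs: int = 15
    head_lr: float = 1e-3
    batch_size: int = 64
    lam: float = 0.5
    use_tga: bool = True
    use_rla: bool = True
    use_scpa: bool = True
    scc_calibrate: bool = True
    scc_pool_factor: int = 4
    leaky_slope: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if not (self.use_tga or self.use_scpa):
            raise ValueError("at least one scoring branch must be enabled")

    @property
    def effective_lambda(self) -> float:
        if not self.use_tga:
            return 0.0
        if not self.use_scpa:
            return 1.0
        return self.lam


@dataclass
class TrainedModel:
    """Frozen parameters and cached embeddings for scoring arbitrary pairs."""

    config: TrainConfig
    matrices: tuple              # (m_chem, m_dise, s, o_train)
    topo_params: dict | None
    att_params: dict | None
    scc_pool_factor: int
    h_chem: np.ndarray | None = field(default=None, repr=False)
    h_dise: np.ndarray | None = field(default=None, repr=False)
    gan_histories: dict = field(default_factory=dict, repr=False)
    head_history: pd.DataFrame | None = field(default=None, repr=False)

    def score_pairs(self, pairs, batch_size: int = 128) -> np.ndarray:
        """Fused association scores for an array of (drug, side-effect)
        index pairs."""
        pairs = np.asarray(pairs)
        n_drugs = self.matrices[3].shape[0]
        out = np.empty(len(pairs))
        lam = self.config.effective_lambda
        for lo in range(0, len(pairs), batch_size):
            chunk = pairs[lo: lo + batch_size]
            s_topo = s_att = 0.0
            if self.topo_params is not None and lam > 0.0:
                p = _topo_forward(self.topo_params, self.h_chem, self.h_dise,
                                  chunk, n_drugs, self.config)
                s_topo = np.asarray(p)[:, 1]
            if self.att_params is not None and lam < 1.0:
                x_att = build_pair_attr_batch(*self.matrices, chunk)
                p = _att_forward(self.att_params, x_att, self.scc_pool_factor,
                                 self.config.scc_calibrate)
                s_att = np.asarray(p)[:, 1]
            out[lo: lo + len(chunk)] = fuse_scores(s_topo, s_att, lam)
        return out


def _topo_forward(tree, h_chem, h_dise, pairs, n_drugs, config: TrainConfig):
    """Softmax pair probabilities from the topology branch for a pair batch."""
    di, sj = pairs[:, 0], pairs[:, 1]
    hc = anp.concatenate([h_chem[di], h_chem[n_drugs + sj]], axis=0)
    hd = anp.concatenate([h_dise[di], h_dise[n_drugs + sj]], axis=0)
    fused = _fuse_tree(hc, hd, tree.get("att"), config.leaky_slope,
                       config.use_rla)
    n = len(pairs)
    x_topo = anp.stack([fused[:n], fused[n:]], axis=1)  # (B, 2, N_f)
    maps = _topo_conv_tree(x_topo, tree["conv"])
    z = anp.reshape(maps, (n, -1))
    return softmax(dense(z, tree["head"]["w"], tree["head"]["b"]), axis=-1)


def _att_forward(tree, x_att, pool_factor, calibrate):
    maps = _scc_tree(x_att, tree["scc"], pool_factor, calibrate)
    z = anp.reshape(maps, (x_att.shape[0], -1))
    return softmax(dense(z, tree["head"]["w"], tree["head"]["b"]), axis=-1)


def _feature_sizes(n_f: int, width: int, calibrate: bool) -> tuple[int, int]:
    """Flattened feature lengths of (topology, attribute) branch maps."""
    w1 = (n_f - 1) // 2       # conv 2x2 valid + pool
    topo = 32 * ((w1 - 1) // 2)
    if calibrate:
        att = 64 * min(width // 2, width - 2)
    else:
        att = 32 * (width - 2)
    return topo, att


def _init_topo_tree(rng, n_f, config) -> dict:
    tree = {"conv": fusion.init_topo_conv(rng).tree()}
    if config.use_rla:
        tree["att"] = fusion.init_attention(rng, n_f, config.leaky_slope).tree()
    topo_feats, _ = _feature_sizes(n_f, 1, True)
    tree["head"] = {"w": glorot(rng, (2, topo_feats)), "b": np.zeros(2)}
    return tree


def _init_att_tree(rng, width, config) -> dict:
    scc = init_scc(rng, pool_factor=config.scc_pool_factor)
    _, att_feats = _feature_sizes(8, width, config.scc_calibrate)
    return {"scc": scc.tree(),
            "head": {"w": glorot(rng, (2, att_feats)), "b": np.zeros(2)}}


def train_model(m_chem, m_dise, s, o_train, train_pairs, train_labels,
                config: TrainConfig | None = None) -> TrainedModel:
    """Train the full model on one fold.

    ``o_train`` must already have held-out test associations zeroed.
    Stage-wise schedule: the per-view GANs are trained first (frozen
    afterwards), then the attention, convolution and head parameters of the
    enabled branches are optimised jointly with Adam on the summed
    cross-entropy losses over balanced mini-batches.  Deterministic for a
    fixed ``config.seed``.
    """
    config = config or TrainConfig()
    m_chem, m_dise = np.asarray(m_chem, float), np.asarray(m_dise, float)
    s, o_train = np.asarray(s, float), np.asarray(o_train, float)
    train_pairs = np.asarray(train_pairs)
    train_labels = np.asarray(train_labels, float)
    n_drugs = o_train.shape[0]
    width = o_train.shape[0] + o_train.shape[1]

    ss = np.random.SeedSequence(config.seed)
    seed_gan_chem, seed_gan_dise, seed_init, seed_batch = (
        int(c.generate_state(1)[0]) for c in ss.spawn(4))
    rng_init = np.random.default_rng(seed_init)
    rng_batch = np.random.default_rng(seed_batch)

    h_chem = h_dise = None
    gan_histories = {}
    if config.use_tga:
        g_chem = build_hetero_graph(m_chem, s, o_train, view="chem")
        g_dise = build_hetero_graph(m_dise, s, o_train, view="dise")
        res_c = adversarial_train(g_chem, replace(config.gan, seed=seed_gan_chem))
        res_d = adversarial_train(g_dise, replace(config.gan, seed=seed_gan_dise))
        h_chem, h_dise = res_c.embedding.h_en, res_d.embedding.h_en
        gan_histories = {"chem": res_c.history, "dise": res_d.history}

    params = {}
    if config.use_tga:
        params["topo"] = _init_topo_tree(rng_init, config.gan.n_f, config)
    if config.use_scpa:
        params["att"] = _init_att_tree(rng_init, width, config)

    matrices = (m_chem, m_dise, s, o_train)

    def batch_loss(tree, pairs, labels):
        loss = 0.0
        if "topo" in tree:
            probs = _topo_forward(tree["topo"], h_chem, h_dise, pairs,
                                  n_drugs, config)
            loss = loss + ce_loss(probs, labels)
        if "att" in tree:
            x_att = build_pair_attr_batch(*matrices, pairs)
            probs = _att_forward(tree["att"], x_att, config.scc_pool_factor,
                                 config.scc_calibrate)
            loss = loss + ce_loss(probs, labels)
        return loss / len(pairs)

    loss_grad = grad(batch_loss)
    opt = Adam(lr=config.head_lr)
    n = len(train_pairs)
    history = []
    for epoch in range(config.head_epochs):
        order = rng_batch.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, config.batch_size):
            idx = order[lo: lo + config.batch_size]
            bl = batch_loss(params, train_pairs[idx], train_labels[idx])
            if not np.isfinite(bl):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {lo}")
            g = loss_grad(params, train_pairs[idx], train_labels[idx])
            params = opt.step(params, g)
            epoch_loss += float(bl) * len(idx)
        history.append({"epoch": epoch, "loss": epoch_loss / n})
        logger.debug("epoch %d loss %.5f", epoch, epoch_loss / n)

    return TrainedModel(config=config, matrices=matrices,
                        topo_params=params.get("topo"),
                        att_params=params.get("att"),
                        scc_pool_factor=config.scc_pool_factor,
                        h_chem=h_chem, h_dise=h_dise,
                        gan_histories=gan_histories,
                        head_history=pd.DataFrame(history))
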