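"""Representation-level attention over the two view embeddings and the
per-pair topological convolution branch.

Each node row gets a per-feature attention weight in each view
(LeakyReLU-scored, softmax-normalized); the fused embedding is the sum of
the two attention-gated rows plus both residuals:

    h_i = (alpha_i * h_i_chem + h_i_chem) + (beta_i * h_i_dise + h_i_dise)

A drug/side-effect pair is represented by stacking its two fused rows into
a 2 x N_f map, which two conv-pool stages (16 then 32 filters, 2x2 kernels,
no height padding, average 2x2 pooling) turn into the branch feature map.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .nn import avg_pool2d, conv2d, glorot, leaky_relu, relu, softmax

__all__ = [
    "AttentionParams",
    "TopoConvParams",
    "attention_scores",
    "fuse_views",
    "pair_topo_embedding",
    "topo_conv",
    "init_attention",
    "init_topo_conv",
    "min_embedding_width",
]


@dataclass
class AttentionParams:
    """One (W_fea, b_fea) pair per view, shared across nodes."""

    w_chem: np.ndarray
    b_chem: np.ndarray
    w_dise: np.ndarray
    b_dise: np.ndarray
    negative_slope: float = 0.01

    def tree(self) -> dict:
        return {"w_chem": self.w_chem, "b_chem": self.b_chem,
                "w_dise": self.w_dise, "b_dise": self.b_dise}


@dataclass
class TopoConvParams:
    """Two conv-pool stages: 16 filters (2x2) then 32 filters (1x2)."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray

    def tree(self) -> dict:
        return {"w1": self.w1, "b1": self.b1, "w2": self.w2, "b2": self.b2}


def attention_scores(h_rows, w, b, negative_slope: float = 0.01):
    """Normalized per-feature attention weights for one or more embedding
    rows: softmax over ``LeakyReLU(h @ W.T + b)``; each output row sums
    to 1."""
    s = leaky_relu(anp.matmul(h_rows, anp.swapaxes(w, -1, -2)) + b, negative_slope)
    return softmax(s, axis=-1)


def _fuse_tree(h_chem, h_dise, tree, negative_slope, use_attention):
    if h_chem.shape != h_dise.shape:
        raise ValueError(f"view embedding shape mismatch: "
                         f"{h_chem.shape} vs {h_dise.shape}")
    if not use_attention:
        return h_chem + h_dise
    alpha = attention_scores(h_chem, tree["w_chem"], tree["b_chem"], negative_slope)
    beta = attention_scores(h_dise, tree["w_dise"], tree["b_dise"], negative_slope)
    return (alpha * h_chem + h_chem) + (beta * h_dise + h_dise)


def fuse_views(h_chem, h_dise, params: AttentionParams | None = None,
               use_attention: bool = True):
    """Attention-gated residual fusion of the two view embeddings.

    With ``use_attention=False`` (the representation-level-attention
    ablation) the result is the plain residual sum ``h_chem + h_dise``.
    """
    if use_attention and params is None:
        raise ValueError("attention parameters required when use_attention=True")
    tree = params.tree() if params is not None else None
    slope = params.negative_slope if params is not None else 0.01
    return _fuse_tree(h_chem, h_dise, tree, slope, use_attention)


def pair_topo_embedding(h_fused, drug_index: int, side_effect_index: int,
                        n_drugs: int):
    """Stack the drug row and the side-effect row (offset by ``n_drugs``)
    of the fused embedding into the 2 x N_f pair map."""
    n_nodes = h_fused.shape[0]
    n_se = n_nodes - n_drugs
    if not 0 <= drug_index < n_drugs:
        raise IndexError(f"drug index {drug_index} out of range [0, {n_drugs})")
    if not 0 <= side_effect_index < n_se:
        raise IndexError(
            f"side-effect index {side_effect_index} out of range [0, {n_se})")
    return anp.stack([h_fused[drug_index],
                      h_fused[n_drugs + side_effect_index]], axis=0)


def min_embedding_width() -> int:
    """Smallest N_f for which both conv-pool stages are defined."""
    # conv 2x2 -> w-1; pool -> (w-1)//2 >= 2; conv 1x2 -> -1; pool -> >= 1
    return 7


def _topo_conv_tree(x, tree):
    single = x.ndim == 2
    if single:
        x = x[None, None, :, :]
    elif x.ndim == 3:
        x = x[:, None, :, :]
    if x.shape[2] != 2:
        raise ValueError("pair map must have height 2")
    if x.shape[3] < min_embedding_width():
        raise ValueError(f"embedding width {x.shape[3]} too small for two "
                         "conv-pool stages")
    h = avg_pool2d(relu(conv2d(x, tree["w1"], tree["b1"])), (2, 2))
    h = avg_pool2d(relu(conv2d(h, tree["w2"], tree["b2"])), (2, 2))
    return h[0] if single else h


def topo_conv(x_topo, params: TopoConvParams):
    """Z_topo: two conv-pool stages over the stacked pair map.

    Accepts a single 2 x N_f map or a batch (B x 2 x N_f); returns the
    pooled feature map(s) with 32 channels.
    """
    return _topo_conv_tree(x_topo, params.tree())


def init_attention(rng: np.random.Generator, n_f: int,
                   negative_slope: float = 0.01) -> AttentionParams:
    return AttentionParams(
        w_chem=glorot(rng, (n_f, n_f)), b_chem=np.zeros(n_f),
        w_dise=glorot(rng, (n_f, n_f)), b_dise=np.zeros(n_f),
        negative_slope=negative_slope)


def init_topo_conv(rng: np.random.Generator, n_filters: tuple[int, int] = (16, 32),
                   ) -> TopoConvParams:
    f1, f2 = n_filters
    return TopoConvParams(
        w1=glorot(rng, (f1, 1, 2, 2)), b1=np.zeros(f1),
        w2=glorot(rng, (f2, f1, 1, 2)), b2=np.zeros(f2))
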