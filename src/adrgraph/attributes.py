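"""Per-pair attribute tensors and their self-calibrated convolutional
encoding.

For a drug i and side effect j the attribute map stacks, per view, the
drug's profile row ``[M_i || O_i]`` over the side effect's profile row
``[O.T_j || S_j]``; the two views form the channels of the
2 x 2 x (N_r + N_s) tensor ``X_att``.

The self-calibrated encoder runs two paths over ``X_att``:

* latent path - average-pool along the long axis (greater receptive
  field), one 2x2 same-padded conv with a single filter, ReLU, then
  bilinear interpolation back to the original spatial shape;
* calibration - a channel-preserving same-padded conv of ``X_att`` gated
  elementwise by ``sigmoid(X_att + X'_att)``, then a 32-filter same-padded
  conv, sigmoid, and 2x2 average pooling (``Y_att``);
* original path - two unpadded convs (16 then 32 filters) preserving edge
  information (``Y_ori``).

``Z_att`` concatenates ``Y_att`` and ``Y_ori`` along channels after
center-cropping the wider map.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .nn import (avg_pool2d, avg_pool_width, bilinear_resize, conv2d, glorot,
                 relu, sigmoid)

__all__ = [
    "PairAttrEmbedding",
    "SCCParams",
    "build_pair_attr",
    "build_pair_attr_batch",
    "scc_latent_path",
    "scc_calibrate",
    "scc_original_path",
    "scc_encode",
    "init_scc",
]


@dataclass
class PairAttrEmbedding:
    """Raw attribute maps for one drug/side-effect pair."""

    x_chem: np.ndarray  # (2, N_r + N_s)
    x_dise: np.ndarray  # (2, N_r + N_s)

    @property
    def x_att(self) -> np.ndarray:
        """Channel-stacked tensor of shape (2, 2, N_r + N_s): channel 0 is
        the chem view, channel 1 the dise view."""
        return np.stack([self.x_chem, self.x_dise], axis=0)


@dataclass
class SCCParams:
    """Self-calibrated convolution parameters (all kernels 2x2 except the
    height-1 second original-path conv)."""

    w_latent: np.ndarray   # (1, 2, kh, kw) - single filter, same padding
    b_latent: np.ndarray
    w_cal: np.ndarray      # (2, 2, 2, 2)  - channel-preserving, same padding
    b_cal: np.ndarray
    w_fus: np.ndarray      # (32, 2, 2, 2) - same padding
    b_fus: np.ndarray
    w_ori1: np.ndarray     # (16, 2, 2, 2) - valid
    b_ori1: np.ndarray
    w_ori2: np.ndarray     # (32, 16, 1, 2) - valid
    b_ori2: np.ndarray
    pool_factor: int = 4

    def tree(self) -> dict:
        return {k: getattr(self, k) for k in
                ("w_latent", "b_latent", "w_cal", "b_cal", "w_fus", "b_fus",
                 "w_ori1", "b_ori1", "w_ori2", "b_ori2")}


def _check_pair_indices(n_drugs, n_se, i, j):
    if not 0 <= i < n_drugs:
        raise IndexError(f"drug index {i} out of range [0, {n_drugs})")
    if not 0 <= j < n_se:
        raise IndexError(f"side-effect index {j} out of range [0, {n_se})")


def build_pair_attr(m_chem, m_dise, s, o, i: int, j: int) -> PairAttrEmbedding:
    """Attribute embedding of the pair (drug i, side effect j)."""
    m_chem, m_dise = np.asarray(m_chem), np.asarray(m_dise)
    s, o = np.asarray(s), np.asarray(o)
    nr, ns = o.shape
    if m_chem.shape != (nr, nr) or m_dise.shape != (nr, nr) or s.shape != (ns, ns):
        raise ValueError("matrix dimensions inconsistent with association matrix")
    _check_pair_indices(nr, ns, i, j)
    x2 = np.concatenate([o.T[j], s[j]])
    x_chem = np.stack([np.concatenate([m_chem[i], o[i]]), x2])
    x_dise = np.stack([np.concatenate([m_dise[i], o[i]]), x2])
    return PairAttrEmbedding(x_chem=x_chem, x_dise=x_dise)


def build_pair_attr_batch(m_chem, m_dise, s, o, pairs) -> np.ndarray:
    """Vectorised ``X_att`` for many pairs: output (B, 2, 2, N_r + N_s)."""
    m_chem, m_dise = np.asarray(m_chem), np.asarray(m_dise)
    s, o = np.asarray(s), np.asarray(o)
    pairs = np.asarray(pairs)
    di, sj = pairs[:, 0], pairs[:, 1]
    row2 = np.concatenate([o.T[sj], s[sj]], axis=1)            # (B, Nr+Ns)
    row1_chem = np.concatenate([m_chem[di], o[di]], axis=1)
    row1_dise = np.concatenate([m_dise[di], o[di]], axis=1)
    x_chem = np.stack([row1_chem, row2], axis=1)               # (B, 2, Nr+Ns)
    x_dise = np.stack([row1_dise, row2], axis=1)
    return np.stack([x_chem, x_dise], axis=1)                  # (B, 2, 2, W)


def _batched(x):
    x = anp.reshape(x, (1,) + x.shape) if x.ndim == 3 else x
    if x.ndim != 4:
        raise ValueError("expected a (2, 2, W) tensor or a batch of them")
    return x


def _latent_tree(x, tree, pool_factor):
    pooled = avg_pool_width(x, pool_factor)
    h = relu(conv2d(pooled, tree["w_latent"], tree["b_latent"], padding="same"))
    return bilinear_resize(h, x.shape[2], x.shape[3])


def scc_latent_path(x_att, params: SCCParams):
    """Low-dimensional latent embedding mapped back to the original
    spatial shape (single-filter output, broadcastable over channels)."""
    x = _batched(x_att)
    out = _latent_tree(x, params.tree(), params.pool_factor)
    return out[0] if np.ndim(x_att) == 3 else out


def _calibrate_tree(x, x_prime, tree):
    gate = sigmoid(x + x_prime)
    y_cal = conv2d(x, tree["w_cal"], tree["b_cal"], padding="same") * gate
    y = sigmoid(conv2d(y_cal, tree["w_fus"], tree["b_fus"], padding="same"))
    return avg_pool2d(y, (2, 2))


def scc_calibrate(x_att, x_prime, params: SCCParams):
    """Gate the convolved original-space features with the latent-path map
    and fuse (conv, sigmoid, 2x2 pooling)."""
    x = _batched(x_att)
    xp = _batched(x_prime) if np.ndim(x_prime) == 3 else x_prime
    if np.ndim(xp) != 4 or xp.shape[2:] != x.shape[2:]:
        raise ValueError("calibration map spatial shape mismatch")
    out = _calibrate_tree(x, xp, params.tree())
    return out[0] if np.ndim(x_att) == 3 else out


def _original_tree(x, tree):
    h = relu(conv2d(x, tree["w_ori1"], tree["b_ori1"], padding="valid"))
    return relu(conv2d(h, tree["w_ori2"], tree["b_ori2"], padding="valid"))


def scc_original_path(x_att, params: SCCParams):
    """Two unpadded conv layers (16 then 32 filters) over ``X_att``."""
    x = _batched(x_att)
    out = _original_tree(x, params.tree())
    return out[0] if np.ndim(x_att) == 3 else out


def _crop_width(t, target):
    extra = t.shape[-1] - target
    if extra < 0:
        raise ValueError("cannot crop to a larger width")
    lo = extra // 2
    return t[..., lo: lo + target]


def _scc_tree(x, tree, pool_factor, calibrate):
    y_ori = _original_tree(x, tree)
    if not calibrate:
        return y_ori
    x_prime = _latent_tree(x, tree, pool_factor)
    y_att = _calibrate_tree(x, x_prime, tree)
    width = min(y_att.shape[-1], y_ori.shape[-1])
    return anp.concatenate([_crop_width(y_att, width), _crop_width(y_ori, width)],
                           axis=1)


def scc_encode(x_att, params: SCCParams, calibrate: bool = True):
    """Full self-calibrated encoding ``Z_att = [Y_att, Y_ori]``.

    With ``calibrate=False`` (the self-calibration ablation) only the
    original-path features are returned.
    """
    x = _batched(x_att)
    out = _scc_tree(x, params.tree(), params.pool_factor, calibrate)
    return out[0] if np.ndim(x_att) == 3 else out


def init_scc(rng: np.random.Generator, pool_factor: int = 4,
             n_filters: tuple[int, int] = (16, 32)) -> SCCParams:
    f1, f2 = n_filters
    return SCCParams(
        w_latent=glorot(rng, (1, 2, 2, 2)), b_latent=np.zeros(1),
        w_cal=glorot(rng, (2, 2, 2, 2)), b_cal=np.zeros(2),
        w_fus=glorot(rng, (f2, 2, 2, 2)), b_fus=np.zeros(f2),
        w_ori1=glorot(rng, (f1, 2, 2, 2)), b_ori1=np.zeros(f1),
        w_ori2=glorot(rng, (f2, f1, 1, 2)), b_ori2=np.zeros(f2),
        pool_factor=pool_factor)
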