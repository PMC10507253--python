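"""Independent loop-based reference implementations used by the tests.

Everything here is deliberately naive (explicit Python loops, no shared
code with the package) so it can serve as an oracle for the vectorised
implementations.
"""

import math

import numpy as np


def laplace_normalize_loop(a):
    a = np.asarray(a, float)
    n = a.shape[0]
    deg = [sum(a[i, j] for j in range(n)) for i in range(n)]
    out = np.zeros_like(a)
    for i in range(n):
        for j in range(n):
            out[i, j] = a[i, j] / math.sqrt(deg[i]) / math.sqrt(deg[j])
    return out


def gcn_layer_loop(a, h, w):
    a, h, w = np.asarray(a, float), np.asarray(h, float), np.asarray(w, float)
    ah = np.zeros((a.shape[0], h.shape[1]))
    for i in range(a.shape[0]):
        for j in range(h.shape[1]):
            ah[i, j] = sum(a[i, k] * h[k, j] for k in range(a.shape[1]))
    out = np.zeros((a.shape[0], w.shape[1]))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            v = sum(ah[i, k] * w[k, j] for k in range(w.shape[0]))
            out[i, j] = max(v, 0.0)
    return out


def conv2d_loop(x, w, b=None, padding="valid"):
    """Direct sliding-window cross-correlation, NCHW, stride 1."""
    x, w = np.asarray(x, float), np.asarray(w, float)
    bsz, c_in, h, wd = x.shape
    n_out, _, kh, kw = w.shape
    if padding == "same":
        ph_lo, ph_hi = (kh - 1) // 2, kh // 2
        pw_lo, pw_hi = (kw - 1) // 2, kw // 2
        xp = np.zeros((bsz, c_in, h + ph_lo + ph_hi, wd + pw_lo + pw_hi))
        xp[:, :, ph_lo:ph_lo + h, pw_lo:pw_lo + wd] = x
        x, h, wd = xp, h + ph_lo + ph_hi, wd + pw_lo + pw_hi
    ho, wo = h - kh + 1, wd - kw + 1
    out = np.zeros((bsz, n_out, ho, wo))
    for n in range(bsz):
        for f in range(n_out):
            for i in range(ho):
                for j in range(wo):
                    acc = 0.0
                    for c in range(c_in):
                        for di in range(kh):
                            for dj in range(kw):
                                acc += x[n, c, i + di, j + dj] * w[f, c, di, dj]
                    out[n, f, i, j] = acc + (b[f] if b is not None else 0.0)
    return out


def avg_pool2d_loop(x, window=(2, 2)):
    x = np.asarray(x, float)
    wh = min(window[0], x.shape[2])
    ww = min(window[1], x.shape[3])
    ho, wo = x.shape[2] // wh, x.shape[3] // ww
    out = np.zeros((x.shape[0], x.shape[1], ho, wo))
    for n in range(x.shape[0]):
        for c in range(x.shape[1]):
            for i in range(ho):
                for j in range(wo):
                    out[n, c, i, j] = np.mean(
                        x[n, c, i * wh:(i + 1) * wh, j * ww:(j + 1) * ww])
    return out


def auc_loop(scores, labels):
    """O(n^2) concordant-pair AUC with half credit for ties."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def aupr_step_loop(scores, labels):
    """Average-precision step integration: sum (R_i - R_{i-1}) * P_i over
    descending-score thresholds."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    sorted_scores = scores[order]
    n_pos = labels.sum()
    tp = fp = 0
    prev_recall = 0.0
    area = 0.0
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and sorted_scores[j] == sorted_scores[i]:
            tp += labels[j]
            fp += 1 - labels[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


def ce_loss_loop(p1_list, labels):
    total = 0.0
    for p, y in zip(p1_list, labels):
        p = min(max(p, 1e-12), 1 - 1e-12)
        total += -(y * math.log(p) + (1 - y) * math.log(1 - p))
    return total


def bilinear_resize_1d_loop(values, n_out):
    """Half-pixel-centres linear interpolation with edge clamping."""
    values = np.asarray(values, float)
    n_in = len(values)
    out = np.zeros(n_out)
    for i in range(n_out):
        src = (i + 0.5) * n_in / n_out - 0.5
        lo = math.floor(src)
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        out[i] = values[lo_c] * (1 - frac) + values[hi_c] * frac
    return out
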