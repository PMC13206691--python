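"""Independent brute-force oracles used by the test suite.

Everything here is written with plain loops / explicit formulas, never by
calling the implementation under test, so that agreement is evidence.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------------------
# scalar-loop oracles for the gated-attention forward passes


def gated_scores_oracle(H, W_V, W_U, w):
    """a_i = w^T (tanh(W_V h_i) * sigmoid(W_U h_i)), element by element."""
    N, D = H.shape
    L = len(w)
    scores = []
    for i in range(N):
        total = 0.0
        for l in range(L):
            v = 0.0
            u = 0.0
            for d in range(D):
                v += W_V[l][d] * H[i][d]
                u += W_U[l][d] * H[i][d]
            total += w[l] * math.tanh(v) * (1.0 / (1.0 + math.exp(-u)))
        scores.append(total)
    return scores


def softmax_oracle(a):
    m = max(a)
    e = [math.exp(x - m) for x in a]
    s = sum(e)
    return [x / s for x in e]


def pool_oracle(H, W_V, W_U, w):
    a = gated_scores_oracle(H, W_V, W_U, w)
    alpha = softmax_oracle(a)
    D = H.shape[1]
    z = [sum(alpha[i] * H[i][d] for i in range(len(alpha))) for d in range(D)]
    return z, alpha


def slide_forward_oracle(H, model):
    """Probabilities of the slide model via pure-python loops."""
    att = model.attention
    z, alpha = pool_oracle(np.asarray(H, float), att.W_V, att.W_U, att.w)
    W, b = model.classifier.weight, model.classifier.bias
    logits = [sum(W[c][d] * z[d] for d in range(len(z))) + b[c]
              for c in range(len(b))]
    return softmax_oracle(logits), alpha, z


def patient_forward_oracle(slides, model):
    zs = []
    for H in slides:
        z, _ = pool_oracle(np.asarray(H, float), model.level1.W_V,
                           model.level1.W_U, model.level1.w)
        zs.append(z)
    Z = np.asarray(zs, float)
    z_pat, beta = pool_oracle(Z, model.level2.W_V, model.level2.W_U,
                              model.level2.w)
    W, b = model.classifier.weight, model.classifier.bias
    logits = [sum(W[c][d] * z_pat[d] for d in range(len(z_pat))) + b[c]
              for c in range(len(b))]
    return softmax_oracle(logits), beta


# ---------------------------------------------------------------------------
# pair-counting AUC oracle


def pair_count_auc(scores, y):
    """Mann-Whitney AUC by brute force over all positive-negative pairs."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# brute-force QC evaluation (independent of the tiling_qc implementation)

_LUMA = (0.2125, 0.7154, 0.0721)


def _gray01(img):
    a = img.astype(np.float64)
    return (_LUMA[0] * a[..., 0] + _LUMA[1] * a[..., 1]
            + _LUMA[2] * a[..., 2]) / 255.0


def otsu_exhaustive(values):
    """Otsu threshold by exhaustive search over 256 histogram bin edges."""
    v = np.asarray(values, dtype=np.float64).ravel()
    lo, hi = v.min(), v.max()
    edges = lo + (hi - lo) * (np.arange(1, 256) / 256.0)
    best_t, best_var = edges[0], -1.0
    for t in edges:
        lower = v[v < t]
        upper = v[v >= t]
        if lower.size == 0 or upper.size == 0:
            continue
        wb = lower.size / v.size
        var = wb * (1 - wb) * (lower.mean() - upper.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def brute_force_mask(img, factor):
    gray = _gray01(img)
    h, w = gray.shape
    mh = -(-h // factor)
    mw = -(-w // factor)
    ph, pw = mh * factor - h, mw * factor - w
    if ph or pw:
        gray = np.pad(gray, ((0, ph), (0, pw)), mode="edge")
    small = np.empty((mh, mw))
    for r in range(mh):
        for c in range(mw):
            small[r, c] = gray[r * factor:(r + 1) * factor,
                               c * factor:(c + 1) * factor].mean()
    thr = otsu_exhaustive(small)
    return small < thr


def brute_force_qc(img, cfg):
    """Re-derive grid, mask, and all four filter decisions from pixels.

    Returns (per-cell first-fail stage or None, per-stage survivor counts).
    """
    h, w = img.shape[:2]
    side = cfg.patch_side_40x
    f = cfg.mask_downsample
    mask = brute_force_mask(img, f)

    stages = []
    for y in range(0, h - side + 1, side):
        for x in range(0, w - side + 1, side):
            px = img[y:y + side, x:x + side].astype(np.float64)
            # tissue
            sub = mask[y // f:(y + side - 1) // f + 1,
                       x // f:(x + side - 1) // f + 1]
            if sub.mean() < cfg.min_tissue_fraction:
                stages.append("tissue")
                continue
            # background: all channels strictly above threshold
            bg = ((px[..., 0] > cfg.white_rgb_threshold)
                  & (px[..., 1] > cfg.white_rgb_threshold)
                  & (px[..., 2] > cfg.white_rgb_threshold))
            if bg.mean() > cfg.max_background_fraction:
                stages.append("background")
                continue
            # saturation: S = (max-min)/max over non-background pixels
            mx = px.max(axis=-1)
            mn = px.min(axis=-1)
            with np.errstate(invalid="ignore", divide="ignore"):
                sat = np.where(mx > 0, (mx - mn) / mx, 0.0)
            fg = ~bg
            if not fg.any() or sat[fg].mean() < cfg.saturation_threshold:
                stages.append("saturation")
                continue
            # blur: 3x3 Laplacian with edge-duplicating reflection
            g = _gray01(px) * 255.0
            p = np.pad(g, 1, mode="symmetric")
            lap = (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:]
                   - 4.0 * p[1:-1, 1:-1])
            if lap.var() < cfg.min_laplacian_variance:
                stages.append("blur")
                continue
            stages.append(None)

    order = ["tissue", "background", "saturation", "blur"]
    counts = {}
    alive = len(stages)
    for s in order:
        alive -= stages.count(s)
        counts[s] = alive
    return stages, counts
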