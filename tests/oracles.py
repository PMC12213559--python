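"""Independent explicit-loop oracles for the network operators.

These deliberately use nothing from the package's compute engine: plain
nested loops and numpy scalars, following the operator contracts step by
step.  They are the reference implementations the fast paths are tested
against.
"""

import math

import numpy as np
from scipy.special import erf


def gelu_scalar(x: float) -> float:
    return 0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))


def conv1d_loop(x: np.ndarray, w: np.ndarray, b: np.ndarray,
                groups: int = 1) -> np.ndarray:
    """Same-padded stride-1 grouped cross-correlation on a (C, T) array."""
    c, t = x.shape
    c_out, c_g, k = w.shape
    og = c_out // groups
    p = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (p, p)))
    y = np.zeros((c_out, t))
    for o in range(c_out):
        grp = o // og
        for tt in range(t):
            s = float(b[o])
            for ci in range(c_g):
                for kk in range(k):
                    s += w[o, ci, kk] * xp[grp * c_g + ci, tt + kk]
            y[o, tt] = s
    return y


def dsc_loop(x: np.ndarray, store, prefix: str) -> np.ndarray:
    """Depthwise 1x3 then pointwise 1x1, by loops."""
    c = x.shape[0]
    h = conv1d_loop(x, store[f"{prefix}.dw.w"], store[f"{prefix}.dw.b"], groups=c)
    return conv1d_loop(h, store[f"{prefix}.pw.w"], store[f"{prefix}.pw.b"])


def maxpool_loop(x: np.ndarray, size: int) -> np.ndarray:
    c, t = x.shape
    t2 = t // size
    out = np.empty((c, t2))
    for ci in range(c):
        for tt in range(t2):
            out[ci, tt] = max(x[ci, tt * size:(tt + 1) * size])
    return out


def upsample_pad_loop(x: np.ndarray, factor: int, target_len: int) -> np.ndarray:
    """Nearest-neighbor repeat, then right edge-replication to target_len."""
    c = x.shape[0]
    rep = np.repeat(x, factor, axis=-1)
    out = np.empty((c, target_len))
    for tt in range(target_len):
        out[:, tt] = rep[:, min(tt, rep.shape[-1] - 1)]
    return out


def dafm_loop(x: np.ndarray, cfg, store, prefix: str) -> np.ndarray:
    """Channel split -> per-scale depthwise conv (pool/up for coarse scales)
    -> 1x1 fusion -> GELU gate multiplied into the input."""
    c, t = x.shape
    cl = c // cfg.n_levels
    branches = []
    for lvl in range(cfg.n_levels):
        xi = x[lvl * cl:(lvl + 1) * cl]
        w = store[f"{prefix}.dw{lvl}.w"]
        b = store[f"{prefix}.dw{lvl}.b"]
        if lvl == 0:
            branches.append(conv1d_loop(xi, w, b, groups=cl))
        else:
            factor = min(cfg.dafm_pool**lvl, t)
            down = maxpool_loop(xi, factor)
            h = conv1d_loop(down, w, b, groups=cl)
            branches.append(upsample_pad_loop(h, factor, t))
    cat = np.concatenate(branches, axis=0)
    fused = conv1d_loop(cat, store[f"{prefix}.fuse.w"], store[f"{prefix}.fuse.b"])
    out = np.empty_like(x)
    for ci in range(c):
        for tt in range(t):
            out[ci, tt] = gelu_scalar(fused[ci, tt]) * x[ci, tt]
    return out


def cot_loop(x: np.ndarray, cfg, store, prefix: str) -> np.ndarray:
    """Static context (grouped conv) + softmax-attended dynamic context."""
    c, t = x.shape
    k = cfg.cot_kernel
    p = (k - 1) // 2
    k1 = conv1d_loop(x, store[f"{prefix}.key.w"], store[f"{prefix}.key.b"],
                     groups=cfg.cot_groups)
    qk = np.concatenate([k1, x], axis=0)
    a1 = conv1d_loop(qk, store[f"{prefix}.att1.w"], store[f"{prefix}.att1.b"])
    a1 = np.vectorize(gelu_scalar)(a1)
    a2 = conv1d_loop(a1, store[f"{prefix}.att2.w"], store[f"{prefix}.att2.b"])
    attn = a2.reshape(c, k, t)
    v = conv1d_loop(x, store[f"{prefix}.value.w"], store[f"{prefix}.value.b"])
    vp = np.pad(v, ((0, 0), (p, p)))
    y = np.empty_like(x)
    for ci in range(c):
        for tt in range(t):
            logits = attn[ci, :, tt]
            e = np.exp(logits - logits.max())
            soft = e / e.sum()
            k2 = sum(soft[kk] * vp[ci, tt + kk] for kk in range(k))
            y[ci, tt] = k1[ci, tt] + k2
    return y


def classify_loop(x: np.ndarray, store) -> np.ndarray:
    """Temporal mean, then two dense maps with a GELU between."""
    gap = x.mean(axis=-1)
    w1, b1 = store["cls.fc1.w"][:, :, 0], store["cls.fc1.b"]
    w2, b2 = store["cls.fc2.w"][:, :, 0], store["cls.fc2.b"]
    h = np.array([gelu_scalar(v) for v in (w1 @ gap + b1)])
    return w2 @ h + b2
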