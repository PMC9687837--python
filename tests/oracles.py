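"""Independent brute-force oracles used across the test suite.

Every function here recomputes a quantity by direct enumeration or a
double-loop transcription of the defining formula, deliberately sharing no
code with the package implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def otsu_bruteforce(gray: np.ndarray) -> int:
    """Exhaustive between-class-variance scan over all 256 thresholds."""
    vals = gray.ravel().astype(float)
    best_t, best_v = 0, -1.0
    for t in range(256):
        lo = vals[vals <= t]
        hi = vals[vals > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / len(vals), len(hi) / len(vals)
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def nlm_bruteforce(img: np.ndarray, patch_size: int, patch_distance: int,
                   h: float) -> np.ndarray:
    """Double-loop classic NLM with a Gaussian patch kernel."""
    x = img.astype(np.float64)
    pr = patch_size // 2
    a = max((patch_size - 1) / 4.0, 1e-12)
    kern = np.empty((patch_size, patch_size))
    for u in range(patch_size):
        for v in range(patch_size):
            kern[u, v] = math.exp(-(((u - pr) ** 2 + (v - pr) ** 2)
                                    / (2.0 * a * a)))
    kern /= kern.sum()
    pad = np.pad(x, pr, mode="reflect")
    H, W = x.shape
    out = np.zeros_like(x)
    for i in range(H):
        for j in range(W):
            p0 = pad[i:i + patch_size, j:j + patch_size]
            wsum = acc = 0.0
            for di in range(-patch_distance, patch_distance + 1):
                for dj in range(-patch_distance, patch_distance + 1):
                    ii, jj = i + di, j + dj
                    if not (0 <= ii < H and 0 <= jj < W):
                        continue
                    p1 = pad[ii:ii + patch_size, jj:jj + patch_size]
                    d = float((kern * (p0 - p1) ** 2).sum())
                    w = math.exp(-d / (h * h))
                    wsum += w
                    acc += w * x[ii, jj]
            out[i, j] = acc / wsum
    return out


def ssim_bruteforce(a: np.ndarray, b: np.ndarray, win: int = 7,
                    k1: float = 0.01, k2: float = 0.03, L: float = 255.0) -> float:
    """Per-window SSIM with unbiased covariances, averaged over all windows."""
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    H, W = a.shape
    n = win * win
    vals = []
    for i in range(H - win + 1):
        for j in range(W - win + 1):
            x = a[i:i + win, j:j + win].astype(float).ravel()
            y = b[i:i + win, j:j + win].astype(float).ravel()
            mx, my = x.mean(), y.mean()
            norm = n / (n - 1)
            vx = norm * ((x * x).mean() - mx * mx)
            vy = norm * ((y * y).mean() - my * my)
            vxy = norm * ((x * y).mean() - mx * my)
            vals.append(((2 * mx * my + c1) * (2 * vxy + c2))
                        / ((mx * mx + my * my + c1) * (vx + vy + c2)))
    return float(np.mean(vals))


def mcc_bruteforce(counts: np.ndarray) -> float:
    """Multiclass Matthews correlation from the covariance definition."""
    c = counts.astype(float)
    n = c.sum()
    k = len(c)
    t = c.sum(axis=1)
    p = c.sum(axis=0)
    cov_yp = np.trace(c) * n - sum(t[i] * p[i] for i in range(k))
    cov_yy = n * n - sum(t[i] * t[i] for i in range(k))
    cov_pp = n * n - sum(p[i] * p[i] for i in range(k))
    if cov_yy == 0 or cov_pp == 0:
        return math.nan
    return cov_yp / math.sqrt(cov_yy * cov_pp)


def wilcoxon_bruteforce(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    from scipy.stats import rankdata

    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return w_obs, min(1.0, 2.0 * min(p_le, p_ge))


def auc_bruteforce(y_bin: np.ndarray, score: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic (pair counting)."""
    pos = score[np.asarray(y_bin, dtype=bool)]
    neg = score[~np.asarray(y_bin, dtype=bool)]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def macs_conv(out_h: int, out_w: int, out_c: int, in_c: int, kh: int, kw: int) -> int:
    return out_h * out_w * out_c * in_c * kh * kw
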