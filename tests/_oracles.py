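"""Independent brute-force oracles for the feature extractors.

Everything here is written as plain loops over pixels/pairs/cut-points,
deliberately sharing no code with the package implementation.
"""

import math
from collections import Counter

import numpy as np

GLCM_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
LBP_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]


def otsu_exhaustive(patch):
    """Smallest cut point t maximising between-class variance of {<=t}|{>t}."""
    vals = [int(round(v)) for v in np.asarray(patch).ravel()]
    best_t, best_var = None, -1.0
    n = len(vals)
    for t in range(255):
        lo = [v for v in vals if v <= t]
        hi = [v for v in vals if v > t]
        if not lo or not hi:
            continue
        w0, w1 = len(lo) / n, len(hi) / n
        var = w0 * w1 * (sum(lo) / len(lo) - sum(hi) / len(hi)) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


def quantize(image, mask, levels):
    vals = [image[r, c] for r, c in zip(*np.nonzero(mask))]
    lo, hi = min(vals), max(vals)
    q = np.zeros(image.shape, dtype=int)
    for r, c in zip(*np.nonzero(mask)):
        if hi > lo:
            q[r, c] = min(int((image[r, c] - lo) / (hi - lo) * levels), levels - 1)
    return q


def glcm_direction(image, mask, levels, angle):
    """Symmetric co-occurrence probabilities for one direction, mask-restricted."""
    dr, dc = GLCM_OFFSETS[angle]
    q = quantize(np.asarray(image, dtype=float), mask, levels)
    P = np.zeros((levels, levels))
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols and mask[r, c] and mask[r2, c2]:
                P[q[r, c], q[r2, c2]] += 1
                P[q[r2, c2], q[r, c]] += 1
    if P.sum() == 0:
        return None
    return P / P.sum()


def glcm_stats(P):
    levels = P.shape[0]
    energy = sum(P[i, j] ** 2 for i in range(levels) for j in range(levels))
    contrast = sum((i - j) ** 2 * P[i, j] for i in range(levels) for j in range(levels))
    entropy = -sum(
        P[i, j] * math.log2(P[i, j])
        for i in range(levels)
        for j in range(levels)
        if P[i, j] > 0
    )
    deficit = sum(
        P[i, j] / (1 + (i - j) ** 2) for i in range(levels) for j in range(levels)
    )
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = sum(i * pi[i] for i in range(levels))
    mu_j = sum(j * pj[j] for j in range(levels))
    var_i = sum((i - mu_i) ** 2 * pi[i] for i in range(levels))
    var_j = sum((j - mu_j) ** 2 * pj[j] for j in range(levels))
    if var_i <= 0 or var_j <= 0:
        corr = 0.0
    else:
        corr = sum(
            (i - mu_i) * (j - mu_j) * P[i, j]
            for i in range(levels)
            for j in range(levels)
        ) / math.sqrt(var_i * var_j)
    return (energy, contrast, corr, entropy, deficit)


def glcm_averaged(image, mask, levels=16):
    stats = [glcm_stats(P) for a in (0, 45, 90, 135)
             if (P := glcm_direction(image, mask, levels, a)) is not None]
    return tuple(float(np.mean([s[k] for s in stats])) for k in range(5))


def lbp_code_direct(image, r, c):
    code = 0
    for p, (dr, dc) in enumerate(LBP_OFFSETS):
        if image[r + dr, c + dc] - image[r, c] >= 0:
            code += 2**p
    return code


def lbp_retained_hist(image, mask):
    rows, cols = image.shape
    codes = []
    for r, c in zip(*np.nonzero(mask)):
        if 1 <= r < rows - 1 and 1 <= c < cols - 1:
            codes.append(lbp_code_direct(image, r, c))
    retained = list(range(1, 16)) + list(range(240, 256))
    if not codes:
        return [0.0] * len(retained)
    counts = Counter(codes)
    return [counts.get(b, 0) / len(codes) for b in retained]


def pixelwise_rate_stats(phase_T, phase_t, mask):
    r_vals = []
    for r, c in zip(*np.nonzero(mask)):
        if phase_t[r, c] > 0:
            r_vals.append((phase_T[r, c] - phase_t[r, c]) / phase_t[r, c])
    n = len(r_vals)
    mean = sum(r_vals) / n
    var = sum((v - mean) ** 2 for v in r_vals) / n
    return (math.sqrt(var), mean, max(r_vals))


def first_order_stats(image, mask):
    vals = [float(image[r, c]) for r, c in zip(*np.nonzero(mask))]
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    std = math.sqrt(var)
    counts = Counter(min(255, max(0, int(round(v)))) for v in vals)
    entropy = -sum((c / n) * math.log2(c / n) for c in counts.values())
    vmax = max(vals)
    if std == 0:
        bias = peak = 0.0
    else:
        bias = sum(((v - mean) / std) ** 3 for v in vals) / n
        peak = sum(((v - mean) / std) ** 4 for v in vals) / n - 3.0
    return (mean, std, entropy, vmax, bias, peak)


def random_lesion(rng, max_side=10):
    """Random integer image with a random blob-ish mask (at least 4 px)."""
    side = int(rng.integers(4, max_side + 1))
    image = rng.integers(0, 256, size=(side, side)).astype(float)
    while True:
        mask = rng.random((side, side)) < 0.6
        if mask.sum() >= 4:
            return image, mask
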