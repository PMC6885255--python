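"""Radiomics feature suite for segmented lesions on a three-phase series.

The extractor emits a fixed, labelled schema of 146 values per lesion:

* ``F1``–``F15`` — GLCM texture (energy, contrast, correlation, entropy,
  deficit matrix) per phase T0/T1/T2, averaged over the four offsets
  0°/45°/90°/135° at distance 1.  "Deficit matrix" is the inverse
  difference moment (homogeneity) statistic.
* ``F16_b``/``F17_b``/``F18_b`` — LBP histogram frequencies at the 31
  retained codes b ∈ {1..15, 240..255}, per phase.
* ``T1``–``T9`` — pixel-wise enhancement statistics (std, mean, max of the
  per-pixel rate (I_T - I_t)/I_t) for phase pairs (1,0), (2,0), (2,1).
* ``T10``–``T13`` — whole-lesion enhancement rate S_i/S_0 and absorption
  rate (S_i - S_0)/S_0 × 100% for i = 1, 2.
* ``C1``–``C18`` — first-order statistics (mean, std, entropy, max, bias =
  skewness, peak = excess kurtosis) per phase.
* ``M1``–``M7`` — morphology from the normalised radial length (NRL):
  NRL mean and std, tightness P²/(4πA), roughness, smoothness, roundness
  4πA/P², and area.

All standard deviations are population standard deviations; histogram
entropies use log base 2 with 0·log 0 ≡ 0.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_SCHEMA",
    "RETAINED_LBP_BINS",
    "glcm_features",
    "lbp_code",
    "lbp_image",
    "lbp_histogram",
    "kinetic_whole",
    "kinetic_pixelwise",
    "stats_features",
    "morphology_features",
    "extract_all",
    "drop_invalid_columns",
]

RETAINED_LBP_BINS = tuple(range(1, 16)) + tuple(range(240, 256))

GLCM_STAT_NAMES = ("energy", "contrast", "correlation", "entropy", "deficit_matrix")

# (dr, dc) offsets for GLCM directions 0°, 45°, 90°, 135° at distance 1.
_GLCM_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

# LBP neighbour order: top-left then clockwise; bit weight 2^p from p = 0.
_LBP_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))


def _build_schema() -> tuple[str, ...]:
    labels: list[str] = [f"F{i}" for i in range(1, 16)]
    for f in (16, 17, 18):
        labels += [f"F{f}_{b}" for b in RETAINED_LBP_BINS]
    labels += [f"T{i}" for i in range(1, 14)]
    labels += [f"C{i}" for i in range(1, 19)]
    labels += [f"M{i}" for i in range(1, 8)]
    return tuple(labels)


#: Fixed, ordered feature schema (146 labels).
FEATURE_SCHEMA: tuple[str, ...] = _build_schema()


def _as_mask(mask) -> np.ndarray:
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("empty lesion mask")
    return m


def glcm_features(image, mask, levels: int = 16):
    """GLCM statistics of the lesion, averaged over the four directions.

    Lesion intensities are min–max quantised to ``levels`` grey levels; the
    co-occurrence matrix per direction counts symmetric pixel pairs at
    distance 1 with both pixels inside the mask, normalised to probabilities.

    Returns ``(energy, contrast, correlation, entropy, deficit_matrix)``.
    When a direction's variance vanishes, its correlation is 0 by convention.
    """
    mask = _as_mask(mask)
    image = np.asarray(image, dtype=np.float64)
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    q = np.zeros(image.shape, dtype=np.intp)
    if hi > lo:
        q[mask] = np.minimum((image[mask] - lo) / (hi - lo) * levels, levels - 1).astype(np.intp)

    stats = []
    for dr, dc in _GLCM_OFFSETS:
        P = _direction_glcm(q, mask, dr, dc, levels)
        if P is None:
            continue
        stats.append(_glcm_stats(P))
    if not stats:
        raise ValueError("no valid pixel pair in any GLCM direction")
    return tuple(float(np.mean([s[k] for s in stats])) for k in range(5))


def _direction_glcm(q, mask, dr, dc, levels):
    rows, cols = mask.shape
    r0s, r0e = max(0, -dr), min(rows, rows - dr)
    c0s, c0e = max(0, -dc), min(cols, cols - dc)
    a = q[r0s:r0e, c0s:c0e]
    b = q[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    valid = mask[r0s:r0e, c0s:c0e] & mask[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    if not valid.any():
        return None
    i = a[valid].ravel()
    j = b[valid].ravel()
    P = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(P, (i, j), 1.0)
    P += P.T.copy()            # symmetric accumulation
    return P / P.sum()


def _glcm_stats(P):
    levels = P.shape[0]
    idx = np.arange(levels, dtype=np.float64)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    energy = float((P**2).sum())
    contrast = float(((ii - jj) ** 2 * P).sum())
    nz = P[P > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    deficit = float((P / (1.0 + (ii - jj) ** 2)).sum())
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float((idx * pi).sum())
    mu_j = float((idx * pj).sum())
    var_i = float(((idx - mu_i) ** 2 * pi).sum())
    var_j = float(((idx - mu_j) ** 2 * pj).sum())
    if var_i <= 0 or var_j <= 0:
        corr = 0.0
    else:
        corr = float((((ii - mu_i) * (jj - mu_j) * P).sum()) / np.sqrt(var_i * var_j))
    return (energy, contrast, corr, entropy, deficit)


def lbp_code(center: float, neighbors) -> int:
    """8-bit local binary pattern code of one 3×3 neighbourhood.

    Neighbours are ordered top-left then clockwise; bit p is set when
    ``g_p - g_c >= 0`` (ties count as 1) and weighted ``2^p``.
    """
    neighbors = np.asarray(neighbors, dtype=np.float64)
    if neighbors.shape != (8,):
        raise ValueError("expected exactly 8 neighbours")
    bits = (neighbors - float(center)) >= 0
    return int((bits * (1 << np.arange(8))).sum())


def lbp_image(image) -> np.ndarray:
    """LBP codes for every interior pixel; border pixels are coded -1."""
    image = np.asarray(image, dtype=np.float64)
    rows, cols = image.shape
    codes = np.full((rows, cols), -1, dtype=np.int64)
    if rows < 3 or cols < 3:
        return codes
    center = image[1:-1, 1:-1]
    acc = np.zeros_like(center, dtype=np.int64)
    for p, (dr, dc) in enumerate(_LBP_OFFSETS):
        nb = image[1 + dr : rows - 1 + dr, 1 + dc : cols - 1 + dc]
        acc |= ((nb - center) >= 0).astype(np.int64) << p
    codes[1:-1, 1:-1] = acc
    return codes


def lbp_histogram(image, mask) -> np.ndarray:
    """Retained-bin LBP frequencies of the lesion (31 values).

    Codes are computed for every mask pixel whose 3×3 window lies inside the
    image; neighbours are read from the raw image regardless of mask
    membership.  The full 256-bin histogram is normalised by the number of
    coded pixels before the bins {1..15, 240..255} are retained.  A mask
    with no codable pixel yields an all-zero histogram with a warning.
    """
    mask = _as_mask(mask)
    codes = lbp_image(image)
    sel = codes[mask]
    sel = sel[sel >= 0]
    if sel.size == 0:
        warnings.warn("no codable pixel in mask: all-zero LBP histogram")
        logger.warning("LBP: mask has no interior pixel; emitting zeros")
        return np.zeros(len(RETAINED_LBP_BINS))
    hist = np.bincount(sel, minlength=256).astype(np.float64) / sel.size
    return hist[list(RETAINED_LBP_BINS)]


def kinetic_whole(s0: float, s1: float, s2: float):
    """Whole-lesion enhancement and absorption rates (T10–T13).

    ``ER_i0 = S_i/S_0`` and ``AR_i0 = (S_i - S_0)/S_0 × 100`` (percent),
    with S_i the mean lesion grey level of phase i.
    """
    if s0 <= 0:
        raise ValueError("S0 must be > 0")
    er1, er2 = s1 / s0, s2 / s0
    return (er1, (s1 - s0) / s0 * 100.0, er2, (s2 - s0) / s0 * 100.0)


def kinetic_pixelwise(phase_T, phase_t, mask):
    """Per-pixel enhancement-rate statistics between two phases.

    R collects ``(I_T - I_t)/I_t`` over mask pixels with ``I_t > 0``;
    returns ``(std, mean, max)`` of R (population std).
    """
    mask = _as_mask(mask)
    a = np.asarray(phase_T, dtype=np.float64)[mask]
    b = np.asarray(phase_t, dtype=np.float64)[mask]
    valid = b > 0
    if not valid.any():
        raise ValueError("all lesion pixels have zero intensity in the earlier phase")
    r = (a[valid] - b[valid]) / b[valid]
    return (float(r.std()), float(r.mean()), float(r.max()))


def stats_features(image, mask):
    """First-order statistics of the lesion grey levels.

    Returns ``(mean, std, entropy, max, bias, peak)`` where entropy is the
    Shannon entropy (bits) of the 256-bin grey-level histogram, bias is the
    skewness and peak the excess kurtosis; both are 0 when std is 0.
    """
    mask = _as_mask(mask)
    vals = np.asarray(image, dtype=np.float64)[mask]
    mean = float(vals.mean())
    std = float(vals.std())
    binned = np.clip(np.rint(vals), 0, 255).astype(np.int64)
    p = np.bincount(binned, minlength=256).astype(np.float64) / binned.size
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    vmax = float(vals.max())
    if std == 0:
        bias = peak = 0.0
    else:
        z = (vals - mean) / std
        bias = float((z**3).mean())
        peak = float((z**4).mean() - 3.0)
    return (mean, std, entropy, vmax, bias, peak)


def _boundary_pixels(mask) -> np.ndarray:
    """Mask pixels with at least one 4-neighbour outside the mask."""
    rows, cols = mask.shape
    padded = np.zeros((rows + 2, cols + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return mask & ~interior


def morphology_features(mask):
    """Shape descriptors M1–M7 from the normalised radial length.

    The boundary (mask pixels with a 4-neighbour outside) is ordered by polar
    angle about the mask centroid; radial lengths d_k are normalised by their
    maximum (NRL).  M1/M2 are the NRL mean and population std; M3 tightness =
    P²/(4πA); M4 roughness and M5 smoothness are cyclic first- and
    second-difference means of the NRL sequence; M6 roundness = 4πA/P²;
    M7 = area in pixels.  The perimeter P sums steps between consecutive
    angle-ordered boundary pixels (1 axial, √2 diagonal).
    """
    mask = _as_mask(mask)
    boundary = _boundary_pixels(mask)
    br, bc = np.nonzero(boundary)
    if br.size < 3:
        raise ValueError("boundary shorter than 3 pixels")
    cy, cx = np.nonzero(mask)
    centroid = (cy.mean(), cx.mean())
    dy = br - centroid[0]
    dx = bc - centroid[1]
    d = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    order = np.lexsort((d, theta))
    d = d[order]
    pr, pc = br[order], bc[order]

    nrl = d / d.max()
    m1 = float(nrl.mean())
    m2 = float(nrl.std())
    steps = np.hypot(np.diff(pr, append=pr[:1]), np.diff(pc, append=pc[:1]))
    perimeter = float(steps.sum())
    area = float(mask.sum())
    m3 = perimeter**2 / (4.0 * np.pi * area)
    m4 = float(np.abs(nrl - np.roll(nrl, -1)).mean())
    m5 = float(np.abs(nrl - (np.roll(nrl, 1) + np.roll(nrl, -1)) / 2.0).mean())
    m6 = 4.0 * np.pi * area / perimeter**2
    return (m1, m2, float(m3), m4, m5, float(m6), area)


def extract_all(phases, mask, levels: int = 16) -> pd.Series:
    """Extract the full 146-value feature vector for one lesion.

    ``phases`` is an array-like of at least three same-shaped grey-level
    images (T0 pre-contrast, T1/T2 post-contrast); ``mask`` the segmented
    lesion.  Returns a :class:`pandas.Series` indexed by the fixed schema.
    """
    phases = np.asarray(phases, dtype=np.float64)
    if phases.ndim != 3 or phases.shape[0] < 3:
        raise ValueError("need a stack of >= 3 phases")
    mask = _as_mask(mask)
    t0, t1, t2 = phases[0], phases[1], phases[2]

    values: list[float] = []
    for ph in (t0, t1, t2):
        values.extend(glcm_features(ph, mask, levels=levels))
    for ph in (t0, t1, t2):
        values.extend(lbp_histogram(ph, mask))
    for hi, lo in ((t1, t0), (t2, t0), (t2, t1)):
        values.extend(kinetic_pixelwise(hi, lo, mask))
    s0, s1, s2 = (float(ph[mask].mean()) for ph in (t0, t1, t2))
    values.extend(kinetic_whole(s0, s1, s2))
    for ph in (t0, t1, t2):
        values.extend(stats_features(ph, mask))
    values.extend(morphology_features(mask))

    vec = pd.Series(values, index=list(FEATURE_SCHEMA), dtype=np.float64)
    if not np.isfinite(vec.to_numpy()).all():
        bad = vec.index[~np.isfinite(vec.to_numpy())].tolist()
        raise ValueError(f"non-finite feature values: {bad}")
    return vec


def drop_invalid_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Remove feature columns that are zero for every case.

    Only numeric columns are candidates; removed labels are logged.
    """
    if table.empty:
        raise ValueError("empty feature table")
    numeric = table.select_dtypes(include=[np.number])
    dead = [c for c in numeric.columns if (numeric[c] == 0).all()]
    if dead:
        logger.info("dropping %d all-zero columns: %s", len(dead), dead)
    return table.drop(columns=dead)
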