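"""Lesion segmentation by seeded region growing.

The lesion is annotated by a loose rectangular ROI; the segmentation grows a
connected region from the ROI centroid. Two growth criteria are provided:

* ``dynamic_otsu`` — the growth threshold is determined per case by Otsu's
  method on the ROI patch, so no per-case parameter is needed.  The mask is
  the connected component of the Otsu foreground that contains the seed.
* ``fixed`` — the classical criterion: a neighbour is accepted when its
  absolute intensity difference from the seed value is below a preset
  threshold ``T``.

Masks are scored against reference masks with the Dice coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ROIBox",
    "GrowOptions",
    "DegenerateThresholdError",
    "EmptySegmentationError",
    "otsu_threshold",
    "region_grow",
    "region_grow_fixed",
    "dice",
]


class DegenerateThresholdError(ValueError):
    """The patch histogram occupies a single bin; no threshold separates it."""


class EmptySegmentationError(ValueError):
    """Region growing produced an empty mask."""


@dataclass(frozen=True)
class ROIBox:
    """Rectangular lesion annotation, 0-based half-open pixel coordinates.

    The box spans rows ``[row0, row1)`` and columns ``[col0, col1)``.
    """

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError(f"empty ROI box {self}")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError(f"negative ROI origin {self}")
        if self.area < 9:
            raise ValueError(f"ROI area {self.area} < 9 px")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row1 - self.row0, self.col1 - self.col0)

    @property
    def area(self) -> int:
        return self.shape[0] * self.shape[1]

    @property
    def center(self) -> tuple[int, int]:
        """Geometric centre pixel (integer, floor of the midpoint)."""
        return ((self.row0 + self.row1 - 1) // 2, (self.col0 + self.col1 - 1) // 2)

    def validate_in(self, shape: tuple[int, int]) -> None:
        if self.row1 > shape[0] or self.col1 > shape[1]:
            raise ValueError(f"ROI {self} exceeds image bounds {shape}")

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row1), slice(self.col0, self.col1))

    def to_list(self) -> list[int]:
        return [self.row0, self.col0, self.row1, self.col1]

    @classmethod
    def from_list(cls, v) -> "ROIBox":
        r0, c0, r1, c1 = (int(x) for x in v)
        return cls(r0, c0, r1, c1)


@dataclass
class GrowOptions:
    """Options for :func:`region_grow`.

    mode
        ``"dynamic_otsu"`` (threshold from the ROI-patch Otsu level) or
        ``"fixed"`` (absolute difference-from-seed below ``fixed_threshold``).
    criterion
        For dynamic mode only: ``"otsu_foreground"`` keeps pixels with
        intensity above the Otsu level (default); ``"seed_delta"`` keeps
        pixels with ``|I(p) - I(seed)| < |I(seed) - t*|``.
    seed_relocation_window
        Half-width of the window searched for the brightest pixel when the
        ROI centroid falls below the threshold (a concave lesion can leave
        the centroid on background).
    """

    mode: str = "dynamic_otsu"
    fixed_threshold: float | None = None
    criterion: str = "otsu_foreground"
    connectivity: int = 8
    restrict_to_roi: bool = True
    fill_holes: bool = False
    seed_relocation_window: int = 3

    def __post_init__(self) -> None:
        if self.mode not in ("dynamic_otsu", "fixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "fixed":
            if self.fixed_threshold is None or self.fixed_threshold <= 0:
                raise ValueError("fixed mode requires fixed_threshold > 0")
        if self.criterion not in ("otsu_foreground", "seed_delta"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def otsu_threshold(patch: np.ndarray) -> int:
    """Otsu threshold of an integer-valued patch over a 256-bin histogram.

    Returns the level ``t*`` maximising the between-class variance of the
    split background ``{I <= t*}`` / foreground ``{I > t*}``; among tied
    maximisers the smallest level is returned.

    Raises
    ------
    DegenerateThresholdError
        If the patch is constant (single occupied bin).
    """
    patch = np.asarray(patch)
    if patch.size == 0:
        raise ValueError("empty patch")
    vals = np.clip(np.rint(patch), 0, 255).astype(np.int64).ravel()
    hist = np.bincount(vals, minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateThresholdError(
            f"constant patch (value {vals[0]}): Otsu threshold undefined"
        )
    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)[:-1]                      # weight of {I <= t}, t = 0..254
    w1 = 1.0 - w0
    m0 = np.cumsum(p * levels)[:-1]             # unnormalised class means
    mu = (p * levels).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu * w0 - m0) ** 2 / (w0 * w1)
    sigma_b[(w0 == 0) | (w1 == 0)] = -np.inf
    return int(np.argmax(sigma_b))              # argmax returns the first (smallest) tie


def _component_containing(fg: np.ndarray, seed: tuple[int, int], connectivity: int) -> np.ndarray:
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    labels, _ = ndimage.label(fg, structure=structure)
    lab = labels[seed]
    if lab == 0:
        return np.zeros_like(fg, dtype=bool)
    return labels == lab


def _relocate_seed(image: np.ndarray, roi: ROIBox, seed: tuple[int, int], window: int) -> tuple[int, int]:
    r, c = seed
    r0 = max(roi.row0, r - window)
    r1 = min(roi.row1, r + window + 1)
    c0 = max(roi.col0, c - window)
    c1 = min(roi.col1, c + window + 1)
    patch = image[r0:r1, c0:c1]
    idx = np.unravel_index(int(np.argmax(patch)), patch.shape)
    return (r0 + idx[0], c0 + idx[1])


def region_grow(image: np.ndarray, roi: ROIBox, options: GrowOptions | None = None) -> np.ndarray:
    """Segment the lesion inside ``roi`` by seeded region growing.

    The seed is the geometric centre of the ROI, relocated to the brightest
    pixel in a small window when the centre falls below the growth threshold.
    Returns a boolean mask in full-image coordinates.
    """
    options = options or GrowOptions()
    image = np.asarray(image, dtype=np.float64)
    roi.validate_in(image.shape)
    if options.mode == "fixed":
        return region_grow_fixed(image, roi, options.fixed_threshold, options)

    patch = image[roi.slices()]
    t_star = otsu_threshold(patch)

    seed = roi.center
    if image[seed] <= t_star:
        seed = _relocate_seed(image, roi, seed, options.seed_relocation_window)

    if options.criterion == "otsu_foreground":
        fg = image > t_star
    else:  # seed_delta: difference-from-seed bounded by the seed's margin over t*
        fg = np.abs(image - image[seed]) < abs(image[seed] - t_star)
        fg[seed] = True
    if options.restrict_to_roi:
        inroi = np.zeros(image.shape, dtype=bool)
        inroi[roi.slices()] = True
        fg &= inroi
    mask = _component_containing(fg, seed, options.connectivity)
    if options.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise EmptySegmentationError(f"no foreground component contains seed {seed}")
    return mask


def region_grow_fixed(
    image: np.ndarray,
    roi: ROIBox,
    threshold: float,
    options: GrowOptions | None = None,
) -> np.ndarray:
    """Classical region growing: accept pixels with ``|I(p) - I(seed)| < T``.

    Grows an 8-connected region from the ROI centre, restricted to the ROI by
    default. The grown region is non-shrinking in ``T``.
    """
    if threshold is None or threshold <= 0:
        raise ValueError("threshold must be > 0")
    opts = options or GrowOptions(mode="fixed", fixed_threshold=threshold)
    image = np.asarray(image, dtype=np.float64)
    roi.validate_in(image.shape)
    seed = roi.center
    fg = np.abs(image - image[seed]) < threshold
    if opts.restrict_to_roi:
        inroi = np.zeros(image.shape, dtype=bool)
        inroi[roi.slices()] = True
        fg &= inroi
    mask = _component_containing(fg, seed, opts.connectivity)
    if opts.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise EmptySegmentationError(f"empty region grown from seed {seed} at T={threshold}")
    return mask


def dice(mask_x: np.ndarray, mask_y: np.ndarray) -> float:
    """Dice coefficient ``S = 2|X ∩ Y| / (|X| + |Y|)`` of two binary masks.

    ``S = 1`` for identical nonempty masks, ``S = 0`` for disjoint masks.
    Raises on shape mismatch or two empty masks.
    """
    x = np.asarray(mask_x).astype(bool)
    y = np.asarray(mask_y).astype(bool)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    nx = int(x.sum())
    ny = int(y.sum())
    if nx + ny == 0:
        raise ValueError("dice undefined for two empty masks")
    return 2.0 * int((x & y).sum()) / (nx + ny)
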