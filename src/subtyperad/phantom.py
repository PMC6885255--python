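"""Synthetic DCE-MRI phantom cohorts with known ground truth.

Each case is a short multi-phase series of one breast slice: a pre-contrast
phase T0 and two post-contrast phases T1, T2.  The lesion is a star-convex
blob whose boundary irregularity, intra-lesion texture and contrast-uptake
kinetics depend on the molecular-subtype class, so that shape, texture and
kinetic features all carry class signal.  Class frequencies default to the
imbalanced four-subtype composition of a 637-case clinical cohort
(183 / 241 / 143 / 70 for luminal A, luminal B, HER-2, basal-like).

The generator is fully deterministic given its seed, which makes every
downstream stage testable without any external data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .segmentation import ROIBox

__all__ = [
    "SUBTYPES",
    "COHORT_COUNTS",
    "KineticProfile",
    "ShapeProfile",
    "TextureProfile",
    "PhantomSpec",
    "PhantomCase",
    "generate_lesion_shape",
    "generate_case",
    "generate_cohort",
    "allocate_counts",
    "planted_feature_table",
]

SUBTYPES = ("A", "B", "C", "D")
#: Clinical cohort composition: luminal A, luminal B, HER-2, basal-like.
COHORT_COUNTS = (183, 241, 143, 70)


@dataclass(frozen=True)
class KineticProfile:
    """Target contrast-uptake kinetics of a lesion class.

    ``enhancement_ratio_1`` and ``enhancement_ratio_2`` are the target
    whole-lesion ratios S1/S0 and S2/S0; ``heterogeneity_sd`` is the spread
    of the per-pixel ratios around those targets (tumour heterogeneity).
    """

    enhancement_ratio_1: float
    enhancement_ratio_2: float
    heterogeneity_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.enhancement_ratio_1 <= 0 or self.enhancement_ratio_2 <= 0:
            raise ValueError("enhancement ratios must be > 0")
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be >= 0")


@dataclass(frozen=True)
class ShapeProfile:
    """Star-convex lesion shape: radius r(θ) = r0·(1 + Σ_j a_j·cos(jθ + φ_j)).

    ``irregularity`` sets the total amplitude of the radial perturbation;
    ``n_harmonics`` its angular frequency content.  Amplitude 0 gives a disk.
    """

    base_radius: float = 14.0
    irregularity: float = 0.1
    n_harmonics: int = 5

    def __post_init__(self) -> None:
        if self.base_radius < 5:
            raise ValueError("base_radius must be >= 5 px")
        if self.irregularity < 0:
            raise ValueError("irregularity must be >= 0")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")


@dataclass(frozen=True)
class TextureProfile:
    """Intra-lesion texture: a smooth Gaussian random field added to the
    lesion baseline, with amplitude ``contrast`` (intensity units) and
    spatial ``correlation_length`` (pixels)."""

    contrast: float = 8.0
    correlation_length: float = 2.0

    def __post_init__(self) -> None:
        if self.contrast < 0 or self.correlation_length <= 0:
            raise ValueError("invalid texture profile")


def _default_class_profiles():
    # Stand-in subtype appearance models: kinetics, boundary irregularity and
    # texture separate the classes; no claim of biological fidelity.
    kinetics = {
        "A": KineticProfile(1.4, 1.3, 0.05),
        "B": KineticProfile(1.7, 1.6, 0.08),
        "C": KineticProfile(2.0, 1.7, 0.12),
        "D": KineticProfile(2.3, 2.0, 0.15),
    }
    shapes = {
        "A": ShapeProfile(14.0, 0.05, 4),
        "B": ShapeProfile(16.0, 0.12, 5),
        "C": ShapeProfile(13.0, 0.20, 5),
        "D": ShapeProfile(12.0, 0.30, 6),
    }
    textures = {
        "A": TextureProfile(6.0, 3.0),
        "B": TextureProfile(10.0, 2.5),
        "C": TextureProfile(14.0, 2.0),
        "D": TextureProfile(18.0, 1.5),
    }
    return kinetics, shapes, textures


@dataclass
class PhantomSpec:
    """Full description of a synthetic cohort; together with ``rng_seed``
    it determines every generated byte."""

    image_size: tuple[int, int] = (128, 128)
    n_cases: int = 100
    class_proportions: tuple[float, float, float, float] = tuple(
        c / sum(COHORT_COUNTS) for c in COHORT_COUNTS
    )
    kinetic_profiles: dict = field(default_factory=lambda: _default_class_profiles()[0])
    shape_profiles: dict = field(default_factory=lambda: _default_class_profiles()[1])
    texture_profiles: dict = field(default_factory=lambda: _default_class_profiles()[2])
    background_level: float = 30.0
    lesion_baseline: float = 100.0
    noise_sd: float = 4.0
    n_phases: int = 3
    roi_padding: int = 4
    quantize: bool = True          # round phases to integer grey levels 0..255
    rng_seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.class_proportions, dtype=float)
        if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must be non-negative and sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_phases < 3:
            raise ValueError("need >= 3 phases (one pre-contrast, two post)")
        for label in SUBTYPES:
            sp = self.shape_profiles[label]
            # lesion (with perturbation) must fit inside the image with margin
            max_r = sp.base_radius * (1.0 + sp.irregularity)
            if 2 * max_r + 8 > min(self.image_size):
                raise ValueError(f"class {label} lesion cannot fit inside {self.image_size}")

    @classmethod
    def from_json(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            raw = json.load(fh)
        for key, typ in (
            ("kinetic_profiles", KineticProfile),
            ("shape_profiles", ShapeProfile),
            ("texture_profiles", TextureProfile),
        ):
            if key in raw:
                raw[key] = {k: typ(**v) for k, v in raw[key].items()}
        for key in ("image_size", "class_proportions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_json(self, path) -> None:
        raw = asdict(self)
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=2, sort_keys=True)


@dataclass
class PhantomCase:
    """One synthetic case: phase stack, ground-truth mask, loose ROI, label."""

    case_id: str
    label: str
    phases: np.ndarray          # (n_phases, rows, cols) float64 in [0, 255]
    truth_mask: np.ndarray      # (rows, cols) bool
    roi: ROIBox


def generate_lesion_shape(
    shape_profile: ShapeProfile,
    rng: np.random.Generator,
    image_size: tuple[int, int] = (128, 128),
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Rasterise a star-convex lesion mask from a random radial function.

    The boundary is r(θ) = r0·(1 + Σ_j a_j·cos(jθ + φ_j)) with random phases
    φ_j and harmonic amplitudes summing to ``irregularity``.  The result is a
    single 8-connected component; a lesion that would exceed the image bounds
    raises a generation error.
    """
    rows, cols = image_size
    if center is None:
        center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    sp = shape_profile
    # split the total amplitude across harmonics with random weights
    weights = rng.uniform(0.5, 1.0, sp.n_harmonics)
    amps = sp.irregularity * weights / weights.sum()
    phis = rng.uniform(0, 2 * np.pi, sp.n_harmonics)
    js = np.arange(1, sp.n_harmonics + 1)

    rr, cc = np.mgrid[0:rows, 0:cols]
    dy = rr - center[0]
    dx = cc - center[1]
    theta = np.arctan2(dy, dx)
    r_theta = sp.base_radius * (
        1.0 + np.sum(amps[:, None, None] * np.cos(js[:, None, None] * theta + phis[:, None, None]), axis=0)
    )
    max_r = sp.base_radius * (1.0 + sp.irregularity)
    if (
        center[0] - max_r < 4
        or center[0] + max_r > rows - 5
        or center[1] - max_r < 4
        or center[1] + max_r > cols - 5
    ):
        raise ValueError("lesion exceeds image bounds (margin 4 px)")
    mask = dy * dy + dx * dx <= r_theta * r_theta
    if not mask.any():
        raise ValueError("degenerate lesion: empty mask")
    # star-convex rasterisation can pinch off slivers; keep the main component
    structure = ndimage.generate_binary_structure(2, 2)
    labels, n = ndimage.label(mask, structure=structure)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def generate_case(
    spec: PhantomSpec,
    class_label: str,
    rng: np.random.Generator,
    case_id: str = "case",
) -> PhantomCase:
    """Generate one multi-phase case for the given subtype class.

    Phase T0 holds the background plus the textured lesion baseline; each
    post-contrast phase multiplies every lesion pixel by a per-pixel
    enhancement ratio drawn around the class target.  Gaussian noise is added
    everywhere and intensities clipped to [0, 255].
    """
    if class_label not in SUBTYPES:
        raise ValueError(f"unknown class {class_label!r}")
    rows, cols = spec.image_size
    sp = spec.shape_profiles[class_label]
    kp = spec.kinetic_profiles[class_label]
    tp = spec.texture_profiles[class_label]

    # random lesion centre, keeping the full perturbed radius inside bounds
    max_r = sp.base_radius * (1.0 + sp.irregularity)
    lo_r, hi_r = 4 + max_r, rows - 5 - max_r
    lo_c, hi_c = 4 + max_r, cols - 5 - max_r
    center = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
    mask = generate_lesion_shape(sp, rng, spec.image_size, center)

    # textured lesion baseline: smooth Gaussian random field
    noise_field = rng.standard_normal((rows, cols))
    smooth = ndimage.gaussian_filter(noise_field, tp.correlation_length)
    sd = smooth.std()
    texture = tp.contrast * (smooth / sd if sd > 0 else smooth)

    base = np.full((rows, cols), spec.background_level, dtype=np.float64)
    base[mask] = spec.lesion_baseline + texture[mask]
    base[mask] = np.maximum(base[mask], 1.0)      # baseline must stay positive

    ratios = [1.0]
    targets = [kp.enhancement_ratio_1, kp.enhancement_ratio_2]
    # phases beyond T2 hold at the T2 level (plateau)
    while len(targets) < spec.n_phases - 1:
        targets.append(kp.enhancement_ratio_2)
    for t in targets:
        r = t + kp.heterogeneity_sd * rng.standard_normal(int(mask.sum()))
        ratios.append(np.maximum(r, 0.05))

    phases = np.empty((spec.n_phases, rows, cols), dtype=np.float64)
    for i, r in enumerate(ratios):
        img = base.copy()
        img[mask] = base[mask] * r
        if spec.noise_sd > 0:
            img = img + spec.noise_sd * rng.standard_normal((rows, cols))
        np.clip(img, 0.0, 255.0, out=img)
        if spec.quantize:
            np.rint(img, out=img)
        phases[i] = img

    rs, cs = np.nonzero(mask)
    pad = spec.roi_padding
    roi = ROIBox(
        max(0, int(rs.min()) - pad),
        max(0, int(cs.min()) - pad),
        min(rows, int(rs.max()) + 1 + pad),
        min(cols, int(cs.max()) + 1 + pad),
    )
    return PhantomCase(case_id=case_id, label=class_label, phases=phases, truth_mask=mask, roi=roi)


def allocate_counts(n_cases: int, proportions) -> list[int]:
    """Largest-remainder allocation of ``n_cases`` across classes.

    Exactly reproduces the clinical composition at the cohort size: 637 cases
    at proportions (183, 241, 143, 70)/637 allocate to those integer counts.
    """
    props = np.asarray(proportions, dtype=float)
    quotas = props * n_cases
    counts = np.floor(quotas).astype(int)
    remainder = n_cases - counts.sum()
    if remainder > 0:
        order = np.argsort(-(quotas - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts.tolist()


def generate_cohort(spec: PhantomSpec) -> tuple[list[PhantomCase], dict]:
    """Generate a full cohort plus manifest, reproducible from the seed."""
    if spec.n_cases < 4:
        raise ValueError("n_cases must be >= 4")
    counts = allocate_counts(spec.n_cases, spec.class_proportions)
    for label, cnt, prop in zip(SUBTYPES, counts, spec.class_proportions):
        if cnt == 0 and prop > 0 and spec.n_cases >= len(SUBTYPES):
            warnings.warn(f"class {label} received 0 cases at n={spec.n_cases}")
    rng = np.random.default_rng(spec.rng_seed)
    labels = [lab for lab, cnt in zip(SUBTYPES, counts) for _ in range(cnt)]
    cases = []
    width = len(str(spec.n_cases))
    for i, lab in enumerate(labels):
        cid = f"case_{i:0{width}d}"
        cases.append(generate_case(spec, lab, rng, case_id=cid))
    manifest = {
        "n_cases": spec.n_cases,
        "class_counts": dict(zip(SUBTYPES, counts)),
        "rng_seed": spec.rng_seed,
        "cases": [
            {"case_id": c.case_id, "label": c.label, "roi": c.roi.to_list()}
            for c in cases
        ],
    }
    return cases, manifest


def planted_feature_table(
    n_samples: int = 640,
    n_features: int = 60,
    n_informative: int = 10,
    class_proportions=None,
    class_sep: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Tabular benchmark with known informative features, for feature-selection
    recovery studies.

    The informative features carry class-dependent Gaussian means (separation
    ``class_sep``); the remainder are pure noise.  Returns
    ``(DataFrame X, Series y, informative labels)``; class counts follow the
    largest-remainder allocation of ``class_proportions`` (clinical-cohort
    imbalance by default).
    """
    import pandas as pd

    if class_proportions is None:
        class_proportions = tuple(c / sum(COHORT_COUNTS) for c in COHORT_COUNTS)
    rng = np.random.default_rng(seed)
    counts = allocate_counts(n_samples, class_proportions)
    y = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
    n_classes = len(counts)
    centers = rng.standard_normal((n_classes, n_informative)) * class_sep
    X = rng.standard_normal((n_samples, n_features)) * noise_sd
    X[:, :n_informative] += centers[y]
    perm = rng.permutation(n_features)
    X = X[:, perm]
    labels = [f"feat_{j:02d}" for j in range(n_features)]
    informative = [labels[int(np.where(perm == j)[0][0])] for j in range(n_informative)]
    frame = pd.DataFrame(X, columns=labels)
    target = pd.Series([SUBTYPES[i] for i in y], name="label")
    return frame, target, sorted(informative)
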