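"""Artifact I/O: 8-bit grayscale PNGs, optional NIfTI stacks, JSON manifests.

One PNG per phase (``<case_id>_phase<i>.png``) and a 0/255 mask PNG per
case; alternatively a single NIfTI volume with phases stacked along the
third axis.  Annotations live in a JSON manifest (case_id, label,
roi = [row0, col0, row1, col1], 0-based half-open).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .segmentation import ROIBox

__all__ = [
    "write_case_images",
    "read_phase_stack",
    "write_mask",
    "read_mask",
    "read_image",
    "write_manifest",
    "read_manifest",
]


def _to_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(np.asarray(img, dtype=np.float64)), 0, 255).astype(np.uint8)


def read_image(path) -> np.ndarray:
    """Read one 2D grayscale image (PNG; DICOM via pydicom as a convenience)."""
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        import pydicom

        return np.asarray(pydicom.dcmread(path).pixel_array, dtype=np.float64)
    arr = np.asarray(iio.imread(path), dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr


def write_case_images(case, out_dir, fmt: str = "png") -> list[str]:
    """Write the phase stack of one case; returns the relative file names."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "png":
        names = []
        for i in range(case.phases.shape[0]):
            name = f"{case.case_id}_phase{i}.png"
            iio.imwrite(out_dir / name, _to_uint8(case.phases[i]))
            names.append(name)
        return names
    if fmt == "nifti":
        import nibabel as nib

        name = f"{case.case_id}.nii"
        vol = np.moveaxis(_to_uint8(case.phases), 0, -1)
        nib.save(nib.Nifti1Image(vol, np.eye(4)), out_dir / name)
        return [name]
    raise ValueError(f"unknown image format {fmt!r}")


def read_phase_stack(out_dir, case_id: str, fmt: str = "png") -> np.ndarray:
    out_dir = Path(out_dir)
    if fmt == "png":
        paths = sorted(out_dir.glob(f"{case_id}_phase*.png"))
        if not paths:
            raise FileNotFoundError(f"no phase images for {case_id} in {out_dir}")
        return np.stack([read_image(p) for p in paths])
    if fmt == "nifti":
        import nibabel as nib

        vol = np.asarray(nib.load(out_dir / f"{case_id}.nii").get_fdata())
        return np.moveaxis(vol, -1, 0)
    raise ValueError(f"unknown image format {fmt!r}")


def write_mask(mask: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.asarray(mask).astype(bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(path)) > 127


def write_manifest(manifest: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        manifest = json.load(fh)
    for entry in manifest.get("cases", []):
        ROIBox.from_list(entry["roi"])        # validate coordinates
    return manifest
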