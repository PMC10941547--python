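"""Volume and VOI-mask I/O, geometry validation, muscle normalization.

CT-like scalar volumes and binary volume-of-interest (VOI) masks live on a
common voxel grid.  Lesion masks follow the naming convention ``TL_<k>``
(target lesion) / ``NTL_<k>`` (non-target lesion); the reference region of
normal pectoralis-major muscle is named ``MUSCLE``.  Within-phase
normalization z-scores the whole volume against the muscle VOI so that
downstream intensity features are invariant to scanner/phase offsets.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .errors import DegenerateReferenceError, GeometryError, ValidationError

__all__ = [
    "CTVolume",
    "VOISet",
    "load_volume_and_masks",
    "save_volume",
    "save_mask",
    "muscle_normalize",
    "voi_volume_cc",
]

MUSCLE_NAME = "MUSCLE"


@dataclass
class CTVolume:
    """A 3D scalar intensity grid (HU-like) with physical voxel spacing."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class VOISet:
    """Named binary lesion masks plus the muscle reference mask."""

    lesion_masks: dict[str, np.ndarray]
    muscle_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lesion_masks = {k: np.asarray(m) > 0 for k, m in self.lesion_masks.items()}
        if self.muscle_mask is not None:
            self.muscle_mask = np.asarray(self.muscle_mask) > 0
        for name, m in self.lesion_masks.items():
            if not m.any():
                raise ValidationError(f"lesion mask {name!r} is empty")

    def validate_against(self, volume: CTVolume) -> None:
        for name, m in self.lesion_masks.items():
            if m.shape != volume.shape:
                raise GeometryError(
                    f"mask {name!r} shape {m.shape} != volume shape {volume.shape}"
                )
        if self.muscle_mask is not None and self.muscle_mask.shape != volume.shape:
            raise GeometryError(
                f"muscle mask shape {self.muscle_mask.shape} != volume shape {volume.shape}"
            )


def _affine(spacing: tuple[float, float, float], origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.spacing_mm, volume.origin))
    nib.save(img, str(path))


def save_mask(mask: np.ndarray, spacing_mm, path: str | os.PathLike, origin=(0.0, 0.0, 0.0)) -> None:
    img = nib.Nifti1Image((np.asarray(mask) > 0).astype(np.uint8), _affine(tuple(spacing_mm), origin))
    nib.save(img, str(path))


def _load_nifti(path: str | os.PathLike):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, spacing, origin


def load_volume_and_masks(
    volume_path: str | os.PathLike,
    mask_paths: Mapping[str, str | os.PathLike] | None = None,
    masks_dir: str | os.PathLike | None = None,
) -> tuple[CTVolume, VOISet]:
    """Load a volume and its VOI masks, validating a shared grid.

    Masks are passed either explicitly (``{"TL_1": path, "MUSCLE": path}``)
    or discovered from ``masks_dir`` where each ``<NAME>.nii[.gz]`` file
    contributes one mask.  Any nonzero stored label binarizes to 1.
    """
    data, spacing, origin = _load_nifti(volume_path)
    volume = CTVolume(data, spacing, origin)

    if mask_paths is None:
        if masks_dir is None:
            raise ValidationError("provide mask_paths or masks_dir")
        mask_paths = {}
        for p in sorted(Path(masks_dir).iterdir()):
            if p.name.endswith((".nii", ".nii.gz")):
                name = p.name[: -len(".nii.gz")] if p.name.endswith(".nii.gz") else p.stem
                # only files following the documented VOI naming convention
                if name.upper().startswith(("TL_", "NTL_")) or name.upper() == MUSCLE_NAME:
                    mask_paths[name] = p

    lesions: dict[str, np.ndarray] = {}
    muscle = None
    for name, path in mask_paths.items():
        mdata, mspacing, _ = _load_nifti(path)
        if mdata.shape != volume.shape:
            raise GeometryError(
                f"mask {name!r} grid {mdata.shape} does not match volume {volume.shape}"
            )
        if not np.allclose(mspacing, volume.spacing_mm, rtol=1e-4):
            raise GeometryError(
                f"mask {name!r} spacing {mspacing} does not match volume {volume.spacing_mm}"
            )
        binary = mdata > 0
        if name.upper() == MUSCLE_NAME:
            muscle = binary
        else:
            lesions[name] = binary

    voi = VOISet(lesion_masks=lesions, muscle_mask=muscle)
    voi.validate_against(volume)
    return volume, voi


def muscle_normalize(volume: CTVolume, voi: VOISet) -> CTVolume:
    """Z-score the whole volume against the muscle VOI.

    Output intensities are ``(x - mu_muscle) / sd_muscle`` (population SD),
    so muscle voxels of the result have mean 0 and SD 1.  Any positive
    affine rescaling of the input maps to the identical output.
    """
    if voi.muscle_mask is None or not voi.muscle_mask.any():
        raise ValidationError("muscle mask is empty; cannot normalize")
    ref = volume.data[voi.muscle_mask]
    mu = float(ref.mean())
    sd = float(ref.std())
    if sd == 0.0:
        raise DegenerateReferenceError("muscle region has zero intensity SD")
    return CTVolume((volume.data - mu) / sd, volume.spacing_mm, volume.origin)


def voi_volume_cc(mask: np.ndarray, spacing_mm) -> float:
    """Physical volume of a mask in cm^3 (voxel count x voxel volume)."""
    mask = np.asarray(mask) > 0
    n = int(mask.sum())
    if n == 0:
        raise ValidationError("mask is empty")
    voxel_mm3 = math.prod(float(s) for s in spacing_mm)
    return n * voxel_mm3 / 1000.0
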