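"""Lesion image containers and NIfTI round-trip helpers.

A :class:`LesionVolume` bundles a CT intensity array (Hounsfield units),
its voxel spacing in millimetres and a binary region-of-interest mask.
Axial slices are indexed along the last axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class LesionVolume:
    """CT intensities (HU) with voxel spacing (mm) and a lesion ROI mask."""

    image: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.image.ndim != 3:
            raise ValueError(f"image must be 3-D, got ndim={self.image.ndim}")
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )
        if self.spacing is None or len(self.spacing) != 3:
            raise ValueError("spacing must give one positive value per axis (mm)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.image.shape

    def largest_roi_slice(self) -> int:
        """Index of the axial slice with the largest ROI area."""
        if not self.mask.any():
            raise ValueError("mask is empty")
        areas = self.mask.sum(axis=(0, 1))
        return int(np.argmax(areas))

    def roi_values(self) -> np.ndarray:
        return self.image[self.mask]


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_nifti_pair(volume: LesionVolume, image_path: str | Path, mask_path: str | Path) -> None:
    aff = _affine(volume.spacing)
    nib.save(nib.Nifti1Image(volume.image.astype(np.float32), aff), str(image_path))
    nib.save(nib.Nifti1Image(volume.mask.astype(np.uint8), aff), str(mask_path))


def load_nifti_pair(image_path: str | Path, mask_path: str | Path) -> LesionVolume:
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LesionVolume(
        image=np.asarray(img.dataobj, dtype=np.float64),
        spacing=spacing,
        mask=np.asarray(msk.dataobj) > 0,
    )
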