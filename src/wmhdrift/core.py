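"""Shared image/mask data model, NIfTI I/O, mask algebra and volume accounting.

All volumes of one subject live on a single aligned voxel grid; no resampling
is performed anywhere in the package.  Volumes are handled in stored voxel
order and header affines are carried through untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

MODALITIES = ("FLAIR", "T2W", "T2SW")
TIMEPOINTS = ("baseline", "followup")

#: acquisition geometry: 0.94 x 0.94 mm in plane, 5 mm slices + 1.5 mm gap
DEFAULT_VOXEL_DIMS = (0.94, 0.94, 6.5)


@dataclass
class ImageVolume:
    """One modality at one time point: a 3-D non-negative intensity grid.

    Parameters
    ----------
    data
        3-D float array of intensities, finite and >= 0.
    voxel_dims
        (dx, dy, dz) voxel edge lengths in mm, strictly positive.
    modality
        One of ``FLAIR``, ``T2W``, ``T2SW``.
    timepoint
        ``baseline`` or ``followup``.
    affine
        Optional 4x4 NIfTI affine, carried through I/O untouched.
    """

    data: np.ndarray
    voxel_dims: tuple = DEFAULT_VOXEL_DIMS
    modality: str = "FLAIR"
    timepoint: str = "baseline"
    affine: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError(f"voxel_dims must be positive, got {self.voxel_dims}")

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_dims
        return dx * dy * dz

    def copy_with(self, data: np.ndarray) -> "ImageVolume":
        return ImageVolume(
            data=data,
            voxel_dims=self.voxel_dims,
            modality=self.modality,
            timepoint=self.timepoint,
            affine=self.affine,
        )


@dataclass
class BinaryMask:
    """A boolean region on the same grid as the images it annotates."""

    data: np.ndarray
    voxel_dims: tuple = DEFAULT_VOXEL_DIMS
    label: str = "ICV"
    affine: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data) > 0
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={self.data.ndim}")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError(f"voxel_dims must be positive, got {self.voxel_dims}")

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_dims
        return dx * dy * dz

    def copy_with(self, data: np.ndarray, label: Optional[str] = None) -> "BinaryMask":
        return BinaryMask(
            data=data,
            voxel_dims=self.voxel_dims,
            label=label if label is not None else self.label,
            affine=self.affine,
        )


@dataclass
class LongitudinalSubject:
    """Aligned baseline + follow-up multimodal volumes with ICV/stroke masks.

    ``images`` maps ``(modality, timepoint)`` to an :class:`ImageVolume`;
    masks are per time point.  ``ground_truth`` (phantoms only) carries the
    true tissue masks, bias fields and planned change volumes.
    """

    subject_id: str
    images: Mapping[tuple, ImageVolume]
    icv_mask: Mapping[str, BinaryMask]
    stroke_mask: Mapping[str, BinaryMask]
    ground_truth: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self):
        shapes = {v.shape for v in self.images.values()}
        shapes |= {m.shape for m in self.icv_mask.values()}
        shapes |= {m.shape for m in self.stroke_mask.values()}
        if len(shapes) > 1:
            raise ValueError(f"subject {self.subject_id}: inconsistent grid shapes {shapes}")

    def image(self, modality: str, timepoint: str) -> ImageVolume:
        return self.images[(modality, timepoint)]


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path, modality: str = "FLAIR", timepoint: str = "baseline") -> ImageVolume:
    """Read a NIfTI-1 volume (optionally gzipped) into an :class:`ImageVolume`.

    Intensities are cast to float64; negative values are clipped to zero with
    a logged warning.  Voxel dims come from the header zooms.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got shape {data.shape}")
    if np.any(data < 0):
        logger.warning("%s: %d negative voxels clipped to 0", path, int((data < 0).sum()))
        data = np.clip(data, 0, None)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(
        data=data, voxel_dims=zooms, modality=modality, timepoint=timepoint, affine=img.affine
    )


def read_mask(path, label: str = "ICV") -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(data=vol.data > 0.5, voxel_dims=vol.voxel_dims, label=label, affine=vol.affine)


def write_volume(vol, path) -> None:
    """Write an :class:`ImageVolume` (float32) or :class:`BinaryMask` (uint8 0/1)."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float32)
    affine = vol.affine
    if affine is None:
        affine = np.diag(list(vol.voxel_dims) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.voxel_dims)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Mask algebra


def _check_same_shape(a: BinaryMask, b: BinaryMask) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")


def jaccard(a: BinaryMask, b: BinaryMask) -> float:
    """Jaccard similarity |a ∩ b| / |a ∪ b|.

    Two empty masks are in perfect agreement about "nothing", so the index is
    defined as 1.0 there (logged); this keeps cohort tables free of NaNs for
    subjects with, e.g., no intense-WMH voxels.
    """
    _check_same_shape(a, b)
    union = int(np.logical_or(a.data, b.data).sum())
    if union == 0:
        logger.info("jaccard of two empty masks: defined as 1.0")
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return inter / union


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice coefficient 2|a ∩ b| / (|a| + |b|); 1.0 when both are empty."""
    _check_same_shape(a, b)
    total = a.n_voxels + b.n_voxels
    if total == 0:
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / total


def volume_ml(mask: BinaryMask) -> float:
    """Mask volume in millilitres: voxel count x voxel volume / 1000."""
    return mask.n_voxels * mask.voxel_volume_mm3 / 1000.0


def percent_icv(mask: BinaryMask, icv: BinaryMask) -> float:
    """Mask size as a percentage of the intracranial volume."""
    _check_same_shape(mask, icv)
    n_icv = icv.n_voxels
    if n_icv == 0:
        raise ValueError("empty ICV mask")
    return 100.0 * mask.n_voxels / n_icv
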