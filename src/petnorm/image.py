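"""Volumes, NIfTI I/O, SUV conversion and preprocessing.

The in-memory container is :class:`VoxelImage`: a 3D float64 grid plus
voxel size (mm), an intensity-unit tag and the voxel coordinates of the
grid corner in the frame of the original (uncropped) volume.  All spatial
analysis in this package is voxel-space: inputs are assumed coregistered
onto one grid, and the only alignment offered is an integer-voxel
center-of-mass translation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DimensionError, FormatError, ValidationError

#: Valid intensity-unit tags.
UNITS = ("kBq_cc", "SUV", "normalized", "ratio", "statistic")

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma.
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _as_triple(value) -> tuple[float, float, float]:
    if np.isscalar(value):
        value = (value, value, value)
    t = tuple(float(v) for v in value)
    if len(t) != 3:
        raise ValidationError(f"expected a scalar or length-3 sequence, got {value!r}")
    return t


@dataclasses.dataclass
class VoxelImage:
    """A 3D scalar volume with voxel-size metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values; stored as float64.  NaN is allowed only for images
        tagged ``ratio`` or ``statistic``, where it marks out-of-mask voxels.
    voxel_size_mm : float or (float, float, float)
        Edge length of a voxel along each axis, in millimetres.
    unit : str
        One of ``kBq_cc``, ``SUV``, ``normalized``, ``ratio``, ``statistic``.
    origin : (int, int, int)
        Voxel coordinates of this grid's corner in the original frame;
        updated by cropping.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    unit: str = "SUV"
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionError(f"expected 3D data, got {self.data.ndim}D")
        self.voxel_size_mm = _as_triple(self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValidationError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        self.origin = tuple(int(v) for v in self.origin)
        if self.unit not in ("ratio", "statistic") and not np.all(np.isfinite(self.data)):
            raise ValidationError("image data contains NaN or Inf")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, unit: str | None = None) -> "VoxelImage":
        """New image on the same grid with replaced values (and optionally unit)."""
        return VoxelImage(data, self.voxel_size_mm, unit or self.unit, self.origin)

    def copy(self) -> "VoxelImage":
        return self.with_data(self.data.copy())


@dataclasses.dataclass(frozen=True)
class AcquisitionInfo:
    """Injection data needed for SUV conversion.

    ``injected_dose_kBq`` is the decay-corrected injected activity D (kBq)
    and ``weight_g`` the subject weight W (g).
    """

    injected_dose_kBq: float
    weight_g: float

    def __post_init__(self):
        if self.injected_dose_kBq <= 0 or self.weight_g <= 0:
            raise ValidationError(
                f"dose and weight must be positive, got D={self.injected_dose_kBq}, "
                f"W={self.weight_g}"
            )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, unit: str = "SUV") -> VoxelImage:
    """Read a 3D NIfTI-1 volume.

    Voxel size is taken from the header zooms.  Raises
    :class:`~petnorm.errors.FormatError` for files that are not 3D scalar
    NIfTI volumes.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"{path} is not a readable NIfTI file: {exc}") from exc
    if len(img.shape) != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {img.shape}")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if not np.all(np.isfinite(data)) and unit not in ("ratio", "statistic"):
        raise FormatError(f"{path}: volume contains non-finite values")
    zooms = img.header.get_zooms()[:3]
    return VoxelImage(data, tuple(float(z) for z in zooms), unit=unit)


def write_volume(img: VoxelImage, path: str | Path) -> None:
    """Write as NIfTI-1, float32, with a diagonal affine from the voxel size."""
    affine = np.diag(list(img.voxel_size_mm) + [1.0])
    affine[:3, 3] = np.asarray(img.origin) * np.asarray(img.voxel_size_mm)
    out = nib.Nifti1Image(img.data.astype(np.float32), affine)
    out.header.set_zooms(img.voxel_size_mm)
    nib.save(out, str(path))


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def to_suv(img: VoxelImage, acq: AcquisitionInfo) -> VoxelImage:
    """Convert activity concentration (kBq/cc) to standard uptake values.

    SUV = C / (D / W) = C * W / D, with C the voxel concentration, D the
    decay-corrected injected dose (kBq) and W the subject weight (g).
    """
    if img.unit != "kBq_cc":
        raise ValidationError(f"to_suv expects unit 'kBq_cc', got {img.unit!r}")
    factor = acq.weight_g / acq.injected_dose_kBq
    return img.with_data(img.data * factor, unit="SUV")


def crop_to_brain(
    img: VoxelImage,
    target_shape: Sequence[int],
    center: Sequence[int] | None = None,
) -> VoxelImage:
    """Extract a ``target_shape`` window centered at ``center`` (voxel coords).

    No implicit padding: a window that does not fit inside the volume is a
    :class:`~petnorm.errors.DimensionError`.  Default center is the grid
    center.
    """
    target = tuple(int(t) for t in target_shape)
    if len(target) != 3 or any(t <= 0 for t in target):
        raise DimensionError(f"invalid target shape {target_shape}")
    if center is None:
        center = tuple(s // 2 for s in img.shape)
    center = tuple(int(c) for c in center)
    starts = tuple(c - t // 2 for c, t in zip(center, target))
    for ax, (s, t, n) in enumerate(zip(starts, target, img.shape)):
        if s < 0 or s + t > n:
            raise DimensionError(
                f"crop window axis {ax}: [{s}, {s + t}) exceeds volume extent {n}"
            )
    sl = tuple(slice(s, s + t) for s, t in zip(starts, target))
    origin = tuple(o + s for o, s in zip(img.origin, starts))
    return VoxelImage(img.data[sl].copy(), img.voxel_size_mm, img.unit, origin)


def gaussian_smooth(img: VoxelImage, fwhm_mm: float) -> VoxelImage:
    """3D Gaussian smoothing with the kernel width given as FWHM in mm.

    sigma per axis (in voxels) is ``fwhm_mm / (2*sqrt(2 ln 2)) / voxel_size``.
    Reflective boundary handling; ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValidationError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return img.copy()
    sigma = [fwhm_mm / FWHM_PER_SIGMA / v for v in img.voxel_size_mm]
    return img.with_data(ndimage.gaussian_filter(img.data, sigma=sigma, mode="reflect"))


def align_center_of_mass(
    img: VoxelImage, reference: VoxelImage
) -> tuple[VoxelImage, tuple[int, int, int]]:
    """Integer-voxel translation matching intensity centers of mass.

    The center of mass is computed over voxels above 25% of each volume's
    maximum, so the low-uptake background (which does not move with the
    brain) cannot bias the shift.  Returns the shifted image (vacated
    voxels zero-filled) and the applied shift in voxels.  Raises
    :class:`~petnorm.errors.ValidationError` if either volume is all-zero.
    """
    if img.shape != reference.shape:
        raise DimensionError(f"shape mismatch: {img.shape} vs {reference.shape}")
    if not np.any(img.data > 0) or not np.any(reference.data > 0):
        raise ValidationError("center-of-mass alignment requires positive volumes")

    def _com(data: np.ndarray) -> np.ndarray:
        fg = np.where(data > 0.25 * data.max(), data, 0.0)
        return np.array(ndimage.center_of_mass(fg))

    com_img = _com(img.data)
    com_ref = _com(reference.data)
    shift = tuple(int(np.round(d)) for d in com_ref - com_img)
    shifted = np.zeros_like(img.data)
    src = tuple(
        slice(max(0, -s), min(n, n - s)) for s, n in zip(shift, img.shape)
    )
    dst = tuple(
        slice(max(0, s), min(n, n + s)) for s, n in zip(shift, img.shape)
    )
    shifted[dst] = img.data[src]
    return img.with_data(shifted), shift
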