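"""Volumes, masks and VOI extraction.

A :class:`Volume3D` is one MR sequence (T2, DWI or ADC) for one patient; a
:class:`VoiMask` is the aligned binary tumor mask. Interchange format is
NIfTI via nibabel. The mask and volume must share a shape exactly — no
resampling is performed, because VOIs are drawn per sequence and
cross-sequence registration is out of scope. By convention the axial
(slice) axis is the third array axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import (
    EmptyMaskError,
    RadiomicsError,
    ShapeMismatchError,
    VolumeDimensionError,
)

SEQUENCE_TAGS = ("T2", "DWI", "ADC")

#: axial slices are indexed along this array axis
AXIAL_AXIS = 2


@dataclass
class Volume3D:
    """A 3D intensity grid for one MR sequence.

    Parameters
    ----------
    grid : ndarray
        3D array of intensities in arbitrary MR units.
    spacing : tuple of float
        Voxel size in mm per axis.
    sequence_tag : str
        One of ``T2``, ``DWI``, ``ADC``.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 4.0)
    sequence_tag: str = "T2"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3:
            raise VolumeDimensionError(
                f"expected a 3D volume, got {self.grid.ndim} axes "
                f"(shape {self.grid.shape})"
            )
        if not np.all(np.isfinite(self.grid)):
            raise RadiomicsError("volume contains non-finite intensities")
        if any(s <= 0 for s in self.spacing):
            raise RadiomicsError(f"voxel spacing must be positive, got {self.spacing}")


@dataclass
class VoiMask:
    """Binary tumor mask aligned with a companion :class:`Volume3D`."""

    grid: np.ndarray
    axial_axis: int = AXIAL_AXIS

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise VolumeDimensionError(
                f"expected a 3D mask, got {grid.ndim} axes (shape {grid.shape})"
            )
        self.grid = grid > 0
        if not self.grid.any():
            raise EmptyMaskError("mask contains no voxels")

    @property
    def axial_slices(self) -> list[int]:
        """Indices of axial slices containing at least one mask voxel."""
        axes = tuple(i for i in range(3) if i != self.axial_axis)
        return [int(k) for k in np.flatnonzero(self.grid.any(axis=axes))]

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


@dataclass
class Voi:
    """In-mask intensities plus a masked bounding-box subvolume.

    ``values`` lists the in-mask intensities in C raster order; ``subgrid``
    and ``submask`` are the bounding-box crop used for matrix construction
    (out-of-mask voxels are carried as absent via ``submask``).
    """

    values: np.ndarray
    subgrid: np.ndarray
    submask: np.ndarray
    bbox: tuple[slice, slice, slice] = field(repr=False, default=None)


def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def read_volume(path, sequence_tag: str = "T2") -> Volume3D:
    """Load a NIfTI volume.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    VolumeDimensionError
        If the image is not 3D (e.g. a 4D multi-b-value stack).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeDimensionError(
            f"{path} has {data.ndim} axes (shape {data.shape}); expected 3 — "
            f"axis 3 and beyond are not supported"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(grid=data.astype(np.float64), spacing=spacing, sequence_tag=sequence_tag)


def read_mask(path) -> VoiMask:
    """Load a NIfTI mask, binarizing any value > 0 to 1."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeDimensionError(
            f"{path} has {data.ndim} axes (shape {data.shape}); expected 3"
        )
    return VoiMask(grid=data > 0)


def write_volume(volume: Volume3D, path) -> None:
    img = nib.Nifti1Image(volume.grid.astype(np.float64), _affine(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_mask(mask: VoiMask, path, spacing=(1.0, 1.0, 4.0)) -> None:
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), _affine(spacing))
    nib.save(img, str(path))


def extract_voi(volume: Volume3D, mask: VoiMask) -> Voi:
    """Select the in-mask intensities and the masked bounding-box subvolume.

    The voxel count is preserved: ``values`` has exactly ``mask.n_voxels``
    entries, in C raster order over the full grid.
    """
    if volume.grid.shape != mask.grid.shape:
        raise ShapeMismatchError(
            f"volume shape {volume.grid.shape} != mask shape {mask.grid.shape}"
        )
    m = mask.grid
    if not m.any():
        raise EmptyMaskError("empty volume/mask intersection")
    idx = np.nonzero(m)
    bbox = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
    return Voi(
        values=volume.grid[m],
        subgrid=volume.grid[bbox].copy(),
        submask=m[bbox].copy(),
        bbox=bbox,
    )


def estimate_intensity_range(
    volumes: list[Volume3D],
    masks: list[VoiMask],
    n_samples: int = 2,
) -> tuple[float, float]:
    """Min/max signal intensity over representative tumor slices.

    For each lesion the ``n_samples`` axial slices with the largest in-mask
    area are sampled (all slices if fewer exist); the per-slice in-mask
    extrema are then combined across lesions. This emulates measuring
    representative slices manually, and is only a fallback: the default
    pipeline uses the fixed published per-sequence ranges instead.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2 (at least two measurements per tumor)")
    if not volumes:
        raise ValueError("no volumes supplied")
    if len(volumes) != len(masks):
        raise ShapeMismatchError("volumes and masks lists differ in length")
    lo, hi = np.inf, -np.inf
    for vol, msk in zip(volumes, masks):
        if vol.grid.shape != msk.grid.shape:
            raise ShapeMismatchError(
                f"volume shape {vol.grid.shape} != mask shape {msk.grid.shape}"
            )
        axis = msk.axial_axis
        areas = {
            k: int(np.take(msk.grid, k, axis=axis).sum()) for k in msk.axial_slices
        }
        top = sorted(areas, key=lambda k: (-areas[k], k))[:n_samples]
        for k in top:
            sl_vol = np.take(vol.grid, k, axis=axis)
            sl_msk = np.take(msk.grid, k, axis=axis)
            vals = sl_vol[sl_msk]
            lo = min(lo, float(vals.min()))
            hi = max(hi, float(vals.max()))
    return lo, hi
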