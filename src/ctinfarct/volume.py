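"""Volume data model and NIfTI-1 / DICOM I/O.

The pipeline's canonical container is :class:`CTVolume`: a 3-D scalar grid
with a voxel size, a space tag (``native`` or ``template``) and a unit tag
(``HU``, ``transformed`` or ``tscore``).  Axis order is (sagittal, coronal,
axial); "slice" everywhere in this package means an axial plane, indexed by
the last axis, matching the 181x217x181 template convention.  All voxel
coordinates are 0-based with half-open ranges.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np

#: Default template grid (1-mm isotropic MNI-like bounding box).
TEMPLATE_SHAPE: tuple[int, int, int] = (181, 217, 181)

Space = Literal["native", "template"]
Unit = Literal["HU", "transformed", "tscore"]
MaskRole = Literal["parenchyma", "ventricle", "skull", "lesion", "atlas"]


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted as a CT volume."""


@dataclass
class CTVolume:
    """A 3-D scalar grid with voxel size, space and unit metadata.

    Parameters
    ----------
    data:
        3-D array, axis order (sagittal, coronal, axial).
    voxel_size_mm:
        Positive edge lengths of a voxel in millimetres.
    space:
        ``"template"`` for volumes on the common analysis grid, else
        ``"native"``.
    unit:
        ``"HU"`` for raw Hounsfield units, ``"transformed"`` after the
        piecewise intensity transformation, ``"tscore"`` for statistic maps.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    space: Space = "template"
    unit: Unit = "HU"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.data.shape}")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be three positive reals, got {vs}")
        self.voxel_size_mm = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        """Number of axial slices (last axis)."""
        return self.data.shape[2]

    def axial_slice(self, k: int) -> np.ndarray:
        """Return axial plane ``k`` as a 2-D (row, col) array."""
        return self.data[:, :, k]

    def with_data(self, data: np.ndarray, unit: Unit | None = None) -> "CTVolume":
        """Copy of this volume with new voxel data (and optionally a new unit)."""
        return replace(self, data=data, unit=unit if unit is not None else self.unit)


@dataclass
class BinaryMask:
    """A boolean grid tagging a set of voxels with a role."""

    data: np.ndarray
    role: MaskRole = "parenchyma"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.data.sum())


def _unit_from_range(data: np.ndarray) -> Unit:
    # Heuristic for files written outside this package: HU live in
    # [-1024, 3071]; transformed intensities in [0, 4000].
    if data.size and data.min() < -0.5:
        return "HU"
    return "transformed"


def read_volume(path: str | os.PathLike, unit: Unit | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI-1 file or a DICOM series directory.

    NIfTI voxel sizes are taken from the header.  A directory is treated as a
    single DICOM series: slices are sorted by position along the slice normal
    and the rescale slope/intercept is applied so the result is in HU.
    """
    p = Path(path)
    if p.is_dir():
        return _read_dicom_series(p)
    try:
        img = nib.load(str(p))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {p} as NIfTI-1: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{p}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    vol_unit = unit if unit is not None else _unit_from_range(data)
    space: Space = "template" if data.shape == TEMPLATE_SHAPE else "native"
    return CTVolume(data=data, voxel_size_mm=tuple(float(z) for z in zooms),
                    space=space, unit=vol_unit)


def _read_dicom_series(directory: Path) -> CTVolume:
    import pydicom

    files = sorted(f for f in directory.iterdir() if f.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # skip non-DICOM files (DICOMDIR etc.)
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no DICOM image files found in {directory}")

    orientations = {tuple(np.round(np.asarray(getattr(ds, "ImageOrientationPatient",
                                                      [1, 0, 0, 0, 1, 0]), float), 4))
                    for ds in slices}
    if len(orientations) > 1:
        raise FormatError(f"inconsistent DICOM series in {directory}: mixed orientations")

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=sort_key)
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(slope * arr + intercept)
    data = np.stack(planes, axis=-1)  # rows x cols x slices -> axial last

    ds0 = slices[0]
    pixel_spacing = getattr(ds0, "PixelSpacing", [1.0, 1.0])
    if len(slices) > 1:
        z0, z1 = sort_key(slices[0]), sort_key(slices[1])
        dz = abs(z1 - z0) or float(getattr(ds0, "SliceThickness", 1.0))
    else:
        dz = float(getattr(ds0, "SliceThickness", 1.0))
    return CTVolume(data=data,
                    voxel_size_mm=(float(pixel_spacing[0]), float(pixel_spacing[1]), dz),
                    space="native", unit="HU")


def write_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1, with header voxel sizes matching ``vol``."""
    affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data), affine)
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path: str | os.PathLike,
               voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    """Write a binary mask as a 0/1 uint8 NIfTI-1 volume."""
    affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(voxel_size_mm)
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike, role: MaskRole = "lesion") -> BinaryMask:
    """Read a NIfTI-1 volume and threshold it at 0.5 into a boolean mask."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return BinaryMask(data=data > 0.5, role=role)
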