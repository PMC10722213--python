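"""Volume and label-mask containers plus NIfTI / MetaImage readers and writers.

Conventions
-----------
Arrays are indexed ``(x, y, z)`` with ``z`` the slice axis; all per-slice 2D
operations elsewhere in the package iterate over ``z``.  Spacing is carried in
millimetres per axis and used for every physical-distance computation; voxel
counted operations (structuring elements, box-counting windows) work in voxel
units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import FormatError, IOFailure, ValidationError

#: Canonical label table. Foreign masks may override via a JSON sidecar.
DEFAULT_LABEL_MAP = {
    "background": 0,
    "la": 1,
    "pv": 2,
    "mv": 3,
    "laa": 4,
    "fibrosis": 5,
}

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mha", ".mhd")


def _check_grid(data: np.ndarray, spacing, origin) -> tuple[tuple, tuple]:
    if data.ndim != 3 or min(data.shape) < 1:
        raise ValidationError(f"expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be three positive values, got {spacing}")
    if len(origin) != 3:
        raise ValidationError(f"origin must have three components, got {origin}")
    return spacing, origin


@dataclass
class Volume:
    """A 3D scalar image with grid metadata.

    Attributes
    ----------
    data : float ndarray, shape (nx, ny, nz)
    spacing : per-axis voxel size in mm
    origin : physical coordinate of voxel (0, 0, 0)
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing, self.origin = _check_grid(self.data, self.spacing, self.origin)
        if not np.isfinite(self.data).all():
            raise ValidationError("volume contains NaN or Inf values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMask:
    """A 3D integer label image sharing the grid of a companion :class:`Volume`."""

    data: np.ndarray
    label_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        data = np.asarray(self.data)
        if not np.issubdtype(data.dtype, np.integer):
            if not np.all(data == np.round(data)):
                raise ValidationError("label mask must hold integer values")
            data = data.astype(np.int32)
        self.data = data.astype(np.int32, copy=False)
        self.spacing, self.origin = _check_grid(self.data, self.spacing, self.origin)
        known = set(self.label_map.values())
        present = set(np.unique(self.data).tolist())
        unknown = present - known - {0}
        if unknown:
            raise ValidationError(f"mask contains labels not in label_map: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def region(self, *names: str) -> np.ndarray:
        """Boolean mask of the union of the named labels."""
        values = [self.label_map[n] for n in names]
        return np.isin(self.data, values)

    def same_grid_as(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        return "nifti"
    if name.endswith(_META_SUFFIXES):
        return "meta"
    raise FormatError(f"unsupported image format: {path.name} "
                      f"(expected .nii, .nii.gz, .mha or .mhd)")


def _read_raw(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    fmt = _detect_format(path)
    if fmt == "nifti":
        try:
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj)
        except Exception as exc:  # nibabel raises a zoo of classes
            raise FormatError(f"could not read {path} as NIfTI: {exc}") from exc
        if data.ndim != 3:
            raise ValidationError(f"{path}: expected 3D data, got {data.ndim}D")
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return data, tuple(float(z) for z in zooms), origin
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:
        raise FormatError(f"could not read {path} as MetaImage: {exc}") from exc
    # SimpleITK arrays come back (z, y, x); transpose to (x, y, z).
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return data, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def read_volume(path) -> Volume:
    """Read a 3D scalar volume from NIfTI or MetaImage.

    Intensities are promoted to float64.  Volumes containing NaN/Inf are
    rejected with :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise IOFailure(f"no such file: {path}")
    data, spacing, origin = _read_raw(path)
    return Volume(data=np.asarray(data, dtype=np.float64), spacing=spacing, origin=origin)


def write_volume(volume: Volume, path) -> None:
    """Write a :class:`Volume` as NIfTI or MetaImage (chosen by extension)."""
    path = Path(path)
    fmt = _detect_format(path)
    try:
        if fmt == "nifti":
            affine = np.diag(list(volume.spacing) + [1.0])
            affine[:3, 3] = volume.origin
            nib.save(nib.Nifti1Image(volume.data.astype(np.float64), affine), str(path))
        else:
            img = sitk.GetImageFromArray(volume.data.transpose(2, 1, 0))
            img.SetSpacing(volume.spacing)
            img.SetOrigin(volume.origin)
            sitk.WriteImage(img, str(path))
    except OSError as exc:
        raise IOFailure(f"could not write {path}: {exc}") from exc


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in _NIFTI_SUFFIXES + _META_SUFFIXES:
        if name.lower().endswith(suf):
            return path.with_name(name[: -len(suf)] + ".labels.json")
    return path.with_suffix(".labels.json")


def write_mask(mask: LabelMask, path) -> None:
    """Write a :class:`LabelMask` with its label table as a JSON sidecar.

    Integer data round-trips bit-exactly through :func:`read_mask`.
    """
    path = Path(path)
    fmt = _detect_format(path)
    try:
        if fmt == "nifti":
            affine = np.diag(list(mask.spacing) + [1.0])
            affine[:3, 3] = mask.origin
            nib.save(nib.Nifti1Image(mask.data.astype(np.int32), affine), str(path))
        else:
            img = sitk.GetImageFromArray(mask.data.astype(np.int32).transpose(2, 1, 0))
            img.SetSpacing(mask.spacing)
            img.SetOrigin(mask.origin)
            sitk.WriteImage(img, str(path))
        _sidecar_path(path).write_text(json.dumps(mask.label_map, indent=2, sort_keys=True))
    except OSError as exc:
        raise IOFailure(f"could not write {path}: {exc}") from exc


def read_mask(path, label_map: dict[str, int] | None = None) -> LabelMask:
    """Read a :class:`LabelMask`; the label table comes from ``label_map``,
    a ``.labels.json`` sidecar, or the package default, in that order."""
    path = Path(path)
    if not path.exists():
        raise IOFailure(f"no such file: {path}")
    data, spacing, origin = _read_raw(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.floating):
        if not np.isfinite(data).all() or not np.all(data == np.round(data)):
            raise ValidationError(f"{path}: mask data is not integer-valued")
        data = data.astype(np.int32)
    if label_map is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            label_map = {str(k): int(v) for k, v in json.loads(sidecar.read_text()).items()}
        else:
            label_map = dict(DEFAULT_LABEL_MAP)
    return LabelMask(data=data, label_map=label_map, spacing=spacing, origin=origin)
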