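"""Volume/mask containers and file I/O with voxel-size metadata.

Spatial conventions used throughout the package:

* arrays are 3D with axis order ``(z, y, x)``, 0-based, ``z`` the scan axis;
* voxels are isotropic — anisotropic input is rejected at load time because
  every diameter threshold downstream is defined in voxel units;
* physical thresholds are stored in mm and converted exactly once through
  :func:`mm_to_voxels`.

Supported formats: MetaImage (``.mha``/``.mhd``), NIfTI (``.nii``/``.nii.gz``)
via SimpleITK, and multi-page TIFF stacks with a JSON sidecar
``{"voxel_size_mm": x}`` (or an explicit ``voxel_size_mm`` argument).
Masks are written as unsigned 8-bit 0/1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "ScanLayout",
    "MaskRole",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "mm_to_voxels",
]

#: Roles a binary mask can play in the pipeline.
MASK_ROLES = ("bone", "outer_contour", "cortical_mask", "roi", "void", "interruption")

MaskRole = str

_ISO_RTOL = 1e-3


@dataclass
class ImageVolume:
    """A 3D scalar image with isotropic voxel size.

    Parameters
    ----------
    data:
        3D array, axis order ``(z, y, x)``.
    voxel_size_mm:
        Isotropic voxel edge length in millimetres (> 0).
    """

    data: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have length >= 1")
        if not (self.voxel_size_mm > 0):
            raise ValueError(f"voxel_size_mm must be > 0, got {self.voxel_size_mm}")
        self.voxel_size_mm = float(self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3


@dataclass
class BinaryMask:
    """A boolean 3D mask aligned to a parent :class:`ImageVolume`."""

    data: np.ndarray
    voxel_size_mm: float
    role: MaskRole = "bone"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.data.ndim}")
        if self.data.dtype != bool:
            if not np.isin(np.unique(self.data), (0, 1)).all():
                raise ValueError("mask data must be boolean or 0/1")
            self.data = self.data.astype(bool)
        if not (self.voxel_size_mm > 0):
            raise ValueError(f"voxel_size_mm must be > 0, got {self.voxel_size_mm}")
        self.voxel_size_mm = float(self.voxel_size_mm)
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}; expected one of {MASK_ROLES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3

    def with_role(self, role: MaskRole) -> "BinaryMask":
        return BinaryMask(self.data, self.voxel_size_mm, role)


@dataclass
class ScanLayout:
    """Axial stack layout of an acquisition.

    The default matches the clinical metacarpophalangeal protocol: 3 stacks of
    110 slices at 82 μm, i.e. 330 slices / 27.06 mm total scan length.
    """

    n_stacks: int = 3
    slices_per_stack: int = 110
    voxel_size_mm: float = 0.082

    def __post_init__(self) -> None:
        if self.n_stacks < 1 or self.slices_per_stack < 1:
            raise ValueError("n_stacks and slices_per_stack must be >= 1")
        if not (self.voxel_size_mm > 0):
            raise ValueError("voxel_size_mm must be > 0")

    @property
    def total_slices(self) -> int:
        return self.n_stacks * self.slices_per_stack

    @property
    def stack_length_mm(self) -> float:
        return self.slices_per_stack * self.voxel_size_mm

    @property
    def total_length_mm(self) -> float:
        return self.total_slices * self.voxel_size_mm

    def validate_volume(self, vol: ImageVolume) -> None:
        """Check the layout tiles the volume's z-extent exactly."""
        if vol.shape[0] != self.total_slices:
            raise ValueError(
                f"layout covers {self.total_slices} slices but volume has "
                f"{vol.shape[0]} along z"
            )

    def stack_slices(self) -> list[slice]:
        """Contiguous z-blocks, one per stack, distal to proximal."""
        s = self.slices_per_stack
        return [slice(i * s, (i + 1) * s) for i in range(self.n_stacks)]


def mm_to_voxels(length_mm: float, voxel_size_mm: float) -> int:
    """Convert a physical length to a voxel count (nearest integer).

    This is the single conversion point used by every diameter/depth threshold
    in the package, e.g. 0.328 mm at 82 μm → 4 voxels, 3.936 mm → 48 voxels.
    """
    if not (length_mm > 0) or not (voxel_size_mm > 0):
        raise ValueError("length_mm and voxel_size_mm must both be > 0")
    return int(round(length_mm / voxel_size_mm))


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".mha", ".mhd")):
        return "mha"
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff_stack"
    raise ValueError(f"cannot infer format from file name {path.name!r}")


def _check_isotropic(spacing: tuple[float, float, float], path: Path) -> float:
    sx, sy, sz = spacing
    ref = float(spacing[0])
    if not np.allclose(spacing, ref, rtol=_ISO_RTOL):
        raise ValueError(
            f"{path}: anisotropic voxel spacing {(sx, sy, sz)}; only isotropic "
            "volumes are supported"
        )
    return ref


def read_volume(
    path: str | Path,
    format: str | None = None,
    voxel_size_mm: float | None = None,
) -> ImageVolume:
    """Read a 3D volume with voxel-size metadata.

    Parameters
    ----------
    path:
        Input file. Format inferred from the extension unless ``format`` given.
    format:
        One of ``{"mha", "nifti", "tiff_stack"}``.
    voxel_size_mm:
        Required for TIFF stacks without a ``<stem>.json`` sidecar; ignored for
        self-describing formats.

    Raises
    ------
    ValueError
        If the spacing is missing/ambiguous ("voxel size unknown") or
        anisotropic (the offending spacings are named).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)

    if fmt in ("mha", "nifti"):
        img = sitk.ReadImage(str(path))
        spacing = img.GetSpacing()  # (x, y, z)
        size = _check_isotropic(spacing, path)
        data = sitk.GetArrayFromImage(img)  # (z, y, x)
        if data.ndim == 4 and data.shape[0] == 1:
            data = data[0]
        return ImageVolume(data, size)

    if fmt == "tiff_stack":
        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
        sidecar = path.with_suffix(".json")
        if voxel_size_mm is None:
            if sidecar.exists():
                meta = json.loads(sidecar.read_text())
                voxel_size_mm = meta.get("voxel_size_mm")
            if voxel_size_mm is None:
                raise ValueError(
                    f"{path}: voxel size unknown — supply voxel_size_mm or a "
                    f"JSON sidecar {sidecar.name}"
                )
        return ImageVolume(data, float(voxel_size_mm))

    raise ValueError(f"unknown format {fmt!r}")


def write_volume(vol: ImageVolume, path: str | Path, format: str | None = None) -> Path:
    """Write a volume losslessly with its spacing metadata."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("mha", "nifti"):
        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data))
        img.SetSpacing((vol.voxel_size_mm,) * 3)
        sitk.WriteImage(img, str(path))
    elif fmt == "tiff_stack":
        tifffile.imwrite(str(path), np.ascontiguousarray(vol.data))
        path.with_suffix(".json").write_text(
            json.dumps({"voxel_size_mm": vol.voxel_size_mm})
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def write_mask(mask: BinaryMask, path: str | Path, format: str | None = None) -> Path:
    """Write a mask as unsigned 8-bit 0/1 with spacing metadata."""
    vol = ImageVolume(mask.data.astype(np.uint8), mask.voxel_size_mm)
    return write_volume(vol, path, format)


def read_mask(
    path: str | Path,
    role: MaskRole = "bone",
    format: str | None = None,
    voxel_size_mm: float | None = None,
) -> BinaryMask:
    """Read a 0/1 volume back as a :class:`BinaryMask` with the given role."""
    vol = read_volume(path, format=format, voxel_size_mm=voxel_size_mm)
    return BinaryMask(vol.data > 0, vol.voxel_size_mm, role)
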