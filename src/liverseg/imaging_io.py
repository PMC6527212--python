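"""NIfTI volume I/O, geometry handling, and intensity preprocessing.

Volumes are held as plain 3D numpy grids plus a :class:`VolumeGeometry`
describing voxel spacing (mm), world origin and anatomical axis labels.
Preprocessing follows the standard contrast-enhanced abdominal MR recipe:
resampling to isotropic voxel size (default 2 mm) and linear mapping of the
2nd--98th intensity percentiles to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class FormatError(ValueError):
    """Raised for files that are readable but not usable 3D volumes."""


class DegenerateImageError(ValueError):
    """Raised when an image has no intensity spread to normalize."""


@dataclass(frozen=True)
class VolumeGeometry:
    """Voxel-to-world geometry of a 3D grid.

    Parameters
    ----------
    spacing_mm : tuple of 3 floats
        Voxel edge length along each array axis, in mm; all > 0.
    origin_mm : tuple of 3 floats
        World coordinate of the center of voxel (0, 0, 0).
    axcodes : tuple of 3 str
        Anatomical direction of increasing index per array axis, one of
        R/L, A/P, S/I (nibabel convention, e.g. ``('R', 'A', 'S')``).
    """

    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axcodes: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self):
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 positive values, got {self.spacing_mm}")
        groups = [frozenset("RL"), frozenset("AP"), frozenset("SI")]
        seen = [g for c in self.axcodes for g in groups if c in g]
        if len(self.axcodes) != 3 or len(set(seen)) != 3:
            raise ValueError(f"axcodes must be a signed permutation of R/L, A/P, S/I: {self.axcodes}")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (1 ml = 1000 mm^3)."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (RAS mm) affine."""
        signs = {"R": (0, 1), "L": (0, -1), "A": (1, 1), "P": (1, -1),
                 "S": (2, 1), "I": (2, -1)}
        aff = np.zeros((4, 4))
        aff[3, 3] = 1.0
        for axis, code in enumerate(self.axcodes):
            world_axis, sign = signs[code]
            aff[world_axis, axis] = sign * self.spacing_mm[axis]
        aff[:3, 3] = _origin_to_world(self.origin_mm, self.axcodes)
        return aff


def _origin_to_world(origin, axcodes):
    signs = {"R": (0, 1), "L": (0, -1), "A": (1, 1), "P": (1, -1), "S": (2, 1), "I": (2, -1)}
    world = np.zeros(3)
    for axis, code in enumerate(axcodes):
        world_axis, sign = signs[code]
        world[world_axis] = sign * origin[axis]
    return world


@dataclass
class ImageVolume:
    """3D scalar intensity grid with geometry."""

    voxels: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise FormatError(f"expected a 3D grid, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("image contains non-finite intensities")


@dataclass
class MaskVolume:
    """3D binary grid with geometry; foreground = liver."""

    voxels: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self):
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise FormatError(f"expected a 3D grid, got shape {arr.shape}")
        self.voxels = (arr != 0).astype(np.uint8)

    @property
    def volume_ml(self) -> float:
        return float(self.voxels.sum()) * self.geometry.voxel_volume_ml


def _geometry_from_img(img: nib.Nifti1Image) -> VolumeGeometry:
    aff = img.affine
    axcodes = nib.aff2axcodes(aff)
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    origin_world = aff[:3, 3]
    signs = {"R": (0, 1), "L": (0, -1), "A": (1, 1), "P": (1, -1), "S": (2, 1), "I": (2, -1)}
    origin = [0.0, 0.0, 0.0]
    for axis, code in enumerate(axcodes):
        world_axis, sign = signs[code]
        origin[axis] = sign * origin_world[world_axis]
    return VolumeGeometry(spacing_mm=spacing, origin_mm=tuple(origin), axcodes=tuple(axcodes))


def read_volume(path: str | Path, as_mask: bool = False) -> ImageVolume | MaskVolume:
    """Read a NIfTI file into an :class:`ImageVolume` or :class:`MaskVolume`.

    A trailing 4th dimension of size 1 is squeezed. Masks are binarized as
    ``value != 0``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of types
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D data, got shape {data.shape}")
    geom = _geometry_from_img(img)
    if as_mask:
        return MaskVolume(data, geom)
    return ImageVolume(np.asarray(data, dtype=np.float32), geom)


def write_volume(vol: ImageVolume | MaskVolume, path: str | Path) -> None:
    """Write a volume as NIfTI, preserving spacing, origin and orientation."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = vol.voxels
    if isinstance(vol, MaskVolume):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, vol.geometry.affine())
    img.header.set_zooms(vol.geometry.spacing_mm)
    nib.save(img, str(path))


def _resample_to(vol, target_spacing, target_shape, target_geom):
    src = vol.voxels
    in_spacing = np.asarray(vol.geometry.spacing_mm, dtype=float)
    out_spacing = np.asarray(target_spacing, dtype=float)
    # map output voxel centers onto input index space; both grids share the origin
    coords = np.meshgrid(*[np.arange(n) for n in target_shape], indexing="ij")
    idx = [c * (out_spacing[a] / in_spacing[a]) for a, c in enumerate(coords)]
    if isinstance(vol, MaskVolume):
        out = ndimage.map_coordinates(src.astype(np.float32), idx, order=0, mode="nearest")
        return MaskVolume(out > 0.5, target_geom)
    out = ndimage.map_coordinates(src, idx, order=1, mode="nearest")
    return ImageVolume(out, target_geom)


def resample_isotropic(vol: ImageVolume | MaskVolume, target_mm: float = 2.0):
    """Resample to isotropic voxels of ``target_mm`` (default 2 mm).

    Output shape is ``ceil(shape * spacing / target_mm)`` anchored at the
    input origin, so no anatomy is cropped. Images are interpolated
    linearly, masks by nearest neighbor (output stays binary).
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be > 0, got {target_mm}")
    in_spacing = np.asarray(vol.geometry.spacing_mm, dtype=float)
    in_shape = np.asarray(vol.voxels.shape)
    out_shape = tuple(int(n) for n in np.ceil(in_shape * in_spacing / target_mm))
    geom = replace(vol.geometry, spacing_mm=(float(target_mm),) * 3)
    return _resample_to(vol, (target_mm,) * 3, out_shape, geom)


def resample_mask_to_geometry(mask: MaskVolume, target: VolumeGeometry,
                              target_shape: tuple[int, int, int]) -> MaskVolume:
    """Nearest-neighbor resample of a mask onto an explicit target grid."""
    return _resample_to(mask, target.spacing_mm, target_shape, target)


def normalize_intensity(vol: ImageVolume, p_low: float = 2.0, p_high: float = 98.0) -> ImageVolume:
    """Map the [p2, p98] intensity window linearly onto [0, 1], clipping tails.

    Percentiles are taken over all voxels with the linear-interpolation
    definition. Invariant under positive affine intensity transforms.
    """
    lo, hi = np.percentile(vol.voxels, [p_low, p_high])
    if hi <= lo:
        raise DegenerateImageError(
            f"percentiles p{p_low:g}={lo:g} and p{p_high:g}={hi:g} leave no intensity range")
    out = np.clip((vol.voxels - lo) / (hi - lo), 0.0, 1.0)
    return ImageVolume(out.astype(np.float32), vol.geometry)
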