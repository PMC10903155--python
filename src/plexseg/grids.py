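"""Spatial containers and operations for volumetric images and label masks.

Volumes live on 3-D voxel grids with a NIfTI-style 4x4 voxel-to-world affine
(RAS+ world coordinates, millimetres, 0-based voxel indexing).  Spatial
transforms map native world coordinates to template world coordinates; the
transform itself is read from external files or constructed synthetically --
estimation (registration) is out of scope here, only application and
inversion of supplied transforms.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
from scipy import ndimage


class FormatError(ValueError):
    """Raised for files or arrays that violate a container invariant."""


class TransformError(ValueError):
    """Raised when a spatial transform cannot be applied or inverted."""


@dataclasses.dataclass
class ImageVolume:
    """A 3-D scalar image with its voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is not invertible")
        if min(self.data.shape) < 1:
            raise FormatError("every grid axis must have length >= 1")

    @property
    def spacing_mm(self) -> np.ndarray:
        """Per-axis voxel size in mm, derived from the affine columns."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclasses.dataclass
class LabelMask:
    """A binary 3-D mask sharing the grid of a reference :class:`ImageVolume`."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise FormatError(f"expected a 3-D mask, got ndim={arr.ndim}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise FormatError(f"mask values must be in {{0,1}}, found {vals[:10]}")
        self.data = arr.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")

    @property
    def spacing_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclasses.dataclass
class SpatialTransform:
    """Mapping between native and template world coordinates.

    ``affine`` maps native world (mm) to template world (mm).  Optional dense
    displacement fields refine the mapping: ``disp_forward`` is sampled on the
    template grid and gives, per template voxel, the offset (mm, native world)
    added after the affine pull-back when resampling native -> template;
    ``disp_inverse`` plays the symmetric role for template -> native.  Dense
    fields are supplied externally (e.g. from a registration run) -- this
    class never estimates them.
    """

    affine: np.ndarray = dataclasses.field(default_factory=lambda: np.eye(4))
    disp_forward: Optional[np.ndarray] = None  # (X,Y,Z,3) on the template grid
    disp_inverse: Optional[np.ndarray] = None  # (X,Y,Z,3) on the native grid

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise TransformError("transform affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise TransformError("transform affine is not invertible")

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    @classmethod
    def identity(cls) -> "SpatialTransform":
        return cls(np.eye(4))

    def check_roundtrip(self, grid_shape, grid_affine, tol_voxel: float = 0.5) -> bool:
        """Verify forward∘inverse is identity to ``tol_voxel`` on grid corners."""
        corners = np.array(
            [[i, j, k, 1.0] for i in (0, grid_shape[0] - 1)
             for j in (0, grid_shape[1] - 1) for k in (0, grid_shape[2] - 1)]
        ).T
        world = grid_affine @ corners
        back = self.inverse_affine @ (self.affine @ world)
        err_mm = np.abs(back - world)[:3].max()
        spacing = np.linalg.norm(np.asarray(grid_affine)[:3, :3], axis=0).min()
        return bool(err_mm <= tol_voxel * spacing)


def read_volume(path) -> ImageVolume:
    """Load a 3-D NIfTI-1 image as an :class:`ImageVolume`."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3-D data, got shape {data.shape}")
    return ImageVolume(np.asarray(data, dtype=np.float32), img.affine)


def write_volume(vol: ImageVolume, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine), str(path))


def read_mask(path) -> LabelMask:
    """Load a binary NIfTI-1 mask; non-{0,1} values are rejected."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return LabelMask(np.asarray(data), img.affine)


def write_mask(mask: LabelMask, path) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), str(path))


def read_affine_transform(path) -> SpatialTransform:
    """Read a 4x4 whitespace-delimited world-affine text file."""
    mat = np.loadtxt(str(path))
    if mat.shape != (4, 4):
        raise TransformError(f"{path}: expected a 4x4 matrix, got {mat.shape}")
    return SpatialTransform(mat)


def write_affine_transform(t: SpatialTransform, path) -> None:
    np.savetxt(str(path), t.affine, fmt="%.17g")


def _pullback_coords(template_grid_shape, template_affine, native_affine,
                     world_map_3x4: np.ndarray, disp: Optional[np.ndarray]):
    """Voxel coordinates in the source grid for each target-grid voxel.

    ``world_map_3x4`` maps target world -> source world (rows of a 4x4).
    ``disp`` (if given) adds a per-target-voxel offset in source-world mm.
    """
    idx = np.indices(template_grid_shape, dtype=np.float64)  # (3, X, Y, Z)
    ta = np.asarray(template_affine, dtype=float)
    world = np.einsum("ab,b...->a...", ta[:3, :3], idx) + ta[:3, 3, None, None, None]
    src_world = (np.einsum("ab,b...->a...", world_map_3x4[:, :3], world)
                 + world_map_3x4[:, 3, None, None, None])
    if disp is not None:
        if disp.shape[:3] != tuple(template_grid_shape) or disp.shape[3] != 3:
            raise TransformError(
                f"displacement grid {disp.shape} does not match target grid "
                f"{tuple(template_grid_shape)} + (3,)")
        src_world = src_world + np.moveaxis(disp, 3, 0)
    na_inv = np.linalg.inv(np.asarray(native_affine, dtype=float))
    vox = (np.einsum("ab,b...->a...", na_inv[:3, :3], src_world)
           + na_inv[:3, 3, None, None, None])
    return vox


def resample_to_template(vol: ImageVolume, t: SpatialTransform,
                         template_grid: ImageVolume | tuple,
                         interp: str = "linear") -> ImageVolume:
    """Resample a native-space volume onto the template grid.

    ``template_grid`` is either an :class:`ImageVolume` defining shape+affine
    or a ``(shape, affine)`` pair.  ``interp`` is ``linear`` (intensities) or
    ``nearest`` (labels).
    """
    if isinstance(template_grid, ImageVolume):
        tshape, taff = template_grid.shape, template_grid.affine
    else:
        tshape, taff = template_grid
        taff = np.asarray(taff, dtype=float)
    if interp not in ("linear", "nearest"):
        raise ValueError(f"interp must be 'linear' or 'nearest', got {interp!r}")
    vox = _pullback_coords(tshape, taff, vol.affine,
                           t.inverse_affine[:3], t.disp_forward)
    order = 1 if interp == "linear" else 0
    out = ndimage.map_coordinates(np.asarray(vol.data, dtype=np.float64), vox,
                                  order=order, mode="constant", cval=0.0)
    return ImageVolume(out.astype(np.float32), np.array(taff))


def inverse_resample_mask(mask_template: LabelMask, t: SpatialTransform,
                          native_grid: ImageVolume | tuple) -> LabelMask:
    """Bring a template-space mask back to the native grid (nearest neighbour)."""
    if isinstance(native_grid, ImageVolume):
        nshape, naff = native_grid.shape, native_grid.affine
    else:
        nshape, naff = native_grid
        naff = np.asarray(naff, dtype=float)
    vox = _pullback_coords(nshape, naff, mask_template.affine,
                           t.affine[:3], t.disp_inverse)
    out = ndimage.map_coordinates(mask_template.data, vox, order=0,
                                  mode="constant", cval=0)
    return LabelMask(out.astype(np.uint8), np.array(naff))


def mask_volume_cm3(mask: LabelMask) -> float:
    """Foreground volume in cm^3: voxel count x voxel volume (mm^3) / 1000."""
    return float(mask.data.sum(dtype=np.int64)) * mask.voxel_volume_mm3 / 1000.0


def mirror_sagittal(data: np.ndarray) -> np.ndarray:
    """Reflect a grid across the mid-sagittal plane (axis-0 reversal)."""
    return data[::-1, ...].copy()
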