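"""Probabilistic atlas of the target structure in template space.

The atlas is the voxelwise average of training masks; its support (prob > 0)
drives both patch-center sampling during training and the crop region used
at inference.  Crop boxes are padded so every dimension is divisible by 8,
which guarantees that three successive 2x poolings and unpoolings in the
network reproduce the input shape.
"""

from __future__ import annotations

import dataclasses
import json
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .grids import ImageVolume, LabelMask

Box = Tuple[Tuple[int, int], Tuple[int, int], Tuple[int, int]]  # [lo, hi) per axis


class AtlasError(ValueError):
    pass


@dataclasses.dataclass
class ProbabilisticAtlas:
    prob: np.ndarray          # in [0,1], template grid
    affine: np.ndarray
    crop_box: Box

    @property
    def support(self) -> np.ndarray:
        return self.prob > 0

    def support_indices(self) -> np.ndarray:
        return np.argwhere(self.support)

    def threshold_mask(self, level: float = 0.5) -> LabelMask:
        """Majority-vote style baseline mask: prob > level."""
        return LabelMask((self.prob > level).astype(np.uint8), self.affine.copy())


def build_atlas(masks: Sequence[LabelMask], margin: int = 8,
                min_size: Optional[int] = None) -> ProbabilisticAtlas:
    """Average template-space masks into a probability map + crop box.

    ``prob(v)`` is the fraction of masks with foreground at ``v``.  All masks
    must share one grid; an all-empty stack is rejected because it yields no
    support to sample or crop.
    """
    if len(masks) == 0:
        raise AtlasError("at least one mask is required")
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise AtlasError(f"mask grids differ: {m.shape} vs {shape}")
    acc = np.zeros(shape, dtype=np.float64)
    for m in masks:
        acc += m.data
    prob = acc / len(masks)
    if not prob.any():
        raise AtlasError("all masks are empty; atlas has no support")
    atlas = ProbabilisticAtlas(prob=prob, affine=masks[0].affine.copy(),
                               crop_box=((0, shape[0]), (0, shape[1]), (0, shape[2])))
    atlas.crop_box = derive_crop_box(atlas, margin=margin, min_size=min_size)
    return atlas


def derive_crop_box(atlas: ProbabilisticAtlas, margin: int = 8,
                    min_size: Optional[int] = None) -> Box:
    """Bounding box of the support, expanded by ``margin``, padded to
    multiples of 8 (and optionally to ``min_size``), clamped to the grid."""
    support = atlas.support
    if not support.any():
        raise AtlasError("atlas has empty support")
    shape = support.shape
    box = []
    for ax in range(3):
        proj = support.any(axis=tuple(a for a in range(3) if a != ax))
        idx = np.where(proj)[0]
        lo = max(0, int(idx[0]) - margin)
        hi = min(shape[ax], int(idx[-1]) + 1 + margin)
        length = hi - lo
        target = ((length + 7) // 8) * 8
        if min_size is not None:
            target = max(target, ((min_size + 7) // 8) * 8)
        if target > shape[ax]:
            raise AtlasError(
                f"crop box of length {target} exceeds grid extent {shape[ax]} "
                f"on axis {ax}")
        # symmetric padding, shifted inward at the grid faces
        pad = target - length
        lo = lo - pad // 2
        hi = hi + (pad - pad // 2)
        if lo < 0:
            hi -= lo
            lo = 0
        if hi > shape[ax]:
            lo -= hi - shape[ax]
            hi = shape[ax]
        box.append((lo, hi))
    return tuple(box)  # type: ignore[return-value]


def crop(data: np.ndarray, box: Box) -> np.ndarray:
    (x0, x1), (y0, y1), (z0, z1) = box
    return data[x0:x1, y0:y1, z0:z1]


def decrop(patch: np.ndarray, box: Box, full_shape, fill=0.0) -> np.ndarray:
    out = np.full(full_shape, fill, dtype=patch.dtype)
    (x0, x1), (y0, y1), (z0, z1) = box
    out[x0:x1, y0:y1, z0:z1] = patch
    return out


def save_atlas(atlas: ProbabilisticAtlas, nifti_path, box_json_path=None) -> None:
    import nibabel as nib
    nib.save(nib.Nifti1Image(atlas.prob.astype(np.float32), atlas.affine), str(nifti_path))
    if box_json_path is not None:
        with open(box_json_path, "w") as fh:
            json.dump({"crop_box": [list(b) for b in atlas.crop_box]}, fh)


def load_atlas(nifti_path, box_json_path=None, margin: int = 8,
               min_size: Optional[int] = None) -> ProbabilisticAtlas:
    import nibabel as nib
    img = nib.load(str(nifti_path))
    prob = np.asarray(np.asanyarray(img.dataobj), dtype=np.float64)
    atlas = ProbabilisticAtlas(prob=prob, affine=img.affine,
                               crop_box=((0, prob.shape[0]), (0, prob.shape[1]),
                                         (0, prob.shape[2])))
    if box_json_path is not None:
        with open(box_json_path) as fh:
            atlas.crop_box = tuple(tuple(b) for b in json.load(fh)["crop_box"])  # type: ignore
    else:
        atlas.crop_box = derive_crop_box(atlas, margin=margin, min_size=min_size)
    return atlas
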