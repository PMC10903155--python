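"""Atlas-centred patch extraction, mirror augmentation and score reassembly.

Training patches are cubes centred on voxels drawn uniformly from the atlas
support; a window that would extend past the grid is shifted inward so the
patch stays fully inside (its nominal centre may then be off-centre).
Mirror augmentation doubles the sample set by reflecting every patch across
the mid-sagittal plane (template x axis), which is how a per-subject set of
41 patches over 50 subjects becomes 4100 training samples.  At inference a
regular sliding window tiles the atlas crop box with stride = half the
patch edge; overlapping scores are averaged and uncovered voxels keep the
background score -1.
"""

from __future__ import annotations

import dataclasses
from typing import List, Sequence, Tuple

import numpy as np

from .atlas import AtlasError, Box, ProbabilisticAtlas
from .grids import ImageVolume


@dataclasses.dataclass
class PatchSample:
    intensities: np.ndarray   # (k,k,k) float
    labels: np.ndarray        # (k,k,k) {0,1}
    center: Tuple[int, int, int]
    flipped: bool = False
    subject_id: str = ""


def sample_patch_centers(atlas: ProbabilisticAtlas, n: int,
                         rng_seed: int) -> List[Tuple[int, int, int]]:
    """Draw ``n`` centres uniformly (with replacement) from the atlas support."""
    if n < 1:
        raise ValueError("n must be >= 1")
    support = atlas.support_indices()
    if len(support) == 0:
        raise AtlasError("atlas has empty support; cannot sample patch centers")
    rng = np.random.default_rng(rng_seed)
    picks = rng.integers(0, len(support), size=n)
    return [tuple(int(v) for v in support[i]) for i in picks]


def _window_start(center: int, size: int, extent: int) -> int:
    start = center - size // 2
    return int(np.clip(start, 0, extent - size))


def extract_patch(vol: ImageVolume | np.ndarray, center, size: int = 64) -> np.ndarray:
    """A ``size``^3 window around ``center``, shifted inward at grid faces."""
    data = vol.data if isinstance(vol, ImageVolume) else np.asarray(vol)
    for ax in range(3):
        if data.shape[ax] < size:
            raise ValueError(
                f"grid extent {data.shape[ax]} on axis {ax} is smaller than "
                f"patch size {size}")
        if not (0 <= center[ax] < data.shape[ax]):
            raise ValueError(f"center {tuple(center)} outside grid {data.shape}")
    starts = [_window_start(center[ax], size, data.shape[ax]) for ax in range(3)]
    return data[starts[0]:starts[0] + size,
                starts[1]:starts[1] + size,
                starts[2]:starts[2] + size]


def make_patch_samples(image: ImageVolume | np.ndarray, truth: np.ndarray,
                       centers: Sequence[Tuple[int, int, int]], size: int = 64,
                       subject_id: str = "") -> List[PatchSample]:
    """Paired intensity/label patches at the given centres."""
    data = image.data if isinstance(image, ImageVolume) else np.asarray(image)
    return [PatchSample(intensities=np.ascontiguousarray(extract_patch(data, c, size)),
                        labels=np.ascontiguousarray(extract_patch(truth, c, size)),
                        center=tuple(int(v) for v in c), subject_id=subject_id)
            for c in centers]


def flip_augment(samples: Sequence[PatchSample]) -> List[PatchSample]:
    """Each sample plus its left-right mirror; output length is doubled.

    Implemented as deterministic doubling (rather than coin-flip flipping) so
    the augmented sample count is exactly 2x the input.
    """
    out: List[PatchSample] = []
    for s in samples:
        out.append(s)
        out.append(PatchSample(intensities=s.intensities[::-1, :, :].copy(),
                               labels=s.labels[::-1, :, :].copy(),
                               center=s.center, flipped=not s.flipped,
                               subject_id=s.subject_id))
    return out


def sliding_window_starts(box: Box, size: int, stride: int,
                          grid_shape) -> List[Tuple[int, int, int]]:
    """Window start corners tiling the crop box with full coverage.

    Windows are anchored inside the full grid (inward-shifted at faces); the
    final window on each axis is placed flush with the box end so coverage
    is guaranteed even when the box length is not a multiple of the stride.
    """
    per_axis = []
    for ax, (lo, hi) in enumerate(box):
        extent = grid_shape[ax]
        if extent < size:
            raise ValueError(f"grid axis {ax} ({extent}) smaller than patch {size}")
        starts = list(range(lo, max(lo, hi - size) + 1, stride))
        last = int(np.clip(hi - size, 0, extent - size))
        if starts[-1] != last:
            starts.append(last)
        starts = sorted({int(np.clip(s, 0, extent - size)) for s in starts})
        per_axis.append(starts)
    return [(x, y, z) for x in per_axis[0] for y in per_axis[1] for z in per_axis[2]]


def assemble_patches(patches: Sequence[Tuple[Tuple[int, int, int], np.ndarray]],
                     target_shape, background: float = -1.0) -> np.ndarray:
    """Average overlapping patch scores onto the target grid.

    ``patches`` is a list of (start corner, score grid).  Voxels covered by
    no patch are set to ``background``.
    """
    if len(patches) == 0:
        raise ValueError("at least one patch is required")
    acc = np.zeros(target_shape, dtype=np.float64)
    cnt = np.zeros(target_shape, dtype=np.int32)
    for start, grid in patches:
        grid = np.asarray(grid)
        sl = tuple(slice(start[ax], start[ax] + grid.shape[ax]) for ax in range(3))
        for ax in range(3):
            if start[ax] < 0 or start[ax] + grid.shape[ax] > target_shape[ax]:
                raise ValueError(
                    f"patch at {start} with shape {grid.shape} exceeds "
                    f"target grid {tuple(target_shape)}")
        acc[sl] += grid
        cnt[sl] += 1
    out = np.full(target_shape, background, dtype=np.float64)
    covered = cnt > 0
    out[covered] = acc[covered] / cnt[covered]
    return out
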