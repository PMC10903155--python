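"""Mask- and volume-agreement metrics: Dice-Sorensen, 95% Hausdorff distance,
voxelwise AUC, ICC and Bland-Altman statistics.

Conventions (also recorded in report metadata):

* Dice of two empty masks is 1 (perfect agreement on emptiness).
* HD95 is the max of the two directed 95th percentiles of surface-to-surface
  distances, in world mm with anisotropic spacing honoured; surface voxels
  are foreground voxels with at least one background face-neighbour (the
  outside of the grid counts as background).  A pooled-percentile dialect is
  available behind a flag.
* Voxelwise AUC uses the Mann-Whitney rank formulation, so binary
  predictions score (sensitivity + specificity)/2 and ties count 1/2.
* ICC defaults to the two-way random-effects, absolute-agreement,
  single-measure form ICC(2,1), treating methods as raters.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .grids import LabelMask


class UndefinedMetricError(ValueError):
    """The metric is mathematically undefined for this input."""


@dataclasses.dataclass
class MetricReport:
    subject_id: str
    dice: float
    hd95_mm: float
    auc: float
    volume_pred_cm3: float
    volume_truth_cm3: float


def dice(a: LabelMask, b: LabelMask) -> float:
    """2|A∩B| / (|A|+|B|); two empty masks agree perfectly (1.0)."""
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    na = int(a.data.sum(dtype=np.int64))
    nb = int(b.data.sum(dtype=np.int64))
    if na + nb == 0:
        return 1.0
    inter = int((a.data & b.data).sum(dtype=np.int64))
    return 2.0 * inter / (na + nb)


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices (m,3) of foreground voxels with a background face-neighbour."""
    fg = mask.astype(bool)
    struct = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(fg, structure=struct, border_value=0)
    return np.argwhere(fg & ~eroded)


def hausdorff95(a: LabelMask, b: LabelMask, spacing_mm: Optional[np.ndarray] = None,
                pooled: bool = False) -> float:
    """95% Hausdorff distance between mask surfaces in world mm.

    ``pooled=True`` switches to the pooled-percentile dialect (one 95th
    percentile over both directed distance sets) instead of the default
    max-of-directed-percentiles.
    """
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    if a.data.sum() == 0 or b.data.sum() == 0:
        raise UndefinedMetricError("HD95 undefined for an empty mask")
    sp = np.asarray(spacing_mm if spacing_mm is not None else a.spacing_mm, dtype=float)
    sa = surface_voxels(a.data) * sp[None, :]
    sb = surface_voxels(b.data) * sp[None, :]
    d_ab, _ = cKDTree(sb).query(sa)
    d_ba, _ = cKDTree(sa).query(sb)
    if pooled:
        return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


def auc_voxelwise(scores: np.ndarray, truth: np.ndarray,
                  region: Optional[np.ndarray] = None) -> float:
    """Mann-Whitney AUC of per-voxel scores against binary truth.

    ``region`` optionally restricts the evaluation to a boolean submask
    (e.g. the atlas crop box), so true negatives outside the region of
    interest do not inflate the statistic.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValueError(f"shape mismatch: {scores.shape} vs {truth.shape}")
    if region is not None:
        scores = scores[region]
        truth = truth[region]
    s = scores.ravel()
    t = truth.ravel().astype(bool)
    n_fg = int(t.sum())
    n_bg = t.size - n_fg
    if n_fg == 0 or n_bg == 0:
        raise UndefinedMetricError("AUC undefined for a single-class region")
    ranks = stats.rankdata(s)
    return float((ranks[t].sum() - n_fg * (n_fg + 1) / 2.0) / (n_fg * n_bg))


def icc(measurements: np.ndarray, form: str = "icc2_1") -> float:
    """Intraclass correlation of an (n subjects x k methods) table.

    Default form is ICC(2,1): two-way random effects, absolute agreement,
    single measure, computed from the ANOVA mean squares.  ``icc3_1``
    (consistency) is available for comparison.
    """
    y = np.asarray(measurements, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need an (n>=2 subjects) x (k>=2 methods) table")
    if np.isnan(y).any():
        raise ValueError("missing cells are not supported")
    n, k = y.shape
    gm = y.mean()
    if np.allclose(y, gm):
        raise UndefinedMetricError("ICC undefined for zero total variance")
    row_m = y.mean(axis=1)
    col_m = y.mean(axis=0)
    ssr = k * ((row_m - gm) ** 2).sum()
    ssc = n * ((col_m - gm) ** 2).sum()
    sst = ((y - gm) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if form == "icc2_1":
        return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))
    if form == "icc3_1":
        return float((msr - mse) / (msr + (k - 1) * mse))
    raise ValueError(f"unknown ICC form {form!r}")


def bland_altman(x, y) -> Tuple[float, float, float]:
    """(bias, lower limit, upper limit) of x-y; limits are bias +/- 1.96 sd."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd
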