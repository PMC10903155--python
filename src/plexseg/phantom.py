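"""Synthetic 3-D brain phantoms with ventricle-like CSF compartments and an
embedded choroid-plexus-like target.

The phantoms make the whole pipeline testable without MRI: two mirror-image
ellipsoidal "lateral ventricles" sit inside a head ellipsoid of brain-like
parenchyma, and a thin curved tube -- the plexus surrogate -- lies strictly
inside the atrium of each ventricle.  Per-sequence intensity lookups mimic
the clinical contrast situation: near-isointense against parenchyma on
T1-like images, intermediate between CSF and parenchyma on T2-like images,
and relatively bright against suppressed CSF on FLAIR-like images.  Target
volume grows multiplicatively with age (default 15% per decade) and carries
an additive male offset, so the lifespan statistics have a known planted
signal to recover.

Intensities are unitless in [0,1]; noise is additive Gaussian.  No MR
physics (bias fields, partial voluming, Rician noise) is simulated.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import interpolate, ndimage
from scipy.spatial import cKDTree

from .grids import ImageVolume, LabelMask, SpatialTransform

SEQUENCES = ("t1like", "t2like", "flairlike")

_SEQ_ALIASES = {
    "t1": "t1like", "t1like": "t1like", "t1w": "t1like",
    "t2": "t2like", "t2like": "t2like", "t2w": "t2like",
    "flair": "flairlike", "flairlike": "flairlike",
}

# Unitless tissue intensities per sequence: (parenchyma, CSF, plexus).
INTENSITY_LOOKUP: Dict[str, Dict[str, float]] = {
    "t1like": {"parenchyma": 0.70, "csf": 0.20, "plexus": 0.55},
    "t2like": {"parenchyma": 0.40, "csf": 0.90, "plexus": 0.55},
    "flairlike": {"parenchyma": 0.45, "csf": 0.15, "plexus": 0.60},
}
_BACKGROUND = 0.02


class PhantomSizingError(ValueError):
    """The requested anatomy does not fit the grid; names the limiting axis."""


def normalize_sequence(name: str) -> str:
    key = name.strip().lower().replace("-", "").replace("_", "")
    if key not in _SEQ_ALIASES:
        raise ValueError(f"unknown sequence {name!r}; expected one of {SEQUENCES}")
    return _SEQ_ALIASES[key]


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    Volumes are in cm^3; the expected plexus volume follows
    ``base * (1+growth)^((age-20)/10) + male_offset`` and the ventricle
    volume scales the same way with its own growth rate (an atrophy proxy).
    """

    grid_shape: Tuple[int, int, int] = (96, 96, 96)
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    sequence: str = "t1like"
    age_years: float = 20.0
    sex: str = "F"
    base_plexus_volume_cm3: float = 1.5
    volume_growth_per_decade: float = 0.15
    male_volume_offset_cm3: float = 0.4
    ventricle_base_volume_cm3: float = 14.0
    ventricle_growth_per_decade: float = 0.20
    noise_sd: float = 0.05
    volume_scatter_cm3: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if min(self.grid_shape) < 32:
            raise ValueError("every grid axis must be >= 32 voxels")
        if min(self.spacing_mm) <= 0:
            raise ValueError("spacing must be strictly positive")
        if self.age_years <= 0:
            raise ValueError("age must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.expected_plexus_volume_cm3 <= 0:
            raise ValueError("expected plexus volume must be strictly positive")

    @property
    def expected_plexus_volume_cm3(self) -> float:
        v = self.base_plexus_volume_cm3 * (
            (1.0 + self.volume_growth_per_decade) ** ((self.age_years - 20.0) / 10.0))
        if self.sex == "M":
            v += self.male_volume_offset_cm3
        return v

    @property
    def expected_ventricle_volume_cm3(self) -> float:
        return self.ventricle_base_volume_cm3 * (
            (1.0 + self.ventricle_growth_per_decade) ** ((self.age_years - 20.0) / 10.0))


@dataclasses.dataclass
class SubjectRecord:
    """Per-subject covariates used by the cohort statistics layer."""

    id: str
    age_years: float
    sex: str
    group: str = "control"
    tiv_cm3: float = float("nan")
    lvv_cm3: float = float("nan")
    cp_volume_cm3: Dict[str, float] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class PhantomSubject:
    """Images (one per requested sequence), ground truth and covariates."""

    images: Dict[str, ImageVolume]
    truth_mask: LabelMask
    record: SubjectRecord
    transform: SpatialTransform = dataclasses.field(default_factory=SpatialTransform.identity)
    spec: Optional[PhantomSpec] = None


def _affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _ellipsoid_mask(shape, center_vox, semi_vox) -> np.ndarray:
    idx = np.indices(shape, dtype=np.float64)
    r2 = sum(((idx[a] - center_vox[a]) / semi_vox[a]) ** 2 for a in range(3))
    return r2 <= 1.0


def _ventricle_geometry(spec: PhantomSpec):
    """Solve the left-ventricle ellipsoid (voxel center + semi-axes) for the
    requested ventricular volume; raise naming the limiting axis if it
    cannot fit the grid."""
    shape = np.array(spec.grid_shape)
    sp = np.array(spec.spacing_mm)
    # unit semi-axis ratios (x: left-right, y: anterior-posterior, z: axial)
    u = np.array([1.0, 2.4, 1.5])
    v_one_mm3 = spec.expected_ventricle_volume_cm3 * 1000.0 / 2.0
    s = (v_one_mm3 / (4.0 / 3.0 * np.pi * u.prod())) ** (1.0 / 3.0)
    semi_mm = s * u
    semi_vox = semi_mm / sp
    gap_vox = max(2.0, 3.0 / sp[0])  # midline gap
    center = np.array([ (shape[0] - 1) / 2.0 - gap_vox - semi_vox[0],
                        shape[1] * 0.52,
                        shape[2] * 0.50 ])
    # fit check with a 2-voxel margin per face
    limits = {
        "x": center[0] - semi_vox[0] >= 2.0,
        "y": (center[1] - semi_vox[1] >= 2.0) and (center[1] + semi_vox[1] <= shape[1] - 3.0),
        "z": (center[2] - semi_vox[2] >= 2.0) and (center[2] + semi_vox[2] <= shape[2] - 3.0),
    }
    for axis, ok in limits.items():
        if not ok:
            raise PhantomSizingError(
                f"ventricle volume {spec.expected_ventricle_volume_cm3:.1f} cm^3 "
                f"does not fit the grid along axis {axis} "
                f"(grid {tuple(spec.grid_shape)}, spacing {tuple(spec.spacing_mm)})")
    return center, semi_vox


def _plexus_curve(center, semi, rng) -> np.ndarray:
    """A jittered spline through the atrium of one ventricle, sampled finely.

    Returned as (m, 3) voxel coordinates.  The curve runs through the
    posterior half of the ellipsoid with a gentle bend, emulating the thin
    elongated glomus of the real structure.
    """
    ts = np.array([0.0, 0.3, 0.6, 1.0])
    base = np.stack([
        center[0] + semi[0] * np.array([0.15, 0.00, -0.10, 0.05]),
        center[1] + semi[1] * np.array([0.05, 0.30, 0.55, 0.78]),
        center[2] + semi[2] * np.array([-0.25, 0.00, 0.15, 0.05]),
    ], axis=1)
    jitter = rng.normal(0.0, 0.06, size=base.shape) * semi[None, :]
    pts = base + jitter
    spl = interpolate.make_interp_spline(ts, pts, k=3)
    return spl(np.linspace(0.0, 1.0, 160))


def _rasterize_plexus(inside: np.ndarray, curve_vox: np.ndarray,
                      spacing: np.ndarray, n_target: int) -> np.ndarray:
    """Select the ``n_target`` candidate voxels nearest the curve (world mm).

    Choosing by distance rank rather than a fixed tube radius calibrates the
    rasterized volume to the requested voxel count exactly (up to the
    candidate supply), while the shape stays a curved tube.
    """
    cand = np.argwhere(inside)
    if len(cand) < n_target:
        raise PhantomSizingError(
            f"ventricle interior ({len(cand)} voxels) cannot hold a "
            f"{n_target}-voxel plexus target; enlarge the ventricle or grid")
    tree = cKDTree(curve_vox * spacing[None, :])
    d, _ = tree.query(cand * spacing[None, :])
    keep = cand[np.argsort(d, kind="stable")[:n_target]]
    out = np.zeros(inside.shape, dtype=bool)
    out[tuple(keep.T)] = True
    return out


def make_phantom(spec: PhantomSpec,
                 sequences: Optional[Iterable[str]] = None) -> PhantomSubject:
    """Build one synthetic subject; deterministic given ``spec.seed``."""
    seqs = [normalize_sequence(s) for s in (sequences or [spec.sequence])]
    if not seqs:
        raise ValueError("at least one sequence is required")
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    sp = np.array(spec.spacing_mm, dtype=float)
    aff = _affine(sp)
    vox_mm3 = float(sp.prod())

    center_l, semi = _ventricle_geometry(spec)
    vent_left = _ellipsoid_mask(shape, center_l, semi)
    vent = vent_left | vent_left[::-1, ...]  # exact mirror symmetry

    head_center = (np.array(shape) - 1) / 2.0
    # per-subject head-size jitter gives the cohort a varying TIV covariate
    head_scale = rng.uniform(0.94, 1.0)
    head_semi = (np.array(shape) - 1) * np.array([0.47, 0.48, 0.46]) * head_scale
    head = _ellipsoid_mask(shape, head_center, head_semi)
    vent &= head

    # plexus target: one jittered curve per side, strictly inside the ventricle;
    # optional per-subject scatter emulates inter-individual volume variability
    target_cm3 = spec.expected_plexus_volume_cm3
    if spec.volume_scatter_cm3 > 0:
        target_cm3 = max(target_cm3 + rng.normal(0.0, spec.volume_scatter_cm3),
                         0.25 * target_cm3)
    n_total = int(round(target_cm3 * 1000.0 / vox_mm3))
    struct = ndimage.generate_binary_structure(3, 1)
    interior_l = ndimage.binary_erosion(vent_left, structure=struct)
    curve_l = _plexus_curve(center_l, semi, rng)
    plexus_l = _rasterize_plexus(interior_l, curve_l, sp, n_total - n_total // 2)
    center_r = center_l.copy()
    center_r[0] = (shape[0] - 1) - center_l[0]
    curve_r = _plexus_curve(center_r, semi, rng)
    interior_r = ndimage.binary_erosion(vent_left[::-1, ...], structure=struct)
    plexus_r = _rasterize_plexus(interior_r, curve_r, sp, n_total // 2)
    plexus = plexus_l | plexus_r

    images: Dict[str, ImageVolume] = {}
    for seq in seqs:
        lut = INTENSITY_LOOKUP[seq]
        img = np.full(shape, _BACKGROUND, dtype=np.float32)
        img[head] = lut["parenchyma"]
        img[vent] = lut["csf"]
        img[plexus] = lut["plexus"]
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
        images[seq] = ImageVolume(img.astype(np.float32), aff.copy())

    truth = LabelMask(plexus.astype(np.uint8), aff.copy())
    record = SubjectRecord(
        id=f"phantom-{spec.seed:08d}",
        age_years=spec.age_years,
        sex=spec.sex,
        tiv_cm3=float(head.sum()) * vox_mm3 / 1000.0,
        lvv_cm3=float(vent.sum()) * vox_mm3 / 1000.0,
        cp_volume_cm3={seq: float(plexus.sum()) * vox_mm3 / 1000.0 for seq in seqs},
    )
    return PhantomSubject(images=images, truth_mask=truth, record=record,
                          transform=SpatialTransform.identity(), spec=spec)


def make_cohort(n: int, age_range: Tuple[float, float] = (21.0, 89.0),
                sequences: Iterable[str] = ("t1like",), seed: int = 0,
                grid_shape: Tuple[int, int, int] = (96, 96, 96),
                spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0),
                noise_sd: float = 0.05,
                **spec_kwargs) -> Tuple[List[PhantomSubject], pd.DataFrame]:
    """Generate ``n`` subjects with ~uniform ages and balanced sexes.

    Returns the subjects and a covariate table (id, age, sex, tiv_cm3,
    lvv_cm3, plus one cp volume column per sequence).  Deterministic given
    ``seed``; per-subject seeds are spawned from the master seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = age_range
    if not (18.0 < lo <= hi < 100.0):
        raise ValueError("age_range must lie within (18, 100)")
    seqs = [normalize_sequence(s) for s in sequences]
    if not seqs:
        raise ValueError("at least one sequence is required")
    ages = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2.0])
    child_seeds = [int(ss.generate_state(1)[0] % (2 ** 31))
                   for ss in np.random.SeedSequence(seed).spawn(n)]
    subjects: List[PhantomSubject] = []
    rows = []
    for i in range(n):
        spec = PhantomSpec(grid_shape=grid_shape, spacing_mm=spacing_mm,
                           sequence=seqs[0], age_years=float(ages[i]),
                           sex="M" if i % 2 == 0 else "F",
                           noise_sd=noise_sd, seed=child_seeds[i], **spec_kwargs)
        subj = make_phantom(spec, sequences=seqs)
        subj.record.id = f"sub-{i:03d}"
        subjects.append(subj)
        row = {"id": subj.record.id, "age": subj.record.age_years,
               "sex": subj.record.sex, "tiv_cm3": subj.record.tiv_cm3,
               "lvv_cm3": subj.record.lvv_cm3}
        for seq in seqs:
            row[f"cp_volume_cm3_{seq}"] = subj.record.cp_volume_cm3[seq]
        rows.append(row)
    return subjects, pd.DataFrame(rows)
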