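"""Orchestration: cross-validated train/segment/evaluate runs on a cohort,
and method-vs-method statistical comparison.

Each fold builds its probabilistic atlas from the fold's training masks
only -- using validation or test masks would leak ground truth into the
crop region and patch sampling -- trains one network, segments the fold's
held-out test subjects and scores them against ground truth.  A provenance
manifest (config, seeds, fold assignments) accompanies every run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics, patching, stats, unet
from .atlas import ProbabilisticAtlas, build_atlas
from .grids import LabelMask, mask_volume_cm3, resample_to_template
from .phantom import PhantomSubject, normalize_sequence


class LeakageError(RuntimeError):
    """A fold attempted to use its own test subjects during training."""


@dataclasses.dataclass
class RunConfig:
    sequence: str = "t1like"
    model: unet.UNetConfig = dataclasses.field(default_factory=unet.UNetConfig)
    train: unet.TrainConfig = dataclasses.field(default_factory=unet.TrainConfig)
    fold_seed: int = 0
    patches_per_subject: int = 41
    patch_size: int = 64
    val_patches_per_subject: Optional[int] = None
    inference_stride: Optional[int] = None
    atlas_margin: int = 8

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a run configuration from a YAML file; nested ``model`` and
        ``train`` sections map onto UNetConfig / TrainConfig."""
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "model" in raw:
            raw["model"] = unet.UNetConfig(**raw["model"])
        if "train" in raw:
            raw["train"] = unet.TrainConfig(**raw["train"])
        return cls(**raw)

    def manifest(self) -> Dict:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str)
        return {"config": d,
                "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16]}


@dataclasses.dataclass
class CrossvalResult:
    reports: List[metrics.MetricReport]
    per_fold: List[Dict]
    summary: pd.DataFrame
    baseline_reports: List[metrics.MetricReport]
    manifest: Dict
    models: List = dataclasses.field(default_factory=list)
    atlases: List[ProbabilisticAtlas] = dataclasses.field(default_factory=list)


def _subject_template_image(subj: PhantomSubject, sequence: str,
                            template_grid) -> np.ndarray:
    vol = subj.images[sequence]
    return resample_to_template(vol, subj.transform, template_grid, "linear").data


def _subject_template_mask(subj: PhantomSubject, template_grid) -> LabelMask:
    vol = resample_to_template(
        type(subj.images[next(iter(subj.images))])(subj.truth_mask.data.astype(np.float32),
                                                   subj.truth_mask.affine),
        subj.transform, template_grid, "nearest")
    return LabelMask((vol.data > 0.5).astype(np.uint8), vol.affine)


def _crop_region(atlas: ProbabilisticAtlas, shape) -> np.ndarray:
    region = np.zeros(shape, dtype=bool)
    (x0, x1), (y0, y1), (z0, z1) = atlas.crop_box
    region[x0:x1, y0:y1, z0:z1] = True
    return region


def evaluate_mask(subject_id: str, pred: LabelMask, truth: LabelMask,
                  scores: Optional[np.ndarray] = None,
                  region: Optional[np.ndarray] = None) -> metrics.MetricReport:
    """Score one predicted mask against ground truth on a shared grid."""
    d = metrics.dice(pred, truth)
    try:
        hd = metrics.hausdorff95(pred, truth)
    except metrics.UndefinedMetricError:
        hd = float("nan")
    op = scores if scores is not None else pred.data.astype(float)
    try:
        auc = metrics.auc_voxelwise(op, truth.data, region=region)
    except metrics.UndefinedMetricError:
        auc = float("nan")
    return metrics.MetricReport(
        subject_id=subject_id, dice=d, hd95_mm=hd, auc=auc,
        volume_pred_cm3=mask_volume_cm3(pred),
        volume_truth_cm3=mask_volume_cm3(truth))


def reports_to_frame(reports: Sequence[metrics.MetricReport]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in reports])


def summarize_reports(reports: Sequence[metrics.MetricReport],
                      method: str) -> pd.DataFrame:
    """Mean (range) rows for each metric, one table row per method."""
    df = reports_to_frame(reports)
    row = {"method": method}
    for col in ("dice", "hd95_mm", "auc"):
        vals = df[col].dropna()
        row[col] = f"{vals.mean():.2f} ({vals.min():.2f}-{vals.max():.2f})"
    return pd.DataFrame([row])


def run_crossval(subjects: Sequence[PhantomSubject], cfg: RunConfig,
                 n_folds: int = 5, verbose: bool = False) -> CrossvalResult:
    """Five-fold cross-validation over a cohort with per-fold atlases.

    Returns per-subject test metrics pooled over folds, an atlas-threshold
    baseline (probability > 0.5 mask) on the same test subjects, and a
    Table-1-style mean (range) summary.
    """
    by_id = {s.record.id: s for s in subjects}
    if len(by_id) != len(subjects):
        raise ValueError("subject ids must be unique")
    plan = unet.make_folds(sorted(by_id), seed=cfg.fold_seed, n_folds=n_folds)
    template_grid = None
    reports: List[metrics.MetricReport] = []
    baseline_reports: List[metrics.MetricReport] = []
    per_fold: List[Dict] = []
    models_out: List = []
    atlases_out: List[ProbabilisticAtlas] = []
    for f, fold in enumerate(plan.folds):
        t0 = time.time()
        if set(fold["test"]) & (set(fold["train"]) | set(fold["val"])):
            raise LeakageError(f"fold {f}: test subjects appear in training data")
        first = by_id[fold["train"][0]]
        template_grid = (first.truth_mask.shape, first.truth_mask.affine)
        train_masks = [_subject_template_mask(by_id[i], template_grid)
                       for i in fold["train"]]
        atlas = build_atlas(train_masks, margin=cfg.atlas_margin,
                            min_size=cfg.patch_size)
        samples: List[patching.PatchSample] = []
        for sid in fold["train"]:
            subj = by_id[sid]
            img = _subject_template_image(subj, cfg.sequence, template_grid)
            msk = _subject_template_mask(subj, template_grid).data
            centers = patching.sample_patch_centers(
                atlas, cfg.patches_per_subject,
                rng_seed=(cfg.train.seed * 100003 + zlib.crc32(sid.encode())) % (2 ** 31))
            samples.extend(patching.make_patch_samples(
                img, msk, centers, size=cfg.patch_size, subject_id=sid))
        samples = patching.flip_augment(samples)
        val_samples: List[patching.PatchSample] = []
        n_val = cfg.val_patches_per_subject or max(2, cfg.patches_per_subject // 4)
        for sid in fold["val"]:
            subj = by_id[sid]
            img = _subject_template_image(subj, cfg.sequence, template_grid)
            msk = _subject_template_mask(subj, template_grid).data
            centers = patching.sample_patch_centers(
                atlas, n_val,
                rng_seed=(cfg.train.seed * 200003 + zlib.crc32(sid.encode())) % (2 ** 31))
            val_samples.extend(patching.make_patch_samples(
                img, msk, centers, size=cfg.patch_size, subject_id=sid))
        model = unet.build_model(cfg.model, seed=cfg.train.seed + f)
        model, history = unet.train(model, samples, val_samples, cfg.train)
        region = _crop_region(atlas, template_grid[0])
        baseline_mask = atlas.threshold_mask(0.5)
        for sid in fold["test"]:
            subj = by_id[sid]
            scores, pred_native, _vol = unet.segment_subject(
                model, subj.images[cfg.sequence], subj.transform, atlas,
                patch_size=cfg.patch_size, stride=cfg.inference_stride)
            truth_t = _subject_template_mask(subj, template_grid)
            pred_t = LabelMask((scores.data > 0).astype(np.uint8), scores.affine)
            rep = evaluate_mask(sid, pred_t, truth_t, scores=scores.data,
                                region=region)
            rep.volume_pred_cm3 = mask_volume_cm3(pred_native)
            reports.append(rep)
            baseline_reports.append(
                evaluate_mask(sid, baseline_mask, truth_t, region=region))
        models_out.append(model)
        atlases_out.append(atlas)
        per_fold.append({"fold": f, "train": fold["train"], "val": fold["val"],
                         "test": fold["test"], "epochs": len(history["train_loss"]),
                         "final_train_loss": history["train_loss"][-1],
                         "seconds": round(time.time() - t0, 1)})
        if verbose:
            print(f"[fold {f}] epochs={per_fold[-1]['epochs']} "
                  f"loss={per_fold[-1]['final_train_loss']:.3f} "
                  f"time={per_fold[-1]['seconds']}s")
    summary = pd.concat([summarize_reports(reports, f"unet_{cfg.sequence}"),
                         summarize_reports(baseline_reports, "atlas_threshold")],
                        ignore_index=True)
    manifest = cfg.manifest()
    manifest["folds"] = [{k: v for k, v in pf.items() if k != "seconds"}
                         for pf in per_fold]
    return CrossvalResult(reports=reports, per_fold=per_fold, summary=summary,
                          baseline_reports=baseline_reports, manifest=manifest,
                          models=models_out, atlases=atlases_out)


def compare_methods(ours: Sequence[metrics.MetricReport],
                    external: Sequence[metrics.MetricReport]) -> pd.DataFrame:
    """Paired Wilcoxon per metric between two methods, FDR-corrected.

    Pairs by subject id; external masks come from other software (e.g.
    FreeSurfer-style outputs read from NIfTI), never computed here.
    """
    a = reports_to_frame(ours).set_index("subject_id")
    b = reports_to_frame(external).set_index("subject_id")
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no overlapping subject ids to pair")
    if len(common) < len(a.index.union(b.index)):
        raise ValueError("subject id sets differ; cannot pair all reports")
    rows = []
    for col in ("dice", "hd95_mm", "auc"):
        x = a.loc[common, col].to_numpy()
        y = b.loc[common, col].to_numpy()
        try:
            p = stats.wilcoxon_paired(x, y)
            note = ""
        except stats.DegenerateDataError:
            p = np.nan
            note = "degenerate: all paired differences zero"
        rows.append({"metric": col, "mean_ours": float(np.nanmean(x)),
                     "mean_external": float(np.nanmean(y)), "p": p, "note": note})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    adj = np.full(len(out), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = stats.fdr_adjust(out.loc[ok, "p"].to_numpy())
    out["p_fdr"] = adj
    return out
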