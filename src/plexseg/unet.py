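"""3-D U-Net for single-structure segmentation, with generalized Dice
training and full-subject inference.

The network is a three-level (configurable) encoder--decoder: each encoder
block is two (conv 3x3x3, batch norm, ReLU) layers, blocks are separated by
2x2x2 max pooling, filters start at ``base_filters`` and double per block.
The decoder mirrors this with 2x2x2-stride transposed convolutions and
(by default) skip concatenations, halving the filters per block; a 1x1x1
convolution with a hyperbolic tangent produces a score map in (-1, 1).
Scores map to foreground probabilities via p = (y+1)/2, so the binarization
threshold y > 0 is the p > 0.5 point.

Training minimises the two-class generalized Dice loss (inverse squared
class-volume weights) with Adam; one independent model is trained per MRI
sequence.  Cross-validation follows a five-fold plan in which every subject
serves exactly once as a test case.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import patching
from .atlas import ProbabilisticAtlas
from .grids import ImageVolume, LabelMask, SpatialTransform, inverse_resample_mask, \
    mask_volume_cm3, resample_to_template
from .nn.layers import Adam, BatchNorm3d, Conv3d, ConvTranspose3d, Layer, MaxPool3d, \
    ReLU, Tanh


class TrainingError(RuntimeError):
    pass


@dataclasses.dataclass
class UNetConfig:
    levels: int = 3
    base_filters: int = 64
    in_channels: int = 1
    out_channels: int = 1
    skip_connections: bool = True

    def __post_init__(self) -> None:
        if self.levels < 1 or self.base_filters < 1:
            raise ValueError("levels and base_filters must be >= 1")


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 4
    max_epochs: int = 200
    early_stop_patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class _Block:
    """Two conv-BN-ReLU layers."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.layers: List[Layer] = [
            Conv3d(c_in, c_out, 3, rng), BatchNorm3d(c_out), ReLU(),
            Conv3d(c_out, c_out, 3, rng), BatchNorm3d(c_out), ReLU(),
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class UNet3D:
    """Encoder--decoder with skip concatenations; see module docstring."""

    def __init__(self, cfg: UNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        L, F = cfg.levels, cfg.base_filters
        self.enc: List[_Block] = []
        self.pools: List[MaxPool3d] = []
        c = cfg.in_channels
        enc_out = []
        for i in range(L):
            out = F * (2 ** i)
            self.enc.append(_Block(c, out, rng))
            self.pools.append(MaxPool3d())
            enc_out.append(out)
            c = out
        self.ups: List[ConvTranspose3d] = []
        self.dec: List[_Block] = []
        for i in range(L - 1, -1, -1):
            self.ups.append(ConvTranspose3d(c, c, rng))
            c_in = c + (enc_out[i] if cfg.skip_connections else 0)
            out = F * (2 ** max(i - 1, 0))
            self.dec.append(_Block(c_in, out, rng))
            c = out
        self.head = Conv3d(c, cfg.out_channels, 1, rng)
        self.tanh = Tanh()

    # -- plumbing ---------------------------------------------------------
    def layers(self) -> List[Layer]:
        out: List[Layer] = []
        for b in self.enc:
            out.extend(b.layers)
        out.extend(self.pools)
        for u, b in zip(self.ups, self.dec):
            out.append(u)
            out.extend(b.layers)
        out.extend([self.head, self.tanh])
        return out

    def set_training(self, flag: bool) -> None:
        for l in self.layers():
            l.training = flag

    def num_parameters(self) -> int:
        return sum(int(p.size) for l in self.layers() for p in l.params.values())

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {}
        for i, l in enumerate(self.layers()):
            for k, v in l.params.items():
                state[f"{i}.{k}"] = v.copy()
            if isinstance(l, BatchNorm3d):
                state[f"{i}.running_mean"] = l.running_mean.copy()
                state[f"{i}.running_var"] = l.running_var.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self.layers()):
            for k in l.params:
                l.params[k][...] = state[f"{i}.{k}"]
            if isinstance(l, BatchNorm3d):
                l.running_mean[...] = state[f"{i}.running_mean"]
                l.running_var[...] = state[f"{i}.running_var"]

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Input (D,H,W), (N,D,H,W) or (N,D,H,W,C); output (N,D,H,W,C_out)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None, ..., None]
        elif x.ndim == 4:
            x = x[..., None]
        div = 2 ** self.cfg.levels
        for ax, s in enumerate(x.shape[1:4]):
            if s % div:
                raise ValueError(
                    f"spatial dim {s} on axis {ax} not divisible by 2^levels={div}")
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        self._skip_channels = []
        for u, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = u.forward(x)
            if self.cfg.skip_connections:
                self._skip_channels.append((x.shape[-1], skip.shape[-1]))
                x = np.concatenate([x, skip], axis=-1)
            x = blk.forward(x)
        x = self.head.forward(x)
        return self.tanh.forward(x)

    def backward(self, dy: np.ndarray) -> None:
        dy = self.tanh.backward(dy)
        dy = self.head.backward(dy)
        dskips: List[Optional[np.ndarray]] = [None] * len(self.enc)
        for j in range(len(self.dec) - 1, -1, -1):
            dy = self.dec[j].backward(dy)
            if self.cfg.skip_connections:
                c_up, c_skip = self._skip_channels[j]
                enc_idx = len(self.enc) - 1 - j
                dskips[enc_idx] = dy[..., c_up:]
                dy = np.ascontiguousarray(dy[..., :c_up])
            dy = self.ups[j].backward(dy)
        for i in range(len(self.enc) - 1, -1, -1):
            dy = self.pools[i].backward(dy)
            if dskips[i] is not None:
                dy = dy + dskips[i]
            dy = self.enc[i].backward(dy)

    __call__ = forward


def build_model(cfg: UNetConfig, seed: int = 0) -> UNet3D:
    return UNet3D(cfg, seed=seed)


def generalized_dice_loss(pred: np.ndarray, truth: np.ndarray,
                          eps: float = 1e-8,
                          with_grad: bool = False):
    """Two-class generalized Dice loss of a tanh score grid against a binary
    truth grid.

    With p = (pred+1)/2 and class weights w_l = 1/((sum_n r_ln)^2 + eps),
    loss = 1 - 2 (sum_l w_l sum_n r_ln p_ln) / (sum_l w_l sum_n (r_ln + p_ln)).
    Returns the loss, or ``(loss, dloss/dpred)`` when ``with_grad``.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if not np.all(np.isin(np.unique(truth), (0, 1))):
        raise ValueError("truth grid must be binary")
    r = truth.astype(np.float64)
    p = (pred + 1.0) / 2.0
    sf, sb = r.sum(), (1.0 - r).sum()
    wf, wb = 1.0 / (sf * sf + eps), 1.0 / (sb * sb + eps)
    num = wf * (r * p).sum() + wb * ((1.0 - r) * (1.0 - p)).sum()
    den = wf * (r + p).sum() + wb * ((1.0 - r) + (1.0 - p)).sum()
    loss = 1.0 - 2.0 * num / den
    if not with_grad:
        return float(loss)
    dnum = wf * r - wb * (1.0 - r)
    dden = wf - wb
    dp = -2.0 * (dnum * den - num * dden) / (den * den)
    return float(loss), (0.5 * dp).astype(np.float32)


def _stack(samples: Sequence[patching.PatchSample]):
    x = np.stack([s.intensities for s in samples]).astype(np.float32)
    y = np.stack([s.labels for s in samples]).astype(np.float32)[..., None]
    return x, y


def _eval_loss(model: UNet3D, samples, batch_size: int) -> float:
    model.set_training(False)
    total, nvox = 0.0, 0
    for i in range(0, len(samples), batch_size):
        x, y = _stack(samples[i:i + batch_size])
        pred = model.forward(x)
        total += generalized_dice_loss(pred, y) * x.shape[0]
        nvox += x.shape[0]
    model.set_training(True)
    return total / nvox


def train(model: UNet3D, train_samples: Sequence[patching.PatchSample],
          val_samples: Optional[Sequence[patching.PatchSample]],
          tcfg: TrainConfig) -> Tuple[UNet3D, Dict[str, list]]:
    """Adam / generalized-Dice training with early stopping on validation loss.

    Returns the model carrying the best-validation weights plus a history of
    per-epoch mean train and validation losses.  Deterministic given
    ``tcfg.seed``.
    """
    if len(train_samples) == 0:
        raise ValueError("train_samples must be nonempty")
    rng = np.random.default_rng(tcfg.seed)
    opt = Adam(model.layers(), lr=tcfg.learning_rate)
    history: Dict[str, list] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = model.state_dict()
    stall = 0
    model.set_training(True)
    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(len(train_samples))
        epoch_loss, nb = 0.0, 0
        for i in range(0, len(order), tcfg.batch_size):
            batch = [train_samples[j] for j in order[i:i + tcfg.batch_size]]
            x, y = _stack(batch)
            pred = model.forward(x)
            loss, dpred = generalized_dice_loss(pred, y, with_grad=True)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(dpred)
            opt.step()
            epoch_loss += loss
            nb += 1
        history["train_loss"].append(epoch_loss / nb)
        if val_samples:
            vloss = _eval_loss(model, val_samples, tcfg.batch_size)
            history["val_loss"].append(vloss)
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_state = model.state_dict()
                stall = 0
            else:
                stall += 1
                if stall >= tcfg.early_stop_patience:
                    break
        else:
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    model.set_training(False)
    return model, history


@dataclasses.dataclass
class FoldPlan:
    folds: List[Dict[str, List[str]]]
    seed: int


def make_folds(subject_ids: Sequence[str], seed: int = 0, n_folds: int = 5) -> FoldPlan:
    """Five-fold split: per fold n/5 test, n/5 validation, the rest train.

    Every subject is a test case in exactly one fold; the same seed gives
    the same plan, so models trained per sequence share their participant
    groups.
    """
    ids = list(subject_ids)
    n = len(ids)
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} subjects, got {n}")
    if n % n_folds:
        raise ValueError(f"number of subjects ({n}) must divide into {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(n)]
    chunk = n // n_folds
    chunks = [order[i * chunk:(i + 1) * chunk] for i in range(n_folds)]
    folds = []
    for f in range(n_folds):
        test = chunks[f]
        val = chunks[(f + 1) % n_folds]
        trainset = [s for c in range(n_folds) if c not in (f, (f + 1) % n_folds)
                    for s in chunks[c]]
        folds.append({"train": trainset, "val": val, "test": test})
    return FoldPlan(folds=folds, seed=seed)


def predict_scores(model: UNet3D, template_vol: ImageVolume,
                   atlas: ProbabilisticAtlas, patch_size: int = 64,
                   stride: Optional[int] = None, batch_size: int = 4) -> np.ndarray:
    """Sliding-window inference over the atlas crop box; mean-overlap scores
    on the full template grid, -1 where no window reaches."""
    stride = stride or patch_size // 2
    starts = patching.sliding_window_starts(atlas.crop_box, patch_size, stride,
                                            template_vol.shape)
    model.set_training(False)
    pieces = []
    for i in range(0, len(starts), batch_size):
        chunk = starts[i:i + batch_size]
        x = np.stack([template_vol.data[s[0]:s[0] + patch_size,
                                        s[1]:s[1] + patch_size,
                                        s[2]:s[2] + patch_size] for s in chunk])
        scores = model.forward(x.astype(np.float32))[..., 0]
        pieces.extend(zip(chunk, scores))
    return patching.assemble_patches(pieces, template_vol.shape, background=-1.0)


def segment_subject(model: UNet3D, native_vol: ImageVolume, t: SpatialTransform,
                    atlas: ProbabilisticAtlas, patch_size: int = 64,
                    stride: Optional[int] = None
                    ) -> Tuple[ImageVolume, LabelMask, float]:
    """Full-subject segmentation: native -> template resampling, cropped
    sliding-window inference, reassembly, binarization at score > 0,
    inverse nearest-neighbour resampling, volume in cm^3."""
    template_grid = (atlas.prob.shape, atlas.affine)
    tvol = resample_to_template(native_vol, t, template_grid, interp="linear")
    scores = predict_scores(model, tvol, atlas, patch_size=patch_size, stride=stride)
    mask_t = LabelMask((scores > 0).astype(np.uint8), atlas.affine.copy())
    mask_n = inverse_resample_mask(mask_t, t, (native_vol.shape, native_vol.affine))
    score_vol = ImageVolume(scores.astype(np.float32), atlas.affine.copy())
    return score_vol, mask_n, mask_volume_cm3(mask_n)


def save_model(model: UNet3D, path) -> None:
    """Checkpoint: weights + embedded architecture config."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(dataclasses.asdict(model.cfg)).encode(), dtype=np.uint8)
    np.savez_compressed(str(path), **state)


def load_model(path) -> UNet3D:
    with np.load(str(path)) as data:
        cfg = UNetConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = UNet3D(cfg)
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    model.set_training(False)
    return model
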