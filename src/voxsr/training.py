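"""Training and evaluation: splits, scale-generic sampling, the optimisation
loop with gradient accumulation, checkpointing, and full-volume evaluation.

The training regime mirrors the patch-based recipe the architectures were
designed for: every epoch the subject order is shuffled, a fixed number of
patches per volume is drawn uniformly at random with the low-resolution
(pre-interpolated) and high-resolution patches cut at identical corners,
gradients are accumulated to reach the configured effective batch size,
and Adam updates the weights.  Validation runs every epoch; the learning
rate is reduced on a validation plateau and the best-validation weights
are kept.  Evaluation metrics are always computed on grid-aggregated full
volumes, never on patches.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from voxsr.degradation import (
    DEFAULT_FACTORS,
    PairedSample,
    ScaleFactor,
    make_pair,
    theoretical_acceleration,
)
from voxsr.errors import DivergenceError, ParameterError
from voxsr.nn import Adam, ReduceLROnPlateau, Tensor
from voxsr.objectives import LossSpec, mse, nrmse, psnr, ssim, training_loss
from voxsr.patching import (
    PatchSpec,
    _pad_volume_data,
    _padding,
    aggregate,
    extract_grid_patches,
    plan_grid,
)
from voxsr.volumes import Volume


@dataclass(frozen=True)
class SplitSpec:
    """Subject split: 70% training; of the remaining 30%, 60% test, 40% validation."""

    train_fraction: float = 0.70
    test_fraction_of_rest: float = 0.60


def split_subjects(n: int, spec: SplitSpec = SplitSpec()):
    """Floor-based split counts ``(train, test, val)`` summing to ``n``."""
    if n < 3:
        raise ParameterError("need at least 3 subjects to split")
    train = int(np.floor(spec.train_fraction * n))
    rest = n - train
    test = int(np.floor(spec.test_fraction_of_rest * rest))
    val = rest - test
    return train, test, val


def split_indices(n: int, spec: SplitSpec = SplitSpec(), seed: int = 0):
    """Deterministic subject assignment: a seeded shuffle partitioned by
    :func:`split_subjects`; returns (train_idx, test_idx, val_idx)."""
    train, test, val = split_subjects(n, spec)
    order = np.random.default_rng(seed).permutation(n)
    return (
        np.sort(order[:train]),
        np.sort(order[train : train + test]),
        np.sort(order[train + test :]),
    )


def assign_epoch_scales(volume_ids, scale_set, epoch: int, seed: int):
    """Independent uniform factor draw per (volume, epoch); deterministic."""
    scale_set = list(scale_set)
    if not scale_set:
        raise ParameterError("scale set must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(epoch), 17]))
    draws = rng.integers(0, len(scale_set), size=len(volume_ids))
    return {vid: scale_set[k] for vid, k in zip(volume_ids, draws)}


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run."""

    learning_rate: float = 1e-4
    epochs: int = 50
    effective_batch: int = 22
    micro_batch: int = 1
    plateau_patience: int = 3
    plateau_factor: float = 0.1
    patches_per_volume: int = 60
    patch_size: int = 64
    val_patches_per_volume: int = 4
    seed: int = 0
    scale_set: tuple = DEFAULT_FACTORS
    loss: LossSpec = field(default_factory=LossSpec)
    scale_generic: bool = True

    def __post_init__(self):
        if self.effective_batch % self.micro_batch:
            raise ParameterError("effective_batch must be a multiple of micro_batch")
        if self.epochs < 1 or self.patches_per_volume < 1:
            raise ParameterError("epochs and patches_per_volume must be positive")

    @property
    def accumulation_steps(self) -> int:
        return self.effective_batch // self.micro_batch


@dataclass
class TrainingRun:
    """Per-epoch loss history plus the best-validation checkpoint."""

    history: list = field(default_factory=list)
    best_epoch: int = -1
    best_val: float = np.inf
    best_state: dict = field(default_factory=dict)
    seed: int = 0

    def restore_best(self, model):
        for name, p in model.named_parameters():
            p.data[...] = self.best_state[name]
        return model


def _aligned_patches(pair: PairedSample, n: int, size: int, seed: int):
    """Cut (lr_interp, hr) patch pairs at identical uniformly random corners."""
    spec3 = (size, size, size)
    before, after = _padding(pair.hr.shape, spec3)
    lr = _pad_volume_data(pair.lr_interp.data, before, after)
    hr = _pad_volume_data(pair.hr.data, before, after)
    rng = np.random.default_rng(seed)
    hi = [d - s + 1 for d, s in zip(lr.shape, spec3)]
    corners = rng.integers(0, hi, size=(n, 3))
    out = []
    for c in corners:
        sl = tuple(slice(int(ci), int(ci) + size) for ci in c)
        out.append((lr[sl][None], hr[sl][None]))  # add channel axis
    return out


def _pairs_for_epoch(subjects, cfg: TrainConfig, epoch: int):
    """Resolve the epoch's training pairs.

    ``subjects`` is either a list of ready PairedSamples (used as-is) or a
    list of high-resolution Volumes, in which case a per-(volume, epoch)
    uniform random scale factor is drawn and the degradation is applied on
    the fly (the scale-generic regime).
    """
    if subjects and isinstance(subjects[0], PairedSample):
        return list(subjects)
    ids = [v.ident or str(i) for i, v in enumerate(subjects)]
    factors = assign_epoch_scales(ids, cfg.scale_set, epoch, cfg.seed)
    return [
        make_pair(v, ScaleFactor.isotropic(factors[vid]))
        for vid, v in zip(ids, subjects)
    ]


def _epoch_loss(model, loss_fn, patch_pairs, optimizer, cfg, train=True):
    """One pass over ``patch_pairs``; returns the mean loss.

    With training on, gradients of (loss / batch) are accumulated over each
    effective batch before an Adam step, so the update equals the gradient
    of the mean batch loss regardless of accumulation chunking.
    """
    losses = []
    n = len(patch_pairs)
    if train:
        batches = [
            patch_pairs[i : i + cfg.effective_batch]
            for i in range(0, n, cfg.effective_batch)
        ]
    else:
        batches = [patch_pairs]
    for batch in batches:
        if train:
            optimizer.zero_grad()
        for lr_p, hr_p in batch:
            out = model(Tensor(lr_p))
            loss = loss_fn(out, hr_p)
            losses.append(loss.item())
            if train:
                scaled = loss * (1.0 / len(batch))
                scaled.backward()
        if train:
            optimizer.step()
    return float(np.mean(losses))


def train(model, subjects, cfg: TrainConfig, val_subjects=None) -> TrainingRun:
    """Optimise ``model`` on ``subjects`` under ``cfg``.

    ``subjects``/``val_subjects`` are lists of PairedSamples (fixed factor)
    or high-resolution Volumes (scale-generic per-epoch factor draw).  The
    model must already be initialised.  Fully deterministic given
    ``cfg.seed`` on a fixed platform.
    """
    if not subjects:
        raise ParameterError("training set is empty")
    loss_fn = training_loss(cfg.loss, model.spec.name)
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    scheduler = ReduceLROnPlateau(
        optimizer, patience=cfg.plateau_patience, factor=cfg.plateau_factor
    )
    run = TrainingRun(seed=cfg.seed)
    for epoch in range(cfg.epochs):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, epoch]))
        pairs = _pairs_for_epoch(subjects, cfg, epoch)
        order = rng.permutation(len(pairs))
        patch_pairs = []
        for j in order:
            patch_seed = int(rng.integers(0, 2 ** 31))
            patch_pairs.extend(
                _aligned_patches(pairs[j], cfg.patches_per_volume, cfg.patch_size, patch_seed)
            )
        # mix subjects within the epoch: seeded permutation of the patch list
        mix = rng.permutation(len(patch_pairs))
        patch_pairs = [patch_pairs[k] for k in mix]
        train_loss_val = _epoch_loss(model, loss_fn, patch_pairs, optimizer, cfg, train=True)
        if not np.isfinite(train_loss_val):
            raise DivergenceError(epoch)

        if val_subjects:
            vpairs = _pairs_for_epoch(val_subjects, cfg, epoch)
            vpatches = []
            for i, p in enumerate(vpairs):
                vpatches.extend(
                    _aligned_patches(
                        p, cfg.val_patches_per_volume, cfg.patch_size,
                        int(np.random.default_rng([cfg.seed, 991, i]).integers(2 ** 31)),
                    )
                )
            val_loss_val = _epoch_loss(model, loss_fn, vpatches, optimizer, cfg, train=False)
        else:
            val_loss_val = train_loss_val
        reduced = scheduler.step(val_loss_val)
        run.history.append(
            {
                "epoch": epoch,
                "train_loss": train_loss_val,
                "val_loss": val_loss_val,
                "lr": optimizer.lr,
                "lr_reduced": bool(reduced),
            }
        )
        if val_loss_val < run.best_val:
            run.best_val = val_loss_val
            run.best_epoch = epoch
            run.best_state = {
                name: p.data.copy() for name, p in model.named_parameters()
            }
    if run.best_state:
        run.restore_best(model)
    return run


# ------------------------------------------------------------- inference

def predict_volume(model, v: Volume, patch: PatchSpec) -> Volume:
    """Grid-infer ``v`` patch by patch and aggregate with equal-weight
    averaging; output clipped to [0, 1]."""
    grid = plan_grid(v.shape, patch)
    patches = extract_grid_patches(v, grid)
    preds = []
    for p in patches:
        out = model.infer(Tensor(p.data[None].astype(np.float32)))
        preds.append((p, out.data[0]))
    sr = aggregate(preds, grid, like=v)
    return sr.with_data(np.clip(sr.data, 0.0, 1.0))


@dataclass
class MetricsReport:
    """Per-volume metric rows plus mean +/- sd summary."""

    rows: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _summarise(rows):
    metrics = ("ssim", "psnr", "nrmse", "mse")
    out = {}
    for m in metrics:
        vals = np.array([r[m] for r in rows], dtype=float)
        finite = vals[np.isfinite(vals)]
        out[m] = {
            "mean": float(finite.mean()) if finite.size else np.nan,
            "sd": float(finite.std(ddof=1)) if finite.size > 1 else 0.0,
        }
    return out


def evaluate(model, pairs, patch: PatchSpec = PatchSpec()) -> MetricsReport:
    """Full-volume evaluation of ``model`` on PairedSamples."""
    rows = []
    for pair in pairs:
        sr = predict_volume(model, pair.lr_interp, patch)
        rows.append(
            {
                "id": pair.sample_id,
                "factor": theoretical_acceleration(pair.factor),
                "contrast": pair.hr.contrast_tag or "",
                "ssim": ssim(sr, pair.hr),
                "psnr": psnr(sr, pair.hr),
                "nrmse": nrmse(sr, pair.hr),
                "mse": mse(sr, pair.hr),
            }
        )
    return MetricsReport(rows=rows, summary=_summarise(rows))


def baseline_report(pairs, patch: PatchSpec = PatchSpec()) -> MetricsReport:
    """Metrics of the sinc-interpolated inputs themselves (identity model)."""
    rows = []
    for pair in pairs:
        rows.append(
            {
                "id": pair.sample_id,
                "factor": theoretical_acceleration(pair.factor),
                "contrast": pair.hr.contrast_tag or "",
                "ssim": ssim(pair.lr_interp, pair.hr),
                "psnr": psnr(pair.lr_interp, pair.hr),
                "nrmse": nrmse(pair.lr_interp, pair.hr),
                "mse": mse(pair.lr_interp, pair.hr),
            }
        )
    return MetricsReport(rows=rows, summary=_summarise(rows))
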