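"""Desk-scale reference experiments.

These functions reproduce, at phantom scale on one CPU, the two headline
analyses of the pipeline: (1) a reduced-width UNet trained on synthetic
phantoms outperforms the traditional interpolation baselines (nearest,
bicubic, sinc) in mean SSIM at 2x-per-axis downsampling, and (2) the
grey-box uncertainty pipeline produces variance maps that grow with the
perturbation strength and can be correlated with the L1 error map.

The configuration is deliberately small and frozen: 20 phantoms of 96^3
voxels, an 8-channel-wide depth-2 UNet trained for 10 epochs with the
SSIM loss (learning rate 1e-3, effective batch 4, 16 random 32^3 patches
per volume per epoch), evaluated on whole volumes.  Every random choice
derives from the single ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from voxsr.degradation import ScaleFactor, interpolate_baseline, make_pair, sinc_resample
from voxsr.models import ArchitectureSpec, build_model
from voxsr.nn import init_xavier_uniform
from voxsr.objectives import LossSpec, ssim
from voxsr.patching import PatchSpec
from voxsr.synthesis import PhantomSpec, generate_phantom
from voxsr.training import TrainConfig, evaluate, split_indices, train
from voxsr.uncertainty import (
    PerturbationConfig,
    error_correlation,
    uncertainty_map,
)
from voxsr.volumes import Volume

HEADLINE_N_PHANTOMS = 20
HEADLINE_SHAPE = (96, 96, 96)
HEADLINE_FACTOR = 2.0
HEADLINE_EPOCHS = 10

REDUCED_UNET = dict(unet_depth=2, unet_base_width=8)

HEADLINE_TRAIN = dict(
    learning_rate=1e-3,
    epochs=HEADLINE_EPOCHS,
    effective_batch=4,
    micro_batch=1,
    patches_per_volume=16,
    patch_size=32,
    val_patches_per_volume=2,
    scale_set=(HEADLINE_FACTOR,),
)


def _volume_patch(shape) -> PatchSpec:
    return PatchSpec(size=tuple(shape), overlap=(0, 0, 0))


@dataclass
class HeadlineResult:
    """Mean SSIM of the trained model against the interpolation baselines."""

    model_ssim: float
    sinc_ssim: float
    nearest_ssim: float
    bicubic_ssim: float
    per_volume_model: list
    per_volume_sinc: list
    history: list
    model: object = field(repr=False, default=None)
    pairs: list = field(repr=False, default_factory=list)


def headline_superresolution(seed: int, n_phantoms: int = HEADLINE_N_PHANTOMS,
                             epochs: int = HEADLINE_EPOCHS) -> HeadlineResult:
    """Train the reduced-width UNet and compare with interpolation baselines.

    Phantoms are generated from ``seed``; the subject split follows the
    70/18/12 bookkeeping (training subjects train the network, validation
    subjects drive the plateau schedule and best-checkpoint choice); the
    comparison reports mean SSIM over all phantoms.
    """
    phantoms = [
        generate_phantom(PhantomSpec(shape=HEADLINE_SHAPE, seed=seed * 1000 + i))
        for i in range(n_phantoms)
    ]
    factor = ScaleFactor.isotropic(HEADLINE_FACTOR)
    pairs = [make_pair(v, factor) for v in phantoms]

    tr_idx, te_idx, va_idx = split_indices(len(pairs), seed=seed)
    train_pairs = [pairs[i] for i in tr_idx]
    val_pairs = [pairs[i] for i in va_idx]

    spec = ArchitectureSpec("unet", **REDUCED_UNET)
    model = init_xavier_uniform(build_model(spec), seed=seed)
    cfg = TrainConfig(seed=seed, loss=LossSpec(kind="ssim"),
                      **{**HEADLINE_TRAIN, "epochs": epochs})
    run = train(model, train_pairs, cfg, val_subjects=val_pairs)

    patch = _volume_patch(HEADLINE_SHAPE)
    report = evaluate(model, pairs, patch)
    model_ssims = [r["ssim"] for r in report.rows]

    sinc_ssims = [ssim(p.lr_interp, p.hr) for p in pairs]
    nearest_ssims, bicubic_ssims = [], []
    for p in pairs:
        lr_dims = tuple(int(np.floor(n / HEADLINE_FACTOR)) for n in p.hr.shape)
        lr = sinc_resample(p.hr, lr_dims)
        lr = lr.with_data(np.clip(lr.data, 0.0, 1.0))
        for method, bucket in (("nearest", nearest_ssims), ("bicubic", bicubic_ssims)):
            up = interpolate_baseline(lr, p.hr.shape, method)
            up = up.with_data(np.clip(up.data, 0.0, 1.0))
            bucket.append(ssim(up, p.hr))

    return HeadlineResult(
        model_ssim=float(np.mean(model_ssims)),
        sinc_ssim=float(np.mean(sinc_ssims)),
        nearest_ssim=float(np.mean(nearest_ssims)),
        bicubic_ssim=float(np.mean(bicubic_ssims)),
        per_volume_model=model_ssims,
        per_volume_sinc=sinc_ssims,
        history=run.history,
        model=model,
        pairs=pairs,
    )


@dataclass
class UncertaintyResult:
    """Perturbation-strength sanity and L1-map correlation on one volume."""

    mean_variance_weak: float
    mean_variance_strong: float
    l1_correlation: float
    n_runs: int


def uncertainty_analysis(model, pair, seed: int, weak: float = 0.01,
                         strong: float = 0.5, n_runs: int = 5,
                         mode: str = "infer_dropout") -> UncertaintyResult:
    """Grey-box uncertainty sanity on a trained model.

    For each of ``n_runs`` seeds, builds a 2-image variance map at the weak
    and at the strong perturbation parameter and averages the map means;
    also computes the Pearson correlation between a full multi-parameter
    uncertainty map and the per-voxel L1 error of the unperturbed
    prediction.
    """
    patch = _volume_patch(pair.hr.shape)
    weak_means, strong_means = [], []
    for k in range(n_runs):
        for param, bucket in ((weak, weak_means), (strong, strong_means)):
            cfg = PerturbationConfig(
                mode=mode, params=(param,), samples_per_param=2,
                seed=seed * 100 + k,
            )
            umap = uncertainty_map(model, pair.lr_interp, cfg, patch)
            bucket.append(float(umap.variance.mean()))
    full_cfg = PerturbationConfig(mode=mode, seed=seed)
    full_map = uncertainty_map(model, pair.lr_interp, full_cfg, patch)
    from voxsr.training import predict_volume

    pred = predict_volume(model, pair.lr_interp, patch)
    corr = error_correlation(full_map, pred, pair.hr)
    return UncertaintyResult(
        mean_variance_weak=float(np.mean(weak_means)),
        mean_variance_strong=float(np.mean(strong_means)),
        l1_correlation=corr,
        n_runs=n_runs,
    )
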