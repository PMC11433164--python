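"""Training-free grey-box uncertainty mapping.

A trained network is perturbed at known internal sites during inference
only — either voxel-wise dropout at a given rate or additive Gaussian
noise with a given sigma, the same parameter at every site.  One
grid-aggregated prediction is generated per (parameter, sample) pair and
the uncertainty map is the voxel-wise population variance across the
prediction stack.  The map can then be compared against the per-voxel
absolute error (L1 map) by Pearson correlation.

Sites follow the architecture: the RRDB exposes one site at the end of
each of its three dense blocks; UNet and UNetMSS expose five sites —
after each contraction block, the bottleneck, and each expansion block.
The other architectures are not instrumented.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from voxsr.errors import ParameterError
from voxsr.models import ArchitectureSpec, disarm_all_sites
from voxsr.patching import PatchSpec
from voxsr.training import predict_volume
from voxsr.volumes import Volume

DEFAULT_PARAMS = (0.01, 0.02, 0.05, 0.1, 0.2, 0.5)

_MODES = ("infer_dropout", "infer_noise")


@dataclass(frozen=True)
class PerturbationConfig:
    """Which perturbation to apply, at which strengths, how many samples."""

    mode: str = "infer_dropout"
    params: tuple = DEFAULT_PARAMS
    samples_per_param: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ParameterError(f"mode must be one of {_MODES}")
        if not self.params:
            raise ParameterError("params must be non-empty")
        for p in self.params:
            if p <= 0 or (self.mode == "infer_dropout" and p > 1):
                raise ParameterError(
                    f"invalid perturbation parameter {p} for {self.mode}"
                )
        if self.samples_per_param < 1:
            raise ParameterError("samples_per_param must be >= 1")

    @property
    def n_images(self) -> int:
        return len(self.params) * self.samples_per_param


@dataclass
class UncertaintyMap:
    """Voxel-wise variance over perturbed predictions."""

    variance: np.ndarray
    n_images: int
    config: PerturbationConfig
    mean_prediction: np.ndarray | None = None


def perturbation_sites(arch: ArchitectureSpec):
    """Ordered site names for the instrumented architectures."""
    if arch.name == "rrdb":
        return [f"block{i + 1}" for i in range(arch.rrdb_blocks)]
    if arch.name in ("unet", "unetmss"):
        d = arch.unet_depth
        return (
            [f"enc{i + 1}" for i in range(d)]
            + ["bottleneck"]
            + [f"dec{i + 1}" for i in range(d)]
        )
    raise ParameterError(
        f"architecture {arch.name!r} has no perturbation sites "
        "(only rrdb, unet and unetmss are instrumented)"
    )


def infer_perturbed(model, v: Volume, mode: str, param: float, seed: int,
                    patch: PatchSpec = PatchSpec()) -> Volume:
    """One grid-aggregated prediction with the perturbation armed at every site.

    ``param`` = dropout rate or noise sigma; ``param = 0`` reduces to the
    unperturbed prediction.  Deterministic given ``seed``.
    """
    if mode not in _MODES:
        raise ParameterError(f"mode must be one of {_MODES}")
    if param < 0 or (mode == "infer_dropout" and param >= 1):
        raise ParameterError(f"invalid perturbation parameter {param}")
    sites = perturbation_sites(model.spec)
    layer_mode = "dropout" if mode == "infer_dropout" else "noise"
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    try:
        for name in sites:
            model.sites[name].configure(layer_mode, param, rng)
        return predict_volume(model, v, patch)
    finally:
        disarm_all_sites(model)


def uncertainty_map(model, v: Volume, cfg: PerturbationConfig,
                    patch: PatchSpec = PatchSpec()) -> UncertaintyMap:
    """Voxel-wise variance across one prediction per (param, sample) pair."""
    if cfg.n_images < 2:
        raise ParameterError(
            "need at least 2 perturbed predictions for a variance map"
        )
    stack = []
    i = 0
    for param in cfg.params:
        for _ in range(cfg.samples_per_param):
            seed_i = int(
                np.random.SeedSequence([cfg.seed, i]).generate_state(1)[0] % (2 ** 31)
            )
            pred = infer_perturbed(model, v, cfg.mode, param, seed_i, patch)
            stack.append(pred.data.astype(np.float64))
            i += 1
    arr = np.stack(stack)
    return UncertaintyMap(
        variance=arr.var(axis=0),
        n_images=len(stack),
        config=cfg,
        mean_prediction=arr.mean(axis=0).astype(np.float32),
    )


def error_correlation(u: UncertaintyMap, prediction, gt) -> float:
    """Pearson correlation between the variance map and the L1 error map.

    Returns ``nan`` (with a warning) when either map is constant — e.g.
    when all perturbed predictions agree and the variance is identically
    zero, the correlation is undefined.
    """
    pred = np.asarray(prediction.data if isinstance(prediction, Volume) else prediction)
    gta = np.asarray(gt.data if isinstance(gt, Volume) else gt)
    if not (u.variance.shape == pred.shape == gta.shape):
        raise ParameterError("variance, prediction and gt must share dims")
    err = np.abs(pred.astype(np.float64) - gta.astype(np.float64)).ravel()
    var = u.variance.ravel()
    if var.std() == 0 or err.std() == 0:
        warnings.warn(
            "uncertainty/error correlation undefined: one of the maps is constant"
        )
        return math.nan
    return float(np.corrcoef(var, err)[0, 1])


def summarize_nonzero_variance(maps):
    """Per-map mean over non-zero voxels (values ready for a KDE plot).

    All-zero maps are excluded with a warning; an empty result means every
    map was identically zero.
    """
    if not maps:
        raise ParameterError("need at least one uncertainty map")
    values = []
    for m in maps:
        nz = m.variance[m.variance > 0]
        if nz.size == 0:
            warnings.warn("excluding an all-zero variance map from the summary")
            continue
        values.append(float(nz.mean()))
    return np.asarray(values)
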