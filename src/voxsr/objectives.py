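"""Losses and evaluation metrics.

Two parallel surfaces live here:

* plain numpy metric functions operating on :class:`~voxsr.volumes.Volume`
  or bare arrays (SSIM, L1, MSE, Sobel gradients, mGE/MGL, MSS
  combination, PSNR, NRMSE) — these are what evaluation reports;
* differentiable training losses over :class:`~voxsr.nn.Tensor`, used by
  the training loop (``training_loss`` builds the right one for each
  architecture, including the SPSR gradient-map supervision and the
  UNetMSS multi-scale combination).

SSIM follows the windowed formulation with Gaussian weights (window 11,
sigma 1.5, k1 = 0.01, k2 = 0.03, population covariances); the reported
value is the mean of the local SSIM map with the filter-support border
cropped.  L1 and MSE are reported as per-voxel means so values are
comparable across patch and volume sizes.  NRMSE divides RMSE by the
ground-truth intensity range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from voxsr import nn
from voxsr.errors import ParameterError, ShapeError
from voxsr.nn import functional as F
from voxsr.nn.tensor import Tensor, absolute, mean, square
from voxsr.volumes import Volume

LOSS_KINDS = ("ssim", "l1", "mse", "mgl")


@dataclass(frozen=True)
class LossSpec:
    """Loss selection and its constants."""

    kind: str = "ssim"
    window_size: int = 11
    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 1.0
    lambda_g: float = 1.0
    mss_scales: int = 3
    mss_weights: tuple | None = None  # None = equal weights
    spsr_gradient_weight: float = 1.0

    def __post_init__(self):
        if self.kind not in LOSS_KINDS:
            raise ParameterError(f"loss kind must be one of {LOSS_KINDS}")
        if self.window_size % 2 == 0 or self.window_size < 3:
            raise ParameterError("window_size must be odd and >= 3")
        if min(self.k1, self.k2, self.dynamic_range) <= 0:
            raise ParameterError("k1, k2 and dynamic_range must be positive")
        if self.mss_weights is not None and any(w <= 0 for w in self.mss_weights):
            raise ParameterError("mss weights must be positive")


def _arr(v) -> np.ndarray:
    return np.asarray(v.data if isinstance(v, Volume) else v, dtype=np.float64)


def _pair(a, b):
    a, b = _arr(a), _arr(b)
    if a.shape != b.shape:
        raise ShapeError(f"volume dims differ: {a.shape} vs {b.shape}")
    return a, b


# ------------------------------------------------------------------ SSIM

def _gaussian_kernel(size: int, sigma: float = 1.5) -> np.ndarray:
    r = size // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-(x ** 2) / (2 * sigma ** 2))
    return k / k.sum()


def _gaussian_filter(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    for ax in range(x.ndim):
        x = ndimage.correlate1d(x, kernel, axis=ax, mode="reflect")
    return x


def ssim(a, b, spec: LossSpec = LossSpec()) -> float:
    """Mean structural similarity over Gaussian-weighted sliding windows."""
    a, b = _pair(a, b)
    if min(a.shape) < spec.window_size:
        raise ParameterError(
            f"volume dims {a.shape} smaller than the SSIM window {spec.window_size}"
        )
    c1 = (spec.k1 * spec.dynamic_range) ** 2
    c2 = (spec.k2 * spec.dynamic_range) ** 2
    k = _gaussian_kernel(spec.window_size)
    mu_a = _gaussian_filter(a, k)
    mu_b = _gaussian_filter(b, k)
    mu_aa = _gaussian_filter(a * a, k)
    mu_bb = _gaussian_filter(b * b, k)
    mu_ab = _gaussian_filter(a * b, k)
    var_a = mu_aa - mu_a ** 2
    var_b = mu_bb - mu_b ** 2
    cov = mu_ab - mu_a * mu_b
    s = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)
    )
    pad = spec.window_size // 2
    core = s[pad:-pad, pad:-pad, pad:-pad]
    return float(core.mean())


def ssim_loss(a, b, spec: LossSpec = LossSpec()) -> float:
    """1 - mean SSIM."""
    return 1.0 - ssim(a, b, spec)


# ---------------------------------------------------------- basic errors

def l1(a, b) -> float:
    """Mean absolute difference per voxel."""
    a, b = _pair(a, b)
    return float(np.abs(a - b).mean())


def mse(a, b) -> float:
    """Mean squared difference per voxel."""
    a, b = _pair(a, b)
    return float(((a - b) ** 2).mean())


def psnr(a, b, dynamic_range: float = 1.0) -> float:
    """10 log10(L^2 / MSE) in dB; +inf for identical volumes."""
    err = mse(a, b)
    if err == 0:
        return math.inf
    return float(10.0 * np.log10(dynamic_range ** 2 / err))


def nrmse(a, b) -> float:
    """RMSE normalised by the ground-truth (second argument) intensity range."""
    a, b = _pair(a, b)
    rng = float(b.max() - b.min())
    if rng == 0:
        raise ParameterError("ground truth has zero intensity range")
    return float(np.sqrt(((a - b) ** 2).mean()) / rng)


# -------------------------------------------------------- Sobel gradients

@dataclass
class GradientMap:
    """Per-voxel Sobel gradient components and magnitude."""

    magnitude: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray


_SOBEL_DERIV = np.array([-1.0, 0.0, 1.0])
_SOBEL_SMOOTH = np.array([1.0, 2.0, 1.0])


def sobel_gradient(v) -> GradientMap:
    """3D Sobel gradients by separable filtering.

    Each component applies the derivative kernel [-1, 0, 1] along its own
    axis and the smoothing kernel [1, 2, 1] along the two others; the
    magnitude is the Euclidean norm of the three components.  Borders use
    reflected samples so that a constant volume has an exactly zero
    gradient everywhere (zero padding would manufacture spurious edges at
    the volume boundary).
    """
    a = _arr(v)
    if min(a.shape) < 3:
        raise ParameterError(f"volume dims {a.shape} too small for the Sobel operator")
    comps = []
    for axis in range(3):
        g = a
        for ax in range(3):
            kern = _SOBEL_DERIV if ax == axis else _SOBEL_SMOOTH
            g = ndimage.correlate1d(g, kern, axis=ax, mode="reflect")
        comps.append(g)
    gx, gy, gz = comps
    mag = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)
    return GradientMap(magnitude=mag, gx=gx, gy=gy, gz=gz)


def mean_gradient_error(a, b) -> float:
    """Mean squared difference of the Sobel gradient magnitudes."""
    a, b = _pair(a, b)
    ga = sobel_gradient(a).magnitude
    gb = sobel_gradient(b).magnitude
    return float(((ga - gb) ** 2).mean())


def mixed_gradient_loss(a, b, spec: LossSpec = LossSpec(kind="mgl")) -> float:
    """MSE + lambda_G * mean gradient error."""
    a, b = _pair(a, b)
    return mse(a, b) + spec.lambda_g * mean_gradient_error(a, b)


# ------------------------------------------------- multi-scale supervision

def _nearest_upsample_nd(x: np.ndarray, target_shape) -> np.ndarray:
    for ax, (n, m) in enumerate(zip(x.shape, target_shape)):
        if m != n:
            centres = (np.arange(m) + 0.5) * n / m
            idx = np.clip(np.floor(centres).astype(int), 0, n - 1)
            x = np.take(x, idx, axis=ax)
    return x


def mss_loss(outputs, gt, base, spec: LossSpec = LossSpec()) -> float:
    """Weighted multi-scale combination of a base loss.

    ``outputs`` are per-scale predictions ordered full scale first; each
    lower-scale output is upsampled to the ground-truth dims with
    nearest-neighbour interpolation, the base loss is evaluated per
    scale, and the scale losses are combined as the alpha-weighted mean
    (invariant to rescaling all weights by a common factor).
    """
    outputs = list(outputs)
    weights = spec.mss_weights
    if weights is None:
        weights = tuple(1.0 for _ in outputs)
    if len(weights) != len(outputs):
        raise ParameterError(
            f"got {len(outputs)} scales but {len(weights)} weights"
        )
    gt_a = _arr(gt)
    total = 0.0
    for w, out in zip(weights, outputs):
        up = _nearest_upsample_nd(_arr(out), gt_a.shape)
        total += w * base(up, gt_a)
    return float(total / sum(weights))


# ======================================================================
# differentiable training losses (numpy autodiff tensors)
# ======================================================================

def l1_loss_t(pred: Tensor, target: np.ndarray) -> Tensor:
    return mean(absolute(pred - Tensor(target)))


def mse_loss_t(pred: Tensor, target: np.ndarray) -> Tensor:
    return mean(square(pred - Tensor(target)))


def ssim_loss_t(pred: Tensor, target: np.ndarray, spec: LossSpec = LossSpec()) -> Tensor:
    """Differentiable 1 - mean SSIM (zero-padded Gaussian windows).

    The training variant keeps the border windows (no crop); the metric
    in :func:`ssim` crops them, which only matters in the third decimal
    on realistic patches.
    """
    c1 = (spec.k1 * spec.dynamic_range) ** 2
    c2 = (spec.k2 * spec.dynamic_range) ** 2
    k = _gaussian_kernel(spec.window_size).astype(np.float32)
    t = Tensor(target)

    def blur(x: Tensor) -> Tensor:
        for ax in (1, 2, 3):
            x = F.correlate1d(x, k, ax)
        return x

    mu_a = blur(pred)
    mu_b = blur(t)
    mu_aa = blur(square(pred))
    mu_bb = blur(square(t))
    mu_ab = blur(pred * t)
    var_a = mu_aa - square(mu_a)
    var_b = mu_bb - square(mu_b)
    cov = mu_ab - mu_a * mu_b
    num = (2.0 * (mu_a * mu_b) + c1) * (2.0 * cov + c2)
    den = (square(mu_a) + square(mu_b) + c1) * (var_a + var_b + c2)
    return 1.0 - mean(num / den)


def mgl_loss_t(pred: Tensor, target: np.ndarray, spec: LossSpec) -> Tensor:
    gt_mag = F.sobel_magnitude(Tensor(target))
    pr_mag = F.sobel_magnitude(pred)
    return mse_loss_t(pred, target) + spec.lambda_g * mean(
        square(pr_mag - gt_mag)
    )


def _base_loss_t(spec: LossSpec):
    if spec.kind == "ssim":
        return lambda p, t: ssim_loss_t(p, t, spec)
    if spec.kind == "l1":
        return l1_loss_t
    if spec.kind == "mse":
        return mse_loss_t
    if spec.kind == "mgl":
        return lambda p, t: mgl_loss_t(p, t, spec)
    raise ParameterError(spec.kind)


def training_loss(spec: LossSpec, arch_name: str):
    """Build the architecture-appropriate differentiable loss.

    Returns ``fn(model_output, hr_patch) -> Tensor`` where ``hr_patch`` is a
    ``(1, D, H, W)`` array and ``model_output`` is whatever the
    architecture's forward produced: a tensor (rrdb, unet, shuffleunet), a
    list of per-scale outputs (unetmss), or an ``(sr, gradient_map)`` pair
    (spsr).
    """
    base = _base_loss_t(spec)

    if arch_name == "unetmss":
        def fn(outputs, target):
            outputs = list(outputs)
            # the unetmss forward yields the full scale first, deepest last
            weights = spec.mss_weights or tuple(1.0 for _ in outputs)
            if len(weights) != len(outputs):
                raise ParameterError("mss weight/scale count mismatch")
            total = None
            for w, out in zip(weights, outputs):
                factors = [t // o for t, o in zip(target.shape[1:], out.shape[1:])]
                up = F.upsample_nearest(out, factors) if max(factors) > 1 else out
                term = (w / sum(weights)) * base(up, target)
                total = term if total is None else total + term
            return total
        return fn

    if arch_name == "spsr":
        def fn(outputs, target):
            sr, grad_pred = outputs
            gt_mag = F.sobel_magnitude(Tensor(target))
            img_term = base(sr, target)
            grad_term = mean(absolute(grad_pred - gt_mag.detach()))
            return img_term + spec.spsr_gradient_weight * grad_term
        return fn

    def fn(output, target):
        return base(output, target)

    return fn
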