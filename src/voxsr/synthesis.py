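"""Seeded synthetic brain-like phantoms.

The generator stands in for real structural brain MRI so the whole
pipeline is testable without any download.  A phantom is a head-shaped
ellipsoid containing

* smooth nested tissue bands (piecewise-constant intensities with a
  slowly varying multiplicative modulation, mimicking tissue contrast
  plus a bias field),
* thin bright shell boundaries at the band interfaces, and
* curvilinear filaments 1-2 voxels thick (vessel-like structures).

The shell interfaces and filaments carry energy above the Nyquist limit
of a 2x-downsampled grid, so band-limited degradation measurably
destroys detail and super-resolution is non-trivial.  No MR physics or
anatomy atlas is involved.

Contrast profiles assign intensities to the tissue bands: a T1-like
profile makes outer tissue bright and interior fluid dark, the T2-like
profile inverts that ordering, and PD sits in a narrow mid-grey range.
Two phantoms built from the same geometry seed with T1-like and T2-like
profiles therefore share their support mask exactly while their interior
intensities anti-correlate.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from voxsr.errors import ParameterError
from voxsr.volumes import Volume, rescale_intensity, write_volume

#: default voxel spacing, mm — the average voxel size of typical research
#: structural brain MRI
DEFAULT_SPACING = (0.9, 0.9, 1.2)

# per contrast profile: band intensities from outermost tissue to
# innermost fluid (interpolated linearly between the first two values)
# and the intensity of fine structures (interfaces, filaments) — bright
# on T1-like images, dark on T2-like ones (flow-void-like behaviour)
_PROFILES = {
    "T1": (0.75, 0.15, 0.95),
    "T2": (0.25, 0.95, 0.05),
    "PD": (0.55, 0.75, 0.85),
    "synthetic": (0.70, 0.30, 0.95),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom; identical spec + seed gives a bit-identical volume."""

    shape: tuple = (96, 96, 96)
    n_shells: int = 3
    n_filaments: int = 12
    noise_sd: float = 0.01
    seed: int = 0
    contrast: str = "synthetic"

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 32 for s in self.shape):
            raise ParameterError(f"phantom shape must be >= 32 per axis, got {self.shape}")
        if self.n_shells < 1:
            raise ParameterError("n_shells must be >= 1")
        if self.n_filaments < 0:
            raise ParameterError("n_filaments must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.contrast not in _PROFILES:
            raise ParameterError(f"unknown contrast profile {self.contrast!r}")


def _ellipsoid_radius(shape, rng):
    """Normalised ellipsoid coordinate rho (1 at the head boundary)."""
    grids = np.meshgrid(
        *[np.arange(n, dtype=np.float32) - (n - 1) / 2.0 for n in shape],
        indexing="ij",
    )
    semi = [0.42 * n * (1.0 + 0.05 * rng.uniform(-1, 1)) for n in shape]
    rho = np.sqrt(sum((g / s) ** 2 for g, s in zip(grids, semi)))
    return rho.astype(np.float32)


def _draw_filaments(shape, n, rng):
    """Boolean mask of n random smooth curves, 1-2 voxels thick."""
    mask = np.zeros(shape, dtype=bool)
    if n == 0:
        return mask
    dims = np.asarray(shape, dtype=np.float32)
    for _ in range(n):
        pos = dims * (0.25 + 0.5 * rng.random(3))
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        n_steps = int(0.8 * dims.min())
        for _ in range(n_steps):
            turn = 0.35 * rng.standard_normal(3)
            direction = direction + turn
            direction /= np.linalg.norm(direction)
            pos = pos + direction  # one-voxel steps
            idx = np.round(pos).astype(int)
            if np.any(idx < 1) or np.any(idx >= dims - 1):
                break
            mask[idx[0], idx[1], idx[2]] = True
            # thicken to ~2 voxels along a random neighbour
            off = rng.integers(0, 2, 3)
            j = idx + off
            mask[j[0], j[1], j[2]] = True
    return mask


def _smooth_modulation(shape, rng, amplitude=0.08):
    """Slowly varying multiplicative field (bias-field-like), mean 1."""
    coarse = rng.standard_normal((5, 5, 5)).astype(np.float32)
    zoom = [s / 5.0 for s in shape]
    field = ndimage.zoom(coarse, zoom, order=3)[: shape[0], : shape[1], : shape[2]]
    field = field / max(float(np.abs(field).max()), 1e-6)
    return 1.0 + amplitude * field


def generate_phantom(spec: PhantomSpec) -> Volume:
    """Render the phantom described by ``spec`` deterministically."""
    shape = tuple(int(s) for s in spec.shape)
    geo_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    contrast_idx = list(_PROFILES).index(spec.contrast)
    noise_rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 1, contrast_idx])
    )

    rho = _ellipsoid_radius(shape, geo_rng)
    head = rho <= 1.0

    hi, lo, structure = _PROFILES[spec.contrast]
    k = spec.n_shells
    band_edges = np.linspace(1.0, 0.0, k + 1)[1:-1]  # interior interfaces
    band_values = np.linspace(hi, lo, k)
    data = np.zeros(shape, dtype=np.float32)
    # piecewise-constant bands from outside in
    band_idx = np.clip((k * (1.0 - rho)).astype(int), 0, k - 1)
    data[head] = band_values[band_idx[head]]

    data *= _smooth_modulation(shape, geo_rng)

    # thin bright interfaces at the band boundaries (~1-2 voxels)
    interface_width = 1.2 / (0.42 * min(shape))  # ~1 voxel in rho units
    for edge in band_edges:
        on_edge = np.abs(rho - edge) < interface_width
        data[on_edge & head] = structure

    filaments = _draw_filaments(shape, spec.n_filaments, geo_rng) & head
    data[filaments] = structure

    if spec.noise_sd > 0:
        data = data + noise_rng.normal(0.0, spec.noise_sd, shape).astype(np.float32)

    v = Volume(
        data=data.astype(np.float32),
        spacing=DEFAULT_SPACING,
        contrast_tag="synthetic" if spec.contrast == "synthetic" else spec.contrast,
        ident=f"phantom-{spec.seed}-{spec.contrast}",
    )
    return rescale_intensity(v)


def generate_cohort(n: int, base_spec: PhantomSpec, contrasts, seed: int):
    """Generate ``n`` phantoms with per-volume seeds ``seed + index``.

    Contrast labels cycle through ``contrasts`` in order, so e.g.
    ``n=3, contrasts=("T1","T2","PD")`` yields one phantom per contrast.
    """
    contrasts = list(contrasts)
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not contrasts:
        raise ParameterError("contrast set must be non-empty")
    for c in contrasts:
        if c not in _PROFILES:
            raise ParameterError(f"unknown contrast profile {c!r}")
    volumes = []
    for i in range(n):
        spec = replace(base_spec, seed=int(seed) + i, contrast=contrasts[i % len(contrasts)])
        volumes.append(generate_phantom(spec))
    return volumes


def write_cohort(volumes, out_dir, manifest_name="manifest.csv"):
    """Write a cohort as NIfTI files plus a CSV manifest; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    manifest = os.path.join(out_dir, manifest_name)
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "contrast", "ident"])
        for i, v in enumerate(volumes):
            path = os.path.join(out_dir, f"{v.ident or f'vol{i:03d}'}.nii.gz")
            write_volume(v, path)
            writer.writerow([path, v.contrast_tag or "", v.ident])
    return manifest
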