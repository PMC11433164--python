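"""Patch extraction and grid aggregation.

Training draws fixed-size cubes uniformly at random; inference tiles the
volume with a regular grid of overlapping cubes and re-assembles the
predictions by equal-weight averaging wherever patches overlap.  All
evaluation metrics in this toolkit are computed on aggregated full
volumes, never on patches.

Volumes smaller than the patch are zero-padded symmetrically before
patching; :func:`aggregate` crops the padding off again.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from voxsr.errors import IncompleteGridError, ParameterError
from voxsr.volumes import Volume


@dataclass(frozen=True)
class PatchSpec:
    """Patch geometry: cube size and (inference-only) overlap per axis."""

    size: tuple = (64, 64, 64)
    overlap: tuple = (8, 8, 8)

    def __post_init__(self):
        size = tuple(int(s) for s in self.size)
        overlap = tuple(int(o) for o in self.overlap)
        if len(size) != 3 or any(s < 8 for s in size):
            raise ParameterError(f"patch size must be >= 8 per axis, got {self.size}")
        if len(overlap) != 3 or any(o < 0 or o >= s for o, s in zip(overlap, size)):
            raise ParameterError(
                f"overlap must satisfy 0 <= overlap < size, got {self.overlap}"
            )
        object.__setattr__(self, "size", size)
        object.__setattr__(self, "overlap", overlap)


@dataclass
class Patch:
    """A cube cut from a source volume at ``corner`` (padded-grid coordinates)."""

    data: np.ndarray
    corner: tuple
    source_id: str = ""


@dataclass
class PatchGrid:
    """Deterministic tiling of a (possibly padded) volume with full coverage."""

    source_dims: tuple
    spec: PatchSpec
    corners: list = field(default_factory=list)
    pad_before: tuple = (0, 0, 0)
    pad_after: tuple = (0, 0, 0)

    @property
    def padded_dims(self) -> tuple:
        return tuple(
            d + b + a
            for d, b, a in zip(self.source_dims, self.pad_before, self.pad_after)
        )


def _padding(dims, size):
    before, after = [], []
    for d, s in zip(dims, size):
        deficit = max(s - d, 0)
        before.append(deficit // 2)
        after.append(deficit - deficit // 2)
    return tuple(before), tuple(after)


def _pad_volume_data(data, before, after):
    if not any(before) and not any(after):
        return data
    return np.pad(data, tuple(zip(before, after)), mode="constant")


def _axis_corners(dim: int, size: int, stride: int):
    """Corner positions covering [0, dim) with the last patch clamped flush."""
    corners = list(range(0, max(dim - size, 0) + 1, stride))
    last = dim - size
    if corners[-1] != last:
        corners.append(last)
    return corners


def sample_uniform_patches(v: Volume, n: int, spec: PatchSpec, seed: int):
    """Draw ``n`` patches with corners i.i.d. uniform over all valid positions."""
    if n <= 0:
        raise ParameterError("number of patches must be positive")
    before, after = _padding(v.shape, spec.size)
    data = _pad_volume_data(v.data, before, after)
    rng = np.random.default_rng(seed)
    hi = [d - s + 1 for d, s in zip(data.shape, spec.size)]
    corners = rng.integers(0, hi, size=(n, 3))
    patches = []
    for c in corners:
        sl = tuple(slice(int(ci), int(ci) + s) for ci, s in zip(c, spec.size))
        patches.append(Patch(data=data[sl], corner=tuple(int(x) for x in c), source_id=v.ident))
    return patches


def plan_grid(dims, spec: PatchSpec) -> PatchGrid:
    """Enumerate grid corners at stride ``size - overlap`` with clamped final patch."""
    dims = tuple(int(d) for d in dims)
    before, after = _padding(dims, spec.size)
    padded = tuple(d + b + a for d, b, a in zip(dims, before, after))
    per_axis = [
        _axis_corners(d, s, s - o)
        for d, s, o in zip(padded, spec.size, spec.overlap)
    ]
    corners = [tuple(c) for c in product(*per_axis)]
    return PatchGrid(
        source_dims=dims,
        spec=spec,
        corners=corners,
        pad_before=before,
        pad_after=after,
    )


def extract_grid_patches(v: Volume, grid: PatchGrid):
    """Cut every grid patch from ``v`` (padding applied as in the grid plan)."""
    data = _pad_volume_data(v.data, grid.pad_before, grid.pad_after)
    size = grid.spec.size
    out = []
    for c in grid.corners:
        sl = tuple(slice(ci, ci + s) for ci, s in zip(c, size))
        out.append(Patch(data=data[sl], corner=c, source_id=v.ident))
    return out


def aggregate(patch_predictions, grid: PatchGrid, like: Volume | None = None) -> Volume:
    """Average patch predictions into a full volume.

    ``patch_predictions`` is an iterable of ``(Patch, predicted_data)``
    pairs whose corners must cover every planned corner exactly once.
    Overlapping voxels receive the arithmetic mean of all predictions
    covering them; the symmetric padding is cropped off.
    """
    size = grid.spec.size
    acc = np.zeros(grid.padded_dims, dtype=np.float64)
    cnt = np.zeros(grid.padded_dims, dtype=np.float64)
    seen = []
    for patch, pred in patch_predictions:
        pred = np.asarray(pred)
        if pred.shape != tuple(size):
            raise ParameterError(
                f"prediction shape {pred.shape} does not match patch size {size}"
            )
        sl = tuple(slice(c, c + s) for c, s in zip(patch.corner, size))
        acc[sl] += pred
        cnt[sl] += 1.0
        seen.append(tuple(patch.corner))
    if sorted(seen) != sorted(grid.corners):
        missing = set(grid.corners) - set(seen)
        extra = set(seen) - set(grid.corners)
        raise IncompleteGridError(
            f"patch set does not match grid: missing={sorted(missing)[:5]} "
            f"unexpected={sorted(extra)[:5]}"
        )
    out = acc / cnt
    crop = tuple(
        slice(b, b + d) for b, d in zip(grid.pad_before, grid.source_dims)
    )
    out = out[crop].astype(np.float32)
    if like is not None:
        return like.with_data(out)
    return Volume(data=out)
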