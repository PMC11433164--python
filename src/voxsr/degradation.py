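"""Band-limited degradation simulation and interpolation baselines.

Low-resolution volumes are produced from high-resolution ones by sinc
resampling, implemented exactly in the Fourier domain: the spectrum is
cropped (downsampling) or zero-padded (upsampling) symmetrically around
DC.  This realises the textbook semantics of sinc interpolation — energy
outside the retained band is removed exactly, and the down-then-up
round trip is a projection.

Index convention for an axis of length ``N`` resampled to ``M`` (on the
``fftshift``-ed spectrum, DC at ``N//2``): the retained/inserted band is
``centre - M//2 .. centre + (M - M//2) - 1``, i.e. the DC bin stays
centred and the unmatched Nyquist bin of an even-length axis is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from voxsr.errors import ParameterError, VolumeTooSmallError
from voxsr.volumes import Volume

#: isotropic per-axis factors studied throughout the toolkit
DEFAULT_FACTORS = (2.0, 2.5, 3.0, 3.5, 4.0)

_MIN_DIM = 4


@dataclass(frozen=True)
class ScaleFactor:
    """Per-axis downsampling factor; acceleration is the product of the axes."""

    per_axis: tuple

    def __post_init__(self):
        pa = tuple(float(f) for f in self.per_axis)
        if len(pa) != 3 or any(f < 1 for f in pa):
            raise ParameterError(f"per-axis factors must be 3 reals >= 1, got {self.per_axis}")
        object.__setattr__(self, "per_axis", pa)

    @classmethod
    def isotropic(cls, f: float) -> "ScaleFactor":
        return cls((f, f, f))


@dataclass
class PairedSample:
    """A high-resolution volume with its degraded-then-reinterpolated twin."""

    hr: Volume
    lr_interp: Volume
    factor: ScaleFactor
    sample_id: str = ""

    def __post_init__(self):
        if self.hr.shape != self.lr_interp.shape:
            raise ParameterError("hr and lr_interp must share dims")
        if self.hr.spacing != self.lr_interp.spacing:
            raise ParameterError("hr and lr_interp must share spacing")


def theoretical_acceleration(f: ScaleFactor) -> float:
    """Product of the per-axis factors, e.g. (3,3,3) -> 27."""
    return float(np.prod(f.per_axis))


def _band_slice(n: int, band: int):
    """Centred band of length ``band`` on an fftshift-ed axis of length ``n``."""
    start = n // 2 - band // 2
    return slice(start, start + band)


def sinc_resample(v: Volume, target_dims) -> Volume:
    """Fourier crop/pad resampling of ``v`` to ``target_dims``."""
    target_dims = tuple(int(d) for d in target_dims)
    if len(target_dims) != 3 or any(d < _MIN_DIM for d in target_dims):
        raise ParameterError(f"target dims must be >= {_MIN_DIM} per axis, got {target_dims}")
    src = v.data.astype(np.float64, copy=False)
    spec = np.fft.fftshift(np.fft.fftn(src))
    out_spec = np.zeros(target_dims, dtype=complex)
    bands = tuple(min(n, m) for n, m in zip(src.shape, target_dims))
    src_sl = tuple(_band_slice(n, b) for n, b in zip(src.shape, bands))
    dst_sl = tuple(_band_slice(m, b) for m, b in zip(target_dims, bands))
    out_spec[dst_sl] = spec[src_sl]
    # An even-length band has a lone -b/2 bin with no +b/2 partner; keeping
    # it breaks Hermitian symmetry (and hence the projection property), so
    # the unmatched Nyquist plane is dropped whenever the axis is resampled.
    for ax, (n, m, b) in enumerate(zip(src.shape, target_dims, bands)):
        if m != n and b % 2 == 0:
            sl = [slice(None)] * 3
            sl[ax] = m // 2 - b // 2
            out_spec[tuple(sl)] = 0.0
    out = np.fft.ifftn(np.fft.ifftshift(out_spec)).real
    # ifftn divides by prod(target_dims); rescale so the mean is preserved
    out *= np.prod(target_dims) / np.prod(src.shape)
    spacing = tuple(
        s * n / m for s, n, m in zip(v.spacing, src.shape, target_dims)
    )
    affine = None
    if v.affine is not None:
        affine = np.asarray(v.affine, dtype=np.float64).copy()
        for ax, (n, m) in enumerate(zip(src.shape, target_dims)):
            affine[:3, ax] *= n / m
    return Volume(
        data=out.astype(np.float32),
        spacing=spacing,
        affine=affine,
        contrast_tag=v.contrast_tag,
        ident=v.ident,
    )


def make_pair(hr: Volume, f: ScaleFactor) -> PairedSample:
    """Degrade ``hr`` by ``f`` and re-interpolate onto the original grid.

    The low-resolution grid is ``floor(dims / factor)`` per axis.  The
    re-interpolated volume (the model input) is clipped back to [0, 1]
    because ringing from the band limitation can overshoot the range.
    """
    data = hr.data
    if float(data.min()) < -1e-6 or float(data.max()) > 1 + 1e-6:
        raise ParameterError("hr must be intensity-rescaled to [0,1] before pairing")
    lr_dims = tuple(int(np.floor(n / a)) for n, a in zip(hr.shape, f.per_axis))
    if any(d < _MIN_DIM for d in lr_dims):
        raise VolumeTooSmallError(
            f"factor {f.per_axis} on dims {hr.shape} gives low-res dims {lr_dims} < {_MIN_DIM}"
        )
    lr = sinc_resample(hr, lr_dims)
    lr = lr.with_data(np.clip(lr.data, 0.0, 1.0))
    lr_interp = sinc_resample(lr, hr.shape)
    lr_interp = lr_interp.with_data(np.clip(lr_interp.data, 0.0, 1.0))
    # model input lives on the reference grid: restore the hr spacing/affine
    lr_interp.spacing = hr.spacing
    lr_interp.affine = hr.affine
    acc = theoretical_acceleration(f)
    return PairedSample(
        hr=hr,
        lr_interp=lr_interp,
        factor=f,
        sample_id=f"{hr.ident or 'volume'}_f{acc:g}",
    )


def _nearest_indices(n_src: int, n_dst: int) -> np.ndarray:
    """Nearest source index for each target index (centre-aligned grids)."""
    centres = (np.arange(n_dst) + 0.5) * n_src / n_dst
    return np.clip(np.floor(centres).astype(int), 0, n_src - 1)


def interpolate_baseline(lr: Volume, target_dims, method: str) -> Volume:
    """Resample ``lr`` to ``target_dims`` with a named traditional scheme.

    ``nearest``  nearest-index replication in index space;
    ``bicubic``  cubic spline in index space (centre-aligned);
    ``sinc``     Fourier crop/pad (see :func:`sinc_resample`).
    """
    target_dims = tuple(int(d) for d in target_dims)
    if method == "sinc":
        return sinc_resample(lr, target_dims)
    if method == "nearest":
        out = lr.data
        for ax, (n, m) in enumerate(zip(lr.shape, target_dims)):
            out = np.take(out, _nearest_indices(n, m), axis=ax)
    elif method == "bicubic":
        coords = np.meshgrid(
            *[
                (np.arange(m) + 0.5) * n / m - 0.5
                for n, m in zip(lr.shape, target_dims)
            ],
            indexing="ij",
        )
        out = ndimage.map_coordinates(
            lr.data.astype(np.float64), coords, order=3, mode="mirror"
        )
    else:
        raise ParameterError(f"unknown interpolation method {method!r}")
    spacing = tuple(s * n / m for s, n, m in zip(lr.spacing, lr.shape, target_dims))
    return Volume(
        data=out.astype(np.float32),
        spacing=spacing,
        affine=None,
        contrast_tag=lr.contrast_tag,
        ident=lr.ident,
    )
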