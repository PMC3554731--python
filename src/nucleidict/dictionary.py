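"""Disk-atom dictionary and its linear synthesis/adjoint operators.

A nucleus is modeled as a filled disk.  An *atom* is the ideal binary
segmentation of a single nucleus of radius ``r`` centered at a pixel; the
dictionary holds one binary kernel per radius in a discretized size
interval.  A candidate segmentation is synthesized as the superposition of
atoms: per radius, the coefficient map is convolved with the disk kernel
and the results are summed.  Because the superposition is a plain sum,
synthesized values exceed 1 wherever disks overlap, which penalizes
overlapping nuclei in the coupled energy.

Convolutions use zero padding, so an atom centered near the border
contributes only its clipped part.  Small grids (<= 64 px on a side) use
exact direct convolution; larger grids use FFT convolution for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .core import Grid2D, as_field
from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "DiskDictionary",
    "disk_kernel",
    "make_disk_atom",
    "build_dictionary",
    "synthesize",
    "adjoint_synthesize",
]

_DIRECT_CONV_MAX_SIDE = 64


def disk_kernel(radius: float) -> np.ndarray:
    """Binary (float) kernel of the closed Euclidean disk of given radius.

    The kernel is ``(2*floor(r)+1)`` pixels on a side with the disk center
    at the middle pixel; membership is ``distance <= radius`` (ties at
    exactly ``radius`` are inside).
    """
    if radius < 0:
        raise InvalidInputError(f"radius must be >= 0, got {radius}")
    R = int(np.floor(radius))
    rr, cc = np.mgrid[-R : R + 1, -R : R + 1]
    return (rr * rr + cc * cc <= radius * radius).astype(float)


@dataclass(frozen=True)
class DiskDictionary:
    """Ordered set of disk atoms covering a discretized size interval.

    ``radii`` is strictly increasing with all entries >= 1 pixel;
    ``kernels[k]`` is the binary disk kernel for ``radii[k]``.
    """

    radii: tuple[float, ...]
    kernels: tuple[np.ndarray, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.radii) < 1:
            raise ConfigurationError("dictionary needs at least one radius")
        if any(r < 1 for r in self.radii):
            raise ConfigurationError("all dictionary radii must be >= 1 pixel")
        if any(b <= a for a, b in zip(self.radii, self.radii[1:])):
            raise ConfigurationError("dictionary radii must be strictly increasing")

    def __len__(self) -> int:
        return len(self.radii)

    @property
    def areas(self) -> np.ndarray:
        """Pixel count of each atom (unclipped)."""
        return np.array([k.sum() for k in self.kernels])

    @property
    def r_max(self) -> float:
        return self.radii[-1]

    @property
    def median_area(self) -> float:
        """Area of the median-radius atom (used to scale the sparsity weight)."""
        return float(self.kernels[(len(self) - 1) // 2].sum())

    def synthesis_norm_bound(self) -> float:
        """Upper bound on the operator norm of the synthesis map.

        For nonnegative kernels, ``||D|| <= sum_r ||k_r||_1`` (triangle
        inequality plus Young's inequality per radius).
        """
        return float(self.areas.sum())


def make_disk_atom(radius: float, center: tuple[float, float], grid: Grid2D) -> np.ndarray:
    """Binary field that is 1 exactly within ``radius`` of ``center``.

    Disks may be clipped by the image border; the center itself must lie
    inside the grid.
    """
    if radius < 0:
        raise InvalidInputError(f"radius must be >= 0, got {radius}")
    row, col = center
    if not grid.contains(row, col):
        raise InvalidInputError(f"center {center} outside grid {grid.shape}")
    rr, cc = np.ogrid[0 : grid.height, 0 : grid.width]
    return ((rr - row) ** 2 + (cc - col) ** 2 <= radius * radius).astype(float)


def build_dictionary(r_min: float, r_max: float, step: float = 1.0) -> DiskDictionary:
    """Dictionary over the arithmetic radius sequence ``r_min, r_min+step, ...``.

    ``r_max`` is always included: if the sequence misses it, it is
    appended as the final radius.
    """
    if not step > 0:
        raise ConfigurationError(f"step must be > 0, got {step}")
    if r_min < 1:
        raise ConfigurationError(f"r_min must be >= 1 pixel, got {r_min}")
    if r_min > r_max:
        raise ConfigurationError(f"r_min {r_min} exceeds r_max {r_max}")
    radii: list[float] = []
    k = 0
    while True:
        r = r_min + k * step
        if r > r_max + 1e-9:
            break
        radii.append(float(r))
        k += 1
    if radii[-1] < r_max - 1e-9:
        radii.append(float(r_max))
    kernels = tuple(disk_kernel(r) for r in radii)
    return DiskDictionary(radii=tuple(radii), kernels=kernels)


def _conv(field: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    if max(field.shape) <= _DIRECT_CONV_MAX_SIDE:
        return ndimage.convolve(field, kernel, mode="constant", cval=0.0)
    return signal.fftconvolve(field, kernel, mode="same")


def _stack(t, dic: DiskDictionary) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 3 or t.shape[0] != len(dic):
        raise InvalidInputError(
            f"coefficient stack must have shape (e, H, W) with e={len(dic)}, got {t.shape}"
        )
    return t


def synthesize(t, dic: DiskDictionary) -> np.ndarray:
    """Linear synthesis: sum over radii of coefficient maps convolved with atoms."""
    t = _stack(t, dic)
    out = np.zeros(t.shape[1:], dtype=float)
    for k, kern in enumerate(dic.kernels):
        out += _conv(t[k], kern)
    return out


def adjoint_synthesize(field, dic: DiskDictionary) -> np.ndarray:
    """Adjoint of :func:`synthesize`: per-radius correlation with the atom.

    Satisfies ``<synthesize(t), field> == <t, adjoint_synthesize(field)>``
    (zero-padded correlation; disk kernels are reflection-symmetric).
    """
    f = as_field(field)
    out = np.empty((len(dic), *f.shape), dtype=float)
    for k, kern in enumerate(dic.kernels):
        out[k] = _conv(f, kern[::-1, ::-1])
    return out
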