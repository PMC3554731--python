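"""Grid conventions and the discrete differential operators used everywhere.

Conventions
-----------
Images and scalar fields are 2-D ``float64`` numpy arrays indexed
``(row, col)``, 0-based, with pixel centers on the integer lattice.  All
distances are Euclidean in pixel units; :class:`Grid2D.pixel_size` converts
them to micrometres.  The discrete gradient uses forward differences with a
replicate (Neumann) boundary, so the difference in the last row/column is
zero; the total-variation norm is the isotropic one, i.e. the sum over
pixels of ``sqrt(d_row**2 + d_col**2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "Grid2D",
    "as_field",
    "gradient",
    "gradient_adjoint",
    "divergence",
    "inner_product",
    "tv_norm",
]


@dataclass(frozen=True)
class Grid2D:
    """Pixel grid with an isotropic physical scale.

    Parameters
    ----------
    height, width : int
        Grid dimensions in pixels, both at least 1.
    pixel_size : float
        Micrometres per pixel, strictly positive.  Defaults to 1, i.e.
        pixel units double as physical units.
    """

    height: int
    width: int
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise InvalidInputError(
                f"grid dimensions must be >= 1, got {self.height}x{self.width}"
            )
        if not self.pixel_size > 0:
            raise InvalidInputError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def contains(self, row: float, col: float) -> bool:
        """Whether a (row, col) coordinate lies on the pixel lattice extent."""
        return 0 <= row <= self.height - 1 and 0 <= col <= self.width - 1


def as_field(values) -> np.ndarray:
    """Validate and cast an array-like to a nonempty 2-D float64 field."""
    a = np.asarray(values, dtype=float)
    if a.ndim != 2 or a.size == 0:
        raise InvalidInputError(f"expected a nonempty 2-D field, got shape {a.shape}")
    return a


def gradient(field) -> tuple[np.ndarray, np.ndarray]:
    """Forward-difference gradient with Neumann boundary.

    Returns the pair ``(d_row, d_col)``; the difference at the last
    row/column is zero (replicated boundary).
    """
    f = as_field(field)
    dr = np.zeros_like(f)
    dc = np.zeros_like(f)
    dr[:-1, :] = f[1:, :] - f[:-1, :]
    dc[:, :-1] = f[:, 1:] - f[:, :-1]
    return dr, dc


def gradient_adjoint(p, q) -> np.ndarray:
    """Adjoint of :func:`gradient`: ``<gradient(u), (p, q)> == <u, gradient_adjoint(p, q)>``.

    Only the entries of ``p``/``q`` that the forward difference actually
    touches (all but the last row/column respectively) contribute.
    """
    p = as_field(p)
    q = as_field(q)
    if p.shape != q.shape:
        raise InvalidInputError("gradient_adjoint components must share a shape")
    out = np.zeros_like(p)
    out[:-1, :] -= p[:-1, :]
    out[1:, :] += p[:-1, :]
    out[:, :-1] -= q[:, :-1]
    out[:, 1:] += q[:, :-1]
    return out


def divergence(p, q) -> np.ndarray:
    """Discrete divergence, the negative adjoint of :func:`gradient`."""
    return -gradient_adjoint(p, q)


def inner_product(a, b) -> float:
    """Euclidean inner product: sum over all pixels of ``a * b``."""
    a = as_field(a)
    b = as_field(b)
    if a.shape != b.shape:
        raise InvalidInputError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sum(a * b))


def tv_norm(field) -> float:
    """Isotropic total variation: sum of per-pixel gradient magnitudes."""
    dr, dc = gradient(field)
    return float(np.sum(np.hypot(dr, dc)))
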