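"""Illumination normalization and gamma correction.

Fluorescence micrographs suffer from slowly varying illumination and from
faint residual staining of apoptotic cells.  Both are reduced before
segmentation: every pixel is divided by the maximum intensity found within
a disk-shaped neighborhood around it (so the brightest nearby nucleus acts
as a local estimate of the lamp intensity), and the normalized image is
then raised to a power ``gamma >= 1`` to suppress low intensities.

The neighborhood radius should be chosen so that the disk contains at
least one nucleus at the densities of interest; where no nucleus is near,
a floor on the local maximum (a fraction ``epsilon`` of the global
maximum) prevents empty background from being amplified to full
brightness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk as _disk_footprint

from .core import as_field
from .errors import ConfigurationError, InvalidInputError

__all__ = ["PreprocessConfig", "normalize_local", "gamma_correct", "preprocess"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the two preprocessing steps.

    Parameters
    ----------
    norm_radius : int
        Radius (pixels) of the disk over which the local maximum is taken.
        Should be large enough that the disk contains at least one nucleus;
        a practical default is about four times the largest expected
        nucleus radius.
    gamma : float
        Exponent of the pointwise power transform, ``>= 1`` so that low
        intensities are suppressed rather than amplified.
    epsilon : float
        Positive floor on the local maximum, expressed as a fraction of
        the global maximum.  Guards flat dark regions and neighborhoods
        that contain no nucleus.
    """

    norm_radius: int = 40
    gamma: float = 2.0
    epsilon: float = 0.25

    def __post_init__(self) -> None:
        if self.norm_radius < 1:
            raise ConfigurationError(f"norm_radius must be >= 1, got {self.norm_radius}")
        if self.gamma < 1:
            raise ConfigurationError(
                f"gamma must be >= 1 (values < 1 would amplify faint clutter), got {self.gamma}"
            )
        if not self.epsilon > 0:
            raise ConfigurationError(f"epsilon must be > 0, got {self.epsilon}")


def normalize_local(image, cfg: PreprocessConfig) -> np.ndarray:
    """Divide each pixel by the local maximum over a disk neighborhood.

    The window is clipped at the image borders (no padding value is
    invented: with nonnegative intensities, a zero-padded maximum filter
    equals the maximum over the window/image intersection).  The output
    lies in ``[0, 1]``.  An all-zero image is returned unchanged with a
    warning.
    """
    img = as_field(image)
    if np.any(img < 0):
        raise InvalidInputError("normalize_local requires nonnegative intensities")
    global_max = float(img.max())
    if global_max == 0.0:
        logger.warning("normalize_local: all-zero image, returning it unchanged")
        return img.copy()
    footprint = _disk_footprint(cfg.norm_radius)
    local_max = ndimage.maximum_filter(img, footprint=footprint, mode="constant", cval=0.0)
    denom = np.maximum(local_max, cfg.epsilon * global_max)
    return img / denom


def gamma_correct(image, cfg: PreprocessConfig) -> np.ndarray:
    """Pointwise power transform ``value ** gamma`` on a [0, 1] image."""
    img = as_field(image)
    if img.min() < 0 or img.max() > 1:
        raise InvalidInputError("gamma_correct expects values in [0, 1]")
    return img**cfg.gamma


def preprocess(image, cfg: PreprocessConfig) -> np.ndarray:
    """Full preprocessing: local normalization, then gamma correction."""
    return gamma_correct(normalize_local(image, cfg), cfg)
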