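"""From the relaxed segmentation and atom coefficients to individual nuclei.

The coefficient stack ``t`` carries the evidence for nucleus centers, but
with an L1 (rather than L0) sparsity prior the centers are not explicit:
the mass for one nucleus is spread over nearby pixels and neighboring
radii.  The detection chain recovers discrete detections:

1. per pixel, the *dominant radius* (argmax over the per-radius
   coefficients, ties toward the smaller radius) and, in parallel, the
   merged coefficient image ``T`` (sum over radii), whose high values sit
   at nucleus centers;
2. ``T`` is binarized (Otsu over its strictly positive values by default),
   morphologically closed so fragments of one nucleus merge, and masked by
   a clutter mask derived from the binarized segmentation (its
   morphological opening with an oversized disk isolates objects too large
   to be nuclei, e.g. apoptotic debris, and is inverted);
3. 8-connected components of the result are candidate nuclei, scored by
   the mean preprocessed intensity over their pixels;
4. greedy non-maximum suppression: the best-scored candidate is accepted
   and all remaining candidates within its dominant radius are discarded,
   until no candidates remain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import closing as _closing, opening as _opening, disk as _disk

from .core import as_field
from .dictionary import DiskDictionary
from .errors import ConfigurationError, InvalidInputError
from .segmentation import SegmentationResult, threshold_u

__all__ = [
    "Detection",
    "DetectionConfig",
    "dominant_radius_map",
    "merge_coefficients",
    "clutter_mask",
    "candidate_components",
    "score_components",
    "greedy_select",
    "detect",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Detection:
    """A single detected nucleus.

    ``centroid`` is a (row, col) pixel coordinate; ``dominant_radius`` is
    one of the dictionary radii; ``score`` is the mean preprocessed
    intensity of the supporting component.
    """

    centroid: tuple[float, float]
    dominant_radius: float
    score: float


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the detection chain.

    ``t_binarize_mode`` is ``"otsu"`` (threshold chosen over the strictly
    positive values of the merged coefficient image) or ``"fixed"``
    (use ``t_binarize_level``).  ``clutter_opening_radius`` must exceed
    the largest dictionary radius so that legal nuclei survive the
    opening; ``None`` resolves to ``1.5 * r_max`` at detection time.
    """

    t_binarize_mode: str = "otsu"
    t_binarize_level: float = 0.0
    closing_radius: int = 2
    clutter_opening_radius: float | None = None

    def __post_init__(self) -> None:
        if self.t_binarize_mode not in ("otsu", "fixed"):
            raise ConfigurationError(
                f"t_binarize_mode must be 'otsu' or 'fixed', got {self.t_binarize_mode!r}"
            )
        if self.closing_radius < 0:
            raise ConfigurationError("closing_radius must be >= 0")

    def resolved_opening_radius(self, dic: DiskDictionary) -> float:
        r = self.clutter_opening_radius
        if r is None:
            r = 1.5 * dic.r_max
        if r <= dic.r_max:
            raise ConfigurationError(
                f"clutter_opening_radius {r} must exceed the largest dictionary radius {dic.r_max}"
            )
        return float(r)


def dominant_radius_map(t, dic: DiskDictionary) -> np.ndarray:
    """Per pixel, the radius with the largest coefficient (ties -> smaller)."""
    t = np.asarray(t, dtype=float)
    if t.ndim != 3 or t.shape[0] != len(dic):
        raise InvalidInputError(f"stack shape {t.shape} does not match dictionary ({len(dic)})")
    idx = np.argmax(t, axis=0)  # first maximum = smallest radius on ties
    return np.asarray(dic.radii, dtype=float)[idx]


def merge_coefficients(t) -> np.ndarray:
    """Sum the coefficient maps over radii; peaks mark nucleus centers."""
    t = np.asarray(t, dtype=float)
    if t.ndim != 3 or t.shape[0] < 1:
        raise InvalidInputError(f"expected a nonempty (e, H, W) stack, got shape {t.shape}")
    return t.sum(axis=0)


def clutter_mask(u_binary, opening_radius: float) -> np.ndarray:
    """Remove objects too large to be nuclei from the binary segmentation.

    The opening of ``u_binary`` with a disk of ``opening_radius`` keeps
    only components that contain such a disk; the mask is ``u_binary AND
    NOT opened``, i.e. the segmentation with oversized clutter deleted.
    """
    ub = as_field(u_binary)
    if not np.isin(ub, (0.0, 1.0)).all():
        raise InvalidInputError("clutter_mask expects a binary (0/1) field")
    opened = _opening(ub.astype(bool), _disk(int(round(opening_radius))))
    return (ub.astype(bool) & ~opened).astype(float)


def candidate_components(T, u_binary, cfg: DetectionConfig, opening_radius: float) -> list[np.ndarray]:
    """Connected components of the binarized, closed and masked ``T`` image.

    Returns a list of ``(n_i, 2)`` integer arrays of (row, col) pixel
    coordinates, 8-connected.
    """
    T = as_field(T)
    pos = T[T > 0]
    if pos.size == 0:
        return []
    if cfg.t_binarize_mode == "otsu":
        if np.ptp(pos) == 0:  # all positive values equal: keep them all
            binary = T > 0
        else:
            binary = T > threshold_otsu(pos)
    else:
        binary = T > cfg.t_binarize_level
    if cfg.closing_radius > 0:
        binary = _closing(binary, _disk(cfg.closing_radius))
    binary = binary & clutter_mask(u_binary, opening_radius).astype(bool)
    labels = label(binary, connectivity=2)
    return [np.argwhere(labels == i) for i in range(1, labels.max() + 1)]


def score_components(
    components: list[np.ndarray],
    preprocessed,
    radius_map,
) -> list[tuple[Detection, int]]:
    """Score candidates and attach centroid / dominant radius / area.

    Score is the mean preprocessed intensity over the component's pixels;
    centroid is the unweighted pixel mean; the component's dominant radius
    is the mode of the per-pixel dominant-radius map over its pixels (ties
    toward the smaller radius).  Returns ``(Detection, area)`` pairs.
    """
    img = as_field(preprocessed)
    rmap = as_field(radius_map)
    out: list[tuple[Detection, int]] = []
    for comp in components:
        if len(comp) == 0:
            logger.warning("score_components: skipping empty component")
            continue
        rows, cols = comp[:, 0], comp[:, 1]
        score = float(img[rows, cols].mean())
        centroid = (float(rows.mean()), float(cols.mean()))
        radii, counts = np.unique(rmap[rows, cols], return_counts=True)
        dominant = float(radii[np.argmax(counts)])  # first max = smallest radius
        out.append((Detection(centroid=centroid, dominant_radius=dominant, score=score), len(comp)))
    return out


def greedy_select(candidates: list[tuple[Detection, int]]) -> list[Detection]:
    """Greedy non-maximum suppression of scored candidates.

    Repeatedly accept the highest-scoring candidate (ties: larger
    component area, then row-major centroid order) and discard remaining
    candidates whose centroid lies within the accepted candidate's
    dominant radius (Euclidean, pixel units).
    """
    pending = sorted(
        candidates,
        key=lambda ca: (-ca[0].score, -ca[1], ca[0].centroid[0], ca[0].centroid[1]),
    )
    accepted: list[Detection] = []
    while pending:
        best, _ = pending.pop(0)
        accepted.append(best)
        br, bc = best.centroid
        pending = [
            (d, a)
            for d, a in pending
            if (d.centroid[0] - br) ** 2 + (d.centroid[1] - bc) ** 2 > best.dominant_radius**2
        ]
    return accepted


def detect(
    result: SegmentationResult,
    preprocessed,
    dic: DiskDictionary,
    cfg: DetectionConfig | None = None,
    u_threshold: float = 0.5,
) -> list[Detection]:
    """Full detection chain on a completed segmentation."""
    if cfg is None:
        cfg = DetectionConfig()
    opening_radius = cfg.resolved_opening_radius(dic)
    u_binary = threshold_u(result.u, u_threshold)
    radius_map = dominant_radius_map(result.t, dic)
    T = merge_coefficients(result.t)
    components = candidate_components(T, u_binary, cfg, opening_radius)
    scored = score_components(components, preprocessed, radius_map)
    return greedy_select(scored)
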