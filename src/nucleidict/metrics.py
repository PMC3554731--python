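"""Detection and segmentation validation metrics.

A detection is a true positive if a ground-truth centroid lies within a
fixed physical match radius (3.2 micrometres by convention); each ground
truth can be matched to at most one detection and vice versa, with the
closest pairs matched first so the outcome does not depend on input
order.  Detection quality is summarized by precision, recall and the
balanced F-measure (pooled over a data set), plus the root-mean-squared
error of the per-image nucleus count.  Segmentation quality is the Dice
coefficient between the binarized segmentation and a ground-truth mask,
computed over full images (not per nucleus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import as_field
from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "GroundTruth",
    "MetricsReport",
    "match_detections",
    "precision_recall_f",
    "count_rmse",
    "dice",
    "evaluate",
]


@dataclass(frozen=True)
class GroundTruth:
    """Annotated truth for one image: centroids, optionally a binary mask."""

    centroids: np.ndarray  # (n, 2) array of (row, col)
    mask: np.ndarray | None = None


@dataclass(frozen=True)
class MetricsReport:
    """Pooled validation metrics for one image or a data set."""

    rmse: float
    precision: float
    recall: float
    f_measure: float
    dice: float | None
    tp: int
    fp: int
    fn: int

    def as_text(self) -> str:
        lines = [
            f"count RMSE : {self.rmse:.4f}",
            f"precision  : {self.precision:.4f}",
            f"recall     : {self.recall:.4f}",
            f"F-measure  : {self.f_measure:.4f}",
            f"TP/FP/FN   : {self.tp}/{self.fp}/{self.fn}",
        ]
        if self.dice is not None:
            lines.append(f"Dice       : {self.dice:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "dice": self.dice,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
        }


def _as_points(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.size == 0:
        return a.reshape(0, 2)
    if a.ndim != 2 or a.shape[1] != 2:
        raise InvalidInputError(f"expected an (n, 2) point array, got shape {a.shape}")
    return a


def match_detections(
    detections,
    truths,
    match_radius_um: float = 3.2,
    pixel_size: float = 1.0,
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """One-to-one matching of detections to ground-truth centroids.

    Candidate pairs within the match radius are sorted by distance and
    matched greedily, closest pairs first (ties broken by truth index,
    then detection index), so the result is independent of input order.
    Returns ``(tp, fp, fn, pairs)`` with ``pairs`` a list of
    ``(truth_index, detection_index)`` matches.
    """
    if not match_radius_um > 0:
        raise ConfigurationError(f"match radius must be > 0, got {match_radius_um}")
    if not pixel_size > 0:
        raise ConfigurationError(f"pixel_size must be > 0, got {pixel_size}")
    det = _as_points(detections)
    tru = _as_points(truths)
    radius_px = match_radius_um / pixel_size
    if len(det) == 0 or len(tru) == 0:
        return 0, len(det), len(tru), []
    d = cdist(tru, det)
    ti, dj = np.nonzero(d <= radius_px)
    order = np.lexsort((dj, ti, d[ti, dj]))
    matched_t: set[int] = set()
    matched_d: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for k in order:
        i, j = int(ti[k]), int(dj[k])
        if i in matched_t or j in matched_d:
            continue
        matched_t.add(i)
        matched_d.add(j)
        pairs.append((i, j))
    tp = len(pairs)
    assert len(matched_t) == tp and len(matched_d) == tp  # one-to-one by construction
    return tp, len(det) - tp, len(tru) - tp, pairs


def precision_recall_f(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and balanced F-measure with empty-set conventions.

    ``P = 1`` when there are no detections, ``R = 1`` when there are no
    truths, ``F = 0`` when both P and R are zero.
    """
    if min(tp, fp, fn) < 0:
        raise InvalidInputError("counts must be >= 0")
    p = tp / (tp + fp) if tp + fp > 0 else 1.0
    r = tp / (tp + fn) if tp + fn > 0 else 1.0
    f = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f


def count_rmse(detected_counts, true_counts) -> float:
    """Root-mean-squared error of per-image nucleus counts."""
    det = np.asarray(detected_counts, dtype=float)
    tru = np.asarray(true_counts, dtype=float)
    if det.shape != tru.shape or det.ndim != 1 or det.size == 0:
        raise InvalidInputError("count lists must be nonempty and of equal length")
    return float(np.sqrt(np.mean((det - tru) ** 2)))


def dice(seg_binary, truth_mask) -> float:
    """Dice coefficient ``2|A∩B| / (|A|+|B|)`` between two binary fields.

    Defined as 1 when both fields are empty.  Computed over full images.
    """
    a = as_field(seg_binary)
    b = as_field(truth_mask)
    if a.shape != b.shape:
        raise InvalidInputError(f"shape mismatch: {a.shape} vs {b.shape}")
    for x in (a, b):
        if not np.isin(x, (0.0, 1.0)).all():
            raise InvalidInputError("dice expects binary (0/1) fields")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.sum(a * b) / denom)


def evaluate(
    detections_per_image,
    truths_per_image,
    seg_masks=None,
    truth_masks=None,
    match_radius_um: float = 3.2,
    pixel_size: float = 1.0,
) -> MetricsReport:
    """Pooled metrics over a data set.

    True/false positives and negatives are pooled across images (micro
    averaging) for precision/recall/F; the count RMSE is taken over
    per-image detection counts; Dice is averaged over the images for which
    both a segmentation and a truth mask are supplied.
    """
    if len(detections_per_image) != len(truths_per_image):
        raise InvalidInputError("detections and truths must be aligned per image")
    tp = fp = fn = 0
    det_counts = []
    true_counts = []
    for det, tru in zip(detections_per_image, truths_per_image):
        t, f_, n = match_detections(det, tru, match_radius_um, pixel_size)[:3]
        tp, fp, fn = tp + t, fp + f_, fn + n
        det_counts.append(len(_as_points(det)))
        true_counts.append(len(_as_points(tru)))
    p, r, f = precision_recall_f(tp, fp, fn)
    rmse = count_rmse(det_counts, true_counts)
    mean_dice = None
    if seg_masks is not None and truth_masks is not None:
        dices = [
            dice(sm, tm)
            for sm, tm in zip(seg_masks, truth_masks)
            if sm is not None and tm is not None
        ]
        if dices:
            mean_dice = float(np.mean(dices))
    return MetricsReport(
        rmse=rmse, precision=p, recall=r, f_measure=f, dice=mean_dice, tp=tp, fp=fp, fn=fn
    )
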