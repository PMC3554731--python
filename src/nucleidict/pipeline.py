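"""End-to-end composition of the pipeline, shared by the CLI and the benchmark.

``detect_image`` runs preprocess -> intensity estimation -> joint
segmentation -> detection on one raw image.  ``run_fixture_benchmark``
generates a synthetic suite, runs detection on every image and pools the
validation metrics — the desk-scale stand-in for a full benchmark run.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .config import RunConfig
from .detection import Detection, detect
from .errors import DegenerateImageError
from .fixtures import FixtureConfig, generate_suite
from .metrics import MetricsReport, evaluate
from .preprocessing import preprocess
from .segmentation import (
    SegmentationResult,
    estimate_intensities,
    segment,
    threshold_u,
)

__all__ = ["detect_image", "run_fixture_benchmark"]

logger = logging.getLogger(__name__)


def detect_image(
    image: np.ndarray,
    cfg: RunConfig,
) -> tuple[list[Detection], np.ndarray, SegmentationResult]:
    """Run the full pipeline on one raw image.

    Returns the detections, the preprocessed image and the segmentation
    result (for debugging output and Dice evaluation).  A degenerate
    (constant) image yields no detections.
    """
    dic = cfg.build_dictionary()
    pre = preprocess(image, cfg.resolved_preprocess(dic))
    try:
        c_fg, c_bg = estimate_intensities(pre)
    except DegenerateImageError:
        logger.warning("degenerate image: returning an empty detection set")
        empty = SegmentationResult(
            u=np.zeros_like(pre), t=np.zeros((len(dic), *pre.shape)), energy_trace=[0.0],
            converged=True,
        )
        return [], pre, empty
    params = dataclasses.replace(cfg.energy, c_fg=c_fg, c_bg=c_bg)
    result = segment(pre, dic, params)
    detections = detect(result, pre, dic, cfg.detection, u_threshold=params.u_threshold)
    return detections, pre, result


def run_fixture_benchmark(
    run_cfg: RunConfig | None = None,
    fixture_cfg: FixtureConfig | None = None,
    n_images: int = 10,
    seed: int = 0,
) -> tuple[MetricsReport, list[int], list[int]]:
    """Detection benchmark on a generated suite with exact ground truth.

    Returns the pooled metrics report plus the per-image detected and true
    counts.  Dice is computed between the thresholded segmentation and the
    union-of-disks truth mask.
    """
    if run_cfg is None:
        run_cfg = RunConfig()
    if fixture_cfg is None:
        fixture_cfg = FixtureConfig(seed=seed)
    samples = generate_suite(fixture_cfg, n_images, seed)
    detections_per_image = []
    truths_per_image = []
    seg_masks = []
    truth_masks = []
    for i, sample in enumerate(samples):
        dets, _pre, result = detect_image(sample.image, run_cfg)
        detections_per_image.append(np.array([d.centroid for d in dets]).reshape(-1, 2))
        truths_per_image.append(sample.truth_centroids)
        seg_masks.append(threshold_u(result.u, run_cfg.energy.u_threshold))
        truth_masks.append(sample.truth_mask)
        logger.info("image %d: %d detections / %d truths", i, len(dets), len(sample.truth_centroids))
    report = evaluate(
        detections_per_image,
        truths_per_image,
        seg_masks=seg_masks,
        truth_masks=truth_masks,
        match_radius_um=run_cfg.match_radius_um,
        pixel_size=fixture_cfg.grid.pixel_size,
    )
    det_counts = [len(d) for d in detections_per_image]
    true_counts = [len(t) for t in truths_per_image]
    return report, det_counts, true_counts
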