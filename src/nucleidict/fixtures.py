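"""Deterministic synthetic micrographs with exact ground truth.

The generator emulates the degradations that make nuclei detection hard in
real fluorescence micrographs: Gaussian blur, touching nuclei placed in
pairs at boundary-contact distance, a multiplicative linear illumination
gradient, oversized bright clutter blobs (mimicking apoptotic debris), and
additive Gaussian noise.  All randomness flows from one explicit seed, so
samples are bit-reproducible; centroids, radii and the union-of-disks
truth mask are returned alongside the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import Grid2D
from .errors import GenerationError, InvalidInputError

__all__ = ["FixtureConfig", "FixtureSample", "generate", "generate_suite"]

_MAX_ATTEMPTS_PER_OBJECT = 2000


@dataclass(frozen=True)
class FixtureConfig:
    """Generation parameters; the defaults model a desk-scale benchmark image.

    ``touching_fraction`` of the nuclei are placed in pairs whose center
    distance lies in ``(r_i + r_j - 2, r_i + r_j)`` — boundary contact
    with less than 2 px of overlap — while all other center pairs are
    separated by more than ``r_i + r_j + 4``.  ``clutter_blobs`` bright
    disks of radius ``clutter_radius_multiplier * r_max`` are placed away
    from the nuclei.  ``illumination_gradient`` is the fractional
    intensity drop across the field diagonal.
    """

    grid: Grid2D = field(default_factory=lambda: Grid2D(256, 256, pixel_size=1.0))
    n_nuclei: int = 30
    radius_range: tuple[float, float] = (10.0, 10.0)
    touching_fraction: float = 0.3
    fg_level: float = 0.8
    bg_level: float = 0.1
    blur_sigma: float = 2.0
    illumination_gradient: float = 0.3
    clutter_blobs: int = 1
    clutter_radius_multiplier: float = 2.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise InvalidInputError("n_nuclei must be >= 0")
        r_min, r_max = self.radius_range
        if r_min > r_max or r_min <= 0:
            raise InvalidInputError(f"invalid radius_range {self.radius_range}")
        if not self.fg_level > self.bg_level:
            raise InvalidInputError("fg_level must exceed bg_level")
        if not (0 <= self.touching_fraction <= 1):
            raise InvalidInputError("touching_fraction must be in [0, 1]")


@dataclass(frozen=True)
class FixtureSample:
    """One synthetic image with its exact ground truth."""

    image: np.ndarray
    truth_centroids: np.ndarray  # (n, 2) float (row, col)
    truth_radii: np.ndarray  # (n,) float
    truth_mask: np.ndarray  # union of the true nucleus disks, before blur
    clutter_mask_truth: np.ndarray  # union of the clutter blobs
    config: FixtureConfig


def _render_disks(shape, centers, radii) -> np.ndarray:
    mask = np.zeros(shape, dtype=float)
    rr, cc = np.ogrid[0 : shape[0], 0 : shape[1]]
    for (r0, c0), rad in zip(centers, radii):
        mask[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad * rad] = 1.0
    return mask


def _too_close(center, radius, placed, clearance) -> bool:
    for (pr, pc), prad in placed:
        if np.hypot(center[0] - pr, center[1] - pc) <= radius + prad + clearance:
            return True
    return False


def generate(cfg: FixtureConfig) -> FixtureSample:
    """Generate one synthetic micrograph; fully reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.grid.shape
    r_min, r_max = cfg.radius_range

    n_touch = int(round(cfg.touching_fraction * cfg.n_nuclei))
    n_pairs = n_touch // 2
    # an odd touching count extends one pair into a chain of three
    chain_extra = n_touch - 2 * n_pairs

    centers: list[tuple[float, float]] = []
    radii: list[float] = []

    def margin_ok(center, radius):
        r0, c0 = center
        return (
            radius + 1 <= r0 <= H - 2 - radius and radius + 1 <= c0 <= W - 2 - radius
        )

    def sample_center(radius):
        r0 = rng.uniform(radius + 1, H - 2 - radius)
        c0 = rng.uniform(radius + 1, W - 2 - radius)
        return (r0, c0)

    def place_group(group_radii):
        """Place a touching pair/chain (or a singleton) together, with retries."""
        placed_pairs = list(zip(centers, radii))
        for _ in range(_MAX_ATTEMPTS_PER_OBJECT):
            anchor = sample_center(group_radii[0])
            group = [(anchor, group_radii[0])]
            ok = not _too_close(anchor, group_radii[0], placed_pairs, 4.0)
            for rad in group_radii[1:]:
                if not ok:
                    break
                prev_center, prev_rad = group[-1]
                angle = rng.uniform(0, 2 * np.pi)
                dist = rng.uniform(prev_rad + rad - 1.9, prev_rad + rad - 0.1)
                cand = (
                    prev_center[0] + dist * np.sin(angle),
                    prev_center[1] + dist * np.cos(angle),
                )
                if not margin_ok(cand, rad):
                    ok = False
                    break
                # clearance from everything except the chain neighbour it touches
                others = placed_pairs + group[:-1]
                if _too_close(cand, rad, others, 4.0):
                    ok = False
                    break
                group.append((cand, rad))
            if ok:
                for c, rad in group:
                    centers.append(c)
                    radii.append(rad)
                return
        raise GenerationError(
            "could not place all nuclei under the separation rules; "
            "try fewer nuclei or a larger grid"
        )

    draw_r = lambda: float(rng.uniform(r_min, r_max))
    for i in range(n_pairs):
        size = 3 if (i == 0 and chain_extra) else 2
        place_group([draw_r() for _ in range(size)])
    n_single = cfg.n_nuclei - len(centers)
    if n_pairs == 0 and chain_extra:
        # touching count of 1 cannot form a pair; place it as a singleton
        n_single = cfg.n_nuclei - len(centers)
    for _ in range(n_single):
        place_group([draw_r()])

    truth_centroids = np.array(centers, dtype=float).reshape(-1, 2)
    truth_radii = np.array(radii, dtype=float)
    truth_mask = _render_disks((H, W), centers, radii)

    clutter_centers: list[tuple[float, float]] = []
    clutter_r = cfg.clutter_radius_multiplier * r_max
    placed_nuclei = list(zip(centers, radii))
    for _ in range(cfg.clutter_blobs):
        for _ in range(_MAX_ATTEMPTS_PER_OBJECT):
            cand = (
                rng.uniform(clutter_r + 1, H - 2 - clutter_r),
                rng.uniform(clutter_r + 1, W - 2 - clutter_r),
            )
            others = placed_nuclei + [(c, clutter_r) for c in clutter_centers]
            if not _too_close(cand, clutter_r, others, 6.0):
                clutter_centers.append(cand)
                break
        else:
            raise GenerationError(
                "could not place clutter blobs; try fewer blobs or a larger grid"
            )
    clutter_mask_truth = _render_disks((H, W), clutter_centers, [clutter_r] * len(clutter_centers))

    img = cfg.bg_level + (cfg.fg_level - cfg.bg_level) * np.maximum(truth_mask, clutter_mask_truth)
    if cfg.illumination_gradient > 0:
        rr, cc = np.mgrid[0:H, 0:W]
        ramp = (rr / max(H - 1, 1) + cc / max(W - 1, 1)) / 2.0
        img = img * (1.0 - cfg.illumination_gradient * ramp)
    if cfg.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=cfg.blur_sigma)
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    return FixtureSample(
        image=img,
        truth_centroids=truth_centroids,
        truth_radii=truth_radii,
        truth_mask=truth_mask,
        clutter_mask_truth=clutter_mask_truth,
        config=cfg,
    )


def generate_suite(base_cfg: FixtureConfig, n_images: int, seed: int) -> list[FixtureSample]:
    """Independent samples with seeds ``seed, seed + 1, ...`` and shared config."""
    if n_images < 1:
        raise InvalidInputError("n_images must be >= 1")
    return [generate(replace(base_cfg, seed=seed + i)) for i in range(n_images)]
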