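"""Joint convex segmentation with a sparse disk-dictionary shape prior.

The energy minimized here couples a convex relaxation of the active
contour without edges (ACWE) model with a sparse decomposition of the
segmentation into disk atoms::

    E(u, t) = TV(u) + mu * <u, s> + lambda * ||t||_1
              + (alpha / 2) * ||u - D t||_2^2

with ``u`` the relaxed labeling in [0, 1], ``s`` the ACWE data term
``(c_fg - f)^2 - (c_bg - f)^2``, ``t`` the per-radius atom-coefficient
stack in [0, 1], and ``D`` the dictionary synthesis operator.  The hard
constraint ``u = D t`` of the ideal model is relaxed into the quadratic
coupling term, which lets the contour accept nuclei that deviate slightly
from the disk model or partially overlap.

The energy is convex in ``(u, t)`` and is minimized by alternating:

* ``u``-update — primal-dual (Chambolle-Pock) iterations on the exact
  u-subproblem, the standard solver family for convex TV models of this
  form; the [0, 1] box constraint enters through the proximal step as a
  projection (the exact proximal map of the piecewise-linear barrier that
  is flat inside the box), and the returned iterate is guarded by an
  acceptance test on the exact subproblem energy, so the energy trace is
  non-increasing by construction.
* ``t``-update — proximal-gradient sweeps whose closed form is a
  soft-threshold followed by clipping any out-of-bound solution to the
  nearer bound of [0, 1]; steps backtrack from an aggressive size to the
  safe ``1 / L`` majorization step, again accepting only non-increasing
  subproblem energies.

Because the energy is convex, the minimizer — and hence the thresholded
segmentation — does not depend on the initialization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from .core import as_field, gradient, gradient_adjoint, inner_product, tv_norm
from .dictionary import DiskDictionary, synthesize, adjoint_synthesize
from .errors import (
    ConfigurationError,
    DegenerateImageError,
    InvalidInputError,
    OptimizerError,
)

__all__ = [
    "EnergyParams",
    "SegmentationResult",
    "estimate_intensities",
    "data_term",
    "energy",
    "update_u",
    "update_t",
    "segment",
    "threshold_u",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnergyParams:
    """Weights and schedule of the joint energy.

    Parameters
    ----------
    mu : float
        Weight of the ACWE data-fit term relative to total variation.
    lambda_sparsity : float or None
        Weight of the L1 penalty on atom coefficients.  ``None`` resolves
        to ``0.05 * (median atom area) * alpha_coupling``, which prices one
        full atom at 5% of its own coupling benefit.
    alpha_coupling : float
        Weight of the quadratic relaxation of the ``u = D t`` constraint.
    c_fg, c_bg : float
        Expected foreground/background intensities (normally estimated per
        image by :func:`estimate_intensities`).
    max_outer_iters, inner_u_iters, inner_t_iters : int
        Alternation schedule: outer alternations, Newton steps per
        ``u``-update, proximal sweeps per ``t``-update.
    tol : float
        Relative energy-change stopping threshold for the outer loop.
    u_threshold : float
        Binarization level in (0, 1); any level yields a global minimizer
        of the relaxed energy, 0.5 is the conventional choice.
    """

    mu: float = 2.0
    lambda_sparsity: float | None = None
    alpha_coupling: float = 0.5
    c_fg: float = 0.8
    c_bg: float = 0.1
    max_outer_iters: int = 300
    inner_u_iters: int = 30
    inner_t_iters: int = 10
    tol: float = 1e-5
    u_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ConfigurationError(f"mu must be > 0, got {self.mu}")
        if self.lambda_sparsity is not None and self.lambda_sparsity < 0:
            raise ConfigurationError("lambda_sparsity must be >= 0")
        if not self.alpha_coupling > 0:
            raise ConfigurationError("alpha_coupling must be > 0")
        if not (0 <= self.c_bg < self.c_fg <= 1):
            raise ConfigurationError(
                f"need 0 <= c_bg < c_fg <= 1, got c_bg={self.c_bg}, c_fg={self.c_fg}"
            )
        if not (0 < self.u_threshold < 1):
            raise ConfigurationError(f"u_threshold must be in (0, 1), got {self.u_threshold}")

    def resolved_lambda(self, dic: DiskDictionary) -> float:
        if self.lambda_sparsity is not None:
            return self.lambda_sparsity
        return 0.05 * dic.median_area * self.alpha_coupling


@dataclass
class SegmentationResult:
    """Output of :func:`segment`: relaxed labeling, coefficients, diagnostics."""

    u: np.ndarray
    t: np.ndarray
    energy_trace: list = field(default_factory=list)
    converged: bool = False


def estimate_intensities(image) -> tuple[float, float]:
    """Expected foreground/background intensities from an Otsu split.

    Returns ``(c_fg, c_bg)`` as the mean intensity above / at-or-below the
    Otsu threshold of the (preprocessed) image.
    """
    img = as_field(image)
    if img.min() == img.max():
        raise DegenerateImageError("constant image: intensity histogram cannot be split")
    thr = threshold_otsu(img)
    fg = img[img > thr]
    bg = img[img <= thr]
    if fg.size == 0 or bg.size == 0:  # Otsu guarantees a proper split, but be safe
        raise DegenerateImageError("degenerate histogram: Otsu produced an empty class")
    return float(fg.mean()), float(bg.mean())


def data_term(image, params: EnergyParams) -> np.ndarray:
    """ACWE data term ``s = (c_fg - f)^2 - (c_bg - f)^2``.

    Negative where the pixel resembles foreground, positive where it
    resembles background.
    """
    f = as_field(image)
    return (params.c_fg - f) ** 2 - (params.c_bg - f) ** 2


def energy(u, t, image, dic: DiskDictionary, params: EnergyParams) -> float:
    """Full joint energy of a ``(u, t)`` pair."""
    u = as_field(u)
    s = data_term(image, params)
    if u.shape != s.shape:
        raise InvalidInputError(f"u shape {u.shape} != image shape {s.shape}")
    lam = params.resolved_lambda(dic)
    resid = u - synthesize(t, dic)
    return (
        tv_norm(u)
        + params.mu * inner_product(u, s)
        + lam * float(np.abs(t).sum())
        + 0.5 * params.alpha_coupling * float(np.sum(resid * resid))
    )


def _u_subenergy(u: np.ndarray, s: np.ndarray, Dt: np.ndarray, params: EnergyParams) -> float:
    resid = u - Dt
    return (
        tv_norm(u)
        + params.mu * inner_product(u, s)
        + 0.5 * params.alpha_coupling * float(np.sum(resid * resid))
    )


def update_u(
    u, t, image, dic: DiskDictionary, params: EnergyParams, Dt=None, dual_state: dict | None = None
) -> np.ndarray:
    """One block update of ``u`` with ``t`` fixed.

    Runs ``inner_u_iters`` primal-dual iterations on the exact subproblem

        min_{0 <= u <= 1}  TV(u) + mu * <u, s> + (alpha / 2) * ||u - D t||^2,

    alternating a dual ascent step on the TV term (per-pixel projection of
    the dual field onto the unit ball) with the proximal step of the
    smooth part plus box constraint, which is a clipped closed form — the
    projection being the exact proximal map of the piecewise-linear
    barrier that is flat inside [0, 1].  The returned iterate is accepted
    only if the exact subproblem energy did not increase, so the
    u-subproblem energy is non-increasing.

    ``dual_state`` (a dict) optionally persists the dual field across
    calls to warm-start subsequent updates.
    """
    u = np.clip(as_field(u), 0.0, 1.0)
    alpha = params.alpha_coupling
    s = data_term(image, params)
    if Dt is None:
        Dt = synthesize(t, dic)
    e_start = _u_subenergy(u, s, Dt, params)

    # ||grad||^2 <= 8 for forward differences, so tau * sigma * 8 <= 1
    tau, sigma = 0.25, 0.5
    if dual_state is not None and "p" in dual_state:
        pr, pc = dual_state["p"]
    else:
        pr = np.zeros_like(u)
        pc = np.zeros_like(u)
    u_new = u.copy()
    u_bar = u.copy()
    for _ in range(params.inner_u_iters):
        gr, gc = gradient(u_bar)
        pr += sigma * gr
        pc += sigma * gc
        mag = np.maximum(1.0, np.hypot(pr, pc))
        pr /= mag
        pc /= mag
        u_prev = u_new
        v = u_new - tau * gradient_adjoint(pr, pc)
        u_new = np.clip((v - tau * params.mu * s + tau * alpha * Dt) / (1.0 + tau * alpha), 0.0, 1.0)
        u_bar = 2.0 * u_new - u_prev
    if not np.all(np.isfinite(u_new)):
        raise OptimizerError("u-update produced non-finite values", {"start_energy": e_start})
    if dual_state is not None:
        dual_state["p"] = (pr, pc)
    e_new = _u_subenergy(u_new, s, Dt, params)
    if e_new <= e_start + 1e-12 * max(1.0, abs(e_start)):
        return u_new
    return u  # transient increase (cold dual): keep the current iterate


def _t_subenergy(t: np.ndarray, u: np.ndarray, Dt: np.ndarray, lam: float, alpha: float) -> float:
    resid = u - Dt
    return lam * float(np.abs(t).sum()) + 0.5 * alpha * float(np.sum(resid * resid))


def update_t(u, t, dic: DiskDictionary, params: EnergyParams) -> np.ndarray:
    """One block update of ``t`` with ``u`` fixed.

    Proximal-gradient sweeps on

        min_t  lambda * ||t||_1 + (alpha / 2) * ||u - D t||_2^2,
        0 <= t <= 1,

    each sweep moving along the adjoint-synthesized residual and applying
    the closed-form scalar rule: soft-threshold, then clip any
    out-of-bound solution to the nearer bound of [0, 1] (the quadratic is
    monotone on an interval that excludes its extremum).  Steps backtrack
    from an aggressive size down to the safe majorization step
    ``1 / (alpha * ||D||^2)``; a sweep is accepted only if the subproblem
    energy does not increase.
    """
    u = as_field(u)
    t = np.clip(np.asarray(t, dtype=float), 0.0, 1.0)
    alpha = params.alpha_coupling
    lam = params.resolved_lambda(dic)

    norm_bound = dic.synthesis_norm_bound()
    tau_safe = 1.0 / (alpha * norm_bound * norm_bound)
    tau_fast = 1.0 / (alpha * 2.0 * norm_bound)

    Dt = synthesize(t, dic)
    f_cur = _t_subenergy(t, u, Dt, lam, alpha)
    for _ in range(params.inner_t_iters):
        g = alpha * adjoint_synthesize(Dt - u, dic)
        if not np.all(np.isfinite(g)):
            raise OptimizerError("t-update produced non-finite gradient")
        tau = tau_fast
        accepted = False
        while True:
            cand = np.clip(t - tau * (g + lam), 0.0, 1.0)
            Dc = synthesize(cand, dic)
            f_cand = _t_subenergy(cand, u, Dc, lam, alpha)
            if f_cand <= f_cur + 1e-12 * max(1.0, abs(f_cur)):
                t, Dt, f_cur, accepted = cand, Dc, f_cand, True
                break
            if tau <= tau_safe:
                break
            tau = max(tau / 4.0, tau_safe)
        if not accepted:  # at a subproblem stationary point
            break
    return t


def segment(
    image,
    dic: DiskDictionary,
    params: EnergyParams,
    u_init: float = 0.5,
) -> SegmentationResult:
    """Minimize the joint energy by alternating u- and t-updates.

    Starts from ``u = u_init`` everywhere and ``t = 0``; stops when the
    relative energy change falls below ``params.tol`` or after
    ``params.max_outer_iters`` alternations.  Constant images
    short-circuit to an empty segmentation with a warning.
    """
    img = as_field(image)
    e = len(dic)
    if img.min() == img.max():
        logger.warning("segment: constant image, returning empty segmentation")
        u = np.zeros_like(img)
        t = np.zeros((e, *img.shape))
        return SegmentationResult(u=u, t=t, energy_trace=[0.0], converged=True)

    u = np.full(img.shape, float(u_init))
    t = np.zeros((e, *img.shape))
    trace = [energy(u, t, img, dic, params)]
    converged = False
    dual_state: dict = {}
    for _ in range(params.max_outer_iters):
        Dt = synthesize(t, dic)
        u = update_u(u, t, img, dic, params, Dt=Dt, dual_state=dual_state)
        t = update_t(u, t, dic, params)
        E = energy(u, t, img, dic, params)
        trace.append(E)
        if abs(trace[-2] - E) <= params.tol * max(abs(trace[-2]), 1e-12):
            converged = True
            break
    if not converged:
        logger.warning(
            "segment: stopped after %d outer iterations without meeting tol=%g",
            params.max_outer_iters,
            params.tol,
        )
    return SegmentationResult(u=u, t=t, energy_trace=trace, converged=converged)


def threshold_u(u, level: float) -> np.ndarray:
    """Binarize the relaxed labeling: 1 where ``u > level`` (strict), else 0."""
    if not (0 < level < 1):
        raise ConfigurationError(f"threshold level must be in (0, 1), got {level}")
    return (as_field(u) > level).astype(float)
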