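"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as explicit loops / exhaustive
search, independent of the code paths it validates.
"""

from __future__ import annotations

import itertools

import numpy as np


def loop_gradient(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    H, W = f.shape
    dr = np.zeros_like(f)
    dc = np.zeros_like(f)
    for i in range(H):
        for j in range(W):
            if i < H - 1:
                dr[i, j] = f[i + 1, j] - f[i, j]
            if j < W - 1:
                dc[i, j] = f[i, j + 1] - f[i, j]
    return dr, dc


def loop_inner(a: np.ndarray, b: np.ndarray) -> float:
    total = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            total += a[i, j] * b[i, j]
    return total


def loop_tv(f: np.ndarray) -> float:
    dr, dc = loop_gradient(f)
    total = 0.0
    for i in range(f.shape[0]):
        for j in range(f.shape[1]):
            total += np.sqrt(dr[i, j] ** 2 + dc[i, j] ** 2)
    return total


def loop_disk_atom(radius: float, center: tuple[float, float], shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape)
    for i in range(shape[0]):
        for j in range(shape[1]):
            if (i - center[0]) ** 2 + (j - center[1]) ** 2 <= radius**2:
                out[i, j] = 1.0
    return out


def loop_synthesize(t: np.ndarray, radii) -> np.ndarray:
    """Per-atom summation: every nonzero coefficient adds its clipped disk."""
    e, H, W = t.shape
    out = np.zeros((H, W))
    for k, r in enumerate(radii):
        for i in range(H):
            for j in range(W):
                if t[k, i, j] != 0.0:
                    out += t[k, i, j] * loop_disk_atom(r, (i, j), (H, W))
    return out


def loop_local_normalize(img: np.ndarray, radius: int, epsilon: float) -> np.ndarray:
    """Window-scan local max (disk window clipped at borders), then divide."""
    H, W = img.shape
    floor = epsilon * img.max()
    out = np.zeros_like(img)
    for i in range(H):
        for j in range(W):
            m = 0.0
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    if di * di + dj * dj <= radius * radius:
                        ii, jj = i + di, j + dj
                        if 0 <= ii < H and 0 <= jj < W:
                            m = max(m, img[ii, jj])
            out[i, j] = img[i, j] / max(m, floor)
    return out


def loop_energy(u, t, img, radii, mu, lam, alpha, c_fg, c_bg) -> float:
    total = loop_tv(u)
    s = (c_fg - img) ** 2 - (c_bg - img) ** 2
    total += mu * loop_inner(u, s)
    total += lam * float(np.abs(t).sum())
    resid = u - loop_synthesize(t, radii)
    total += 0.5 * alpha * loop_inner(resid, resid)
    return total


def brute_force_otsu_means(img: np.ndarray, nbins: int = 256) -> tuple[float, float]:
    """Exhaustive between-class-variance maximization over histogram bins."""
    counts, edges = np.histogram(img.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_var, best_thr = -1.0, centers[0]
    total = counts.sum()
    for cut in range(1, nbins):
        w0 = counts[:cut].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:cut] * centers[:cut]).sum() / w0
        m1 = (counts[cut:] * centers[cut:]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_thr = var, centers[cut - 1]
    fg = img[img > best_thr]
    bg = img[img <= best_thr]
    return float(fg.mean()), float(bg.mean())


def brute_force_match_count(detections, truths, radius: float) -> int:
    """Max-cardinality (then min total distance) one-to-one matching.

    Exhaustive over all injective assignments; only usable for <= 8 points.
    """
    det = np.asarray(detections, dtype=float).reshape(-1, 2)
    tru = np.asarray(truths, dtype=float).reshape(-1, 2)
    n_t, n_d = len(tru), len(det)
    best = (0, 0.0)
    k_max = min(n_t, n_d)
    for k in range(k_max, -1, -1):
        best_dist = None
        for t_idx in itertools.combinations(range(n_t), k):
            for d_perm in itertools.permutations(range(n_d), k):
                dists = [
                    np.hypot(*(tru[i] - det[j])) for i, j in zip(t_idx, d_perm)
                ]
                if all(d <= radius for d in dists):
                    s = sum(dists)
                    if best_dist is None or s < best_dist:
                        best_dist = s
        if best_dist is not None:
            return k
    return 0


def simulate_greedy_selection(candidates):
    """Literal re-implementation of greedy suppression with list mutation.

    ``candidates`` is a list of (centroid(row, col), dominant_radius,
    score, area) tuples; returns the surviving centroids in acceptance
    order.
    """
    pool = list(candidates)
    out = []
    while pool:
        best = None
        for cand in pool:
            if best is None:
                best = cand
                continue
            c_cen, _c_rad, c_score, c_area = cand
            b_cen, _b_rad, b_score, b_area = best
            if (-c_score, -c_area, c_cen[0], c_cen[1]) < (-b_score, -b_area, b_cen[0], b_cen[1]):
                best = cand
        pool.remove(best)
        out.append(best)
        kept = []
        for cand in pool:
            d = np.hypot(cand[0][0] - best[0][0], cand[0][1] - best[0][1])
            if d > best[1]:
                kept.append(cand)
        pool = kept
    return out
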