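import dataclasses

import numpy as np
import pytest

from nucleidict.core import Grid2D
from nucleidict.dictionary import build_dictionary, make_disk_atom, synthesize
from nucleidict.errors import ConfigurationError, DegenerateImageError
from nucleidict.fixtures import FixtureConfig, generate
from nucleidict.preprocessing import PreprocessConfig, preprocess
from nucleidict.segmentation import (
    EnergyParams,
    data_term,
    energy,
    estimate_intensities,
    segment,
    threshold_u,
    update_t,
    update_u,
)
from nucleidict.metrics import dice

from oracles import brute_force_otsu_means, loop_energy


def test_params_validation():
    with pytest.raises(ConfigurationError):
        EnergyParams(mu=0)
    with pytest.raises(ConfigurationError):
        EnergyParams(c_fg=0.2, c_bg=0.4)
    with pytest.raises(ConfigurationError):
        EnergyParams(u_threshold=1.0)
    with pytest.raises(ConfigurationError):
        EnergyParams(alpha_coupling=0.0)


def test_estimate_intensities_bimodal():
    img = np.full((10, 10), 0.1)
    img.ravel()[:10] = 0.9
    c_fg, c_bg = estimate_intensities(img)
    assert c_fg == pytest.approx(0.9)
    assert c_bg == pytest.approx(0.1)


def test_estimate_intensities_disk_image():
    grid = Grid2D(32, 32)
    img = 0.2 + 0.6 * make_disk_atom(6, (16, 16), grid)
    c_fg, c_bg = estimate_intensities(img)
    assert c_fg == pytest.approx(0.8)
    assert c_bg == pytest.approx(0.2)


def test_estimate_intensities_matches_exhaustive_otsu(rng):
    img = np.where(
        rng.random((40, 40)) < 0.3,
        rng.normal(0.75, 0.05, (40, 40)),
        rng.normal(0.2, 0.05, (40, 40)),
    ).clip(0, 1)
    c_fg, c_bg = estimate_intensities(img)
    o_fg, o_bg = brute_force_otsu_means(img)
    assert c_fg == pytest.approx(o_fg, abs=1e-12)
    assert c_bg == pytest.approx(o_bg, abs=1e-12)


def test_estimate_intensities_constant_image_rejected():
    with pytest.raises(DegenerateImageError):
        estimate_intensities(np.full((5, 5), 0.3))


def test_data_term_signs(rng):
    params = EnergyParams(c_fg=0.8, c_bg=0.2)
    img = np.full((3, 3), 0.8)
    s = data_term(img, params)
    np.testing.assert_allclose(s, -((0.2 - 0.8) ** 2))
    mid = np.full((3, 3), 0.5)
    np.testing.assert_allclose(data_term(mid, params), 0.0, atol=1e-15)
    f = rng.uniform(0, 1, (4, 4))
    np.testing.assert_allclose(
        data_term(f, params), (0.8 - f) ** 2 - (0.2 - f) ** 2, atol=1e-15
    )


def test_energy_zero_and_constant_cases():
    d = build_dictionary(2, 2)
    img = np.full((6, 6), 0.5)
    params = EnergyParams(c_fg=0.9, c_bg=0.1, lambda_sparsity=1.0)
    assert energy(np.zeros((6, 6)), np.zeros((1, 6, 6)), img, d, params) == 0.0
    u1 = np.ones((6, 6))
    s = data_term(img, params)
    expected = params.mu * s.sum() + 0.5 * params.alpha_coupling * 36
    assert energy(u1, np.zeros((1, 6, 6)), img, d, params) == pytest.approx(expected)


def test_energy_matches_loop_oracle(rng):
    d = build_dictionary(1, 2, 1)
    img = rng.uniform(0, 1, (8, 8))
    u = rng.uniform(0, 1, (8, 8))
    t = rng.uniform(0, 1, (2, 8, 8)) * (rng.random((2, 8, 8)) < 0.2)
    params = EnergyParams(c_fg=0.7, c_bg=0.2, lambda_sparsity=0.3, mu=1.7, alpha_coupling=0.9)
    expected = loop_energy(u, t, img, d.radii, 1.7, 0.3, 0.9, 0.7, 0.2)
    assert energy(u, t, img, d, params) == pytest.approx(expected, abs=1e-10)


def _scalar_dict():
    """One pixel, one radius-0-like atom is not allowed (r >= 1); on a 1x1

    grid a radius-1 atom clips to area 1, giving an identity synthesis
    operator, which is what the scalar oracles need.
    """
    return build_dictionary(1, 1)


def test_update_u_saturates_under_strong_forces():
    d = _scalar_dict()
    params = EnergyParams(c_fg=0.9, c_bg=0.1, mu=50.0)
    img_fg = np.full((8, 8), 0.9)
    u = np.full((8, 8), 0.5)
    t = np.ones((1, 8, 8))
    out = update_u(u, t, img_fg, d, params)
    np.testing.assert_array_equal(out, np.ones((8, 8)))
    img_bg = np.full((8, 8), 0.1)
    out = update_u(u, np.zeros((1, 8, 8)), img_bg, d, params)
    np.testing.assert_array_equal(out, np.zeros((8, 8)))


def test_update_u_scalar_closed_form():
    """On 1x1 grids TV vanishes: stationary u is clip(Dt - mu*s/alpha)."""
    d = _scalar_dict()
    for f, tval, mu, alpha in [(0.9, 0.4, 1.0, 0.5), (0.3, 0.2, 2.0, 1.0), (0.75, 0.9, 0.5, 0.25)]:
        params = EnergyParams(c_fg=0.8, c_bg=0.1, mu=mu, alpha_coupling=alpha, lambda_sparsity=0.0)
        img = np.array([[f]])
        t = np.array([[[tval]]])
        s = float(data_term(img, params)[0, 0])
        expected = np.clip(tval - mu * s / alpha, 0.0, 1.0)
        u = np.array([[0.5]])
        for _ in range(200):
            u = update_u(u, t, img, d, params)
        assert u[0, 0] == pytest.approx(expected, abs=1e-8)


def test_update_t_zero_u_keeps_t_zero():
    d = _scalar_dict()
    params = EnergyParams(c_fg=0.8, c_bg=0.1)
    t = update_t(np.zeros((4, 4)), np.zeros((1, 4, 4)), d, params)
    np.testing.assert_array_equal(t, np.zeros((1, 4, 4)))


def test_update_t_scalar_matches_grid_search():
    """One pixel, one unit-area atom: argmin of lam*|t| + a/2*(u-t)^2 over [0,1]."""
    d = _scalar_dict()
    for uval, lam, alpha in [(0.9, 0.05, 0.5), (0.5, 0.3, 1.0), (0.2, 0.5, 2.0), (1.0, 0.0, 0.5)]:
        params = EnergyParams(
            c_fg=0.8, c_bg=0.1, lambda_sparsity=lam, alpha_coupling=alpha, inner_t_iters=200
        )
        u = np.array([[uval]])
        t = update_t(u, np.zeros((1, 1, 1)), d, params)
        grid = np.linspace(0, 1, 10001)
        obj = lam * grid + alpha / 2 * (uval - grid) ** 2
        best = grid[np.argmin(obj)]
        assert t[0, 0, 0] == pytest.approx(best, abs=1e-4)
        assert t[0, 0, 0] == pytest.approx(np.clip(uval - lam / alpha, 0, 1), abs=1e-4)


def test_update_t_single_atom_least_squares():
    """lambda = 0, u = one atom: the coefficient at the center goes to ~1."""
    grid = Grid2D(17, 17)
    d = build_dictionary(4, 4)
    u = make_disk_atom(4, (8, 8), grid)
    params = EnergyParams(c_fg=0.8, c_bg=0.1, lambda_sparsity=0.0, inner_t_iters=300)
    t = np.zeros((1, 17, 17))
    for _ in range(10):
        t = update_t(u, t, d, params)
    T = t[0]
    assert T.max() == T[8, 8]
    resid = u - synthesize(t, d)
    assert np.sum(resid**2) < 0.05 * u.sum()


def test_segment_background_image_gives_empty_mask():
    img = np.full((24, 24), 0.2)
    d = build_dictionary(3, 3)
    res = segment(img, d, EnergyParams(c_fg=0.8, c_bg=0.2))
    assert res.converged
    assert not threshold_u(res.u, 0.5).any()


def test_segment_recovers_single_disk():
    cfg = FixtureConfig(
        grid=Grid2D(64, 64),
        n_nuclei=1,
        radius_range=(7.0, 7.0),
        touching_fraction=0.0,
        clutter_blobs=0,
        blur_sigma=0.0,
        illumination_gradient=0.0,
        noise_sd=0.0,
        seed=11,
    )
    sample = generate(cfg)
    d = build_dictionary(7, 7)
    pre = preprocess(sample.image, PreprocessConfig(norm_radius=28))
    c_fg, c_bg = estimate_intensities(pre)
    params = dataclasses.replace(EnergyParams(), c_fg=c_fg, c_bg=c_bg)
    res = segment(pre, d, params)
    mask = threshold_u(res.u, params.u_threshold)
    assert dice(mask, sample.truth_mask) >= 0.9
    # coefficient mass concentrates within 2 px of the true center
    T = res.t.sum(axis=0)
    peak = np.unravel_index(np.argmax(T), T.shape)
    true_center = sample.truth_centroids[0]
    assert np.hypot(peak[0] - true_center[0], peak[1] - true_center[1]) <= 2.0


def test_segment_energy_trace_monotone(small_sample):
    pre = preprocess(small_sample.image, PreprocessConfig(norm_radius=32))
    c_fg, c_bg = estimate_intensities(pre)
    d = build_dictionary(8, 8)
    params = dataclasses.replace(EnergyParams(max_outer_iters=40), c_fg=c_fg, c_bg=c_bg)
    res = segment(pre, d, params)
    trace = np.asarray(res.energy_trace)
    assert np.all(np.diff(trace) <= 1e-9 * np.abs(trace[:-1]) + 1e-12)
    assert res.u.min() >= 0 and res.u.max() <= 1
    assert res.t.min() >= 0 and res.t.max() <= 1


def test_segment_initialization_independent(small_sample):
    """Convex energy: the thresholded result is the same from u0=0 and u0=0.5."""
    pre = preprocess(small_sample.image, PreprocessConfig(norm_radius=32))
    c_fg, c_bg = estimate_intensities(pre)
    d = build_dictionary(8, 8)
    params = dataclasses.replace(
        EnergyParams(tol=1e-7, max_outer_iters=500), c_fg=c_fg, c_bg=c_bg
    )
    res_a = segment(pre, d, params, u_init=0.5)
    res_b = segment(pre, d, params, u_init=0.0)
    mask_a = threshold_u(res_a.u, 0.5)
    mask_b = threshold_u(res_b.u, 0.5)
    assert dice(mask_a, mask_b) == 1.0


def test_segment_degenerates_to_acwe_otsu_mask():
    """lambda=0, alpha->0: thresholded u equals the Otsu mask on noiseless disks."""
    grid = Grid2D(48, 48)
    img = 0.1 + 0.8 * (
        make_disk_atom(6, (14, 14), grid) + make_disk_atom(6, (32, 33), grid)
    ).clip(0, 1)
    d = build_dictionary(6, 6)
    c_fg, c_bg = estimate_intensities(img)
    params = EnergyParams(
        mu=5.0,  # data term must dominate the TV perimeter cost at the boundary
        lambda_sparsity=0.0,
        alpha_coupling=1e-4,
        c_fg=c_fg,
        c_bg=c_bg,
        tol=1e-8,
        max_outer_iters=500,
    )
    res = segment(img, d, params)
    mask = threshold_u(res.u, 0.5)
    otsu_mask = (img > 0.5).astype(float)  # two-valued image: Otsu splits the levels
    assert dice(mask, otsu_mask) == 1.0


def test_threshold_u():
    u = np.array([[0.2, 0.5, 0.8]])
    np.testing.assert_array_equal(threshold_u(u, 0.5), [[0, 0, 1]])
    np.testing.assert_array_equal(threshold_u(np.ones((2, 2)), 0.5), np.ones((2, 2)))
    with pytest.raises(ConfigurationError):
        threshold_u(u, 0.0)


def test_segment_constant_image_short_circuits(caplog):
    img = np.full((16, 16), 0.4)
    d = build_dictionary(3, 3)
    res = segment(img, d, EnergyParams(c_fg=0.8, c_bg=0.2))
    assert res.converged and not res.u.any() and not res.t.any()
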