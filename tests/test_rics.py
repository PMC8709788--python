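"""ARICS correlation, detrending, diffusion fits, rel.cc arithmetic."""

import numpy as np
import pytest

from cipkit import GAMMA_3D, ScanConfig, SpeciesSpec
from cipkit.rics import (CorrelationMap, binding_efficiency,
                         compute_correlation, fit_diffusion_model,
                         highpass_detrend, relative_cross_correlation,
                         rics_model, screen_expression_balance, RICSFit)
from cipkit.synth import simulate_raster_scan


def brute_force_arics(a, b, mask, max_xi, max_psi):
    """Double-loop reference implementation of the masked correlation."""
    t, ny, nx = a.shape
    mi = a[:, mask].mean()
    mj = b[:, mask].mean()
    g = np.full((2 * max_psi + 1, 2 * max_xi + 1), np.nan)
    for dy in range(-max_psi, max_psi + 1):
        for dx in range(-max_xi, max_xi + 1):
            acc, npair = 0.0, 0
            for f in range(t):
                da = a[f] - a[f][mask].mean()
                db = b[f] - b[f][mask].mean()
                for y in range(ny):
                    for x in range(nx):
                        y2, x2 = y + dy, x + dx
                        if (0 <= y2 < ny and 0 <= x2 < nx
                                and mask[y, x] and mask[y2, x2]):
                            acc += da[y, x] * db[y2, x2]
                            npair += 1
            if npair:
                g[dy + max_psi, dx + max_xi] = acc / (npair * mi * mj)
    return g


# ---------------------------------------------------------------------------
# detrending
# ---------------------------------------------------------------------------

def test_detrend_constant_stack_unchanged():
    out = highpass_detrend(np.full((12, 4, 4), 2.5))
    assert out.shape == (8, 4, 4)
    assert np.allclose(out, 2.5)


def test_detrend_removes_linear_drift_preserves_time_constancy():
    t = np.arange(24, dtype=float)[:, None, None]
    stack = 3.0 + 0.7 * t + np.zeros((1, 3, 3))
    out = highpass_detrend(stack)
    assert np.allclose(out.std(axis=0), 0.0, atol=1e-10)


def test_detrend_white_noise_variance_factor(rng):
    """Residual variance of the symmetric 4-frame moving-average filter:
    1 - 2 sum(w_0) + sum(w^2) with weights (1/8, 1/4, 1/4, 1/4, 1/8)."""
    x = rng.standard_normal((40000, 3, 3))
    out = highpass_detrend(x)
    expected = 1.0 - 2.0 * 0.25 + (2 * (1 / 64) + 3 * (1 / 16))
    assert out.var(axis=0).mean() == pytest.approx(expected, rel=0.03)
    assert out.mean() == pytest.approx(x.mean(), abs=0.01)


def test_detrend_rejects_bad_windows():
    with pytest.raises(ValueError):
        highpass_detrend(np.zeros((10, 2, 2)), window=1)
    with pytest.raises(ValueError):
        highpass_detrend(np.zeros((3, 2, 2)), window=4)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def test_arics_equals_brute_force_with_irregular_mask(rng):
    a = rng.uniform(1.0, 2.0, size=(3, 16, 16))
    b = rng.uniform(1.0, 2.0, size=(3, 16, 16))
    mask = rng.uniform(size=(16, 16)) > 0.35
    ref = brute_force_arics(a, b, mask, 3, 2)
    cm = compute_correlation(a, b, mask, 3, 2)
    assert np.nanmax(np.abs(cm.g - ref)) < 1e-10
    ref_acf = brute_force_arics(a, a, mask, 3, 2)
    cm_acf = compute_correlation(a, None, mask, 3, 2)
    assert np.nanmax(np.abs(cm_acf.g - ref_acf)) < 1e-10


def test_full_frame_mask_equals_classical_rics(rng):
    """With an all-true mask the ARICS estimator reduces to the classical
    unmasked correlation."""
    a = rng.uniform(1.0, 2.0, size=(2, 12, 12))
    full = np.ones((12, 12), dtype=bool)
    ref = brute_force_arics(a, a, full, 4, 3)
    cm = compute_correlation(a, None, None, 4, 3)
    assert np.nanmax(np.abs(cm.g - ref)) < 1e-10


def test_zero_lag_is_variance_over_mean_squared(rng):
    a = rng.uniform(1.0, 3.0, size=(4, 10, 10))
    cm = compute_correlation(a, None, None, 2, 2)
    d = a - a.mean(axis=(1, 2), keepdims=True)
    assert cm.value(0, 0) == pytest.approx((d ** 2).mean() / a.mean() ** 2)


def test_acf_map_is_point_symmetric(rng):
    a = rng.uniform(1.0, 2.0, size=(3, 12, 12))
    cm = compute_correlation(a, None, None, 4, 4)
    assert np.allclose(cm.g, cm.g[::-1, ::-1], equal_nan=True)


def test_correlation_input_validation(rng):
    a = rng.uniform(1, 2, (3, 8, 8))
    with pytest.raises(ValueError):
        compute_correlation(a, None, np.zeros((8, 8), bool), 2, 2)
    with pytest.raises(ValueError):
        compute_correlation(a, None, None, 8, 2)
    with pytest.raises(ValueError):
        compute_correlation(a, rng.uniform(1, 2, (3, 9, 8)), None, 2, 2)


# ---------------------------------------------------------------------------
# model fit
# ---------------------------------------------------------------------------

def model_map(cfg, n, d, offset=0.0, max_xi=16, max_psi=8):
    xi = np.arange(-max_xi, max_xi + 1)
    psi = np.arange(-max_psi, max_psi + 1)
    x, p = np.meshgrid(xi, psi)
    g = rics_model(x, p, n, d, offset, cfg)
    return CorrelationMap(g, xi, psi, np.ones_like(g, dtype=np.int64),
                          10, 1.0, 1.0, True)


def test_fit_recovers_noiseless_model_parameters():
    cfg = ScanConfig(frame_shape=(64, 64), n_frames=10)
    fit = fit_diffusion_model(model_map(cfg, 3.0, 1.2), cfg)
    assert fit.converged
    assert fit.n == pytest.approx(3.0, rel=1e-6)
    assert fit.d == pytest.approx(1.2, rel=1e-6)
    assert fit.offset == pytest.approx(0.0, abs=1e-9)


def test_immobile_limit_is_pure_gaussian():
    """At D -> 0 the model is a Gaussian in lag radius with variance set by
    the PSF waist in pixel units."""
    cfg = ScanConfig(frame_shape=(64, 64), n_frames=10)
    xi = np.arange(-10, 11, dtype=float)
    g = rics_model(xi, np.zeros_like(xi), 2.0, 0.0, 0.0, cfg)
    w0_px = cfg.w0_um / cfg.pixel_size_um
    expected = GAMMA_3D / 2.0 * np.exp(-(xi ** 2) / w0_px ** 2)
    assert np.allclose(g, expected, rtol=1e-12)


def test_fit_failure_reports_nonconvergence_not_exception(rng):
    """A pure-noise cross-correlation map must yield converged=False."""
    cfg = ScanConfig(frame_shape=(64, 64), n_frames=10)
    xi = np.arange(-8, 9)
    psi = np.arange(-4, 5)
    g = rng.normal(0.0, 1e-4, size=(psi.size, xi.size))
    cmap = CorrelationMap(g, xi, psi, np.ones_like(g, dtype=np.int64),
                          10, 1.0, 1.0, False)
    fit = fit_diffusion_model(cmap, cfg)
    assert isinstance(fit.converged, bool)
    assert not fit.converged


def test_fitted_amplitude_halves_when_particle_number_doubles():
    """G(0,0) ~ gamma/N: doubling the simulated concentration halves the
    fitted amplitude."""
    cfg = ScanConfig(frame_shape=(64, 64), n_frames=50,
                     n_spectral_channels=1)
    amps = {}
    for n_part in (1300, 2600):
        vals = []
        for seed in range(4):
            s = SpeciesSpec("a", 1.0, 80.0, np.array([1.0]), n_part)
            stack, _ = simulate_raster_scan(cfg, [s], seed=100 + seed)
            cm = compute_correlation(stack.data[..., 0].astype(float),
                                     None, None, 16, 16)
            fit = fit_diffusion_model(cm, cfg)
            assert fit.converged
            vals.append(fit.g0)
        amps[n_part] = np.mean(vals)
    assert amps[1300] / amps[2600] == pytest.approx(2.0, rel=0.15)


# ---------------------------------------------------------------------------
# rel.cc and binding efficiency
# ---------------------------------------------------------------------------

def fake_fit(g0, converged=True):
    return RICSFit(n=GAMMA_3D / g0, d=1.0, offset=0.0, gamma=GAMMA_3D,
                   converged=converged, redchi=0.0)


def test_relative_cross_correlation_arithmetic():
    res = relative_cross_correlation(fake_fit(0.5), fake_fit(1.0),
                                     fake_fit(2.0))
    assert res.rel_cc == pytest.approx(0.5)
    assert res.g_cc == pytest.approx(0.5)


def test_nonconverged_ccf_gives_zero_rel_cc():
    res = relative_cross_correlation(fake_fit(0.5, converged=False),
                                     fake_fit(1.0), fake_fit(2.0))
    assert res.rel_cc == 0.0
    assert not res.cc_converged


def test_rel_cc_requires_converged_acfs_and_positive_amplitudes():
    with pytest.raises(ValueError):
        relative_cross_correlation(fake_fit(0.5), fake_fit(1.0, False),
                                   fake_fit(2.0))
    with pytest.raises(ValueError):
        relative_cross_correlation(fake_fit(0.5), fake_fit(np.inf),
                                   fake_fit(2.0))


def test_binding_efficiency_endpoints_and_clipping():
    assert binding_efficiency(0.2, 0.2, 0.9).value == pytest.approx(0.0)
    assert binding_efficiency(0.9, 0.2, 0.9).value == pytest.approx(1.0)
    assert binding_efficiency(0.55, 0.2, 0.9).value == pytest.approx(0.5)
    res = binding_efficiency(0.1, 0.2, 0.9)
    assert res.value == 0.0 and res.clipped_low
    res = binding_efficiency(1.0, 0.2, 0.9)
    assert res.value > 1.0 and res.exceeds_unity
    # alternative normalization: divide by the positive control alone
    res = binding_efficiency(0.45, 0.0, 0.9, normalize_span=False)
    assert res.value == pytest.approx(0.5)
    with pytest.raises(ValueError):
        binding_efficiency(0.5, 0.9, 0.2)


def test_expression_balance_screen_boundary():
    assert screen_expression_balance([1.0, 1.0, 1.0])
    assert not screen_expression_balance([1.0, 1.0, 3.5])
    assert not screen_expression_balance([1.0, 1.0, 3.0])   # strict
    assert screen_expression_balance({"a": 1.0, "b": 2.9})
    with pytest.raises(ValueError):
        screen_expression_balance([1.0])
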