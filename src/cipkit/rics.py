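"""Arbitrary-region raster image correlation spectroscopy (ARICS).

Spatial auto- and cross-correlation functions are computed over pixel lags
``xi`` (fast scan axis, x) and line lags ``psi`` (slow axis, y):

    G(xi, psi) = < dI_i(x, y) dI_j(x + xi, y + psi) > / (<I_i> <I_j>)

with ``dI = I - <I>_mask`` per frame and the average taken over *valid*
pixel pairs only — pairs with both pixels inside the region-of-interest
mask, normalized per lag by the number of such pairs.  This is the
arbitrary-region contract: an irregular cytoplasmic ROI yields the same
estimator as a full frame restricted to that region.

The normal-diffusion RICS model fitted to these maps is

    G(xi, psi) = gamma / N
                 * (1 + 4 D tau / w0^2)^-1 * (1 + 4 D tau / wz^2)^-1/2
                 * exp( - dr^2 (xi^2 + psi^2) / (w0^2 + 4 D tau) )
                 + offset,
    tau = tau_p |xi| + tau_l |psi|

with the scan parameters (pixel size ``dr``, dwell time ``tau_p``, line
time ``tau_l``) and PSF waists fixed, ``gamma = 2^(-3/2)``.

From the fitted zero-lag amplitudes the relative cross-correlation

    rel.cc = max{ G_CC,ij(0,0) / G_AC,i(0,0), G_CC,ij(0,0) / G_AC,j(0,0) }

is a proxy for the bound fraction; rescaling it between a negative control
(independent fluorophores) and a positive control (covalent heterodimer)
gives the binding efficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import lmfit
import numpy as np
from scipy.fft import next_fast_len, irfft2, rfft2

from .scan import GAMMA_3D, ScanConfig

__all__ = [
    "CorrelationMap",
    "RICSFit",
    "RelCCResult",
    "BindingEfficiency",
    "highpass_detrend",
    "compute_correlation",
    "fit_diffusion_model",
    "rics_model",
    "relative_cross_correlation",
    "binding_efficiency",
    "screen_expression_balance",
    "binding_analysis",
]


# ---------------------------------------------------------------------------
# high-pass detrending
# ---------------------------------------------------------------------------

def highpass_detrend(stack: np.ndarray, window: int = 4) -> np.ndarray:
    """Remove slow per-pixel signal variations with a moving-window filter.

    Per pixel, the average of the two 4-frame windows adjacent to each frame
    (a symmetric weighting 1/8, 1/4, 1/4, 1/4, 1/8 for ``window=4``) is
    subtracted and the pixel's global temporal mean added back, preserving
    mean intensities for amplitude normalization.  Linear drifts cancel
    exactly.  Edges are trimmed: the output has ``T - window`` frames.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if window < 2:
        raise ValueError("window must be >= 2")
    t = stack.shape[0]
    if t <= window:
        raise ValueError("need more frames than the window length")
    csum = np.cumsum(np.concatenate([np.zeros((1,) + stack.shape[1:]), stack],
                                    axis=0), axis=0)
    ma = (csum[window:] - csum[:-window]) / window   # ma[j] = mean frames j..j+w-1
    half = window // 2
    sym = 0.5 * (ma[:-1] + ma[1:])                   # centred at j + w/2
    pixel_mean = stack.mean(axis=0)
    trimmed = stack[half:half + sym.shape[0]]
    return trimmed - sym + pixel_mean


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMap:
    """Spatial correlation function over (line lag psi, pixel lag xi)."""

    g: np.ndarray               # (2*max_psi+1, 2*max_xi+1)
    xi: np.ndarray              # pixel lags, fast axis
    psi: np.ndarray             # line lags, slow axis
    n_pairs: np.ndarray         # valid pixel pairs per lag (same shape as g)
    n_frames: int
    mean_i: float
    mean_j: float
    is_autocorrelation: bool

    def value(self, xi: int, psi: int) -> float:
        """G at a single (pixel, line) lag."""
        ix = int(np.where(self.xi == xi)[0][0])
        iy = int(np.where(self.psi == psi)[0][0])
        return float(self.g[iy, ix])


def compute_correlation(stack_i: np.ndarray, stack_j: np.ndarray | None = None,
                        roi_mask: np.ndarray | None = None,
                        max_xi: int = 32, max_psi: int = 16) -> CorrelationMap:
    """ARICS auto-/cross-correlation of (detrended) image stacks.

    Parameters
    ----------
    stack_i, stack_j
        Co-registered stacks with axes (frame, y, x).  Pass the same array
        (or ``stack_j=None``) for an autocorrelation.
    roi_mask
        Boolean pixel mask; only pairs with both pixels inside the mask
        contribute, each lag normalized by its own valid-pair count.
        Defaults to the full frame.
    """
    a = np.asarray(stack_i, dtype=np.float64)
    is_acf = stack_j is None or stack_j is stack_i
    b = a if is_acf else np.asarray(stack_j, dtype=np.float64)
    if a.ndim != 3 or b.shape != a.shape:
        raise ValueError("stacks must be 3D (T, Y, X) and share a shape")
    t, ny, nx = a.shape
    if roi_mask is None:
        roi_mask = np.ones((ny, nx), dtype=bool)
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != (ny, nx):
        raise ValueError("mask shape does not match the stacks")
    if not mask.any():
        raise ValueError("empty ROI mask")
    if max_xi >= nx or max_psi >= ny:
        raise ValueError("requested lags exceed the image size")

    mean_i = float(a[:, mask].mean())
    mean_j = float(b[:, mask].mean())
    if mean_i <= 0 or mean_j <= 0:
        raise ValueError("non-positive mean intensity inside the mask")

    sy = next_fast_len(ny + max_psi)
    sx = next_fast_len(nx + max_xi)
    maskf = mask.astype(np.float64)
    fmask = rfft2(maskf, s=(sy, sx))
    pair_map = irfft2(np.conj(fmask) * fmask, s=(sy, sx))

    num = np.zeros((sy, sx))
    for frame in range(t):
        da = (a[frame] - a[frame][mask].mean()) * maskf
        db = da if (is_acf and b is a) else (b[frame] - b[frame][mask].mean()) * maskf
        fa = rfft2(da, s=(sy, sx))
        fb = fa if (is_acf and b is a) else rfft2(db, s=(sy, sx))
        num += irfft2(np.conj(fa) * fb, s=(sy, sx))

    xi = np.arange(-max_xi, max_xi + 1)
    psi = np.arange(-max_psi, max_psi + 1)
    g = np.full((psi.size, xi.size), np.nan)
    n_pairs = np.zeros((psi.size, xi.size), dtype=np.int64)
    for iy, dy in enumerate(psi):
        for ix, dx in enumerate(xi):
            pairs = pair_map[dy % sy, dx % sx]
            npair = int(round(pairs))
            n_pairs[iy, ix] = npair
            if npair > 0:
                g[iy, ix] = num[dy % sy, dx % sx] / (t * npair * mean_i * mean_j)
    if not np.isfinite(g).any():
        raise ValueError("mask has no valid pairs at the requested lags")
    return CorrelationMap(g, xi, psi, n_pairs, t, mean_i, mean_j, is_acf)


# ---------------------------------------------------------------------------
# model fit
# ---------------------------------------------------------------------------

def rics_model(xi: np.ndarray, psi: np.ndarray, n: float, d: float,
               offset: float, config: ScanConfig,
               gamma: float = GAMMA_3D) -> np.ndarray:
    """Normal-diffusion RICS correlation model on a lag grid (in pixels)."""
    xi = np.asarray(xi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    tau = config.dwell_s * np.abs(xi) + config.line_s * np.abs(psi)
    k = 4.0 * d * tau
    w0sq = config.w0_um ** 2
    wzsq = config.wz_um ** 2
    dr = config.pixel_size_um
    diff = (1.0 + k / w0sq) ** -1 * (1.0 + k / wzsq) ** -0.5
    scan = np.exp(-dr ** 2 * (xi ** 2 + psi ** 2) / (w0sq + k))
    return gamma / n * diff * scan + offset


@dataclass
class RICSFit:
    """Result of a normal-diffusion fit to a correlation map."""

    n: float                    # effective particles in the focal volume
    d: float                    # diffusion coefficient, um^2/s
    offset: float
    gamma: float
    converged: bool
    redchi: float
    n_stderr: float | None = None
    d_stderr: float | None = None
    message: str = ""

    @property
    def g0(self) -> float:
        """Fitted zero-lag amplitude gamma / N (offset excluded)."""
        if self.n == 0:
            return float("inf")
        return self.gamma / self.n


# D outside this range (um^2/s), solver failure, or relative parameter
# uncertainties above 100% mark a fit as not converged to meaningful
# parameters.
D_MEANINGFUL = (1e-3, 1e3)


def fit_diffusion_model(cmap: CorrelationMap, config: ScanConfig,
                        init: dict | None = None,
                        exclude_zero_lag: bool = True,
                        gamma: float = GAMMA_3D) -> RICSFit:
    """Least-squares fit of the normal-diffusion RICS model.

    ``exclude_zero_lag`` drops the (0, 0) pixel, which in photon-counting
    data carries the shot-noise spike — for autocorrelations always, and
    also for cross-correlations between spectrally decomposed stacks, where
    the species channels are linear combinations of the *same* detector
    counts and therefore share shot noise at zero lag.

    Fit failure is reported through ``converged=False``, never raised.
    """
    xi_grid, psi_grid = np.meshgrid(cmap.xi, cmap.psi)
    g = cmap.g
    sel = np.isfinite(g)
    if exclude_zero_lag:
        sel &= ~((xi_grid == 0) & (psi_grid == 0))
    if not np.any(sel):
        raise ValueError("no finite correlation values to fit")
    x = xi_grid[sel].astype(float)
    y = psi_grid[sel].astype(float)
    z = g[sel]
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite correlation values")

    amp0 = np.nanmax(z) - np.nanmedian(z)
    if not np.isfinite(amp0) or amp0 <= 0:
        amp0 = 1e-3
    defaults = {"n": gamma / amp0, "d": 1.0, "offset": float(np.nanmedian(z))}
    if init:
        defaults.update(init)
    params = lmfit.Parameters()
    params.add("n", value=float(np.clip(defaults["n"], 1e-4, 1e8)),
               min=1e-6, max=1e10)
    params.add("d", value=float(np.clip(defaults["d"], 1e-5, 1e4)),
               min=1e-6, max=1e6)
    params.add("offset", value=defaults["offset"], min=-1.0, max=1.0)

    def residual(p):
        return rics_model(x, y, p["n"].value, p["d"].value,
                          p["offset"].value, config, gamma) - z

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = lmfit.minimize(residual, params, method="leastsq",
                                    xtol=1e-12, ftol=1e-12)
    except Exception as exc:  # solver blow-up counts as non-convergence
        return RICSFit(np.nan, np.nan, np.nan, gamma, False, np.nan,
                       message=f"solver failure: {exc}")

    n = float(result.params["n"].value)
    d = float(result.params["d"].value)
    offset = float(result.params["offset"].value)
    n_err = result.params["n"].stderr
    d_err = result.params["d"].stderr
    ok = bool(result.success)
    ok &= D_MEANINGFUL[0] <= d <= D_MEANINGFUL[1]
    if n_err is not None and d_err is not None:
        ok &= n_err <= abs(n) and d_err <= abs(d)
    else:
        # uncertainties unavailable: accept only the exact-model corner
        # case where residuals are negligible relative to the amplitude
        rms = float(np.sqrt(result.chisqr / max(result.ndata, 1)))
        ok &= rms < 1e-6 * abs(gamma / n)
    return RICSFit(n, d, offset, gamma, bool(ok), float(result.redchi),
                   n_stderr=None if n_err is None else float(n_err),
                   d_stderr=None if d_err is None else float(d_err),
                   message=str(result.message))


# ---------------------------------------------------------------------------
# relative cross-correlation and binding efficiency
# ---------------------------------------------------------------------------

@dataclass
class RelCCResult:
    """Relative cross-correlation of one channel pair."""

    rel_cc: float
    g_cc: float                 # CCF amplitude (0 if fit not converged)
    g_ac_i: float
    g_ac_j: float
    cc_converged: bool
    pair: tuple[str, str] = ("i", "j")


def relative_cross_correlation(fit_cc: RICSFit, fit_ac_i: RICSFit,
                               fit_ac_j: RICSFit,
                               pair: tuple[str, str] = ("i", "j"),
                               ) -> RelCCResult:
    """rel.cc = max{G_CC/G_AC,i, G_CC/G_AC,j}; zero if the CCF fit did not
    converge to meaningful parameters."""
    if not (fit_ac_i.converged and fit_ac_j.converged):
        raise ValueError("both autocorrelation fits must have converged")
    g_i, g_j = fit_ac_i.g0, fit_ac_j.g0
    if g_i <= 0 or g_j <= 0 or not np.isfinite(g_i * g_j):
        raise ValueError("zero or invalid autocorrelation amplitude")
    if not fit_cc.converged:
        return RelCCResult(0.0, 0.0, g_i, g_j, False, pair)
    g_cc = fit_cc.g0
    rel = max(g_cc / g_i, g_cc / g_j)
    return RelCCResult(float(max(rel, 0.0)), float(g_cc), g_i, g_j, True, pair)


@dataclass
class BindingEfficiency:
    """Control-normalized binding efficiency for one channel pair."""

    value: float
    raw: float                  # before clipping
    clipped_low: bool
    exceeds_unity: bool
    pair: tuple[str, str] = ("i", "j")


def binding_efficiency(sample: RelCCResult | float,
                       negative: RelCCResult | float,
                       positive: RelCCResult | float,
                       normalize_span: bool = True) -> BindingEfficiency:
    """Rescale a sample rel.cc between negative and positive controls.

    ``normalize_span=True`` (default) computes
    ``(sample - negative) / (positive - negative)``; with ``False`` the
    denominator is the positive control alone (the alternative reading of
    the normalization).  Values are clipped below at 0; values above 1 are
    kept but flagged.
    """
    def _v(x):
        return x.rel_cc if isinstance(x, RelCCResult) else float(x)

    s, n, p = _v(sample), _v(negative), _v(positive)
    pair = sample.pair if isinstance(sample, RelCCResult) else ("i", "j")
    if p <= n:
        raise ValueError(
            f"degenerate controls: positive ({p:.4g}) <= negative ({n:.4g})")
    denom = (p - n) if normalize_span else p
    raw = (s - n) / denom
    value = max(raw, 0.0)
    return BindingEfficiency(float(value), float(raw), raw < 0.0,
                             raw > 1.0, pair)


def screen_expression_balance(mean_intensities: Sequence[float] | dict[str, float],
                              max_ratio: float = 3.0) -> bool:
    """Accept a cell only if all species are expressed in comparable amounts.

    Rejects when any pairwise ratio of mean signal intensities reaches
    ``max_ratio`` (strict: a ratio of exactly 3 is rejected).
    """
    if isinstance(mean_intensities, dict):
        values = np.array(list(mean_intensities.values()), dtype=float)
    else:
        values = np.asarray(mean_intensities, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two species to compare")
    if np.any(values <= 0):
        return False
    return bool(values.max() / values.min() < max_ratio)


# ---------------------------------------------------------------------------
# high-level two/three-species binding analysis
# ---------------------------------------------------------------------------

def binding_analysis(species_stacks: dict[str, np.ndarray],
                     config: ScanConfig,
                     roi_mask: np.ndarray | None = None,
                     detrend_window: int = 4,
                     max_xi: int = 32, max_psi: int = 16,
                     ) -> dict:
    """ACFs, pairwise CCFs and rel.cc for spectrally decomposed stacks.

    Parameters
    ----------
    species_stacks
        Mapping species name -> decomposed 3D stack (frame, y, x).

    Returns a dict with per-species ``acf_fits`` and per-pair
    ``rel_cc`` (:class:`RelCCResult`) keyed by the name pair.
    """
    names = list(species_stacks.keys())
    if len(names) < 2:
        raise ValueError("need at least two species")
    processed = {}
    for name in names:
        st = species_stacks[name]
        processed[name] = (highpass_detrend(st, detrend_window)
                           if detrend_window else np.asarray(st, float))
    acf_fits: dict[str, RICSFit] = {}
    for name in names:
        cmap = compute_correlation(processed[name], None, roi_mask,
                                   max_xi, max_psi)
        acf_fits[name] = fit_diffusion_model(cmap, config)
    rel_cc: dict[tuple[str, str], RelCCResult] = {}
    for a_idx in range(len(names)):
        for b_idx in range(a_idx + 1, len(names)):
            na, nb = names[a_idx], names[b_idx]
            cmap = compute_correlation(processed[na], processed[nb],
                                       roi_mask, max_xi, max_psi)
            fit_cc = fit_diffusion_model(cmap, config)
            rel_cc[(na, nb)] = relative_cross_correlation(
                fit_cc, acf_fits[na], acf_fits[nb], pair=(na, nb))
    return {"acf_fits": acf_fits, "rel_cc": rel_cc}
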