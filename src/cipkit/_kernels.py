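"""Low-level line-scan rendering kernels.

A raster frame is rendered line by line: all particles take one Brownian
step per scan line (positions are frozen within a line, valid because the
pixel dwell time is three orders of magnitude shorter than the line time),
then every particle near the current line deposits its 3D-Gaussian PSF
weight onto the pixels of that line.  Boundaries are periodic in all three
axes of the simulation box (periodic replacement in z keeps the particle
number in the slab stationary).

Two implementations with identical arithmetic are provided: a numba-compiled
kernel used when numba is importable and a vectorized numpy reference kernel
(also used to cross-check the compiled kernel in the test suite).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco

__all__ = ["scan_frame", "scan_frame_numpy", "have_numba"]


def have_numba() -> bool:
    return _HAVE_NUMBA


@njit(cache=True)
def _scan_frame_numba(pos, normals, sigma, lx, ly, lz, y0, x0, dr,
                      inv2w0sq, inv2wzsq, cutoff, out):  # pragma: no cover
    rows, ncols = out.shape
    npart = pos.shape[0]
    half_lz = 0.5 * lz
    cut_px = int(math.ceil(cutoff / dr))
    for l in range(rows):
        for p in range(npart):
            x = (pos[p, 0] + sigma * normals[l, p, 0]) % lx
            y = (pos[p, 1] + sigma * normals[l, p, 1]) % ly
            z = (pos[p, 2] + sigma * normals[l, p, 2]) % lz
            pos[p, 0] = x
            pos[p, 1] = y
            pos[p, 2] = z
        y_line = y0 + l * dr
        for p in range(npart):
            dy = pos[p, 1] - y_line
            dy -= ly * round(dy / ly)
            if abs(dy) >= cutoff:
                continue
            zc = pos[p, 2] - half_lz
            amp = math.exp(-dy * dy * inv2w0sq - zc * zc * inv2wzsq)
            if amp < 1e-6:
                continue
            xc = (pos[p, 0] - x0) / dr
            i0 = int(math.ceil(xc - cut_px))
            i1 = int(math.floor(xc + cut_px))
            if i0 < 0:
                i0 = 0
            if i1 > ncols - 1:
                i1 = ncols - 1
            for i in range(i0, i1 + 1):
                dx = x0 + i * dr - pos[p, 0]
                dx -= lx * round(dx / lx)
                if abs(dx) < cutoff:
                    out[l, i] += amp * math.exp(-dx * dx * inv2w0sq)


def scan_frame_numpy(pos: np.ndarray, normals: np.ndarray, sigma: float,
                     lx: float, ly: float, lz: float, y0: float, x0: float,
                     dr: float, inv2w0sq: float, inv2wzsq: float,
                     cutoff: float, out: np.ndarray) -> None:
    """Vectorized reference implementation of one rendered frame.

    Mutates ``pos`` (particle positions after the last line of the frame)
    and accumulates PSF weights into ``out`` (rows, cols).
    """
    rows, ncols = out.shape
    half_lz = 0.5 * lz
    cut_px = int(math.ceil(cutoff / dr))
    xs = x0 + np.arange(ncols) * dr
    for l in range(rows):
        pos[:, 0] = (pos[:, 0] + sigma * normals[l, :, 0]) % lx
        pos[:, 1] = (pos[:, 1] + sigma * normals[l, :, 1]) % ly
        pos[:, 2] = (pos[:, 2] + sigma * normals[l, :, 2]) % lz
        y_line = y0 + l * dr
        dy = pos[:, 1] - y_line
        dy -= ly * np.round(dy / ly)
        zc = pos[:, 2] - half_lz
        amp = np.exp(-dy * dy * inv2w0sq - zc * zc * inv2wzsq)
        sel = (np.abs(dy) < cutoff) & (amp >= 1e-6)
        if not np.any(sel):
            continue
        px = pos[sel, 0]
        a = amp[sel]
        # same pixel window as the compiled kernel
        xc = (px - x0) / dr
        i0 = np.maximum(np.ceil(xc - cut_px).astype(np.int64), 0)
        i1 = np.minimum(np.floor(xc + cut_px).astype(np.int64), ncols - 1)
        for p in range(px.size):
            if i1[p] < i0[p]:
                continue
            dx = xs[i0[p]:i1[p] + 1] - px[p]
            dx = dx - lx * np.round(dx / lx)
            w = np.where(np.abs(dx) < cutoff,
                         np.exp(-dx * dx * inv2w0sq), 0.0)
            out[l, i0[p]:i1[p] + 1] += a[p] * w


def scan_frame(pos, normals, sigma, lx, ly, lz, y0, x0, dr,
               inv2w0sq, inv2wzsq, cutoff, out):
    """Render one frame, preferring the compiled kernel."""
    if _HAVE_NUMBA:
        _scan_frame_numba(pos, normals, sigma, lx, ly, lz, y0, x0, dr,
                          inv2w0sq, inv2wzsq, cutoff, out)
    else:
        scan_frame_numpy(pos, normals, sigma, lx, ly, lz, y0, x0, dr,
                         inv2w0sq, inv2wzsq, cutoff, out)
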