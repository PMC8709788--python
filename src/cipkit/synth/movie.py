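"""Synthetic two-channel translocation time-lapse movies.

Emulates an alternating-excitation epifluorescence acquisition of a cell in
which a cytosolic receiver protein is recruited to mitochondria after
addition of a chemical inducer of proximity (CIP):

* the receptor channel shows a constant mitochondria-mask signal times a
  photobleaching decay;
* the receiver channel starts purely cytosolic; after CIP addition a
  fraction ``depletion`` of the cytosolic pool transfers to the
  mitochondria mask with exponential kinetics ``f(t) = 1 - exp(-k t)``.
  The amount recruited onto mitochondria exactly equals the amount lost
  from the cell-wide cytosolic component, so whole-frame intensity is
  conserved up to bleaching;
* a Gaussian illumination profile, optional sub-pixel channel
  misalignment, per-channel photobleaching, Poisson photon noise, and
  optional corrupted illumination-sequence pairs or focus-loss segments
  exercise the preprocessing and QC stages downstream.

The measured mito/cytosol intensity ratio of this model is analytic
(:meth:`MovieGroundTruth.analytic_ratio`, including the camera background
pedestal), and linear in ``f`` to first order in ``depletion``,

so after min-max normalization between the pre-addition and end anchors the
trajectory equals ``f(t)`` up to a small positive bias of order
``depletion / 4`` in the crossing time (exact expression in the methods
note); at ``depletion=0`` the normalized trajectory is exactly
``1 - exp(-k t)`` but whole-frame conservation no longer holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse
from skimage.morphology import dilation, disk

__all__ = [
    "MovieParams",
    "TimelapseMovie",
    "MovieGroundTruth",
    "simulate_translocation_movie",
    "make_cell_mask",
    "make_mito_mask",
    "gaussian_illumination",
]


@dataclass(frozen=True)
class MovieParams:
    """Acquisition and sample parameters of a simulated translocation movie."""

    shape: tuple[int, int] = (128, 128)
    frame_interval_s: float = 1.0
    duration_s: float = 60.0
    injection_delay_s: float = 3.0      # mixing delay after CIP addition
    t0_time_s: float = -5.0             # pre-addition reference pair
    cytosol_counts: float = 200.0       # mean receiver counts per cytosol px
    receptor_counts: float = 300.0      # mean receptor counts per mito px
    background_counts: float = 5.0
    depletion: float = 0.05             # recruited fraction of the pool
    bleach_rate_receiver: float = 5e-4  # 1/s, mono-exponential
    bleach_rate_receptor: float = 5e-4
    illumination_sigma_frac: float = 0.8  # Gaussian profile sigma / min(shape)
    channel_shift: tuple[float, float] = (0.6, -0.4)  # receptor (dy, dx) px
    psf_sigma_px: float = 1.0
    poisson: bool = True
    mito_area_frac: tuple[float, float] = (0.12, 0.28)
    swapped_pairs: tuple[int, ...] = ()   # pair indices with wrong codes
    focus_loss_pairs: tuple[int, ...] = ()
    n_alignment_beads: int = 40

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be > 0")
        if self.duration_s <= self.injection_delay_s:
            raise ValueError("duration must exceed the injection delay")
        if not 0.0 <= self.depletion < 1.0:
            raise ValueError("depletion must be in [0, 1)")
        if self.t0_time_s >= 0:
            raise ValueError("the t0 pair must precede CIP addition (t < 0)")


@dataclass
class TimelapseMovie:
    """Ordered receiver/receptor image pairs with timestamps.

    Pair 0 is the pre-addition t0 pair; the last pair is t_end.  Timestamps
    are seconds relative to CIP addition.  ``codes`` holds the
    illumination-sequence code of each pair (expected ``("488", "561")``).
    """

    receiver: np.ndarray        # (n_pairs, y, x)
    receptor: np.ndarray
    timestamps: np.ndarray      # (n_pairs,)
    codes: list[tuple[str, str]]
    injection_delay_s: float = 3.0
    alignment_reference: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        n = self.receiver.shape[0]
        if self.receptor.shape != self.receiver.shape:
            raise ValueError("channel shapes differ")
        if self.timestamps.shape != (n,) or len(self.codes) != n:
            raise ValueError("timestamps/codes do not match the pair count")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.timestamps[0] >= 0:
            raise ValueError("the first pair must precede CIP addition")

    @property
    def n_pairs(self) -> int:
        return self.receiver.shape[0]

    def subset(self, keep: np.ndarray) -> "TimelapseMovie":
        keep = np.asarray(keep)
        return TimelapseMovie(self.receiver[keep], self.receptor[keep],
                              self.timestamps[keep],
                              [self.codes[i] for i in np.flatnonzero(keep)]
                              if keep.dtype == bool else
                              [self.codes[i] for i in keep],
                              self.injection_delay_s,
                              self.alignment_reference)


@dataclass
class MovieGroundTruth:
    k_true: float
    t75_true: float             # ln(4) / k_true
    cell_mask: np.ndarray
    mito_mask: np.ndarray
    channel_shift: tuple[float, float]
    bleach_rate_receiver: float
    bleach_rate_receptor: float
    depletion: float
    cytosol_counts: float = 200.0
    background_counts: float = 5.0
    seed: int | None = None

    def analytic_ratio(self, t: np.ndarray) -> np.ndarray:
        """Noise-free mito/cytosol ratio at times ``t`` (s after addition).

        Includes the camera background pedestal present in both ROIs.
        """
        f = np.where(np.asarray(t) > 0,
                     1.0 - np.exp(-self.k_true * np.asarray(t)), 0.0)
        a_cell = self.cell_mask.sum()
        a_mito = self.mito_mask.sum()
        beta = self.depletion
        c0 = self.cytosol_counts
        bg = self.background_counts
        cyto = bg + c0 * (1.0 - beta * f)
        mito = cyto + beta * f * c0 * a_cell / a_mito
        return mito / cyto


def make_cell_mask(shape: tuple[int, int],
                   rng: np.random.Generator) -> np.ndarray:
    """Elliptical whole-cell mask with random size, rotation and offset."""
    ny, nx = shape
    cy = ny / 2 + rng.uniform(-0.04, 0.04) * ny
    cx = nx / 2 + rng.uniform(-0.04, 0.04) * nx
    ry = rng.uniform(0.30, 0.38) * ny
    rx = rng.uniform(0.30, 0.38) * nx
    rot = rng.uniform(0, np.pi)
    rr, cc = ellipse(cy, cx, ry, rx, shape=shape, rotation=rot)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def make_mito_mask(cell_mask: np.ndarray, rng: np.random.Generator,
                   area_frac: tuple[float, float] = (0.12, 0.28),
                   thickness: int = 2, n_steps: int = 80) -> np.ndarray:
    """Random curvilinear blobs inside the cell, mimicking mitochondria.

    Persistent random walks seeded inside the (eroded) cell are dilated to
    ``2*thickness+1`` px wide filaments until the mitochondrial area
    fraction of the cell lies inside ``area_frac``.
    """
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    ny, nx = cell_mask.shape
    interior = ndimage.binary_erosion(cell_mask, iterations=3)
    iy, ix = np.nonzero(interior)
    if iy.size == 0:
        raise ValueError("cell mask too small for mitochondria")
    target = rng.uniform(*area_frac)
    cell_area = cell_mask.sum()
    trace = np.zeros_like(cell_mask)
    selem = disk(thickness)
    for _ in range(200):
        mito = dilation(trace, selem) & cell_mask
        if mito.sum() / cell_area >= target:
            break
        start = rng.integers(iy.size)
        y, x = float(iy[start]), float(ix[start])
        angle = rng.uniform(0, 2 * np.pi)
        for _ in range(n_steps):
            angle += rng.normal(0.0, 0.35)
            y += math.sin(angle)
            x += math.cos(angle)
            yi, xi = int(round(y)), int(round(x))
            if not (0 <= yi < ny and 0 <= xi < nx) or not interior[yi, xi]:
                break
            trace[yi, xi] = True
    mito = dilation(trace, selem) & cell_mask
    if not mito.any():
        raise ValueError("failed to place mitochondria inside the cell")
    return mito


def gaussian_illumination(shape: tuple[int, int], sigma_frac: float,
                          center: tuple[float, float] | None = None,
                          ) -> np.ndarray:
    """Gaussian excitation profile normalized to a maximum of 1."""
    ny, nx = shape
    if center is None:
        center = ((ny - 1) / 2, (nx - 1) / 2)
    sig = sigma_frac * min(ny, nx)
    yy, xx = np.mgrid[0:ny, 0:nx]
    prof = np.exp(-((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
                  / (2 * sig ** 2))
    return prof / prof.max()


def _render_pair(cell, mito, f, beta, params, illum, bleach_factors):
    """Noise-free receiver/receptor images at recruited fraction ``f``."""
    a_cell = cell.sum()
    a_mito = mito.sum()
    c0 = params.cytosol_counts
    receiver = np.full(cell.shape, params.background_counts, dtype=float)
    # cell-wide cytosolic component (also under mitochondria)
    receiver[cell] += c0 * (1.0 - beta * f)
    # recruited component: everything the pool lost, concentrated on mito
    receiver[mito] += beta * f * c0 * a_cell / a_mito
    receptor = np.full(cell.shape, params.background_counts, dtype=float)
    receptor[mito] += params.receptor_counts
    out = []
    for img, bleach in zip((receiver, receptor), bleach_factors):
        img = ndimage.gaussian_filter(img, params.psf_sigma_px)
        out.append(img * illum * bleach)
    return out


def simulate_translocation_movie(params: MovieParams, k_true: float,
                                 seed: int | None = None,
                                 ) -> tuple[TimelapseMovie, MovieGroundTruth]:
    """Simulate a two-channel CIP-translocation time-lapse.

    ``k_true`` is the exponential recruitment rate (1/s); the analytic 75%
    crossing time of the recruitment process is ``ln(4) / k_true``.
    """
    if k_true <= 0:
        raise ValueError("k_true must be > 0")
    rng = np.random.default_rng(seed)
    cell = make_cell_mask(params.shape, rng)
    mito = make_mito_mask(cell, rng, params.mito_area_frac)

    times = [params.t0_time_s]
    t = params.injection_delay_s
    while t <= params.duration_s + 1e-9:
        times.append(t)
        t += params.frame_interval_s
    times = np.asarray(times)
    illum = gaussian_illumination(params.shape, params.illumination_sigma_frac)

    receivers, receptors, codes = [], [], []
    elapsed0 = times - times[0]
    for idx, ti in enumerate(times):
        f = 1.0 - math.exp(-k_true * ti) if ti > 0 else 0.0
        bleach = (math.exp(-params.bleach_rate_receiver * elapsed0[idx]),
                  math.exp(-params.bleach_rate_receptor * elapsed0[idx]))
        rec, cap = _render_pair(cell, mito, f, params.depletion, params,
                                illum, bleach)
        if any(abs(s) > 0 for s in params.channel_shift):
            cap = ndimage.shift(cap, params.channel_shift, order=1,
                                mode="nearest")
        if idx in params.focus_loss_pairs:
            rec = rec * 0.35
            cap = cap * 0.35
        if params.poisson:
            rec = rng.poisson(rec).astype(float)
            cap = rng.poisson(cap).astype(float)
        code = ("488", "561")
        if idx in params.swapped_pairs:
            rec, cap = cap, rec
            code = ("561", "488")
        receivers.append(rec)
        receptors.append(cap)
        codes.append(code)

    align_ref = None
    if params.n_alignment_beads > 0:
        base = np.full(params.shape, params.background_counts, dtype=float)
        by = rng.uniform(5, params.shape[0] - 5, params.n_alignment_beads)
        bx = rng.uniform(5, params.shape[1] - 5, params.n_alignment_beads)
        base[np.round(by).astype(int), np.round(bx).astype(int)] += 2000.0
        base = ndimage.gaussian_filter(base, 1.2)
        ref_a = rng.poisson(base).astype(float)
        shifted = ndimage.shift(base, params.channel_shift, order=1,
                                mode="nearest")
        ref_b = rng.poisson(shifted).astype(float)
        align_ref = (ref_a, ref_b)

    movie = TimelapseMovie(np.stack(receivers), np.stack(receptors), times,
                           codes, params.injection_delay_s, align_ref)
    truth = MovieGroundTruth(k_true, math.log(4.0) / k_true, cell, mito,
                             params.channel_shift,
                             params.bleach_rate_receiver,
                             params.bleach_rate_receptor,
                             params.depletion, params.cytosol_counts,
                             params.background_counts, seed)
    return movie, truth
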