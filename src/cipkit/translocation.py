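"""Translocation-kinetics quantification from two-channel time-lapse movies.

The pipeline turns alternating-excitation receiver/receptor image pairs
into a normalized mitochondria/cytosol intensity-ratio trajectory and the
translocation time ``t0.75`` — the time after CIP addition at which the
normalized trajectory first reaches 75% of its maximum:

1. illumination-sequence validation (corrupted pairs dropped),
2. flat-field correction with an illumination template,
3. sub-pixel channel alignment (phase correlation on bead references),
4. segmentation: whole cell from the purely cytosolic pre-addition
   receiver image, mitochondria per pair from the receptor channel,
5. photobleaching correction from the whole-frame intensity decay,
6. mito/cytosol ratio per pair, min-max normalized between the
   pre-addition anchor ratio_t0 and the final anchor ratio_tend,
7. linear-interpolation estimate of the 0.75 upward crossing,
8. QC flags (unstable receptor signal -> exclude; whole-cell receiver
   drift beyond 2% -> warn).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu
from skimage.morphology import disk, white_tophat
from skimage.registration import phase_cross_correlation

from .synth.movie import TimelapseMovie

__all__ = [
    "ROISet",
    "TranslocationTrajectory",
    "QCFlags",
    "validate_illumination_sequence",
    "flatfield_correct",
    "align_channels",
    "segment_cell",
    "segment_mitochondria",
    "build_rois",
    "extract_trajectory",
    "estimate_t75",
    "qc_exclude",
    "analyze_movie",
]

EXPECTED_CODE = ("488", "561")
TEMPLATE_FLOOR = 0.02
MITO_FRACTION_TYPICAL = (0.10, 0.40)   # sanity range of mito/cell area
MITO_FRACTION_HARD = (0.01, 0.60)      # outside -> QC warning


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def validate_illumination_sequence(movie: TimelapseMovie,
                                   expected: tuple[str, str] = EXPECTED_CODE,
                                   ) -> tuple[TimelapseMovie, float]:
    """Drop image pairs whose illumination-sequence code is wrong.

    Returns the cleaned movie and the fraction of pairs dropped.  Raises if
    nothing survives or if the pre-addition anchor pair itself is bad.
    """
    good = np.array([c == expected for c in movie.codes])
    if not good.any():
        raise ValueError("all image pairs have corrupted illumination codes")
    if not good[0]:
        raise ValueError("the pre-addition (t0) pair has a corrupted code")
    frac = 1.0 - good.mean()
    if frac == 0.0:
        return movie, 0.0
    return movie.subset(good), float(frac)


def flatfield_correct(image: np.ndarray, template: np.ndarray,
                      floor: float = TEMPLATE_FLOOR) -> np.ndarray:
    """Divide out the illumination profile.

    ``template`` is an illumination template normalized to max 1 (so the
    correction multiplies by the reciprocal template).  Pixels where the
    template falls below ``floor`` are masked to 0 rather than amplified.
    """
    template = np.asarray(template, dtype=float)
    if template.shape != image.shape:
        raise ValueError("template shape does not match the image")
    if not math.isclose(float(template.max()), 1.0, rel_tol=1e-6):
        raise ValueError("template must be normalized to a maximum of 1")
    valid = template >= floor
    out = np.zeros_like(np.asarray(image, dtype=float))
    out[valid] = image[valid] / template[valid]
    return out


def align_channels(movie: TimelapseMovie,
                   reference_transform: tuple[float, float] | None = None,
                   upsample_factor: int = 50,
                   ) -> tuple[TimelapseMovie, tuple[float, float]]:
    """Register the receptor channel onto the receiver channel.

    The translation is estimated once per movie by phase correlation on the
    bead reference pair (sub-pixel, Tetraspek-style fiducials) and applied
    to every receptor frame; alternatively a known ``reference_transform``
    (dy, dx) is applied directly.  A low-confidence estimate (weak
    correlation peak) triggers a warning.
    """
    if reference_transform is not None:
        shift = tuple(float(s) for s in reference_transform)
    else:
        if movie.alignment_reference is None:
            return movie, (0.0, 0.0)
        ref_a, ref_b = movie.alignment_reference
        shift_arr, error, _ = phase_cross_correlation(
            ref_a, ref_b, upsample_factor=upsample_factor,
            normalization=None)
        shift = (float(shift_arr[0]), float(shift_arr[1]))
        if error > 0.95:
            warnings.warn("low-confidence channel alignment "
                          f"(phase-correlation error {error:.3f})",
                          stacklevel=2)
        # estimates below the registration resolution are treated as zero
        if all(abs(s) < 0.05 for s in shift):
            shift = (0.0, 0.0)
    if all(abs(s) < 1e-6 for s in shift):
        return movie, (0.0, 0.0)
    aligned = np.stack([ndimage.shift(fr, shift, order=1, mode="nearest")
                        for fr in movie.receptor])
    out = TimelapseMovie(movie.receiver, aligned, movie.timestamps,
                         list(movie.codes), movie.injection_delay_s,
                         movie.alignment_reference)
    return out, shift


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_cell(t0_receiver_image: np.ndarray,
                 smooth_sigma: float = 2.0) -> np.ndarray:
    """Whole-cell mask from the purely cytosolic pre-addition receiver image.

    Gaussian blur, Otsu threshold, hole filling, largest connected
    component.
    """
    img = ndimage.gaussian_filter(np.asarray(t0_receiver_image, float),
                                  smooth_sigma)
    if img.max() <= img.min():
        raise ValueError("blank image: cannot segment the cell")
    mask = img > threshold_otsu(img)
    if not mask.any():
        raise ValueError("cell segmentation produced an empty mask")
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("cell segmentation produced an empty mask")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def segment_mitochondria(receptor_image: np.ndarray,
                         cell_mask: np.ndarray | None = None,
                         tophat_radius: int = 4) -> np.ndarray:
    """Mitochondria mask from one receptor-channel image.

    White top-hat (suppresses smooth background) followed by a per-image
    Otsu threshold; optionally restricted to the cell mask.
    """
    img = np.asarray(receptor_image, dtype=float)
    if img.max() <= img.min():
        raise ValueError("blank image: cannot segment mitochondria")
    flat = white_tophat(img, disk(tophat_radius))
    thresh = threshold_otsu(flat)
    mask = flat > thresh
    if cell_mask is not None:
        mask &= cell_mask
    if not mask.any():
        raise ValueError("mitochondria segmentation produced an empty mask")
    return mask


@dataclass
class ROISet:
    """Per-movie segmentation: one cell mask, per-pair mitochondria masks.

    Cytosol ROIs are the difference between the (t0) whole-cell mask and
    the current pair's mitochondria mask.
    """

    cell_mask: np.ndarray                 # from the t0 receiver image
    mito_masks: list[np.ndarray]          # one per pair

    def cytosol_mask(self, pair_index: int) -> np.ndarray:
        cyto = self.cell_mask & ~self.mito_masks[pair_index]
        if not cyto.any():
            raise ValueError("empty cytosol ROI")
        return cyto

    def mito_fraction(self, pair_index: int) -> float:
        return float(self.mito_masks[pair_index].sum() / self.cell_mask.sum())


def build_rois(movie: TimelapseMovie) -> ROISet:
    """Segment the whole cell (t0 receiver) and per-pair mitochondria."""
    cell = segment_cell(movie.receiver[0])
    mitos = [segment_mitochondria(fr, cell) for fr in movie.receptor]
    rois = ROISet(cell, mitos)
    frac = rois.mito_fraction(0)
    if not MITO_FRACTION_HARD[0] <= frac <= MITO_FRACTION_HARD[1]:
        warnings.warn(
            f"mitochondrial area fraction {frac:.2f} outside "
            f"{MITO_FRACTION_HARD} (typical {MITO_FRACTION_TYPICAL})",
            stacklevel=2)
    return rois


# ---------------------------------------------------------------------------
# trajectory extraction
# ---------------------------------------------------------------------------

@dataclass
class TranslocationTrajectory:
    """Normalized mito/cytosol translocation trajectory of one cell."""

    times: np.ndarray            # s relative to CIP addition, post pairs
    ratio: np.ndarray            # raw mito/cytosol ratios, post pairs
    ratio_t0: float
    ratio_tend: float
    normalized: np.ndarray
    qc: "QCFlags | None" = None

    def normalize(self) -> "TranslocationTrajectory":
        """Re-apply the anchor normalization (idempotent)."""
        span = self.ratio_tend - self.ratio_t0
        if abs(span) < 1e-12:
            raise ValueError("degenerate normalization: ratio_tend equals "
                             "ratio_t0 (no translocation)")
        norm = (self.ratio - self.ratio_t0) / span
        return TranslocationTrajectory(self.times, self.ratio, self.ratio_t0,
                                       self.ratio_tend, norm, self.qc)


def _bleach_correction(frames: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Divide frames by a mono-exponential fitted to whole-frame means.

    Falls back to a linear trend if the exponential fit fails; the
    correction is normalized to the first time point.
    """
    means = frames.mean(axis=(1, 2))
    t = times - times[0]
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, b: a * np.exp(-b * tt), t, means,
            p0=[float(means[0]), 1e-4], maxfev=5000)
        trend = popt[0] * np.exp(-popt[1] * t)
    except Exception:
        coef = np.polyfit(t, means, 1)
        trend = np.polyval(coef, t)
    trend = np.clip(trend / trend[0], 1e-6, None)
    return frames / trend[:, None, None]


def extract_trajectory(movie: TimelapseMovie, rois: ROISet,
                       bleach_correct: bool = True,
                       plateau_mean_pairs: int = 1,
                       ) -> TranslocationTrajectory:
    """Mito/cytosol ratio trajectory, anchored and min-max normalized.

    ``plateau_mean_pairs`` > 1 averages the last pairs for the end anchor
    instead of using the final pair alone.
    """
    receiver = np.asarray(movie.receiver, dtype=float)
    if bleach_correct:
        receiver = _bleach_correction(receiver, movie.timestamps)

    def ratio_at(i: int) -> float:
        mito = rois.mito_masks[i]
        cyto = rois.cytosol_mask(i)
        denom = receiver[i][cyto].mean()
        if denom <= 0:
            raise ValueError("non-positive cytosol intensity")
        return float(receiver[i][mito].mean() / denom)

    ratios = np.array([ratio_at(i) for i in range(movie.n_pairs)])
    ratio_t0 = ratios[0]
    k = max(1, int(plateau_mean_pairs))
    ratio_tend = float(ratios[-k:].mean())
    span = ratio_tend - ratio_t0
    if abs(span) < 1e-12:
        raise ValueError("degenerate normalization: ratio_tend equals "
                         "ratio_t0 (no translocation)")
    # time origin: first post-addition pair minus the injection delay
    origin = movie.timestamps[1] - movie.injection_delay_s
    times = movie.timestamps[1:] - origin
    norm = (ratios[1:] - ratio_t0) / span
    return TranslocationTrajectory(times, ratios[1:], ratio_t0, ratio_tend,
                                   norm)


def estimate_t75(traj: TranslocationTrajectory,
                 threshold: float = 0.75) -> float:
    """First upward crossing of the normalized trajectory, interpolated.

    The trajectory is anchored at (t=0, 0) — the moment of CIP addition —
    so a crossing before the first acquired pair is interpolated from the
    origin.  Raises if the trajectory never reaches the threshold.
    """
    t = np.concatenate([[0.0], traj.times])
    v = np.concatenate([[0.0], traj.normalized])
    above = v >= threshold
    if not above.any():
        raise ValueError(f"trajectory never reached {threshold:g}")
    idx = int(np.argmax(above))
    if idx == 0:
        raise ValueError("trajectory starts above the threshold")
    t0, t1 = t[idx - 1], t[idx]
    v0, v1 = v[idx - 1], v[idx]
    if v1 == v0:
        return float(t1)
    return float(t0 + (threshold - v0) * (t1 - t0) / (v1 - v0))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCFlags:
    excluded: bool
    receptor_mito_cv: float
    whole_cell_variation: float
    warn_whole_cell: bool
    dropped_pair_fraction: float = 0.0


def qc_exclude(movie: TimelapseMovie, rois: ROISet,
               cv_threshold: float = 0.20,
               whole_cell_threshold: float = 0.02,
               dropped_fraction: float = 0.0) -> QCFlags:
    """Flag unreliable segmentations and unstable acquisitions.

    A cell is excluded when the bleach-corrected receptor signal inside the
    mitochondria ROI varies over time with a coefficient of variation above
    ``cv_threshold``; whole-cell receiver intensity variation beyond
    ``whole_cell_threshold`` (2%) after bleach correction raises a warning
    flag only.
    """
    receptor = _bleach_correction(np.asarray(movie.receptor, float),
                                  movie.timestamps)
    mito_means = np.array([receptor[i][rois.mito_masks[i]].mean()
                           for i in range(movie.n_pairs)])
    cv = float(mito_means.std() / mito_means.mean())

    receiver = _bleach_correction(np.asarray(movie.receiver, float),
                                  movie.timestamps)
    cell_means = np.array([receiver[i][rois.cell_mask].mean()
                           for i in range(movie.n_pairs)])
    variation = float((cell_means.max() - cell_means.min())
                      / cell_means.mean())
    return QCFlags(cv > cv_threshold, cv, variation,
                   variation > whole_cell_threshold, dropped_fraction)


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def analyze_movie(movie: TimelapseMovie,
                  template: np.ndarray | None = None,
                  reference_transform: tuple[float, float] | None = None,
                  plateau_mean_pairs: int = 1,
                  ) -> tuple[TranslocationTrajectory, float]:
    """Full pipeline: validation, flat-fielding, alignment, segmentation,
    trajectory extraction and t0.75 estimation.

    Returns the trajectory (with QC flags attached) and the estimated
    t0.75 in seconds.
    """
    movie, dropped = validate_illumination_sequence(movie)
    if template is not None:
        receiver = np.stack([flatfield_correct(fr, template)
                             for fr in movie.receiver])
        receptor = np.stack([flatfield_correct(fr, template)
                             for fr in movie.receptor])
        movie = TimelapseMovie(receiver, receptor, movie.timestamps,
                               list(movie.codes), movie.injection_delay_s,
                               movie.alignment_reference)
    movie, _ = align_channels(movie, reference_transform)
    rois = build_rois(movie)
    traj = extract_trajectory(movie, rois,
                              plateau_mean_pairs=plateau_mean_pairs)
    traj.qc = qc_exclude(movie, rois, dropped_fraction=dropped)
    t75 = estimate_t75(traj)
    return traj, t75
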