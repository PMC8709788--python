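"""Translocation pipeline: preprocessing, segmentation, t0.75 extraction."""

import math

import numpy as np
import pytest

from cipkit.synth import (MovieParams, TimelapseMovie, gaussian_illumination,
                          make_illumination_template,
                          simulate_translocation_movie)
from cipkit.translocation import (ROISet, TranslocationTrajectory,
                                  align_channels, analyze_movie, build_rois,
                                  estimate_t75, extract_trajectory,
                                  flatfield_correct, qc_exclude, segment_cell,
                                  segment_mitochondria,
                                  validate_illumination_sequence)

K_FAST = math.log(4.0) / 10.1


# ---------------------------------------------------------------------------
# illumination-sequence validation
# ---------------------------------------------------------------------------

def test_clean_movie_passes_unchanged():
    movie, _ = simulate_translocation_movie(MovieParams(), K_FAST, seed=0)
    cleaned, frac = validate_illumination_sequence(movie)
    assert frac == 0.0
    assert cleaned is movie


def test_swapped_pair_removed_exactly():
    movie, _ = simulate_translocation_movie(
        MovieParams(swapped_pairs=(5,)), K_FAST, seed=1)
    n0 = movie.n_pairs
    t_bad = movie.timestamps[5]
    cleaned, frac = validate_illumination_sequence(movie)
    assert cleaned.n_pairs == n0 - 1
    assert frac == pytest.approx(1 / n0)
    assert t_bad not in cleaned.timestamps


def test_all_pairs_bad_is_an_error():
    movie, _ = simulate_translocation_movie(MovieParams(), K_FAST, seed=2)
    bad = TimelapseMovie(movie.receiver, movie.receptor, movie.timestamps,
                         [("561", "488")] * movie.n_pairs,
                         movie.injection_delay_s)
    with pytest.raises(ValueError):
        validate_illumination_sequence(bad)


# ---------------------------------------------------------------------------
# flat-field correction
# ---------------------------------------------------------------------------

def test_flatfield_identity_and_profile_removal(rng):
    img = rng.uniform(50, 60, size=(32, 32))
    assert np.allclose(flatfield_correct(img, np.ones((32, 32))), img)
    profile = gaussian_illumination((64, 64), 0.5)
    flat = np.full((64, 64), 200.0)
    observed = rng.poisson(flat * profile).astype(float)
    corrected = flatfield_correct(observed, profile)
    inner = corrected[8:-8, 8:-8]
    assert inner.std() / inner.mean() < 0.12      # Poisson floor only
    assert inner.mean() == pytest.approx(200.0, rel=0.02)


def test_flatfield_floor_masks_instead_of_amplifying():
    template = np.ones((8, 8))
    template[0, 0] = 1e-5
    out = flatfield_correct(np.full((8, 8), 10.0), template)
    assert out[0, 0] == 0.0
    assert np.allclose(out[1:, 1:], 10.0)
    with pytest.raises(ValueError):
        flatfield_correct(np.ones((8, 8)), template * 0.5)  # not normalized


# ---------------------------------------------------------------------------
# channel alignment
# ---------------------------------------------------------------------------

def test_known_shift_recovered_subpixel():
    movie, truth = simulate_translocation_movie(
        MovieParams(channel_shift=(3.0, -2.5)), K_FAST, seed=3)
    _, shift = align_channels(movie)
    assert shift[0] == pytest.approx(-3.0, abs=0.1)
    assert shift[1] == pytest.approx(2.5, abs=0.1)


def test_zero_shift_is_identity():
    movie, _ = simulate_translocation_movie(
        MovieParams(channel_shift=(0.0, 0.0)), K_FAST, seed=4)
    aligned, shift = align_channels(movie)
    assert shift == (0.0, 0.0)
    assert np.array_equal(aligned.receptor, movie.receptor)


def test_pure_noise_reference_warns(rng):
    movie, _ = simulate_translocation_movie(MovieParams(), K_FAST, seed=5)
    noisy = TimelapseMovie(
        movie.receiver, movie.receptor, movie.timestamps, list(movie.codes),
        movie.injection_delay_s,
        alignment_reference=(rng.normal(size=(128, 128)),
                             rng.normal(size=(128, 128))))
    with pytest.warns(UserWarning, match="low-confidence"):
        align_channels(noisy)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def test_segmentation_recovers_generator_masks():
    movie, truth = simulate_translocation_movie(
        MovieParams(channel_shift=(0.0, 0.0)), K_FAST, seed=6)
    cell = segment_cell(movie.receiver[0])
    iou_cell = (cell & truth.cell_mask).sum() / (cell | truth.cell_mask).sum()
    assert iou_cell >= 0.9
    mito = segment_mitochondria(movie.receptor[0], cell)
    iou_mito = (mito & truth.mito_mask).sum() / (mito | truth.mito_mask).sum()
    assert iou_mito >= 0.7


def test_blank_images_rejected():
    with pytest.raises(ValueError):
        segment_cell(np.zeros((64, 64)))
    with pytest.raises(ValueError):
        segment_mitochondria(np.full((64, 64), 3.0))


def test_unusual_mito_fraction_warns():
    movie, _ = simulate_translocation_movie(
        MovieParams(channel_shift=(0.0, 0.0)), K_FAST, seed=7)
    receptor = np.full_like(movie.receptor, 5.0)
    receptor[:, 60:63, 60:63] = 500.0          # one tiny speck -> < 1% area
    tiny = TimelapseMovie(movie.receiver, receptor, movie.timestamps,
                          list(movie.codes), movie.injection_delay_s)
    with pytest.warns(UserWarning, match="area fraction"):
        build_rois(tiny)


# ---------------------------------------------------------------------------
# trajectory extraction and t0.75
# ---------------------------------------------------------------------------

def quiet_movie(**kw):
    defaults = dict(poisson=False, channel_shift=(0.0, 0.0),
                    bleach_rate_receiver=0.0, bleach_rate_receptor=0.0,
                    illumination_sigma_frac=50.0, psf_sigma_px=0.0,
                    n_alignment_beads=0)
    defaults.update(kw)
    return MovieParams(**defaults)


def test_noise_free_trajectory_matches_analytic_model():
    movie, truth = simulate_translocation_movie(quiet_movie(), K_FAST,
                                                seed=8)
    rois = ROISet(truth.cell_mask, [truth.mito_mask] * movie.n_pairs)
    traj = extract_trajectory(movie, rois, bleach_correct=False)
    r_true = truth.analytic_ratio(movie.timestamps)
    expected = (r_true[1:] - r_true[0]) / (r_true[-1] - r_true[0])
    assert np.max(np.abs(traj.normalized - expected)) < 2e-3


def test_no_translocation_is_degenerate():
    movie, truth = simulate_translocation_movie(
        quiet_movie(depletion=0.0), K_FAST, seed=9)
    rois = ROISet(truth.cell_mask, [truth.mito_mask] * movie.n_pairs)
    with pytest.raises(ValueError, match="degenerate"):
        extract_trajectory(movie, rois, bleach_correct=False)


def test_bleaching_only_movie_flat_after_correction():
    """With bleaching but no translocation, the bleach-corrected ratios are
    constant (the degenerate-normalization error signals flatness)."""
    movie, truth = simulate_translocation_movie(
        quiet_movie(depletion=0.0, bleach_rate_receiver=2e-3), K_FAST,
        seed=10)
    rois = ROISet(truth.cell_mask, [truth.mito_mask] * movie.n_pairs)
    with pytest.raises(ValueError, match="degenerate"):
        extract_trajectory(movie, rois, bleach_correct=True)


def test_t75_closed_form_trajectory():
    t = np.linspace(0.05, 80, 1600)
    k = math.log(4.0) / 10.1
    traj = TranslocationTrajectory(t, None, 0.0, 1.0,
                                   1.0 - np.exp(-k * t))
    assert estimate_t75(traj) == pytest.approx(10.1, abs=0.01)


def test_t75_step_trajectory_interpolates():
    traj = TranslocationTrajectory(np.array([1.0, 2.0]), None, 0.0, 1.0,
                                   np.array([0.0, 1.0]))
    assert estimate_t75(traj) == pytest.approx(1.75)


def test_t75_never_crossing_is_an_error():
    t = np.linspace(0, 50, 51)
    traj = TranslocationTrajectory(t, None, 0.0, 1.0,
                                   0.7 * (1 - np.exp(-t / 5)))
    with pytest.raises(ValueError, match="never reached"):
        estimate_t75(traj)


def test_normalization_is_idempotent():
    t = np.linspace(1, 30, 30)
    norm = 1 - np.exp(-0.2 * t)
    traj = TranslocationTrajectory(t, norm.copy(), 0.0, 1.0, norm.copy())
    again = traj.normalize()
    assert np.allclose(again.normalized, traj.normalized)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_stable_movie_not_excluded():
    movie, truth = simulate_translocation_movie(MovieParams(), K_FAST,
                                                seed=11)
    rois = build_rois(movie)
    flags = qc_exclude(movie, rois)
    assert not flags.excluded
    assert not flags.warn_whole_cell


def test_focus_loss_segment_is_excluded():
    n_bad = tuple(range(20, 28))
    movie, _ = simulate_translocation_movie(
        MovieParams(focus_loss_pairs=n_bad), K_FAST, seed=12)
    rois = build_rois(movie)
    flags = qc_exclude(movie, rois)
    assert flags.excluded


def manual_movie(variation):
    """Constant-cell movie with one receiver frame scaled by 1+variation."""
    n, shape = 12, (48, 48)
    cell = np.zeros(shape, bool)
    cell[8:40, 8:40] = True
    mito = np.zeros(shape, bool)
    mito[20:28, 20:28] = True
    receiver = np.full((n,) + shape, 5.0)
    receptor = np.full((n,) + shape, 5.0)
    for i in range(n):
        receiver[i][cell] = 100.0
        receptor[i][mito] = 200.0
    receiver[6][cell] *= 1.0 + variation
    times = np.concatenate([[-5.0], np.arange(3.0, 3.0 + n - 1)])
    movie = TimelapseMovie(receiver, receptor, times,
                           [("488", "561")] * n)
    rois = ROISet(cell, [mito] * n)
    return movie, rois


def test_whole_cell_variation_warning_boundary():
    movie, rois = manual_movie(0.025)
    assert qc_exclude(movie, rois).warn_whole_cell
    movie, rois = manual_movie(0.015)
    assert not qc_exclude(movie, rois).warn_whole_cell


# ---------------------------------------------------------------------------
# end to end
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("t75_true,interval,duration", [
    (5.0, 1.0, 40.0), (30.0, 2.0, 150.0), (300.0, 15.0, 1500.0),
])
def test_end_to_end_recovery_across_rates(t75_true, interval, duration):
    """Median recovered t0.75 within max(1 frame, 10%) of ln(4)/k."""
    params = MovieParams(frame_interval_s=interval, duration_s=duration)
    k = math.log(4.0) / t75_true
    recovered = []
    for seed in range(4):
        movie, _ = simulate_translocation_movie(params, k, seed=40 + seed)
        template = make_illumination_template(
            params.shape, {"kind": "gaussian", "sigma_frac": 0.8},
            seed=80 + seed)
        _, t75 = analyze_movie(movie, template=template)
        recovered.append(t75)
    tol = max(interval, 0.1 * t75_true)
    assert abs(np.median(recovered) - t75_true) <= tol
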