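"""Raster-scan simulator: photon statistics, determinism, dimer physics."""

import numpy as np
import pytest

from cipkit import ScanConfig, SpeciesSpec, focal_volume_um3
from cipkit.synth import simulate_raster_scan, simulate_reference_stacks


def tiny_config(**kw):
    defaults = dict(frame_shape=(17, 17), n_frames=5, n_spectral_channels=2)
    defaults.update(kw)
    return ScanConfig(**defaults)


def test_frozen_particle_gives_constant_frames():
    """A D=0 particle at a beam position yields identical noise-free frames
    peaking at its pixel."""
    cfg = tiny_config()
    s = SpeciesSpec("frozen", 0.0, 100.0, np.array([0.7, 0.3]), 1)
    box = 1.5 * max(cfg.scan_field_um)
    dr = cfg.pixel_size_um
    fy, fx = cfg.scan_field_um
    x0 = (box - fx) / 2.0 + dr / 2.0
    y0 = (box - fy) / 2.0 + dr / 2.0
    pos = np.array([[x0 + 8 * dr, y0 + 8 * dr, 2.0 * cfg.wz_um]])
    stack, _ = simulate_raster_scan(cfg, [s], box_size_um=box, seed=1,
                                    sample_photons=False,
                                    init_positions=[pos])
    data = stack.data
    for f in range(1, cfg.n_frames):
        assert np.allclose(data[f], data[0], rtol=1e-12)
    total = data[0].sum(axis=-1)
    assert np.unravel_index(np.argmax(total), total.shape) == (8, 8)


def test_expected_channel_means_are_linear_in_species():
    """Noise-free channel means equal the sum over species of
    concentration x brightness x dwell x PSF volume x spectrum."""
    cfg = ScanConfig(frame_shape=(32, 32), n_frames=12,
                     n_spectral_channels=3)
    box = 1.5 * max(cfg.scan_field_um)
    spec_a = np.array([0.8, 0.2, 0.0])
    spec_b = np.array([0.0, 0.3, 0.7])
    a = SpeciesSpec("a", 2.0, 30.0, spec_a, 900)
    b = SpeciesSpec("b", 1.0, 12.0, spec_b, 1500)
    stack, truth = simulate_raster_scan(cfg, [a, b], box_size_um=box,
                                        seed=7, sample_photons=False)
    volume = box ** 2 * 2.0 * truth.slab_halfwidth_um
    pred = np.zeros(3)
    for s, spec in ((a, spec_a), (b, spec_b)):
        c = s.n_particles / volume
        pred += c * s.brightness_hz * cfg.dwell_s * \
            (np.pi / 2) ** 1.5 * cfg.w0_um ** 2 * cfg.wz_um * spec
    obs = stack.mean_channel_counts()
    assert obs == pytest.approx(pred, rel=0.05)


def test_sampling_is_reproducible_and_integer():
    cfg = tiny_config()
    s = SpeciesSpec("a", 1.0, 80.0, np.array([0.5, 0.5]), 50)
    s1, _ = simulate_raster_scan(cfg, [s], seed=42)
    s2, _ = simulate_raster_scan(cfg, [s], seed=42)
    s3, _ = simulate_raster_scan(cfg, [s], seed=43)
    assert np.array_equal(s1.data, s2.data)
    assert not np.array_equal(s1.data, s3.data)
    assert np.issubdtype(s1.data.dtype, np.integer)
    assert np.all(s1.data >= 0)


def test_compiled_and_reference_kernels_agree():
    cfg = tiny_config(n_frames=3)
    s = SpeciesSpec("a", 1.5, 60.0, np.array([0.6, 0.4]), 40)
    ref, _ = simulate_raster_scan(cfg, [s], seed=5, sample_photons=False,
                                  use_numpy_kernel=True)
    fast, _ = simulate_raster_scan(cfg, [s], seed=5, sample_photons=False)
    # same arithmetic up to accumulation order (float32 Brownian steps)
    assert np.allclose(ref.data, fast.data, rtol=1e-5, atol=1e-8)


def test_heterodimers_share_trajectories():
    """With 100% bound fraction and disjoint spectra the two channels see
    the same particles, so their pixel fluctuations correlate; independent
    species do not."""
    cfg = ScanConfig(frame_shape=(32, 32), n_frames=8, n_spectral_channels=2)

    def corr(bound):
        a = SpeciesSpec("a", 1.0, 80.0, np.array([1.0, 0.0]), 150,
                        bound_fraction=bound)
        b = SpeciesSpec("b", 1.0, 80.0, np.array([0.0, 1.0]), 150)
        stack, _ = simulate_raster_scan(cfg, [a, b], seed=11,
                                        sample_photons=False)
        x = stack.data[..., 0].ravel()
        y = stack.data[..., 1].ravel()
        return np.corrcoef(x, y)[0, 1]

    assert corr(1.0) > 0.8
    assert abs(corr(0.0)) < 0.2


def test_ground_truth_records_focal_numbers():
    cfg = tiny_config()
    s = SpeciesSpec("a", 1.0, 80.0, np.array([0.5, 0.5]), 200)
    _, truth = simulate_raster_scan(cfg, [s], seed=1, sample_photons=False)
    volume = truth.box_size_um ** 2 * 2.0 * truth.slab_halfwidth_um
    expected = 200 / volume * focal_volume_um3(cfg)
    assert truth.n_true["a"] == pytest.approx(expected)
    assert truth.d_true["a"] == 1.0


@pytest.mark.parametrize("bad", [
    lambda cfg: ([], {}),                                     # no species
    lambda cfg: ([SpeciesSpec("a", 1.0, 10.0, np.array([1.0]), 5)],
                 dict(box_size_um=0.1)),                      # box too small
    lambda cfg: ([SpeciesSpec("a", 1.0, 10.0,
                              np.array([0.5, 0.5]), 5)], {}),  # channels
])
def test_invalid_inputs_rejected(bad):
    cfg = ScanConfig(frame_shape=(16, 16), n_frames=2, n_spectral_channels=1)
    species, kwargs = bad(cfg)
    with pytest.raises(ValueError):
        simulate_raster_scan(cfg, species, seed=1, **kwargs)


def test_more_dimers_than_partners_rejected():
    cfg = tiny_config()
    a = SpeciesSpec("a", 1.0, 10.0, np.array([1.0, 0.0]), 100,
                    bound_fraction=1.0)
    b = SpeciesSpec("b", 1.0, 10.0, np.array([0.0, 1.0]), 50)
    with pytest.raises(ValueError):
        simulate_raster_scan(cfg, [a, b], seed=1)


def test_reference_stacks_are_single_species():
    cfg = tiny_config(n_frames=4)
    a = SpeciesSpec("a", 1.0, 300.0, np.array([1.0, 0.0]), 300)
    b = SpeciesSpec("b", 1.0, 300.0, np.array([0.0, 1.0]), 300)
    stacks = simulate_reference_stacks(cfg, [a, b], seed=3, n_frames=4)
    assert len(stacks) == 2
    # species a emits only into channel 0, species b only into channel 1
    means_a = stacks[0].mean_channel_counts()
    means_b = stacks[1].mean_channel_counts()
    assert means_a[1] == 0
    assert means_b[0] == 0
    assert means_a[0] > 0 and means_b[1] > 0
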