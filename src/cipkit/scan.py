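"""Raster-scan geometry, point-spread-function parameters and fluorophore species.

Conventions used throughout the package:

* image axes are ``(frame, y, x[, channel])``, 0-based pixel coordinates;
* the fast scan axis is x (pixel lag ``xi``), the slow axis is y (line lag
  ``psi``);
* the confocal detection volume is a 3D Gaussian
  ``W(r) = exp(-2 (x^2 + y^2) / w0^2 - 2 z^2 / wz^2)`` with 1/e^2 waists
  ``w0`` (lateral) and ``wz`` (axial);
* the effective particle number ``N`` reported by correlation fits is
  ``N = c * (pi/2)^(3/2) * w0^2 * wz`` for a particle concentration ``c``,
  which makes the zero-lag correlation amplitude ``G(0,0) = gamma / N`` with
  ``gamma = 2^(-3/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ScanConfig",
    "SpeciesSpec",
    "GAMMA_3D",
    "fluorophore_spectrum",
    "default_emission_spectra",
    "focal_volume_um3",
    "particles_for_focal_number",
]

#: Shape factor of the 3D Gaussian detection volume.
GAMMA_3D = 2.0 ** (-1.5)

# Relative slack when checking timing invariants: printed acquisition timings
# are rounded to three significant digits (e.g. a 1.23 ms line time times 256
# lines nominally exceeds the printed 314.57 ms frame time by 0.1%).
_TIMING_RTOL = 5e-3


@dataclass(frozen=True)
class ScanConfig:
    """Geometry, timing and PSF parameters of a spectral raster scan.

    Defaults correspond to a 256 x 256 px confocal photon-counting
    acquisition with 50 nm pixels, 2.05 us pixel dwell time, 1.23 ms line
    time, 314.57 ms frame time and 23 spectral detection channels.
    """

    pixel_size_nm: float = 50.0
    dwell_time_us: float = 2.05
    line_time_ms: float = 1.23
    frame_time_ms: float = 314.57
    frame_shape: tuple[int, int] = (256, 256)
    n_frames: int = 300
    w0_nm: float = 300.0
    wz_nm: float = 1000.0
    n_spectral_channels: int = 23

    def __post_init__(self) -> None:
        rows, cols = self.frame_shape
        if rows <= 0 or cols <= 0 or self.n_frames <= 0:
            raise ValueError("frame_shape and n_frames must be positive")
        for name in ("pixel_size_nm", "dwell_time_us", "line_time_ms",
                     "frame_time_ms", "w0_nm", "wz_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_spectral_channels < 1:
            raise ValueError("n_spectral_channels must be >= 1")
        if self.dwell_time_us * cols > self.line_time_ms * 1e3 * (1 + _TIMING_RTOL):
            raise ValueError(
                "pixel dwell time times columns exceeds the line time "
                "(line time must include the retrace)")
        if self.line_time_ms * rows > self.frame_time_ms * (1 + _TIMING_RTOL):
            raise ValueError("line time times rows exceeds the frame time")

    # -- unit helpers -----------------------------------------------------
    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm * 1e-3

    @property
    def dwell_s(self) -> float:
        return self.dwell_time_us * 1e-6

    @property
    def line_s(self) -> float:
        return self.line_time_ms * 1e-3

    @property
    def frame_s(self) -> float:
        return self.frame_time_ms * 1e-3

    @property
    def w0_um(self) -> float:
        return self.w0_nm * 1e-3

    @property
    def wz_um(self) -> float:
        return self.wz_nm * 1e-3

    @property
    def scan_field_um(self) -> tuple[float, float]:
        """Physical extent (y, x) of the scanned field in micrometres."""
        rows, cols = self.frame_shape
        return rows * self.pixel_size_um, cols * self.pixel_size_um

    def with_(self, **kwargs) -> "ScanConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def focal_volume_um3(config: ScanConfig) -> float:
    """Effective focal volume ``(pi/2)^(3/2) w0^2 wz`` in um^3.

    With this convention a concentration ``c`` gives ``N = c * V`` effective
    particles and a fitted amplitude ``G(0,0) = gamma / N``.
    """
    return (np.pi / 2.0) ** 1.5 * config.w0_um ** 2 * config.wz_um


@dataclass(frozen=True)
class SpeciesSpec:
    """A diffusing fluorophore species in the simulation box.

    ``brightness_khz`` is the mean detected count rate per molecule at the
    beam centre (counts per molecule; ~25 kHz for eGFP, 15-20 kHz for YFP,
    ~10 kHz for mCherry at typical excitation powers).  ``bound_fraction``
    is the fraction of this species' particles that co-diffuse with the last
    species of the simulation (the "receptor"), emitting both partners'
    spectra from a single trajectory.
    """

    name: str
    diffusion_um2_s: float
    brightness_khz: float
    emission_spectrum: np.ndarray
    n_particles: int
    bound_fraction: float = 0.0

    def __post_init__(self) -> None:
        spec = np.asarray(self.emission_spectrum, dtype=float)
        object.__setattr__(self, "emission_spectrum", spec)
        if spec.ndim != 1 or spec.size < 1:
            raise ValueError("emission_spectrum must be a 1D vector")
        if np.any(spec < 0):
            raise ValueError("emission_spectrum must be non-negative")
        if abs(spec.sum() - 1.0) > 1e-9:
            raise ValueError("emission_spectrum must sum to 1 (+- 1e-9)")
        if self.diffusion_um2_s < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if self.brightness_khz <= 0:
            raise ValueError("brightness must be > 0")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ValueError("bound_fraction must be within [0, 1]")

    @property
    def brightness_hz(self) -> float:
        return self.brightness_khz * 1e3


def _channel_wavelengths_nm(n_channels: int, start_nm: float = 490.0,
                            width_nm: float = 8.9) -> np.ndarray:
    return start_nm + width_nm * (np.arange(n_channels) + 0.5)


# Skew-normal emission shapes (peak_nm, width_nm, skew); the long red tail of
# each fluorophore is produced by a positive skew.  Shapes are free
# parameters chosen to mimic the overlap of eGFP / YFP / mCherry emission.
_SPECTRUM_SHAPES = {
    "egfp": (505.0, 16.0, 4.0),
    "yfp": (525.0, 18.0, 4.0),
    "mcherry": (605.0, 25.0, 3.0),
}


def fluorophore_spectrum(name: str, n_channels: int = 23) -> np.ndarray:
    """Normalized emission probability vector of a model fluorophore.

    Supported names: ``egfp``, ``yfp``, ``mcherry``.
    """
    from scipy.stats import skewnorm

    key = name.lower()
    if key not in _SPECTRUM_SHAPES:
        raise KeyError(f"unknown fluorophore {name!r}; "
                       f"choose from {sorted(_SPECTRUM_SHAPES)}")
    loc, scale, a = _SPECTRUM_SHAPES[key]
    wl = _channel_wavelengths_nm(n_channels)
    p = skewnorm.pdf(wl, a, loc=loc, scale=scale)
    total = p.sum()
    if total <= 0:
        raise ValueError("degenerate spectrum shape")
    p = p / total
    # exact renormalization against rounding
    return p / p.sum()


def default_emission_spectra(n_channels: int = 23,
                             names: Sequence[str] = ("egfp", "yfp", "mcherry"),
                             ) -> dict[str, np.ndarray]:
    """Default overlapping emission spectra keyed by fluorophore name."""
    return {n: fluorophore_spectrum(n, n_channels) for n in names}


def particles_for_focal_number(n_focal: float, config: ScanConfig,
                               box_size_um: float,
                               slab_halfwidth_um: float | None = None) -> int:
    """Number of particles in the simulation box giving ``n_focal`` effective
    particles in the focal volume.

    The box is ``box x box`` laterally and ``2 * slab_halfwidth`` thick
    (default slab half-width: ``2 wz``).
    """
    if n_focal <= 0:
        raise ValueError("n_focal must be > 0")
    if slab_halfwidth_um is None:
        slab_halfwidth_um = 2.0 * config.wz_um
    box_volume = box_size_um ** 2 * 2.0 * slab_halfwidth_um
    c = n_focal / focal_volume_um3(config)
    return max(1, int(round(c * box_volume)))
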