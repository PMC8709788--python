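"""Statistical spectral filters for photon-counting stacks.

Spectral decomposition follows the filtered-correlation approach of
fluorescence lifetime / spectral correlation spectroscopy: with reference
emission probabilities ``p_s(k)`` (species s, detection channel k) and
channel weights ``W = diag(1 / <I(k)>)`` (the inverse mean counts, a proxy
for the Poisson variance), the filter matrix

    F = (M^T W M)^{-1} M^T W,     M[k, s] = p_s(k)

is the weighted least-squares unmixing operator.  Applied per pixel to the
channel counts it yields per-species photon weights whose *expectation*
equals the true per-species intensity (statistical unmixing; individual
pixel values may be negative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .synth.raster import SpectralStack

__all__ = [
    "EmissionSpectra",
    "SpectralFilters",
    "estimate_reference_spectra",
    "compute_filters",
    "decompose_stack",
]

#: Channels whose mean counts fall below this floor are excluded from the
#: filter construction (their inverse-variance weights would explode).
DEFAULT_CHANNEL_FLOOR = 1e-3

#: Condition number of (M^T W M) above which the spectra are treated as
#: collinear and an explicit error is raised.
MAX_CONDITION = 1e8


@dataclass
class EmissionSpectra:
    """Per-species emission probabilities over spectral channels."""

    matrix: np.ndarray          # (n_species, n_channels), rows sum to 1
    names: list[str]
    wavelengths_nm: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("spectra matrix must be 2D (species x channel)")
        if np.any(m < -1e-12):
            raise ValueError("emission spectra must be non-negative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each spectrum must sum to 1")
        if m.shape[0] > m.shape[1]:
            raise ValueError("more species than spectral channels")
        if len(self.names) != m.shape[0]:
            raise ValueError("one name per species required")
        self.matrix = m

    @property
    def n_species(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]


@dataclass
class SpectralFilters:
    """Signed per-species filter weights over spectral channels."""

    matrix: np.ndarray          # (n_species, n_channels)
    names: list[str]
    condition_number: float
    channel_mask: np.ndarray    # bool, channels used in the construction

    @property
    def n_species(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]


def estimate_reference_spectra(single_species_stacks: dict[str, Sequence[SpectralStack]]
                               | dict[str, SpectralStack],
                               ) -> EmissionSpectra:
    """Average reference emission spectra from single-species measurements.

    Parameters
    ----------
    single_species_stacks
        Mapping species name -> stack or list of stacks acquired on samples
        containing only that species.

    Each stack contributes its channel-mean counts normalized to unit sum;
    multiple stacks per species are averaged (each stack weighted equally).
    """
    if len(single_species_stacks) == 0:
        raise ValueError("at least one species is required")
    names = list(single_species_stacks.keys())
    rows = []
    for name in names:
        stacks = single_species_stacks[name]
        if isinstance(stacks, SpectralStack):
            stacks = [stacks]
        if len(stacks) == 0:
            raise ValueError(f"no stacks for species {name!r}")
        specs = []
        for st in stacks:
            mean = st.mean_channel_counts().astype(float)
            total = mean.sum()
            if total <= 0:
                raise ValueError(f"all-zero stack for species {name!r}")
            specs.append(mean / total)
        row = np.mean(specs, axis=0)
        rows.append(row / row.sum())
    return EmissionSpectra(np.array(rows), names)


def compute_filters(spectra: EmissionSpectra, mean_channel_counts: np.ndarray,
                    channel_floor: float = DEFAULT_CHANNEL_FLOOR,
                    ) -> SpectralFilters:
    """Weighted least-squares unmixing filters for one measurement.

    ``mean_channel_counts`` are the stack-mean counts per channel of the
    measurement to be decomposed (per-measurement filters).  Channels with
    mean counts below ``channel_floor`` are excluded.
    """
    mean = np.asarray(mean_channel_counts, dtype=float)
    if mean.shape != (spectra.n_channels,):
        raise ValueError("mean_channel_counts does not match the spectra")
    keep = mean > channel_floor
    if keep.sum() < spectra.n_species:
        raise ValueError("not enough informative channels above the floor")
    m = spectra.matrix[:, keep].T              # (K_kept, S)
    w = 1.0 / mean[keep]                       # Poisson variance proxy
    mtwm = m.T @ (w[:, None] * m)              # (S, S)
    cond = float(np.linalg.cond(mtwm))
    if not np.isfinite(cond) or cond > MAX_CONDITION:
        raise np.linalg.LinAlgError(
            f"spectra are collinear (condition number {cond:.3g}); "
            "cannot build unbiased filters")
    f_kept = np.linalg.solve(mtwm, m.T * w[None, :])   # (S, K_kept)
    full = np.zeros((spectra.n_species, spectra.n_channels))
    full[:, keep] = f_kept
    return SpectralFilters(full, list(spectra.names), cond, keep)


def decompose_stack(stack: SpectralStack | np.ndarray,
                    filters: SpectralFilters) -> list[np.ndarray]:
    """Decompose a 4D spectral stack into per-species 3D stacks.

    Returns one float array (frame, y, x) per species, in filter order.
    Values may be negative; only expectations are unbiased.
    """
    data = stack.data if isinstance(stack, SpectralStack) else np.asarray(stack)
    if data.ndim != 4:
        raise ValueError("expected a 4D stack (T, Y, X, K)")
    if data.shape[3] != filters.n_channels:
        raise ValueError(
            f"stack has {data.shape[3]} channels, filters expect "
            f"{filters.n_channels}")
    out = np.einsum("tyxk,sk->styx", data.astype(np.float64), filters.matrix)
    return [out[s] for s in range(filters.n_species)]
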