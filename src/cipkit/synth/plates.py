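"""Synthetic plate-reader luminescence tables for dose-response fitting.

Responses follow the one-site Hill model ``R = Rmax / (1 + EC50 / [CIP])``
in DMSO-normalized units (vehicle control wells read 1 on average).  Well
noise is multiplicative with a given coefficient of variation; each well's
integrated signal is split into 20 individual plate-reader readings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DoseResponseModel", "simulate_dose_response"]

N_READINGS = 20


@dataclass(frozen=True)
class DoseResponseModel:
    """Hill dose-response with implicit Hill coefficient 1."""

    ec50_um: float
    rmax: float = 1.0

    def __post_init__(self) -> None:
        if self.ec50_um <= 0:
            raise ValueError("EC50 must be > 0")
        if self.rmax <= 0:
            raise ValueError("Rmax must be > 0")

    def response(self, concentration_um) -> np.ndarray:
        """R = Rmax / (1 + EC50 / [CIP]); R(EC50) = Rmax / 2."""
        c = np.asarray(concentration_um, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        with np.errstate(divide="ignore"):
            r = self.rmax / (1.0 + self.ec50_um / c)
        return np.where(c == 0, 0.0, r)


def simulate_dose_response(model: DoseResponseModel,
                           concentrations_um: np.ndarray,
                           n_replicates: int = 7,
                           noise_cv: float = 0.05,
                           seed: int | None = None,
                           n_dmso_wells: int = 6,
                           baseline_signal: float = 1000.0) -> pd.DataFrame:
    """Plate table with CIP dilution wells and DMSO vehicle controls.

    Returns a tidy frame with columns ``well``, ``condition``,
    ``concentration_um`` and ``reading_1`` .. ``reading_20`` (each well's
    integrated signal is the sum of its 20 readings).
    ``baseline_signal`` sets the raw instrument scale of the DMSO level.
    """
    conc = np.asarray(concentrations_um, dtype=float)
    if conc.ndim != 1 or conc.size == 0:
        raise ValueError("concentrations must be a non-empty 1D array")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    well = 0

    def add_well(condition, c_um, response):
        nonlocal well
        signal = baseline_signal * response
        noisy = signal * (1.0 + rng.normal(0.0, noise_cv)) if noise_cv else signal
        noisy = max(noisy, 0.0)
        readings = np.full(N_READINGS, noisy / N_READINGS)
        row = {"well": f"W{well:03d}", "condition": condition,
               "concentration_um": c_um}
        row.update({f"reading_{i + 1}": readings[i] for i in range(N_READINGS)})
        rows.append(row)
        well += 1

    for _ in range(n_dmso_wells):
        add_well("DMSO", 0.0, 1.0)
    for rep in range(n_replicates):
        for c in conc:
            add_well("CIP", float(c), float(model.response(c)))
    return pd.DataFrame(rows)
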