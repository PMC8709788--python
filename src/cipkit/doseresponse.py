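"""Plate-reader aggregation and Hill dose-response fitting.

The dose-response model is the one-site Hill equation with implicit Hill
coefficient 1,

    R = Rmax / (1 + EC50 / [CIP])

where R is the DMSO-normalized luciferase signal, Rmax the maximum
asymptote and EC50 the half-maximal effective concentration.  Median
responses per concentration (across all replicates of all experiments) are
fitted by least squares; confidence intervals come from a bootstrap over
replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .synth.plates import N_READINGS, DoseResponseModel

__all__ = [
    "HillFit",
    "WelchResult",
    "integrate_well_signal",
    "integrate_plate",
    "normalize_to_control",
    "median_responses",
    "fit_hill",
    "compare_conditions",
]


def integrate_well_signal(readings: np.ndarray,
                          expected_count: int = N_READINGS) -> float:
    """Integrated well signal: the sum of the individual readings."""
    r = np.asarray(readings, dtype=float).ravel()
    if r.size == 0:
        raise ValueError("empty well: no readings to integrate")
    if expected_count and r.size != expected_count:
        warnings.warn(f"expected {expected_count} readings per well, "
                      f"got {r.size}", stacklevel=2)
    return float(r.sum())


def _reading_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if c.startswith("reading_")]
    if not cols:
        raise ValueError("no reading_* columns in the plate table")
    return cols


def integrate_plate(table: pd.DataFrame) -> pd.DataFrame:
    """Add an ``integrated`` column (sum of the per-well readings)."""
    cols = _reading_columns(table)
    out = table.copy()
    out["integrated"] = table[cols].to_numpy(dtype=float).sum(axis=1)
    return out


def normalize_to_control(signals: np.ndarray,
                         dmso_controls: np.ndarray) -> np.ndarray:
    """Divide integrated signals by the mean of the plate's DMSO wells."""
    controls = np.asarray(dmso_controls, dtype=float)
    if controls.size == 0:
        raise ValueError("no DMSO control wells")
    mean = controls.mean()
    if mean <= 0:
        raise ValueError("non-positive DMSO control mean")
    return np.asarray(signals, dtype=float) / mean


def median_responses(table: pd.DataFrame) -> pd.DataFrame:
    """Integrate, normalize to DMSO and reduce to medians per concentration.

    Expects the plate-table layout of
    :func:`cipkit.synth.simulate_dose_response` (columns ``condition``,
    ``concentration_um``, ``reading_1..20``); returns a frame with
    ``concentration_um``, ``median_response`` and ``n_replicates``.
    """
    integ = integrate_plate(table)
    dmso = integ.loc[integ["condition"] == "DMSO", "integrated"].to_numpy()
    cip = integ[integ["condition"] != "DMSO"].copy()
    if cip.empty:
        raise ValueError("no CIP wells in the plate table")
    cip["response"] = normalize_to_control(cip["integrated"].to_numpy(), dmso)
    grouped = cip.groupby("concentration_um")["response"]
    out = grouped.median().reset_index().rename(
        columns={"response": "median_response"})
    out["n_replicates"] = grouped.count().to_numpy()
    return out


@dataclass
class HillFit:
    ec50_um: float
    rmax: float
    ci_low: float | None = None
    ci_high: float | None = None
    success: bool = True

    @property
    def model(self) -> DoseResponseModel:
        return DoseResponseModel(self.ec50_um, self.rmax)


def _fit_hill_once(conc: np.ndarray, resp: np.ndarray) -> tuple[float, float]:
    params = lmfit.Parameters()
    half = 0.5 * resp.max()
    above = conc[resp >= half]
    ec50_init = float(above.min()) if above.size else float(np.median(conc))
    params.add("log_ec50", value=np.log10(ec50_init), min=-9, max=9)
    params.add("rmax", value=float(max(resp.max(), 1e-9)), min=1e-12)

    def residual(p):
        m = DoseResponseModel(10.0 ** p["log_ec50"].value, p["rmax"].value)
        return m.response(conc) - resp

    result = lmfit.minimize(residual, params, method="leastsq",
                            xtol=1e-12, ftol=1e-12)
    return (10.0 ** float(result.params["log_ec50"].value),
            float(result.params["rmax"].value))


def fit_hill(concentrations_um: np.ndarray, responses: np.ndarray,
             replicate_responses: np.ndarray | None = None,
             n_bootstrap: int = 1000,
             confidence: float = 0.95,
             seed: int | None = None) -> HillFit:
    """Fit the Hill model to median responses per concentration.

    Parameters
    ----------
    concentrations_um, responses
        Distinct concentrations (>= 4, spanning the transition) and their
        median responses.
    replicate_responses
        Optional (n_replicates, n_concentrations) array of per-replicate
        responses; when given, a bootstrap over replicates yields a
        percentile confidence interval on EC50.
    """
    conc = np.asarray(concentrations_um, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape or conc.ndim != 1:
        raise ValueError("concentrations and responses must be 1D and match")
    if np.unique(conc).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    ec50, rmax = _fit_hill_once(conc, resp)
    if ec50 > conc.max() or resp.max() < 0.8 * rmax:
        warnings.warn("dose-response curve does not cover the plateau; "
                      "EC50 is poorly constrained", stacklevel=2)

    ci_low = ci_high = None
    if replicate_responses is not None and n_bootstrap > 0:
        reps = np.asarray(replicate_responses, dtype=float)
        if reps.ndim != 2 or reps.shape[1] != conc.size:
            raise ValueError("replicate_responses must be "
                             "(n_replicates, n_concentrations)")
        rng = np.random.default_rng(seed)
        n_rep = reps.shape[0]
        boot = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n_rep, n_rep)
            med = np.median(reps[idx], axis=0)
            try:
                e, _ = _fit_hill_once(conc, med)
                boot.append(e)
            except Exception:
                continue
        if boot:
            alpha = (1.0 - confidence) / 2.0
            ci_low, ci_high = np.quantile(boot, [alpha, 1.0 - alpha])
    return HillFit(ec50, rmax, ci_low, ci_high)


@dataclass
class WelchResult:
    statistic: float
    pvalue: float
    df: float


def compare_conditions(condition_a: np.ndarray,
                       condition_b: np.ndarray) -> WelchResult:
    """Two-sided unpaired t-test with Welch's correction."""
    a = np.asarray(condition_a, dtype=float)
    b = np.asarray(condition_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per condition")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.pvalue),
                       float(res.df))
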