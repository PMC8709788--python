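"""Ground-truth recovery protocols.

Each protocol seeds the synthetic-data generator with a known parameter
value, runs the corresponding analysis pipeline end to end, and reports the
recovered value — the package's primary way of validating itself, since
the quantities measured in the original live-cell experiments cannot be
recomputed from scratch.  All randomness derives from one master seed.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .doseresponse import fit_hill, median_responses
from .rics import binding_analysis, binding_efficiency
from .scan import ScanConfig, SpeciesSpec, fluorophore_spectrum, \
    particles_for_focal_number
from .synth.movie import MovieParams, simulate_translocation_movie
from .synth.illumination import make_illumination_template
from .synth.plates import DoseResponseModel, simulate_dose_response
from .synth.raster import simulate_raster_scan, simulate_reference_stacks
from .translocation import analyze_movie
from .unmixing import compute_filters, decompose_stack, \
    estimate_reference_spectra

__all__ = [
    "recover_ec50",
    "recover_t75",
    "recover_binding_efficiency",
]


def _child_rng_seed(seed: int, *tags: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed)] + [int(t) for t in tags])


# ---------------------------------------------------------------------------
# EC50
# ---------------------------------------------------------------------------

def recover_ec50(ec50_true_um: float,
                 conc_min_um: float,
                 conc_max_um: float,
                 rmax: float = 1.0,
                 n_concentrations: int = 8,
                 noise_cv: float = 0.05,
                 n_replicates: int = 7,
                 n_seeds: int = 50,
                 seed: int = 0) -> dict:
    """EC50 recovery from synthetic dose-response plates.

    Responses follow the Hill model with ``ec50_true_um``; each replicate
    well carries multiplicative noise of the given CV; medians per
    concentration are fitted; the mean recovered EC50 over ``n_seeds``
    independent plates is reported.
    """
    model = DoseResponseModel(ec50_true_um, rmax)
    conc = np.logspace(math.log10(conc_min_um), math.log10(conc_max_um),
                       n_concentrations)
    recovered = []
    for k in range(n_seeds):
        rng_seed = _child_rng_seed(seed, 1, k)
        table = simulate_dose_response(
            model, conc, n_replicates=n_replicates, noise_cv=noise_cv,
            seed=rng_seed.generate_state(1)[0] % (2 ** 31))
        med = median_responses(table)
        fit = fit_hill(med["concentration_um"].to_numpy(),
                       med["median_response"].to_numpy(), n_bootstrap=0)
        recovered.append(fit.ec50_um)
    recovered = np.asarray(recovered)
    return {
        "ec50_true_um": float(ec50_true_um),
        "mean_ec50_um": float(recovered.mean()),
        "sd_ec50_um": float(recovered.std(ddof=1)) if n_seeds > 1 else 0.0,
        "per_seed": recovered.tolist(),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# t0.75
# ---------------------------------------------------------------------------

def recover_t75(t75_true_s: float,
                frame_interval_s: float,
                duration_s: float,
                n_seeds: int = 10,
                seed: int = 0,
                shape: tuple[int, int] = (128, 128)) -> dict:
    """t0.75 recovery through the full translocation pipeline.

    The movie's exponential recruitment rate is ``k = ln(4) / t75_true``;
    each seeded movie (default acquisition and noise parameters, matched
    flat-field template) is analyzed end to end and the mean estimated
    t0.75 over seeds reported.
    """
    k_true = math.log(4.0) / t75_true_s
    params = MovieParams(shape=tuple(shape),
                         frame_interval_s=frame_interval_s,
                         duration_s=duration_s)
    recovered = []
    for k in range(n_seeds):
        ss = _child_rng_seed(seed, 2, k).generate_state(2) % (2 ** 31)
        movie, truth = simulate_translocation_movie(params, k_true,
                                                    seed=int(ss[0]))
        template = make_illumination_template(
            params.shape,
            {"kind": "gaussian",
             "sigma_frac": params.illumination_sigma_frac},
            seed=int(ss[1]))
        _, t75 = analyze_movie(movie, template=template)
        recovered.append(t75)
    recovered = np.asarray(recovered)
    return {
        "t75_true_s": float(t75_true_s),
        "mean_t75_s": float(recovered.mean()),
        "sd_t75_s": float(recovered.std(ddof=1)) if n_seeds > 1 else 0.0,
        "per_seed": recovered.tolist(),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# binding efficiency
# ---------------------------------------------------------------------------

def _default_species(n_particles: int, bound_fraction: float,
                     n_channels: int) -> list[SpeciesSpec]:
    receiver = SpeciesSpec("receiver", 15.0, 25.0,
                           fluorophore_spectrum("egfp", n_channels),
                           n_particles, bound_fraction=bound_fraction)
    receptor = SpeciesSpec("receptor", 12.0, 10.0,
                           fluorophore_spectrum("mcherry", n_channels),
                           n_particles)
    return [receiver, receptor]


def _rel_cc_of_stack(stack, refs, config, max_xi, max_psi):
    spectra = estimate_reference_spectra(
        {"receiver": refs[0], "receptor": refs[1]})
    filters = compute_filters(spectra, stack.mean_channel_counts())
    dec = decompose_stack(stack, filters)
    res = binding_analysis({"receiver": dec[0], "receptor": dec[1]},
                           config, max_xi=max_xi, max_psi=max_psi)
    return res["rel_cc"][("receiver", "receptor")]


def recover_binding_efficiency(bound_fractions: float | Sequence[float],
                               n_seeds: int = 5,
                               seed: int = 0,
                               frame_shape: tuple[int, int] = (128, 128),
                               n_frames: int = 100,
                               n_focal: float = 2.5,
                               max_xi: int = 32,
                               max_psi: int = 16) -> dict:
    """Binding-efficiency recovery through the full spectral RICS pipeline.

    Per seed, two-color raster scans are simulated for each requested true
    bound fraction together with a positive control (100% covalent
    heterodimer) and a negative control (independent species); reference
    stacks provide the emission spectra.  Each stack runs through spectral
    decomposition, high-pass filtering, ARICS correlation, diffusion fits
    and rel.cc; binding efficiencies are the control-normalized rel.cc
    values.  Controls are shared between samples within a seed, as in the
    daily calibration measurements they emulate.

    Returns ``{"per_fraction": {fraction: {"mean_be": ..., ...}}, ...}``.
    """
    if np.isscalar(bound_fractions):
        fractions = [float(bound_fractions)]
    else:
        fractions = [float(b) for b in bound_fractions]
    config = ScanConfig(frame_shape=tuple(frame_shape), n_frames=n_frames)
    box = 1.5 * max(config.scan_field_um)
    n_particles = particles_for_focal_number(n_focal, config, box)
    results: dict[float, list[float]] = {b: [] for b in fractions}
    rel_ccs: dict[str, list[float]] = {"negative": [], "positive": []}
    for k in range(n_seeds):
        ss = _child_rng_seed(seed, 3, k)
        sub = ss.generate_state(4 + len(fractions)) % (2 ** 31)
        refs = simulate_reference_stacks(
            config, _default_species(n_particles, 0.0,
                                     config.n_spectral_channels),
            seed=int(sub[0]))
        neg_stack, _ = simulate_raster_scan(
            config, _default_species(n_particles, 0.0,
                                     config.n_spectral_channels),
            seed=int(sub[1]))
        pos_stack, _ = simulate_raster_scan(
            config, _default_species(n_particles, 1.0,
                                     config.n_spectral_channels),
            seed=int(sub[2]))
        rc_neg = _rel_cc_of_stack(neg_stack, refs, config, max_xi, max_psi)
        rc_pos = _rel_cc_of_stack(pos_stack, refs, config, max_xi, max_psi)
        rel_ccs["negative"].append(rc_neg.rel_cc)
        rel_ccs["positive"].append(rc_pos.rel_cc)
        for j, b in enumerate(fractions):
            stack, _ = simulate_raster_scan(
                config, _default_species(n_particles, b,
                                         config.n_spectral_channels),
                seed=int(sub[3 + j]))
            rc = _rel_cc_of_stack(stack, refs, config, max_xi, max_psi)
            be = binding_efficiency(rc, rc_neg, rc_pos)
            results[b].append(be.value)
    out = {"per_fraction": {}, "n_seeds": n_seeds,
           "rel_cc_negative": rel_ccs["negative"],
           "rel_cc_positive": rel_ccs["positive"],
           "n_particles_per_species": n_particles}
    for b in fractions:
        vals = np.asarray(results[b])
        out["per_fraction"][b] = {
            "bound_fraction_true": b,
            "mean_be": float(vals.mean()),
            "sd_be": float(vals.std(ddof=1)) if n_seeds > 1 else 0.0,
            "per_seed": vals.tolist(),
        }
    return out
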