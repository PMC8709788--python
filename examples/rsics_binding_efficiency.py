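"""Binding efficiency from simulated two-color spectral raster scans.

A receiver (eGFP-like) and a receptor (mCherry-like) species diffuse in a
periodic box; a fraction of receivers co-diffuses with receptors as
heterodimers.  The pipeline estimates reference spectra, builds statistical
unmixing filters, decomposes the photon-count stack, computes masked
auto-/cross-correlations, fits the normal-diffusion model, and normalizes
the relative cross-correlation between a negative control (independent
species) and a positive control (pure heterodimer).

This example uses a reduced 64 x 64 px / 80-frame scan so it runs in under
a minute; the acceptance protocol uses 128 x 128 px / 100 frames.
"""

from cipkit import ScanConfig, SpeciesSpec, fluorophore_spectrum, \
    particles_for_focal_number
from cipkit.rics import binding_analysis, binding_efficiency
from cipkit.synth import simulate_raster_scan, simulate_reference_stacks
from cipkit.unmixing import (compute_filters, decompose_stack,
                             estimate_reference_spectra)

BOUND_TRUE = 0.5
config = ScanConfig(frame_shape=(64, 64), n_frames=80)
box = 1.5 * max(config.scan_field_um)
n = particles_for_focal_number(2.5, config, box)


def species(bound):
    return [SpeciesSpec("receiver", 15.0, 25.0, fluorophore_spectrum("egfp"),
                        n, bound_fraction=bound),
            SpeciesSpec("receptor", 12.0, 10.0,
                        fluorophore_spectrum("mcherry"), n)]


def rel_cc(stack, refs):
    spectra = estimate_reference_spectra({"receiver": refs[0],
                                          "receptor": refs[1]})
    filters = compute_filters(spectra, stack.mean_channel_counts())
    dec = decompose_stack(stack, filters)
    res = binding_analysis({"receiver": dec[0], "receptor": dec[1]}, config)
    return res["rel_cc"][("receiver", "receptor")]


refs = simulate_reference_stacks(config, species(0.0), seed=10)
sample, truth = simulate_raster_scan(config, species(BOUND_TRUE), seed=11)
negative, _ = simulate_raster_scan(config, species(0.0), seed=12)
positive, _ = simulate_raster_scan(config, species(1.0), seed=13)

rc_s, rc_n, rc_p = (rel_cc(s, refs) for s in (sample, negative, positive))
be = binding_efficiency(rc_s, rc_n, rc_p)

print(f"simulated bound fraction: {BOUND_TRUE:.2f} "
      f"({truth.n_particles['receiver']} particles per species)")
print(f"rel.cc  sample:   {rc_s.rel_cc:.3f}")
print(f"rel.cc  negative: {rc_n.rel_cc:.3f}  (0 when the CCF fit does not "
      f"converge)")
print(f"rel.cc  positive: {rc_p.rel_cc:.3f}")
print(f"binding efficiency = {be.value:.2f}")
# The control-normalized value estimates the true bound fraction; residual
# spread at this reduced scan size is of order +-0.1.
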