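# cipkit

Quantitative analysis of **chemically induced protein proximity** (CIP)
experiments: how fast a cytosolic receiver protein is recruited to its
receptor after adding a small-molecule dimerizer, how completely the two
proteins bind, and how the response scales with dose.

The package reimplements, as a tested library, the four measurement
pipelines such experiments rely on, together with a synthetic-data
generator that emulates every raw input (time-lapse movies, spectral
raster scans, plate-reader tables) with known ground truth — so each
pipeline is validated by parameter recovery rather than by eye.

## What it computes

**Translocation kinetics — t₀.₇₅** (`cipkit.translocation`).
Alternating-excitation receiver/receptor image pairs are cleaned
(illumination-sequence check), flat-fielded, registered (sub-pixel phase
correlation), segmented (whole cell from the pre-addition cytosolic
image; mitochondria per pair from the receptor channel) and bleach
corrected.  The mito/cytosol intensity ratio is min–max normalized
between the pre-addition anchor ratio_t0 and the end anchor ratio_tend;
t₀.₇₅ is the interpolated time at which the normalized trajectory first
reaches 0.75.

**Spectral RICS binding efficiency** (`cipkit.unmixing`, `cipkit.rics`).
4D photon-count stacks (frame × y × x × spectral channel) are decomposed
into per-species stacks with statistical spectral filters
F = (MᵀWM)⁻¹MᵀW (reference spectra M, Poisson weights W = diag(1/⟨I(k)⟩)).
Arbitrary-region spatial correlation functions

    G(ξ, ψ) = ⟨δIᵢ(x, y) δIⱼ(x+ξ, y+ψ)⟩ / (⟨Iᵢ⟩⟨Iⱼ⟩)

are computed over pixel lags ξ and line lags ψ with per-lag valid-pair
normalization inside an arbitrary ROI mask, and fitted with the
normal-diffusion RICS model (γ = 2^(−3/2), scan timings fixed) for N and
D.  The relative cross-correlation

    rel.cc = max{ G_CC(0,0)/G_AC,i(0,0), G_CC(0,0)/G_AC,j(0,0) }

(set to 0 when the CCF fit does not converge to meaningful parameters)
is rescaled between a negative control (independent fluorophores) and a
positive control (covalent heterodimer) to give the binding efficiency.

**Dose–response — EC₅₀** (`cipkit.doseresponse`).  Plate-reader wells are
integrated (sum of 20 readings), normalized to DMSO vehicle controls,
reduced to medians per concentration and fitted with the Hill model

    R = R_max / (1 + EC₅₀ / [CIP])

with bootstrap confidence intervals; conditions are compared with
Welch-corrected unpaired t-tests.

**Colocalization / shuttling** (`cipkit.colocalization`).  Per z slice,
images are background corrected by subtracting a 20-px-Gaussian-smoothed
copy of themselves; Pearson R inside a cell mask is averaged over slices,
and shuttling steps are compared with paired t-tests.

**Synthetic data** (`cipkit.synth`).  Brownian dynamics of monomeric and
heterodimeric species in a periodic slab sampled by a raster scan with a
3D Gaussian PSF and Poisson photon counting over 23 emission channels;
translocation movies with exponential recruitment, Gaussian illumination,
channel misalignment, photobleaching and QC defects; Hill-model plate
tables; illumination templates.  Every generator records its ground truth.

## Worked example

`examples/rsics_binding_efficiency.py` simulates a two-color scan with a
true bound fraction of 0.5 plus controls, and runs the full spectral
pipeline:

```
simulated bound fraction: 0.50 (1300 particles per species)
rel.cc  sample:   0.513
rel.cc  negative: 0.000  (0 when the CCF fit does not converge)
rel.cc  positive: 1.030
binding efficiency = 0.50
```

The sample rel.cc estimates the co-diffusing fraction; the negative
control collapses to zero through the convergence rule, and dividing by
the positive-control span corrects residual calibration bias — the
recovered efficiency matches the simulated truth.

The other examples print a t₀.₇₅ of 10.26 s for a movie generated with an
analytic crossing time of 10.1 s (`translocation_t75.py`), an EC₅₀ of
0.420 µM (95% CI 0.388–0.444) for a plate simulated at 0.43 µM
(`dose_response_ec50.py`), and the receptor-selective Pearson pattern of
a shuttling experiment (`shuttling_pearson.py`).

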