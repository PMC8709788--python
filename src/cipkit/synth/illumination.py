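"""Illumination-profile templates from simulated dye-layer acquisitions."""

from __future__ import annotations

import numpy as np

from .movie import gaussian_illumination

__all__ = ["make_illumination_template"]


def make_illumination_template(shape: tuple[int, int],
                               profile_params: dict | None = None,
                               n_images: int = 25,
                               seed: int | None = None,
                               mean_counts: float = 2000.0) -> np.ndarray:
    """Average ``n_images`` noisy images of a homogeneously dyed surface.

    ``profile_params``: ``{"kind": "gaussian", "sigma_frac": ..,
    "center": ..}`` or ``{"kind": "flat"}``.  The averaged image is
    normalized to a maximum of 1, ready to divide raw images by.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    profile_params = dict(profile_params or {"kind": "gaussian",
                                             "sigma_frac": 0.8})
    kind = profile_params.pop("kind", "gaussian")
    if kind == "flat":
        profile = np.ones(shape)
    elif kind == "gaussian":
        profile = gaussian_illumination(shape, **profile_params)
    else:
        raise ValueError(f"unknown profile kind {kind!r}")
    rng = np.random.default_rng(seed)
    acc = np.zeros(shape, dtype=float)
    for _ in range(n_images):
        acc += rng.poisson(profile * mean_counts)
    acc /= n_images
    return acc / acc.max()
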