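"""Synthetic confocal z-stacks for colocalization and shuttling tests.

Small helper built on the movie-mask generators: a receiver channel either
colocalized with one of two receptor structures (mitochondria-like blobs or
vimentin-like filaments) or cytosolic, plus smooth out-of-focus background
and Poisson noise.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .movie import make_cell_mask, make_mito_mask

__all__ = ["simulate_shuttling_zstack"]


def simulate_shuttling_zstack(shape: tuple[int, int] = (128, 128),
                              n_slices: int = 5,
                              receiver_on: str = "mito",
                              seed: int | None = None,
                              signal_counts: float = 300.0,
                              background_counts: float = 20.0,
                              smooth_background: float = 80.0,
                              ) -> dict[str, np.ndarray]:
    """Three-channel z-stack (receiver + two receptor structures) + mask.

    ``receiver_on``: ``"mito"``, ``"vimentin"`` or ``"cytosol"`` selects the
    structure carrying the receiver signal.  Returns a dict with keys
    ``receiver``, ``mito``, ``vimentin`` (each (z, y, x)) and ``cell_mask``.
    """
    if receiver_on not in ("mito", "vimentin", "cytosol"):
        raise ValueError("receiver_on must be 'mito', 'vimentin' or 'cytosol'")
    rng = np.random.default_rng(seed)
    cell = make_cell_mask(shape, rng)
    mito = make_mito_mask(cell, rng, area_frac=(0.10, 0.20), thickness=2)
    vim = make_mito_mask(cell, rng, area_frac=(0.08, 0.15), thickness=1,
                         n_steps=220)
    structures = {"mito": mito, "vimentin": vim, "cytosol": cell}

    def render(structure_mask):
        stack = []
        for z in range(n_slices):
            depth = 1.0 - 0.5 * abs(z - (n_slices - 1) / 2) / max(n_slices / 2, 1)
            img = np.full(shape, background_counts, dtype=float)
            img[structure_mask] += signal_counts * depth
            img[cell] += smooth_background * depth
            img = ndimage.gaussian_filter(img, 1.0)
            stack.append(rng.poisson(img).astype(float))
        return np.stack(stack)

    return {
        "receiver": render(structures[receiver_on]),
        "mito": render(mito),
        "vimentin": render(vim),
        "cell_mask": cell,
    }
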