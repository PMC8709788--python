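"""Background-corrected Pearson colocalization and shuttling reports.

Each image is background corrected by subtracting a copy of itself
convolved with a wide Gaussian (sigma = 20 px by default); Pearson R is
then computed inside a manually provided cell mask for each z slice
separately and averaged over slices (unweighted), which is deliberately
*not* the same as pooling all voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "background_subtract",
    "pearson_per_cell",
    "shuttle_report",
    "paired_comparison",
    "PairedTResult",
]

DEFAULT_BACKGROUND_SIGMA = 20.0


def background_subtract(image: np.ndarray,
                        sigma: float = DEFAULT_BACKGROUND_SIGMA) -> np.ndarray:
    """Subtract a Gaussian-smoothed copy of the image (reflective edges).

    The result is zero-mean on smooth regions and may be negative.
    """
    img = np.asarray(image, dtype=float)
    return img - ndimage.gaussian_filter(img, sigma, mode="reflect")


def pearson_per_cell(receiver_zstack: np.ndarray,
                     receptor_zstack: np.ndarray,
                     cell_mask: np.ndarray,
                     sigma: float = DEFAULT_BACKGROUND_SIGMA) -> float:
    """Mean over z slices of the masked Pearson correlation coefficient.

    Background subtraction is applied to each full slice first; the mask
    (a manual single-cell segmentation) then selects the pixels entering
    the correlation.  All masked pixels are retained, including zeros.
    """
    a = np.asarray(receiver_zstack, dtype=float)
    b = np.asarray(receptor_zstack, dtype=float)
    if a.ndim == 2:
        a = a[None]
    if b.ndim == 2:
        b = b[None]
    if a.shape != b.shape:
        raise ValueError("z-stacks must share a shape")
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.shape != a.shape[1:]:
        raise ValueError("mask shape does not match the slices")
    if mask.sum() < 3:
        raise ValueError("mask too small for a correlation")
    rs = []
    for z in range(a.shape[0]):
        xa = background_subtract(a[z], sigma)[mask]
        xb = background_subtract(b[z], sigma)[mask]
        if xa.std() == 0 or xb.std() == 0:
            raise ValueError(f"constant slice {z} inside the mask")
        rs.append(float(np.corrcoef(xa, xb)[0, 1]))
    return float(np.mean(rs))


@dataclass
class PairedTResult:
    statistic: float
    pvalue: float
    n_pairs: int


def paired_comparison(scores: pd.DataFrame, receptor: str,
                      timepoint_a: str, timepoint_b: str) -> PairedTResult:
    """Two-sided paired t-test of per-cell R between two time points.

    Cells missing either time point are dropped (pairing on ``cell``).
    """
    sub = scores[scores["receptor"] == receptor]
    a = sub[sub["timepoint"] == timepoint_a].set_index("cell")["pearson_r"]
    b = sub[sub["timepoint"] == timepoint_b].set_index("cell")["pearson_r"]
    common = a.index.intersection(b.index)
    av = a.loc[common].to_numpy(dtype=float)
    bv = b.loc[common].to_numpy(dtype=float)
    ok = np.isfinite(av) & np.isfinite(bv)
    av, bv = av[ok], bv[ok]
    if av.size < 2:
        raise ValueError("need at least two paired cells")
    if np.allclose(av, bv):
        return PairedTResult(0.0, 1.0, int(av.size))
    res = stats.ttest_rel(av, bv)
    return PairedTResult(float(res.statistic), float(res.pvalue),
                         int(av.size))


def shuttle_report(timepoint_scores: dict[str, dict[str, dict[str, float]]]
                   | pd.DataFrame) -> pd.DataFrame:
    """Tidy per-cell Pearson table for a multi-step shuttling experiment.

    Accepts either an already-tidy frame with columns ``cell``,
    ``timepoint``, ``receptor``, ``pearson_r`` or a nested mapping
    ``{cell: {timepoint: {receptor: R}}}``.  Missing combinations become
    explicit NaN rows so downstream paired tests handle them.
    """
    if isinstance(timepoint_scores, pd.DataFrame):
        df = timepoint_scores.copy()
        required = {"cell", "timepoint", "receptor", "pearson_r"}
        if not required.issubset(df.columns):
            raise ValueError(f"tidy scores need columns {sorted(required)}")
    else:
        rows = []
        for cell, tps in timepoint_scores.items():
            for tp, receptors in tps.items():
                for receptor, r in receptors.items():
                    rows.append({"cell": cell, "timepoint": tp,
                                 "receptor": receptor, "pearson_r": r})
        df = pd.DataFrame(rows)
        if df.empty:
            raise ValueError("no scores provided")
    cells = df["cell"].unique()
    tps = df["timepoint"].unique()
    receptors = df["receptor"].unique()
    full = pd.MultiIndex.from_product([cells, tps, receptors],
                                      names=["cell", "timepoint", "receptor"])
    df = (df.set_index(["cell", "timepoint", "receptor"])
            .reindex(full).reset_index())
    return df.sort_values(["cell", "timepoint", "receptor"],
                          ignore_index=True)
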