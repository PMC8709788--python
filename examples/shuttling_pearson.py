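"""Score receiver/receptor colocalization during a shuttling experiment.

Per z slice, images are background corrected by subtracting a 20-px
Gaussian-smoothed copy, Pearson R is computed inside the cell mask, and
slice values are averaged.  Shuttling the receiver between mitochondria
and vimentin swaps which receptor channel it correlates with.
"""

import pandas as pd

from cipkit.colocalization import (paired_comparison, pearson_per_cell,
                                   shuttle_report)
from cipkit.synth import simulate_shuttling_zstack

rows = []
for cell in range(4):
    for step, (timepoint, location) in enumerate(
            (("on_mito", "mito"), ("on_vimentin", "vimentin"))):
        data = simulate_shuttling_zstack(seed=10 * cell + step,
                                         receiver_on=location)
        for receptor in ("mito", "vimentin"):
            r = pearson_per_cell(data["receiver"], data[receptor],
                                 data["cell_mask"])
            rows.append({"cell": f"cell{cell}", "timepoint": timepoint,
                         "receptor": receptor, "pearson_r": r})

report = shuttle_report(pd.DataFrame(rows))
print(report.groupby(["timepoint", "receptor"])["pearson_r"]
      .agg(["mean", "std"]).round(3))

test = paired_comparison(report, "mito", "on_mito", "on_vimentin")
print(f"\npaired t-test, R(mito receptor) on_mito vs on_vimentin: "
      f"t = {test.statistic:.2f}, p = {test.pvalue:.2e} "
      f"(n = {test.n_pairs} cells)")
# High R against the receptor currently carrying the receiver and low R
# against the other one reproduces the selectivity pattern of CIP-driven
# shuttling; the paired test quantifies the per-cell switch.
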