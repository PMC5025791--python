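"""Spatial homogeneity of cluster labels with a shuffle null.

The homogeneity index of a cluster is the mean fraction of same-label
neighbours within 30 um; significance comes from within-animal label
shuffles with Benjamini-Hochberg correction.
"""

import numpy as np

from rampasym import synth
from rampasym.spatial import CellMap, shuffle_test

labels = np.repeat(np.arange(6), 50)
for clumping in (0.0, 0.8):
    pos = synth.spatial_layout(labels, clumping=clumping, seed=4, sigma=35.0)
    res = shuffle_test(CellMap(pos, labels), radius=30.0, n_shuffles=500, seed=0)
    n_sig = int(res["rejected"].sum())
    print(f"clumping={clumping}: mean homogeneity "
          f"{res['homogeneity'].mean():.2f} "
          f"(null {res['null_mean'].mean():.2f}), "
          f"{n_sig}/{len(res)} clusters significant after BH")
# Uniform layouts sit at the null (cluster frequency, ~1/6); clumped
# layouts push the index up and every cluster becomes significant.
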