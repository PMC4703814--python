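"""Compare communities between sites: Bray-Curtis, NMDS, Ward, sharing.

Builds an OTU table with two planted site groups (overlapping OTU pools),
then ordinates the sites by non-metric multidimensional scaling, clusters
them with Ward's method and reports shared-OTU fractions and occupancy
classes (cosmopolitan vs locally restricted OTUs).
"""

import numpy as np
import pandas as pd

from massdiv.community import (bray_curtis, cooccurrence, nmds,
                               shared_fraction, ward_cluster)
from massdiv.diversity import classify_occupancy

rng = np.random.default_rng(11)
sites = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)]
counts = np.zeros((8, 40), dtype=int)
counts[:4, :22] = rng.integers(0, 12, size=(4, 22))   # group A pool
counts[4:, 18:] = rng.integers(0, 12, size=(4, 22))   # group B pool
counts[:, 0] += 2                                     # one cosmopolitan OTU
table = pd.DataFrame(counts, index=sites,
                     columns=[f"OTU#{j + 1}" for j in range(40)])

dm = bray_curtis(table)
ordination = nmds(dm, n_starts=20, seed=0)
print(f"NMDS stress = {ordination.stress:.3f} "
      "(< 0.2 means the 2D map represents the distances well)")
print(ordination.coordinates.round(3).to_string())

dendro = ward_cluster(dm)
print("\nWard dendrogram (Newick):", dendro.to_newick())

within = shared_fraction(table, "A0", "A1")
between = shared_fraction(table, "A0", "B0")
print(f"\nshared OTUs A0-A1 (same group): {within:.0f}%  |  "
      f"A0-B0 (different group): {between:.0f}%")

occ = classify_occupancy(table, min_sites_cosmopolitan=7)
from collections import Counter
print("occupancy classes:", dict(Counter(occ.values())))
print("co-occurrence (sites sharing OTUs):")
print(cooccurrence(table).to_string())
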