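"""Cell-contact enrichment testing on a spatial map with planted attraction.

Cells in four 510 x 510 um fields of view are linked by Delaunay edges
capped at 30 um; 60% of CD8 Trm cells are planted within 15 um of a
macrophage.  Labels are permuted within each fov to get the upper-tail
one-sided p per type pair, and directed composition edges mark A -> B
whenever A makes up at least 5% of B's pooled neighbors.
"""

import numpy as np

from clonebridge import build_contact_graph, composition_edges, contact_enrichment
from clonebridge.simulate import SimConfig, simulate_spatial

cfg = SimConfig(seed=13, attraction={("CD8_Trm", "Macrophage"): 0.6})
cells, truth = simulate_spatial(cfg, np.random.default_rng(13))
smap = build_contact_graph(cells, method="delaunay_capped", cap_um=30.0)
print(f"{smap.n_cells} cells, {len(smap.edges)} contact edges, "
      f"{cells['fov'].nunique()} fovs")

enr = contact_enrichment(smap, n_perm=999, rng=np.random.default_rng(14))
print("\npairwise adjacency enrichment (upper-tail, one-sided):")
print(enr.sort_values("p").to_string(index=False))

print("\nneighborhood composition edges (>= 5% of pooled neighbor slots):")
print(composition_edges(smap, threshold=0.05).to_string(index=False))
# the planted CD8_Trm-Macrophage pair should show -log10 p near 3 (the
# smallest value 999 permutations can resolve); unplanted pairs stay flat.
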