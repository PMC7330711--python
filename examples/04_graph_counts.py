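"""Proportional thresholding and community edge counts.

Thresholds a connectivity matrix at the 15% primary density (every subject
keeps exactly floor(0.15 * n(n-1)/2) strongest edges), maps ROIs onto the
14 hemisphere-resolved resting-state network communities, and counts
intra- vs inter-community edges.  The three buckets always sum to the
retained edge count.
"""

import numpy as np

import envconn as ec

rng = np.random.default_rng(0)
n = 42
C = rng.standard_normal((n, n))
C = (C + C.T) / 2
np.fill_diagonal(C, np.nan)

labels = [f"roi{i:02d}" for i in range(n)]
partition = ec.synthetic_partition(n)

adj = ec.threshold_proportional(C, 0.15)
counts = ec.community_edge_counts(adj, partition, labels)

print(f"{n} ROIs -> {n*(n-1)//2} pairs; 15% density keeps {adj.n_edges} edges")
series = counts.as_series()
intra = series[series.index.str.startswith('intra')]
print("\nintra-community counts:")
print(intra[intra > 0].to_string())
print(f"\ninter-community edges: {series[series.index.str.startswith('inter')].sum()}")
print(f"unassigned-touching:   {counts.unassigned_touching}")
print(f"conservation: {series.sum() + counts.unassigned_touching} == {adj.n_edges}")

sweep = ec.density_sweep(C, partition, labels)
totals = sweep[sweep.measure != 'unassigned_touching'].groupby("density")["count"].sum()
print("\nedges retained across the 5-30% density sweep:")
print(totals.to_string())
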