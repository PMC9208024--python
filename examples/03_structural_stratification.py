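"""Tract-length stratification: short- vs long-range structural edges.

Derives quartile thresholds from the pooled healthy-control tract
lengths, classifies each subject's present edges into short (< Q1) and
long (> Q3) range, and counts them.
"""

import numpy as np

from scfc import CohortConfig, generate_cohort
from scfc.sc import classify_edges, count_range_connections, quartile_thresholds

config = CohortConfig(n_hc=12, n_cp=10, n_ci=8, n_nodes=40, seed=5)
cohort = generate_cohort(config, mode="fc")

thr = quartile_thresholds([r.connectome for r in cohort.by_group("HC")])
print(f"pooled HC tract-length quartiles: Q1 = {thr.q1:.2f} mm, Q3 = {thr.q3:.2f} mm")
print("edges shorter than Q1 are 'short-range', longer than Q3 'long-range'\n")

for group in ("HC", "CP", "CI"):
    counts = [
        count_range_connections(classify_edges(r.connectome, thr))
        for r in cohort.by_group(group)
    ]
    ns, nl = np.mean([c[0] for c in counts]), np.mean([c[1] for c in counts])
    print(f"  {group}: mean {ns:.1f} short-range and {nl:.1f} long-range connections")

n_edges = config.n_nodes * (config.n_nodes - 1) // 2
print(
    f"\nEach subject has {n_edges} possible edges; only structurally present"
    "\nedges (FA > 0) are classified, so counts vary slightly across subjects."
)
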