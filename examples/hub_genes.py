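"""Rank hub genes inside precomputed PPI clusters by within-cluster degree."""

import numpy as np

from pyropattern import EdgeList, hub_genes

rng = np.random.default_rng(0)
clusters = {}
edges = []
for cl, members in {
    "interferon": [f"IFN_{i}" for i in range(8)],
    "proteasome": [f"PSM_{i}" for i in range(6)],
}.items():
    for g in members:
        clusters[g] = cl
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            if rng.random() < 0.5:
                edges.append((members[i], members[j]))
edges.append(("IFN_0", "PSM_0"))  # cross-cluster edge: ignored for degree

report = hub_genes(EdgeList(edges), clusters, top_n=3)
for cl, hubs in report.hubs.items():
    print(f"cluster {cl!r}: top hubs {hubs}")
print("\nfull degree table:")
print(report.degrees.to_string(index=False))
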