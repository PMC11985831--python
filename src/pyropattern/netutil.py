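"""Degree-based hub-gene ranking within precomputed PPI clusters.

Cluster membership is an input (e.g. from an MCODE-style module detector);
hubs are the highest-degree nodes of each cluster's induced subgraph,
with alphabetical tie-breaking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .iokit import EdgeList

__all__ = ["HubReport", "hub_genes"]


@dataclass
class HubReport:
    """Per-cluster degree tables and top-n hub lists."""

    hubs: dict[str, list[str]]          # cluster -> top_n genes
    degrees: pd.DataFrame               # gene, cluster, degree (sorted)


def hub_genes(edges: EdgeList, clusters: dict[str, str] | pd.Series,
              top_n: int = 3) -> HubReport:
    """Rank genes by within-cluster degree and report the top hubs.

    Degree counts only edges with both endpoints in the same cluster.
    Ties break alphabetically; clusters smaller than ``top_n`` report all
    members.  Genes in the cluster map but absent from the edge list keep
    degree 0 with a warning.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    membership = dict(pd.Series(clusters).items())
    if not membership:
        raise ValueError("cluster map is empty")

    known = edges.nodes()
    orphans = sorted(g for g in membership if g not in known)
    if orphans:
        warnings.warn(f"genes without edges retained at degree 0: {orphans}")

    degree: dict[str, int] = {g: 0 for g in membership}
    for a, b in edges.edges:
        if a in membership and b in membership and membership[a] == membership[b]:
            degree[a] += 1
            degree[b] += 1

    rows = [{"gene": g, "cluster": membership[g], "degree": degree[g]}
            for g in membership]
    table = (pd.DataFrame(rows)
             .sort_values(["cluster", "degree", "gene"],
                          ascending=[True, False, True])
             .reset_index(drop=True))
    hubs = {cl: sub["gene"].head(top_n).tolist()
            for cl, sub in table.groupby("cluster", sort=True)}
    return HubReport(hubs=hubs, degrees=table)
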