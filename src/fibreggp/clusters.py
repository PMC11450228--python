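"""Nucleus-gene clusters: all genes within graph distance k of a nucleus.

A cluster seeded on a known trait gene (e.g. a fasciclin-like
arabinogalactan protein) collects its 1st, 1st+2nd, or 1st+2nd+3rd network
neighbours (k in {1, 2, 3}); the nucleus itself is a member at distance 0.
Distances are unweighted shortest paths (breadth-first search).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx


@dataclass
class GeneCluster:
    nucleus: str
    k: int
    members: list[str]          # includes the nucleus
    distances: dict[str, int]   # member -> shortest-path distance

    def __post_init__(self) -> None:
        if self.distances.get(self.nucleus) != 0:
            raise ValueError("nucleus must be a member at distance 0")
        if any(d > self.k for d in self.distances.values()):
            raise ValueError("member distance exceeds k")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate cluster members")


def khop_neighbourhood(graph: nx.Graph, nucleus: str, k: int) -> GeneCluster:
    """Genes at shortest-path distance <= k from ``nucleus``.

    Edge weights are ignored; k beyond 3 is allowed but warned, since the
    cluster then usually swallows the whole connected component.
    """
    if nucleus not in graph:
        raise KeyError(f"nucleus gene {nucleus!r} not in the network")
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > 3:
        warnings.warn(f"k={k} exceeds the usual 1-3 neighbour depths", stacklevel=2)
    dist = nx.single_source_shortest_path_length(graph, nucleus, cutoff=k)
    members = sorted(dist, key=lambda g: (dist[g], str(g)))
    return GeneCluster(nucleus=nucleus, k=k, members=members, distances=dict(dist))


def cluster_union(clusters: list[GeneCluster]) -> list[str]:
    """Deduplicated union of members across clusters (order: first seen)."""
    seen: dict[str, None] = {}
    for cl in clusters:
        for g in cl.members:
            seen.setdefault(g, None)
    return list(seen)
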