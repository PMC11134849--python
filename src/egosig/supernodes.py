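"""Supernode network construction and functional-module partitioning.

Two supernodes are linked when their egos are connected inside the
Laplacian-re-normalized subgraph induced on the union of their members; the
edge weight is the base-2 Jensen-Shannon distance between the two egos'
one-hot RWR vectors on that subgraph (0 = strongest relationship). The
supernode network is partitioned into functional modules by the Leiden
algorithm on similarity weights 1 - JSD; connected components with fewer
than four supernodes are kept whole, and isolated supernodes are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
from scipy.spatial.distance import jensenshannon

from .ego import Supernode
from .network import WeightedNetwork, laplacian_normalize
from .propagation import rwr

LEIDEN_MIN_COMPONENT = 4


@dataclass
class SupernodeGraph:
    """Supernodes as vertices; JSD edge weights in [0, 1]."""

    graph: nx.Graph  # nodes are ego accessions, edge attr "jsd"
    supernodes: dict[str, Supernode]
    direction: str = ""


@dataclass
class ModulePartition:
    """Disjoint groups of supernodes and their member-protein unions."""

    modules: list[dict]  # {"id", "egos", "proteins", "method"}
    direction: str = ""

    def protein_sets(self) -> list[set[str]]:
        return [set(m["proteins"]) for m in self.modules]


def supernode_edge(
    a: Supernode,
    b: Supernode,
    base: WeightedNetwork,
    damping: float = 0.85,
) -> float | None:
    """JSD between the egos' walks on the pair's union subgraph, or None.

    ``base`` supplies the raw (un-normalized) simGIC weights; the induced
    union subgraph is re-normalized before the two one-hot RWR runs. If the
    egos fall in different components of that subgraph there is no edge.
    """
    if a.ego == b.ego:
        raise ValueError("supernode edge needs two distinct egos")
    union = a.members | b.members
    sub = nx.Graph(base.graph.subgraph(union))
    if a.ego not in sub or b.ego not in sub:
        return None
    if not nx.has_path(sub, a.ego, b.ego):
        return None
    normalized = laplacian_normalize(WeightedNetwork(graph=sub))
    nodes = normalized.nodes
    if a.ego not in nodes or b.ego not in nodes:
        return None
    def one_hot(ego: str) -> np.ndarray:
        v = np.zeros(len(nodes))
        v[nodes.index(ego)] = 1.0
        return v
    pa = rwr(normalized, one_hot(a.ego), damping)
    pb = rwr(normalized, one_hot(b.ego), damping)
    jsd = float(jensenshannon(pa.p, pb.p, base=2))
    if np.isnan(jsd):
        jsd = 0.0
    return min(jsd, 1.0)


def build_supernode_graph(
    supernodes: list[Supernode],
    base: WeightedNetwork,
    damping: float = 0.85,
    direction: str = "",
) -> SupernodeGraph:
    g = nx.Graph()
    index = {sn.ego: sn for sn in supernodes}
    g.add_nodes_from(index)
    for a, b in combinations(supernodes, 2):
        w = supernode_edge(a, b, base, damping)
        if w is not None:
            g.add_edge(a.ego, b.ego, jsd=w, similarity=1.0 - w)
    return SupernodeGraph(graph=g, supernodes=index, direction=direction)


def partition_modules(sg: SupernodeGraph, seed: int = 0) -> ModulePartition:
    """Leiden modules on large components; small components kept whole.

    Isolated supernodes are dropped. Components with at least
    ``LEIDEN_MIN_COMPONENT`` supernodes are partitioned by Leiden
    (modularity objective, resolution 1.0) on similarity weights 1 - JSD;
    smaller components become single modules.
    """
    g = sg.graph
    live = [n for n in g if g.degree(n) > 0]
    if not live:
        warnings.warn("supernode graph has no edges; empty partition")
        return ModulePartition(modules=[], direction=sg.direction)
    modules: list[dict] = []
    def add_module(egos: list[str], method: str) -> None:
        egos = sorted(egos)
        proteins = sorted(set().union(*(sg.supernodes[e].members for e in egos)))
        modules.append(
            {"id": len(modules), "egos": egos, "proteins": proteins, "method": method}
        )
    for comp in sorted(nx.connected_components(g.subgraph(live)), key=sorted):
        comp = sorted(comp)
        if len(comp) < LEIDEN_MIN_COMPONENT:
            add_module(comp, "small-component")
            continue
        sub = g.subgraph(comp)
        h = ig.Graph()
        h.add_vertices(comp)
        edges = [(u, v) for u, v in sub.edges()]
        h.add_edges(edges)
        h.es["weight"] = [sub.edges[u, v]["similarity"] for u, v in edges]
        part = leidenalg.find_partition(
            h,
            leidenalg.ModularityVertexPartition,
            weights="weight",
            seed=seed,
        )
        for cluster in part:
            add_module([h.vs[i]["name"] for i in cluster], "leiden")
    return ModulePartition(modules=modules, direction=sg.direction)
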