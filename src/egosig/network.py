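"""Semantic-similarity-weighted interaction network and its random ensemble.

The base protein-protein interaction graph is undirected and simple. Edge
weights are simGIC similarities of the endpoints; hub bias is corrected by
square-root-degree ("Laplacian") normalization:

    w_ij <- w_ij / sqrt(d_i * d_j)

with d the *weighted* degree on the raw weights. Significance of
propagation scores is later assessed against an ensemble of
degree-preserving rewirings of the raw graph, each re-weighted by simGIC of
its new endpoints and normalized the same way.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .ontology import OntologyAnnotation

logger = logging.getLogger(__name__)


class InputError(ValueError):
    """Unreadable or empty input."""


@dataclass
class WeightedNetwork:
    """Undirected protein graph with nonnegative edge weights.

    ``graph`` is a simple :class:`networkx.Graph` whose edges carry a
    ``weight`` attribute. When ``normalized`` is set, ``raw_degree`` holds
    the weighted degrees of the pre-normalization graph so the raw weights
    stay exactly recoverable as ``w_ij * sqrt(d_i * d_j)``.
    """

    graph: nx.Graph
    normalized: bool = False
    raw_degree: dict[str, float] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]

    def subgraph(self, nodes) -> "WeightedNetwork":
        return WeightedNetwork(
            graph=nx.Graph(self.graph.subgraph(nodes)),
            normalized=self.normalized,
            raw_degree={n: self.raw_degree[n] for n in nodes if n in self.raw_degree},
        )


def load_network(
    edge_list_path: str | Path, annotation: OntologyAnnotation
) -> WeightedNetwork:
    """Read a whitespace/tab-separated edge list into a simGIC-weighted graph.

    Only proteins with at least one ontology annotation are retained;
    self-loops are dropped and duplicate edges collapsed. Edges are weighted
    by simGIC of their endpoints.
    """
    path = Path(edge_list_path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise InputError(f"cannot read network file {path}: {exc}") from exc

    g = nx.Graph()
    dropped: set[str] = set()
    for line in text.splitlines():
        parts = line.split()
        if len(parts) < 2 or line.startswith("#"):
            continue
        # SIF rows are "node relation node"; 2-column TSV is "node node"
        u, v = (parts[0], parts[2]) if len(parts) >= 3 else (parts[0], parts[1])
        for n in (u, v):
            if not annotation.annotated(n):
                dropped.add(n)
        if u == v:
            if annotation.annotated(u):
                g.add_node(u)
            continue
        if annotation.annotated(u) and annotation.annotated(v):
            g.add_edge(u, v, weight=annotation.simgic(u, v))
        else:
            for n in (u, v):
                if annotation.annotated(n):
                    g.add_node(n)
    if dropped:
        warnings.warn(
            f"{len(dropped)} proteins without ontology terms dropped from network"
        )
    if g.number_of_nodes() == 0:
        raise InputError("network empty after annotation filtering")
    return WeightedNetwork(graph=g)


def laplacian_normalize(net: WeightedNetwork) -> WeightedNetwork:
    """Divide each weight by the square root of the endpoint weighted degrees.

    Structurally isolated nodes (no incident edges) cannot take part in
    propagation and are dropped with a warning. Edges of raw weight 0 stay
    at 0 (the 0/0 case is defined as 0), which keeps the node set — and
    hence the degree sequence — of weight-degenerate rewired replicates
    intact.
    """
    if net.normalized:
        raise ValueError("network already normalized")
    g = net.graph
    isolated = [n for n in g if g.degree(n) == 0]
    if isolated:
        warnings.warn(f"dropping {len(isolated)} isolated nodes before normalization")
        g = g.copy()
        g.remove_nodes_from(isolated)
    degree = {n: sum(d["weight"] for _, _, d in g.edges(n, data=True)) for n in g}
    out = nx.Graph()
    out.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        denom = np.sqrt(degree[u] * degree[v])
        w = d["weight"] / denom if denom > 0 else 0.0
        out.add_edge(u, v, weight=w)
    return WeightedNetwork(graph=out, normalized=True, raw_degree=degree)


@dataclass
class SemanticProfile:
    """Per-node mean / population std of simGIC against all other nodes.

    These global statistics later back the z-score filter that prunes ego
    neighborhoods down to functionally coherent cores.
    """

    mean: dict[str, float]
    std: dict[str, float]


def semantic_profile(
    net: WeightedNetwork, annotation: OntologyAnnotation
) -> SemanticProfile:
    nodes = net.nodes
    if len(nodes) < 2:
        raise InputError("semantic profile needs at least 2 nodes")
    mean: dict[str, float] = {}
    std: dict[str, float] = {}
    for a in nodes:
        sims = np.array([annotation.simgic(a, b) for b in nodes if b != a])
        mean[a] = float(sims.mean())
        std[a] = float(sims.std())  # population std
    return SemanticProfile(mean=mean, std=std)


@dataclass
class RandomEnsemble:
    """Degree-preserving rewirings of the raw network, simGIC-reweighted.

    Each replicate has exactly the real (unweighted) degree sequence; edge
    weights are recomputed as simGIC of the rewired endpoints and then
    Laplacian-normalized. Fully determined by ``seed``.
    """

    networks: list[WeightedNetwork]
    seed: int

    def __len__(self) -> int:
        return len(self.networks)


def randomize_ensemble(
    net: WeightedNetwork,
    R: int,
    annotation: OntologyAnnotation,
    seed: int,
    swaps_per_edge: int = 10,
) -> RandomEnsemble:
    """Generate ``R`` degree-preserving random replicates of the raw network.

    Rewiring is a double-edge-swap Markov chain with ``swaps_per_edge * |E|``
    accepted swaps per replicate, constrained to simple graphs (no
    self-loops or multi-edges), which conserves every node's degree exactly.
    """
    if net.normalized:
        raise ValueError("randomize the raw network, not the normalized one")
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    nets: list[WeightedNetwork] = []
    n_edges = net.graph.number_of_edges()
    nswap = max(1, swaps_per_edge * n_edges)
    for _ in range(R):
        g = net.graph.copy()
        if n_edges >= 2:
            rep_seed = int(rng.integers(0, 2**31 - 1))
            try:
                nx.double_edge_swap(
                    g, nswap=nswap, max_tries=100 * nswap, seed=rep_seed
                )
            except nx.NetworkXAlgorithmError:
                logger.warning("double-edge-swap hit max_tries; replicate kept as-is")
        for u, v in g.edges():
            g.edges[u, v]["weight"] = annotation.simgic(u, v)
        nets.append(laplacian_normalize(WeightedNetwork(graph=g)))
    return RandomEnsemble(networks=nets, seed=seed)
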