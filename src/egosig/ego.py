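"""Ego-network decomposition: from coarse direction networks to supernodes.

Each seed of a direction network becomes an *ego*. Its candidate
neighborhood is every node within two steps inside the direction network,
pruned by a one-tailed z-test on semantic similarity to the ego (cutoff
1.64, the 95% standard-normal quantile) against the ego's precomputed
global similarity profile. Edges of the surviving ego network are
re-weighted around the ego:

    w(ego, j)       = simGIC(ego, j)
    w(i, j) (other) = (simGIC(ego, i) + simGIC(ego, j)) / 2

then Laplacian-normalized. Every member is scored on two axes —

    topological affinity = 1000 * log2(2 - JSD(p_ego, p_j))
    functional distance  = 1000 * log2(1 + simGIC(ego, j))

where p_x is the per-node one-hot-restart RWR vector inside the ego
network and JSD the base-2 Jensen-Shannon distance. A 2-D Gaussian KDE
(Silverman bandwidth) over the scaled points yields each node's joint
lower-tail CDF value; nodes in the joint upper-quantile region (CDF >=
threshold, default 0.85) join the ego in a *supernode*. Ego networks with
five or fewer neighbors are kept whole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import jensenshannon
from scipy.stats import norm

from .network import SemanticProfile, WeightedNetwork, laplacian_normalize
from .ontology import OntologyAnnotation
from .propagation import DirectionNetwork, RWRVector, rwr

Z_CUTOFF = 1.64  # one-tailed 95% standard-normal quantile
MIN_EGO_NEIGHBORS = 5
SCALE = 1000.0


@dataclass
class EgoNetwork:
    """Functionally filtered 2-step neighborhood of an ego, re-weighted."""

    ego: str
    network: WeightedNetwork  # Laplacian-normalized ego-centric weights
    first_order: set[str]
    second_order: set[str]

    @property
    def members(self) -> set[str]:
        return set(self.network.nodes)


@dataclass
class DecompositionPoint:
    node: str
    topo: float
    func: float
    cdf: float = float("nan")


@dataclass
class Supernode:
    ego: str
    members: set[str]
    direction: str = ""


def extract_ego(dirnet: DirectionNetwork, ego: str) -> set[str]:
    """All nodes within shortest-path distance 2 of the ego."""
    g = dirnet.network.graph
    if ego not in g:
        raise ValueError(f"ego {ego!r} not in direction network")
    return set(nx.single_source_shortest_path_length(g, ego, cutoff=2))


def z_filter(
    candidates: set[str],
    ego: str,
    profile: SemanticProfile,
    annotation: OntologyAnnotation,
    cutoff: float = Z_CUTOFF,
) -> set[str]:
    """Keep candidates semantically closer to the ego than expected.

    Node j passes iff (simGIC(ego, j) - mean_ego) / std_ego > cutoff; the
    ego itself is always kept. A zero-variance profile degenerates to a
    plain mean comparison (warned).
    """
    mean, std = profile.mean[ego], profile.std[ego]
    kept = {ego}
    if std == 0:
        warnings.warn(f"zero similarity variance for ego {ego}; using mean cutoff")
        kept |= {j for j in candidates if j != ego and annotation.simgic(ego, j) > mean}
        return kept
    for j in candidates:
        if j == ego:
            continue
        if (annotation.simgic(ego, j) - mean) / std > cutoff:
            kept.add(j)
    return kept


def reweight_ego_edges(
    dirnet: DirectionNetwork,
    ego: str,
    members: set[str],
    annotation: OntologyAnnotation,
) -> EgoNetwork:
    """Build the ego network with ego-centric edge weights.

    Edges incident to the ego carry simGIC of their endpoints; all other
    edges (first-first, or touching a second-order node) carry the mean of
    the endpoints' similarities to the ego. The result is
    Laplacian-normalized.
    """
    sub = dirnet.network.graph.subgraph(members)
    first = set(sub.neighbors(ego)) if ego in sub else set()
    second = members - first - {ego}
    g = nx.Graph()
    g.add_nodes_from(members)
    for u, v in sub.edges():
        if ego in (u, v):
            other = v if u == ego else u
            w = annotation.simgic(ego, other)
        else:
            w = (annotation.simgic(ego, u) + annotation.simgic(ego, v)) / 2
        g.add_edge(u, v, weight=w)
    normalized = laplacian_normalize(WeightedNetwork(graph=g))
    kept = set(normalized.graph.nodes)
    return EgoNetwork(
        ego=ego,
        network=normalized,
        first_order=first & kept,
        second_order=second & kept,
    )


def node_rwr(egonet: EgoNetwork, node: str, damping: float = 0.85) -> RWRVector:
    """One-hot-restart RWR from a single node inside the ego network."""
    nodes = egonet.network.nodes
    restart = np.zeros(len(nodes))
    restart[nodes.index(node)] = 1.0
    return rwr(egonet.network, restart, damping)


def topological_affinity(p_ego: RWRVector, p_j: RWRVector) -> float:
    """1000 * log2(2 - JSD); 1000 for identical walks, 0 for disjoint ones."""
    if p_ego.nodes != p_j.nodes:
        raise ValueError("RWR vectors live on different node sets")
    jsd = float(jensenshannon(p_ego.p, p_j.p, base=2))
    if np.isnan(jsd):  # scipy returns NaN for a pair of zero vectors
        jsd = 0.0
    jsd = min(jsd, 1.0)
    return SCALE * np.log2(2 - jsd)


def functional_distance(ego: str, j: str, annotation: OntologyAnnotation) -> float:
    """1000 * log2(1 + simGIC(ego, j)); 0 for unrelated, 1000 for identical."""
    return SCALE * np.log2(1 + annotation.simgic(ego, j))


def decompose_ego(
    egonet: EgoNetwork,
    annotation: OntologyAnnotation,
    damping: float = 0.85,
) -> list[DecompositionPoint]:
    """Topological/functional coordinates for every non-ego member."""
    p_ego = node_rwr(egonet, egonet.ego, damping)
    points = []
    for j in sorted(egonet.members - {egonet.ego}):
        p_j = node_rwr(egonet, j, damping)
        points.append(
            DecompositionPoint(
                node=j,
                topo=topological_affinity(p_ego, p_j),
                func=functional_distance(egonet.ego, j, annotation),
            )
        )
    return points


def _silverman_bandwidth(x: np.ndarray) -> float:
    # per-dimension rule of thumb for a 2-D Gaussian kernel
    return float(np.std(x) * len(x) ** (-1 / 6))


def kde_select(
    points: list[DecompositionPoint], threshold: float = 0.85
) -> set[str]:
    """Select nodes in the joint upper-quantile region of the 2-D KDE.

    Coordinates are rescaled to [0, 1]; a Gaussian product-kernel KDE with
    Silverman bandwidths gives each point the joint lower-tail CDF
    P(X <= topo_j, Y <= func_j), evaluated in closed form from the normal
    CDF of each kernel. Nodes with CDF >= threshold are selected. If the
    point cloud is degenerate (no variance in either coordinate) every
    node is selected with a warning.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if not points:
        return set()
    x = np.array([p.topo for p in points]) / SCALE
    y = np.array([p.func for p in points]) / SCALE
    hx, hy = _silverman_bandwidth(x), _silverman_bandwidth(y)
    if hx == 0 and hy == 0:
        warnings.warn("degenerate decomposition cloud; selecting all nodes")
        for p in points:
            p.cdf = 1.0
        return {p.node for p in points}
    # a flat coordinate contributes a step function instead of a kernel CDF
    cdf_x = (
        norm.cdf((x[:, None] - x[None, :]) / hx) if hx > 0
        else (x[:, None] >= x[None, :]).astype(float)
    )
    cdf_y = (
        norm.cdf((y[:, None] - y[None, :]) / hy) if hy > 0
        else (y[:, None] >= y[None, :]).astype(float)
    )
    cdf = (cdf_x * cdf_y).mean(axis=1)
    for p, c in zip(points, cdf):
        p.cdf = float(c)
    return {p.node for p in points if p.cdf >= threshold}


def build_supernode(
    egonet: EgoNetwork,
    annotation: OntologyAnnotation,
    threshold: float = 0.85,
    damping: float = 0.85,
    min_neighbors: int = MIN_EGO_NEIGHBORS,
    direction: str = "",
) -> tuple[Supernode, list[DecompositionPoint]]:
    """Decompose one ego network into its supernode.

    Ego networks with more than ``min_neighbors`` neighbors are decomposed
    via KDE selection; smaller ones are kept whole. An empty selection
    leaves the ego alone in its supernode.
    """
    n_neighbors = len(egonet.members) - 1
    if n_neighbors <= min_neighbors:
        return (
            Supernode(ego=egonet.ego, members=set(egonet.members), direction=direction),
            [],
        )
    points = decompose_ego(egonet, annotation, damping)
    selected = kde_select(points, threshold)
    return (
        Supernode(ego=egonet.ego, members={egonet.ego} | selected, direction=direction),
        points,
    )


def supernodes_for_direction(
    dirnet: DirectionNetwork,
    profile: SemanticProfile,
    annotation: OntologyAnnotation,
    threshold: float = 0.85,
    damping: float = 0.85,
    z_cutoff: float = Z_CUTOFF,
    min_neighbors: int = MIN_EGO_NEIGHBORS,
) -> tuple[list[Supernode], dict[str, list[DecompositionPoint]]]:
    """Full ego pipeline for every seed of a direction network."""
    supernodes: list[Supernode] = []
    diagnostics: dict[str, list[DecompositionPoint]] = {}
    for ego in sorted(dirnet.seeds):
        if ego not in dirnet.network.graph:
            continue
        candidates = extract_ego(dirnet, ego)
        members = z_filter(candidates, ego, profile, annotation, cutoff=z_cutoff)
        egonet = reweight_ego_edges(dirnet, ego, members, annotation)
        if egonet.ego not in egonet.network.graph:
            # ego lost every neighbor to the z-filter: singleton supernode
            supernodes.append(
                Supernode(ego=ego, members={ego}, direction=dirnet.direction)
            )
            continue
        sn, points = build_supernode(
            egonet, annotation, threshold, damping, min_neighbors,
            direction=dirnet.direction,
        )
        supernodes.append(sn)
        diagnostics[ego] = points
    return supernodes, diagnostics
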