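"""Random-walk-with-restart propagation and empirical significance filtering.

Each seed layer defines a restart distribution; the walk iterates

    p <- damping * T p + (1 - damping) * restart

where ``T`` is the column-stochastic transition operator obtained by
column-normalizing the (Laplacian-normalized) edge weights, and ``damping``
is the continuation probability (default 0.85, i.e. restart probability
0.15). The same restart vector is replayed on every network of a
degree-preserving random ensemble; a node survives only if its real score
strictly exceeds the (1 - alpha) fraction of its null scores.

The surviving nodes of each layer, plus all seeds, form one coarse
subnetwork per direction of phosphorylation change.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .network import RandomEnsemble, WeightedNetwork
from .seeds import SeedLayers, build_restart_vector

logger = logging.getLogger(__name__)

CONVERGENCE_TOL = 1e-10
MAX_ITER = 10_000


@dataclass
class RWRVector:
    """Stationary probability vector of a restarted walk."""

    nodes: list[str]
    p: np.ndarray
    damping: float

    def score(self, node: str) -> float:
        return float(self.p[self.nodes.index(node)])


def _transition_matrix(net: WeightedNetwork) -> tuple[sp.csr_matrix, list[str]]:
    nodes = net.nodes
    A = nx.to_scipy_sparse_array(net.graph, nodelist=nodes, weight="weight", format="csc")
    colsum = np.asarray(A.sum(axis=0)).ravel()
    scale = np.divide(1.0, colsum, out=np.zeros_like(colsum), where=colsum > 0)
    T = A @ sp.diags(scale)
    return T.tocsr(), nodes


def rwr(
    net: WeightedNetwork,
    restart: np.ndarray,
    damping: float = 0.85,
) -> RWRVector:
    """Power-iterate the restarted walk to its fixed point.

    ``restart`` must be a probability vector over ``net.nodes`` order.
    Dangling columns (zero weighted degree) teleport back to the restart
    distribution, keeping the iteration stochastic.
    """
    restart = np.asarray(restart, dtype=float)
    if restart.shape != (len(net.nodes),):
        raise ValueError("restart vector length mismatch")
    if np.any(restart < 0) or not np.isclose(restart.sum(), 1.0, atol=1e-9):
        raise ValueError("restart must be a probability vector")
    if not 0 <= damping < 1:
        raise ValueError("damping must lie in [0, 1)")
    T, nodes = _transition_matrix(net)
    if len(nodes) == 1:
        return RWRVector(nodes=nodes, p=np.array([1.0]), damping=damping)
    dangling = np.asarray(np.abs(T).sum(axis=0)).ravel() == 0
    p = restart.copy()
    for _ in range(MAX_ITER):
        walked = T @ p
        lost = p[dangling].sum()  # mass on dangling nodes re-enters via restart
        new = damping * (walked + lost * restart) + (1 - damping) * restart
        if np.abs(new - p).sum() < CONVERGENCE_TOL:
            p = new
            break
        p = new
    p = np.maximum(p, 0)
    p /= p.sum()
    return RWRVector(nodes=nodes, p=p, damping=damping)


@dataclass
class NullScores:
    """Per-node RWR scores over the R ensemble replicates (layer-specific)."""

    nodes: list[str]
    scores: np.ndarray  # shape (R, n_nodes); columns align with `nodes`

    @property
    def R(self) -> int:
        return self.scores.shape[0]


def null_scores(
    ensemble: RandomEnsemble,
    layer: dict[str, float],
    damping: float = 0.85,
) -> NullScores:
    """Replay a layer's restart vector against every ensemble replicate."""
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    ref_nodes = ensemble.networks[0].nodes
    rows = []
    for net in ensemble.networks:
        restart = build_restart_vector(layer, net)
        if restart is None:
            rows.append(np.zeros(len(net.nodes)))
            continue
        vec = rwr(net, restart, damping)
        # replicates share the node set but may order differently
        order = [vec.nodes.index(n) for n in ref_nodes] if vec.nodes != ref_nodes else None
        rows.append(vec.p[order] if order else vec.p)
    return NullScores(nodes=ref_nodes, scores=np.vstack(rows))


def empirical_filter(
    real: RWRVector, null: NullScores, alpha: float = 0.05
) -> tuple[set[str], dict[str, float]]:
    """Nodes whose real score beats more than (1 - alpha)·R null scores.

    Comparison is strict; ties count against retention. Also returns each
    node's empirical p-value (fraction of null scores >= real).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if null.R == 0:
        raise ValueError("no null scores")
    idx = {n: i for i, n in enumerate(null.nodes)}
    cols = np.array([idx[n] for n in real.nodes])
    nulls = null.scores[:, cols]
    beats = (nulls < real.p[None, :]).sum(axis=0)
    pvals = (nulls >= real.p[None, :]).mean(axis=0)
    if alpha == 1:  # keep-everything switch
        retained = set(real.nodes)
    else:
        threshold = (1 - alpha) * null.R
        retained = {n for n, b in zip(real.nodes, beats) if b > threshold}
    return retained, dict(zip(real.nodes, pvals.tolist()))


@dataclass
class DirectionNetwork:
    """Coarse subnetwork for one direction of phosphorylation change."""

    direction: str
    network: WeightedNetwork
    seeds: set[str]
    layer_scores: dict[str, dict[str, float]] = field(default_factory=dict)
    empirical_p: dict[str, dict[str, float]] = field(default_factory=dict)
    n_layers: int = 3

    def mean_score(self, node: str) -> float:
        """Mean RWR score across all *configured* layers, zeros included.

        Layers that were configured but empty for this direction count as
        zero, so a direction seeded in one layer is not favored over one
        seeded in three when shared proteins are resolved.
        """
        total = sum(scores.get(node, 0.0) for scores in self.layer_scores.values())
        return total / max(self.n_layers, 1)


def propagate_direction(
    net: WeightedNetwork,
    ensemble: RandomEnsemble,
    layers: SeedLayers,
    damping: float = 0.85,
    alpha: float = 0.05,
    n_layers: int = 3,
) -> DirectionNetwork:
    """Run per-layer RWR with empirical filtering and assemble the
    direction subnetwork.

    Every node retained by any layer is kept, and the direction's seeds are
    always included regardless of score.
    """
    retained_union: set[str] = set()
    layer_scores: dict[str, dict[str, float]] = {}
    empirical_p: dict[str, dict[str, float]] = {}
    seeds: set[str] = set()
    node_set = set(net.nodes)
    for name, layer in layers.layers().items():
        if not layer:
            continue
        restart = build_restart_vector(layer, net)
        if restart is None:
            continue
        seeds |= set(layer) & node_set
        real = rwr(net, restart, damping)
        layer_scores[name] = dict(zip(real.nodes, real.p.tolist()))
        null = null_scores(ensemble, layer, damping)
        retained, pvals = empirical_filter(real, null, alpha)
        empirical_p[name] = pvals
        retained_union |= retained
        logger.info(
            "%s/%s: %d seeds, %d nodes retained",
            layers.direction, name, len(layer), len(retained),
        )
    members = retained_union | seeds
    sub = net.subgraph(members)
    return DirectionNetwork(
        direction=layers.direction,
        network=sub,
        seeds=seeds,
        layer_scores=layer_scores,
        empirical_p=empirical_p,
        n_layers=n_layers,
    )


def resolve_dual_membership(
    up: DirectionNetwork, down: DirectionNetwork, keep_dual: bool = False
) -> tuple[DirectionNetwork, DirectionNetwork]:
    """Assign proteins present in both directions to the stronger one.

    A shared protein stays where its mean RWR score over the layers is
    larger and is removed from the other network (edges re-induced). Seeds
    exclusive to one direction are never removed from it. Exact ties go to
    the up network (logged).
    """
    if keep_dual:
        return up, down
    shared = set(up.network.nodes) & set(down.network.nodes)
    drop_up: set[str] = set()
    drop_down: set[str] = set()
    for node in shared:
        if node in up.seeds and node not in down.seeds:
            drop_down.add(node)
            continue
        if node in down.seeds and node not in up.seeds:
            drop_up.add(node)
            continue
        mu, md = up.mean_score(node), down.mean_score(node)
        if mu > md:
            drop_down.add(node)
        elif md > mu:
            drop_up.add(node)
        else:
            logger.info("tie for %s: kept in up network", node)
            drop_down.add(node)
    def _strip(dirnet: DirectionNetwork, drop: set[str]) -> DirectionNetwork:
        keep = [n for n in dirnet.network.nodes if n not in drop]
        return DirectionNetwork(
            direction=dirnet.direction,
            network=dirnet.network.subgraph(keep),
            seeds=dirnet.seeds - drop,
            layer_scores=dirnet.layer_scores,
            empirical_p=dirnet.empirical_p,
            n_layers=dirnet.n_layers,
        )
    if drop_up or drop_down:
        logger.info(
            "dual membership: %d removed from up, %d from down",
            len(drop_up), len(drop_down),
        )
    return _strip(up, drop_up), _strip(down, drop_down)
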