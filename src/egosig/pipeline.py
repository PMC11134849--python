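"""End-to-end orchestration: files in, modules and manifests out.

The pipeline chains network construction, seed selection, per-layer
propagation with empirical filtering, ego decomposition, supernode-graph
module detection and (optionally) enrichment, writing per-direction
artifacts plus a JSON run manifest that suffices to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx

from . import __version__
from .ego import (MIN_EGO_NEIGHBORS, Z_CUTOFF, supernodes_for_direction)
from .enrichment import fisher_enrichment, load_gmt
from .network import (WeightedNetwork, laplacian_normalize, load_network,
                      randomize_ensemble, semantic_profile)
from .ontology import load_ontology_annotation
from .propagation import propagate_direction, resolve_dual_membership
from .seeds import (aggregate_protein_scores, collapse_layers,
                    parse_phospho_table, partition_layers, percentile_filter)
from .supernodes import build_supernode_graph, partition_modules

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All file paths and tunables of one pipeline run."""

    network: str
    ontology: str
    annotations: str
    phospho: str
    kinases: str
    tyr_kinases: str
    outdir: str
    gene_sets: Optional[str] = None
    damping: float = 0.85
    alpha: float = 0.05
    n_randoms: int = 1000
    kde_cutoff: float = 0.85
    z_cutoff: float = Z_CUTOFF
    kinase_percentile: float = 20.0
    substrate_percentile: float = 80.0
    top_n: Optional[int] = None
    n_layers: int = 1 + 2  # three-layer propagation by default
    keep_dual: bool = False
    min_ego_neighbors: int = MIN_EGO_NEIGHBORS
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.damping < 1:
            raise ValueError("damping must lie in [0, 1)")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.n_randoms < 1:
            raise ValueError("n_randoms must be >= 1")
        if not 0 < self.kde_cutoff < 1:
            raise ValueError("kde_cutoff must lie in (0, 1)")
        if self.n_layers not in (1, 2, 3):
            raise ValueError("n_layers must be 1, 2 or 3")


@dataclass
class RunResult:
    config: RunConfig
    direction_networks: dict
    supernodes: dict
    partitions: dict
    enrichment: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _read_list(path: str | Path) -> set[str]:
    return {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_sif(net: WeightedNetwork, path: Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(net.graph.edges()):
            fh.write(f"{u}\tpp\t{v}\n")


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages and write artifacts under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def stage(name: str):
        logger.info("stage: %s", name)

    stage("base network")
    annotation = load_ontology_annotation(config.ontology, config.annotations)
    raw_net = load_network(config.network, annotation)
    counts["network_nodes"] = raw_net.graph.number_of_nodes()
    counts["network_edges"] = raw_net.graph.number_of_edges()
    norm_net = laplacian_normalize(raw_net)
    profile = semantic_profile(norm_net, annotation)
    ensemble = randomize_ensemble(
        raw_net, config.n_randoms, annotation, seed=config.seed
    )

    stage("seed selection")
    records = parse_phospho_table(config.phospho)
    counts["phospho_records"] = len(records)
    kinases = _read_list(config.kinases)
    tyr = _read_list(config.tyr_kinases)
    direction_layers = {}
    for direction in ("up", "down"):
        agg = aggregate_protein_scores(records, direction)
        t, o, s = partition_layers(set(agg), tyr, kinases)
        layers = percentile_filter(
            direction,
            {p: agg[p] for p in t},
            {p: agg[p] for p in o},
            {p: agg[p] for p in s},
            kinase_percentile=config.kinase_percentile,
            substrate_percentile=config.substrate_percentile,
            top_n=config.top_n,
        )
        direction_layers[direction] = collapse_layers(layers, config.n_layers)
        counts[f"seeds_{direction}"] = len(direction_layers[direction].all_proteins())

    stage("propagation")
    dirnets = {
        d: propagate_direction(
            norm_net, ensemble, layers, damping=config.damping,
            alpha=config.alpha, n_layers=config.n_layers,
        )
        for d, layers in direction_layers.items()
    }
    dirnets["up"], dirnets["down"] = resolve_dual_membership(
        dirnets["up"], dirnets["down"], keep_dual=config.keep_dual
    )
    for d, dn in dirnets.items():
        counts[f"coarse_nodes_{d}"] = dn.network.graph.number_of_nodes()

    stage("ego decomposition")
    supernodes = {}
    for d, dn in dirnets.items():
        sns, _diag = supernodes_for_direction(
            dn, profile, annotation,
            threshold=config.kde_cutoff,
            damping=config.damping,
            z_cutoff=config.z_cutoff,
            min_neighbors=config.min_ego_neighbors,
        )
        supernodes[d] = sns
        counts[f"supernodes_{d}"] = len(sns)

    stage("modules")
    partitions = {}
    for d, sns in supernodes.items():
        sg = build_supernode_graph(sns, raw_net, damping=config.damping, direction=d)
        partitions[d] = partition_modules(sg, seed=config.seed)
        counts[f"modules_{d}"] = len(partitions[d].modules)
        nx.write_graphml(sg.graph, outdir / f"supernode_graph_{d}.graphml")

    enrichment = {}
    if config.gene_sets:
        stage("enrichment")
        sets = load_gmt(config.gene_sets)
        background = set(raw_net.nodes)
        for d, part in partitions.items():
            enrichment[d] = {
                m["id"]: fisher_enrichment(
                    set(m["proteins"]) & background, sets, background
                )
                for m in part.modules
            }

    stage("write artifacts")
    for d, dn in dirnets.items():
        nx.write_graphml(dn.network.graph, outdir / f"coarse_network_{d}.graphml")
        _write_sif(dn.network, outdir / f"coarse_network_{d}.sif")
        with open(outdir / f"node_scores_{d}.tsv", "w") as fh:
            layer_names = sorted(dn.layer_scores)
            fh.write("node\t" + "\t".join(
                [f"score_{n}" for n in layer_names]
                + [f"p_{n}" for n in layer_names]
            ) + "\n")
            for node in sorted(dn.network.nodes):
                scores = [f"{dn.layer_scores[n].get(node, 0.0):.6g}" for n in layer_names]
                pvals = [f"{dn.empirical_p[n].get(node, 1.0):.6g}" for n in layer_names]
                fh.write(node + "\t" + "\t".join(scores + pvals) + "\n")
        with open(outdir / f"supernodes_{d}.json", "w") as fh:
            json.dump(
                [
                    {"ego": sn.ego, "members": sorted(sn.members), "direction": d}
                    for sn in supernodes[d]
                ],
                fh, indent=1,
            )
        with open(outdir / f"modules_{d}.tsv", "w") as fh:
            fh.write("module\tmethod\tegos\tproteins\n")
            for m in partitions[d].modules:
                fh.write(
                    f"{m['id']}\t{m['method']}\t{','.join(m['egos'])}\t"
                    f"{','.join(m['proteins'])}\n"
                )

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "input_hashes": {
            k: _sha256(getattr(config, k))
            for k in ("network", "ontology", "annotations", "phospho",
                      "kinases", "tyr_kinases")
        },
        "counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    return RunResult(
        config=config,
        direction_networks=dirnets,
        supernodes=supernodes,
        partitions=partitions,
        enrichment=enrichment,
        manifest=manifest,
    )
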