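"""Synthetic fixtures: toy ontologies, annotated networks, phospho tables.

The generator plants a known community structure so the full pipeline is
testable without any database downloads:

* the term DAG has one branch per community under a shared root, with
  community-wide "general" terms and per-subfamily leaf terms, so proteins
  of the same subfamily share high-information terms, community members
  share moderate-information ancestry, and cross-community pairs score
  near zero simGIC (tunable via ``coherence``);
* the protein network is a nested stochastic-block-model graph (subfamily
  cliques inside moderately dense communities, sparse between), with a
  random spanning tree per community guaranteeing within-community
  connectivity;
* the phospho table places high-|LFC|, high-functional-score sites on one
  designated *active* community (up-regulated), plus a noise fraction of
  low-score sites of random sign spread over the whole network. Kinase and
  tyrosine-kinase lists are drawn from the active community so all three
  propagation layers are populated.

Everything is a pure function of (spec, seed), and the writers emit the
exact text formats the loaders consume (OBO, GAF, edge TSV, phospho TSV,
one-accession-per-line kinase lists).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ontology import OntologyAnnotation, compute_information_content


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study system.

    Defaults describe a small but non-trivial system: 300 proteins in 12
    functional communities of 25, each community organized into 5 kinase
    subfamilies of 5 proteins; subfamilies are wired densest, communities
    moderately, cross-community pairs sparsely. 120 phosphosites (10%
    noise) seed the designated active community.
    """

    n_terms: int = 192
    depth: int = 3
    n_proteins: int = 300
    n_communities: int = 12
    n_subfamilies: int = 5
    p_within: float = 0.2
    p_subfamily: float = 0.5
    p_between: float = 0.002
    coherence: float = 0.95
    terms_per_protein: int = 6
    n_seed_sites: int = 120
    noise: float = 0.1
    n_kinases: int = 5
    n_tyr_kinases: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_within, self.p_subfamily, self.p_between,
                  self.coherence, self.noise):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.depth < 1:
            raise ValueError("ontology depth must be >= 1")
        for c in (self.n_terms, self.n_proteins, self.n_communities,
                  self.n_seed_sites, self.terms_per_protein):
            if c < 1:
                raise ValueError("counts must be >= 1")


@dataclass
class Fixture:
    """In-memory synthetic study system plus its provenance spec."""

    spec: FixtureSpec
    parents: dict[str, set[str]]
    raw_annotations: dict[str, set[str]]
    term_pools: list[dict]
    community: dict[str, int]
    subfamily: dict[str, int]
    edges: list[tuple[str, str]]
    phospho_rows: list[dict]
    kinases: list[str]
    tyr_kinases: list[str]
    annotation: OntologyAnnotation = field(init=False)

    def __post_init__(self) -> None:
        self.annotation = compute_information_content(
            self.raw_annotations, self.parents
        )

    def active_proteins(self) -> set[str]:
        return {p for p, c in self.community.items() if c == 0}


def _protein_names(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n)]


def synth_ontology(
    spec: FixtureSpec, rng: np.random.Generator
) -> tuple[dict[str, set[str]], list[dict]]:
    """Random term DAG with one branch per community and nested subfamilies.

    Under each community's branch root sit a handful of *general* terms
    (shared community-wide, like a biological-process annotation) and
    ``n_subfamilies`` subfamily roots, each carrying specific leaf terms
    (like a protein-family molecular function). Proteins of the same
    subfamily will therefore share high-information terms while all
    community members share the moderate-information branch ancestry —
    giving the ego decomposition a genuine near/far structure to resolve.

    Returns (parents, per-community pool dicts) where each pool dict has
    keys ``general`` (community-wide terms) and ``subfamilies`` (list of
    per-subfamily term lists).
    """
    k, s = spec.n_communities, spec.n_subfamilies
    per_comm = spec.n_terms // k
    if per_comm < 1 + s + 2:
        raise ValueError("too few terms per community for the subfamily layout")
    parents: dict[str, set[str]] = {}
    pools: list[dict] = []
    next_id = 0

    def new_term(parent: str | None) -> str:
        nonlocal next_id
        t = f"T{next_id:04d}"
        next_id += 1
        parents[t] = {parent} if parent else set()
        return t

    n_general = max(2, (per_comm - 1 - s) // 2)
    n_leaves = per_comm - 1 - s - n_general
    for _c in range(k):
        branch = new_term(None)  # attaches to the virtual root at IC time
        general = [new_term(branch) for _ in range(n_general)]
        sub_roots = [new_term(branch) for _ in range(s)]
        sub_pools: list[list[str]] = [[r] for r in sub_roots]
        for i in range(n_leaves):
            f = i % s
            # leaves may nest under other leaves up to the depth budget
            anchor = sub_pools[f][int(rng.integers(len(sub_pools[f])))]
            if len(sub_pools[f]) > spec.depth - 1:
                anchor = sub_pools[f][0]
            sub_pools[f].append(new_term(anchor))
        pools.append({"branch": branch, "general": general, "subfamilies": sub_pools})
    return parents, pools


def synth_annotations(
    spec: FixtureSpec,
    pools: list[dict],
    community: dict[str, int],
    subfamily: dict[str, int],
    rng: np.random.Generator,
) -> dict[str, set[str]]:
    """Draw each protein's terms from its own subfamily and community pools.

    With probability ``coherence`` a draw is on-target (80% subfamily
    terms, 20% community-general terms); otherwise it contaminates from a
    random other community.
    """
    k = spec.n_communities
    raw: dict[str, set[str]] = {}
    for prot, c in community.items():
        f = subfamily[prot]
        chosen: set[str] = set()
        for _ in range(spec.terms_per_protein):
            if k > 1 and rng.random() > spec.coherence:
                other = int(rng.integers(k - 1))
                pool = pools[other if other < c else other + 1]
                allt = pool["general"] + [
                    t for sub in pool["subfamilies"] for t in sub
                ]
                chosen.add(allt[int(rng.integers(len(allt)))])
            elif rng.random() < 0.8:
                sub = pools[c]["subfamilies"][f]
                chosen.add(sub[int(rng.integers(len(sub)))])
            else:
                gen = pools[c]["general"]
                chosen.add(gen[int(rng.integers(len(gen)))])
        raw[prot] = chosen
    return raw


def synth_network(
    spec: FixtureSpec,
    community: dict[str, int],
    subfamily: dict[str, int],
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Nested stochastic-block-model edge list with per-community trees.

    Subfamily members are wired densest, community members moderately,
    cross-community pairs sparsely; a random spanning tree per community
    guarantees within-community connectivity.
    """
    proteins = sorted(community)
    edges: set[tuple[str, str]] = set()
    for i, u in enumerate(proteins):
        for v in proteins[i + 1:]:
            if community[u] != community[v]:
                p = spec.p_between
            elif subfamily[u] == subfamily[v]:
                p = spec.p_subfamily
            else:
                p = spec.p_within
            if rng.random() < p:
                edges.add((u, v))
    for c in range(spec.n_communities):
        members = [p for p in proteins if community[p] == c]
        order = list(rng.permutation(len(members)))
        for j in range(1, len(members)):
            u = members[order[j]]
            v = members[order[int(rng.integers(j))]]
            edges.add(tuple(sorted((u, v))))
    return sorted(edges)


def synth_phospho_table(
    spec: FixtureSpec,
    community: dict[str, int],
    kinases: list[str],
    rng: np.random.Generator,
) -> list[dict]:
    """Plant up-regulated sites on the active community plus noise sites.

    Every designated kinase receives one strong up site (so the kinase
    layers are populated); the remaining signal sites cycle over the active
    community's non-kinase proteins (maximizing seed coverage, as deeply
    sampled phosphoproteomes do) with |LFC| in [2, 5]. Functional scores of
    signal sites track their |LFC| — strong regulatory sites respond more
    strongly — which keeps the joint LFC/score percentile filters from
    decimating the substrate layer. Noise sites have random sign, |LFC| in
    [0.1, 1.5] and score in [0, 0.3], drawn uniformly over all proteins.
    """
    proteins = sorted(community)
    active = [p for p in proteins if community[p] == 0]
    non_kinase = [p for p in active if p not in kinases]
    n_noise = int(round(spec.noise * spec.n_seed_sites))
    n_signal = spec.n_seed_sites - n_noise
    rows: list[dict] = []

    def site(protein: str, lfc: float, fscore: float) -> dict:
        return {
            "protein": protein,
            "position": int(rng.integers(1, 500)),
            "residue": ["S", "T", "Y"][int(rng.integers(3))],
            "lfc": round(float(lfc), 4),
            "fscore": round(float(min(max(fscore, 0.0), 1.0)), 4),
        }

    def signal_site(protein: str) -> dict:
        lfc = rng.uniform(2, 5)
        # logistic link keeps scores strictly inside (0, 1): no ties at the
        # ceiling, which would defeat strict percentile thresholds
        fscore = 1.0 / (1.0 + np.exp(-(lfc - 3.0) - rng.normal(0, 0.3)))
        return site(protein, lfc, fscore)

    for kin in kinases[:n_signal]:
        rows.append(signal_site(kin))
    order = rng.permutation(len(non_kinase))
    for i in range(max(0, n_signal - len(kinases))):
        rows.append(signal_site(non_kinase[order[i % len(non_kinase)]]))
    for _ in range(n_noise):
        prot = proteins[int(rng.integers(len(proteins)))]
        sign = 1 if rng.random() < 0.5 else -1
        rows.append(site(prot, sign * rng.uniform(0.1, 1.5), rng.uniform(0.0, 0.3)))
    return rows


def generate(spec: FixtureSpec) -> Fixture:
    """Deterministically build the complete in-memory fixture."""
    rng = np.random.default_rng(spec.seed)
    proteins = _protein_names(spec.n_proteins)
    community = {
        p: i * spec.n_communities // spec.n_proteins for i, p in enumerate(proteins)
    }
    by_comm: dict[int, list[str]] = {}
    for p, c in community.items():
        by_comm.setdefault(c, []).append(p)
    subfamily = {
        p: i * spec.n_subfamilies // len(members)
        for members in by_comm.values()
        for i, p in enumerate(sorted(members))
    }
    parents, pools = synth_ontology(spec, rng)
    raw = synth_annotations(spec, pools, community, subfamily, rng)
    edges = synth_network(spec, community, subfamily, rng)
    active = sorted(by_comm[0])
    # kinases cycle over the active community's subfamilies, as signaling
    # communities typically contain several kinase families
    by_sub: dict[int, list[str]] = {}
    for p in active:
        by_sub.setdefault(subfamily[p], []).append(p)
    kinases: list[str] = []
    rank = 0
    while len(kinases) < min(spec.n_kinases, len(active)):
        for f in sorted(by_sub):
            if rank < len(by_sub[f]):
                kinases.append(by_sub[f][rank])
                if len(kinases) == spec.n_kinases:
                    break
        rank += 1
    tyr = kinases[: spec.n_tyr_kinases]
    rows = synth_phospho_table(spec, community, kinases, rng)
    return Fixture(
        spec=spec,
        parents=parents,
        raw_annotations=raw,
        term_pools=pools,
        community=community,
        subfamily=subfamily,
        edges=edges,
        phospho_rows=rows,
        kinases=kinases,
        tyr_kinases=tyr,
    )


# ---------------------------------------------------------------- writers

def write_obo(parents: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n\n")
        for term in sorted(parents):
            fh.write(f"[Term]\nid: {term}\nname: synthetic term {term}\n")
            for p in sorted(parents[term]):
                fh.write(f"is_a: {p} ! synthetic term {p}\n")
            fh.write("\n")


def write_gaf(annotations: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for prot in sorted(annotations):
            for term in sorted(annotations[prot]):
                fields = ["SYN", prot, prot, "", term, "SYN:0000001", "IEA",
                          "", "P", "", "", "protein", "taxon:0000", "20240101",
                          "SYN", "", ""]
                fh.write("\t".join(fields) + "\n")


def write_edges(edges: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def write_phospho(rows: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tposition\tresidue\tlfc\tfscore\n")
        for r in rows:
            fh.write(
                f"{r['protein']}\t{r['position']}\t{r['residue']}\t"
                f"{r['lfc']}\t{r['fscore']}\n"
            )


def write_list(items: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in items))


def write_fixture(fix: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write every fixture file; returns the path of each artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "obo": outdir / "ontology.obo",
        "gaf": outdir / "annotations.gaf",
        "edges": outdir / "network.tsv",
        "phospho": outdir / "phospho.tsv",
        "kinases": outdir / "kinases.txt",
        "tyr_kinases": outdir / "tyr_kinases.txt",
    }
    write_obo(fix.parents, paths["obo"])
    write_gaf(fix.raw_annotations, paths["gaf"])
    write_edges(fix.edges, paths["edges"])
    write_phospho(fix.phospho_rows, paths["phospho"])
    write_list(fix.kinases, paths["kinases"])
    write_list(fix.tyr_kinases, paths["tyr_kinases"])
    return paths
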