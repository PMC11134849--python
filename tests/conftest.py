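"""Shared fixtures: hand-built toy ontologies and small synthetic systems."""

from __future__ import annotations

import warnings

import networkx as nx
import pytest

from egosig.network import WeightedNetwork, laplacian_normalize
from egosig.ontology import compute_information_content
from egosig.synth import FixtureSpec, generate


@pytest.fixture(scope="session")
def toy_annotation():
    """Four proteins over a tiny two-branch DAG.

    DAG: root <- a <- t1, t2 ; root <- b <- t3.
    PA: {t1, t2}, PB: {t1}, PC: {t3}, PD: {a}.
    """
    parents = {"a": set(), "b": set(), "t1": {"a"}, "t2": {"a"}, "t3": {"b"}}
    raw = {
        "PA": {"t1", "t2"},
        "PB": {"t1"},
        "PC": {"t3"},
        "PD": {"a"},
    }
    return compute_information_content(raw, parents)


def make_weighted(edges, weights=None) -> WeightedNetwork:
    """Hand-build a raw WeightedNetwork from (u, v[, w]) tuples."""
    g = nx.Graph()
    for i, e in enumerate(edges):
        u, v = e[0], e[1]
        w = e[2] if len(e) > 2 else (weights[i] if weights else 1.0)
        g.add_edge(u, v, weight=w)
    return WeightedNetwork(graph=g)


@pytest.fixture(scope="session")
def small_fixture():
    """Compact synthetic system reused across module tests (in-memory)."""
    spec = FixtureSpec(
        seed=11, n_proteins=120, n_communities=6, n_seed_sites=60, n_terms=96
    )
    return generate(spec)


@pytest.fixture(scope="session")
def small_fixture_files(small_fixture, tmp_path_factory):
    from egosig.synth import write_fixture

    outdir = tmp_path_factory.mktemp("fixture")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return write_fixture(small_fixture, outdir)


@pytest.fixture(scope="session")
def small_network(small_fixture):
    """Raw simGIC-weighted network of the small fixture."""
    ann = small_fixture.annotation
    g = nx.Graph()
    for u, v in small_fixture.edges:
        g.add_edge(u, v, weight=ann.simgic(u, v))
    return WeightedNetwork(graph=g)


@pytest.fixture(scope="session")
def small_normalized(small_network):
    return laplacian_normalize(small_network)
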