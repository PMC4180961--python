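"""Shared fixtures and independent oracles.

Oracles here are deliberately written against raw parent-edge dicts (via
networkx or naive loops), independent of the package's own traversal and
caching, so implementation/oracle agreement is a real check.
"""

from __future__ import annotations

import math
from typing import Dict, FrozenSet, List, Mapping, Tuple

import networkx as nx
import numpy as np
import pytest

from cnvmech.ontology import AnnotationTable, OntologyDAG, information_content, propagate
from cnvmech.simulate import SimulationConfig, generate_dataset


# ---------------------------------------------------------------------------
# tiny hand-built ontologies


@pytest.fixture
def chain_dag() -> OntologyDAG:
    # a -> b -> root
    return OntologyDAG.from_edges([("b", "root"), ("a", "b")])


@pytest.fixture
def diamond_dag() -> OntologyDAG:
    # a has parents b and c, both children of root
    return OntologyDAG.from_edges([("b", "root"), ("c", "root"), ("a", "b"), ("a", "c")])


@pytest.fixture
def diamond_ic(diamond_dag):
    table = propagate(
        diamond_dag,
        AnnotationTable(
            "disease",
            {
                "e1": frozenset({"a"}),
                "e2": frozenset({"b"}),
                "e3": frozenset({"c"}),
                "e4": frozenset({"root"}),
            },
        ),
    )
    return information_content(diamond_dag, table)


# ---------------------------------------------------------------------------
# random DAGs + annotation corpora


def random_parent_edges(rng: np.random.Generator, n_terms: int) -> Dict[str, set]:
    """Random rooted DAG: term i gets 1-2 parents among terms < i."""
    edges: Dict[str, set] = {"t0": set()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(2, i) + 1))
        parents = rng.choice(i, size=k, replace=False)
        edges[f"t{i}"] = {f"t{int(p)}" for p in parents}
    return edges


def random_annotations(
    rng: np.random.Generator, terms: List[str], n_entities: int, kind: str = "disease"
) -> AnnotationTable:
    direct = {}
    for e in range(n_entities):
        k = int(rng.integers(1, min(4, len(terms)) + 1))
        direct[f"e{e}"] = frozenset(rng.choice(terms, size=k, replace=False).tolist())
    return AnnotationTable(kind, direct)


# ---------------------------------------------------------------------------
# networkx-based traversal oracles


def nx_graph(parent_edges: Mapping[str, set]) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(parent_edges)
    for child, parents in parent_edges.items():
        for p in parents:
            g.add_edge(child, p)  # edge child -> parent
    return g


def oracle_ancestors(parent_edges: Mapping[str, set], t: str) -> FrozenSet[str]:
    g = nx_graph(parent_edges)
    return frozenset(nx.descendants(g, t) | {t})


def oracle_descendants(parent_edges: Mapping[str, set], t: str) -> FrozenSet[str]:
    g = nx_graph(parent_edges)
    return frozenset(nx.ancestors(g, t) | {t})


def oracle_ic(annotations_propagated: Mapping[str, FrozenSet[str]]) -> Dict[str, float]:
    n = len(annotations_propagated)
    counts: Dict[str, int] = {}
    for terms in annotations_propagated.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    return {t: -math.log(c / n) for t, c in counts.items()}


def oracle_phenomatch(
    parent_edges: Mapping[str, set],
    gene_terms: Tuple[str, ...],
    annot_direct: FrozenSet[str],
    ic: Mapping[str, float],
) -> float:
    """Exhaustive ancestor-pair enumeration, summing in the given term order."""
    anc_annot: set = set()
    for t in annot_direct:
        anc_annot |= oracle_ancestors(parent_edges, t)
    total = 0.0
    for t_g in gene_terms:
        ca = oracle_ancestors(parent_edges, t_g) & anc_annot
        best = 0.0
        for t in ca:
            if t in ic and ic[t] > best:
                best = ic[t]
        total += best
    return total


# ---------------------------------------------------------------------------
# simulated datasets (session-scoped: reused across modules)


@pytest.fixture(scope="session")
def default_dataset():
    """200-patient planted cohort, zero noise (mixture 10/20/60/10)."""
    return generate_dataset(SimulationConfig(seed=11, n_patients=200))


@pytest.fixture(scope="session")
def default_analysis(default_dataset):
    from cnvmech.pipeline import analyze_simulated

    return analyze_simulated(default_dataset)
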