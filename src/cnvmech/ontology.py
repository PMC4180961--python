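"""Rooted-DAG phenotype ontology with annotation propagation and information content.

The ontology is a set of terms connected by ``is_a``-style parent edges, with a
single root and no cycles.  Entities (patients, genes, diseases) are annotated
to terms; the propagation rule extends each entity's annotation set to all
ancestors of its direct terms.  A term's information content in a corpus is the
negative natural log of the fraction of annotated entities whose propagated
set contains it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional

__all__ = [
    "OntologyError",
    "OntologyDAG",
    "AnnotationTable",
    "ICTable",
    "propagate",
    "information_content",
]


class OntologyError(ValueError):
    """Raised for malformed ontologies or annotation/term mismatches."""


class OntologyDAG:
    """A rooted directed acyclic graph of terms.

    Parameters
    ----------
    parent_edges:
        Mapping from term to an iterable of its parent terms.  The root is the
        unique term with no parents; it may appear only on the right-hand side
        of edges or with an explicit empty parent set.

    Raises
    ------
    OntologyError
        If there is not exactly one root, if the parent relation contains a
        cycle, or if some term cannot reach the root.
    """

    def __init__(self, parent_edges: Mapping[str, Iterable[str]]):
        parents: Dict[str, FrozenSet[str]] = {
            t: frozenset(ps) for t, ps in parent_edges.items()
        }
        terms = set(parents)
        for ps in parents.values():
            terms.update(ps)
        for t in terms:
            parents.setdefault(t, frozenset())

        roots = sorted(t for t in terms if not parents[t])
        if len(roots) != 1:
            raise OntologyError(
                f"ontology must have exactly one root, found {len(roots)}: {roots[:5]}"
            )
        self.root: str = roots[0]
        self.terms: FrozenSet[str] = frozenset(terms)
        self.parents: Dict[str, FrozenSet[str]] = parents

        children: Dict[str, set] = {t: set() for t in terms}
        for t, ps in parents.items():
            for p in ps:
                children[p].add(t)
        self.children: Dict[str, FrozenSet[str]] = {
            t: frozenset(c) for t, c in children.items()
        }

        self._check_acyclic()
        self._anc: Dict[str, FrozenSet[str]] = {}
        self._desc: Dict[str, FrozenSet[str]] = {}
        # reachability: every term's ancestor closure must contain the root
        for t in self.terms:
            if self.root not in self.ancestors(t):
                raise OntologyError(f"term {t!r} cannot reach root {self.root!r}")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[tuple]) -> "OntologyDAG":
        """Build from (child, parent) pairs."""
        pe: Dict[str, set] = {}
        for child, parent in edges:
            pe.setdefault(child, set()).add(parent)
            pe.setdefault(parent, set())
        return cls(pe)

    def _check_acyclic(self) -> None:
        # Kahn's algorithm on the child->parent relation
        indeg = {t: len(self.parents[t]) for t in self.terms}
        queue = [t for t, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            t = queue.pop()
            seen += 1
            for c in self.children[t]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if seen != len(self.terms):
            raise OntologyError("ontology parent relation contains a cycle")

    def _require(self, t: str) -> None:
        if t not in self.terms:
            raise OntologyError(f"unknown ontology term: {t!r}")

    # -- traversal ------------------------------------------------------------

    def ancestors(self, t: str) -> FrozenSet[str]:
        """All terms reachable from ``t`` via parent edges, including ``t``."""
        self._require(t)
        cached = self._anc.get(t)
        if cached is not None:
            return cached
        out = {t}
        stack = list(self.parents[t])
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.parents[p])
        result = frozenset(out)
        self._anc[t] = result
        return result

    def descendants(self, t: str) -> FrozenSet[str]:
        """All terms whose ancestor set contains ``t``, including ``t``."""
        self._require(t)
        cached = self._desc.get(t)
        if cached is not None:
            return cached
        out = {t}
        stack = list(self.children[t])
        while stack:
            c = stack.pop()
            if c not in out:
                out.add(c)
                stack.extend(self.children[c])
        result = frozenset(out)
        self._desc[t] = result
        return result

    def ancestors_of_set(self, terms: Iterable[str]) -> FrozenSet[str]:
        """Union of ancestor sets over ``terms`` (empty input gives empty set)."""
        out: set = set()
        for t in terms:
            out |= self.ancestors(t)
        return frozenset(out)

    def is_ancestor_closed(self, terms: FrozenSet[str]) -> bool:
        """True iff the set contains every parent of each of its members."""
        return all(self.parents[t] <= terms for t in terms if t in self.terms)


@dataclass(frozen=True)
class AnnotationTable:
    """Entity -> term annotations for one kind of entity.

    ``propagated`` is ``None`` until :func:`propagate` has been applied; the
    propagated set of an entity is the ancestor closure of its direct set.
    """

    entity_kind: str
    direct: Mapping[str, FrozenSet[str]]
    propagated: Optional[Mapping[str, FrozenSet[str]]] = None

    ENTITY_KINDS = ("patient", "gene", "disease")

    def __post_init__(self):
        if self.entity_kind not in self.ENTITY_KINDS:
            raise ValueError(
                f"entity_kind must be one of {self.ENTITY_KINDS}, got {self.entity_kind!r}"
            )

    @property
    def is_propagated(self) -> bool:
        return self.propagated is not None

    @property
    def entities(self):
        return self.direct.keys()

    @classmethod
    def from_pairs(cls, entity_kind: str, pairs: Iterable[tuple]) -> "AnnotationTable":
        direct: Dict[str, set] = {}
        for entity, term in pairs:
            direct.setdefault(entity, set()).add(term)
        return cls(entity_kind, {e: frozenset(ts) for e, ts in direct.items()})


def propagate(dag: OntologyDAG, table: AnnotationTable) -> AnnotationTable:
    """Replace each entity's term set by the union of ancestor sets of its terms.

    Raises
    ------
    OntologyError
        If any annotated term is absent from the ontology; the message names
        the offending entity and term.
    """
    prop: Dict[str, FrozenSet[str]] = {}
    for entity, terms in table.direct.items():
        for t in terms:
            if t not in dag.terms:
                raise OntologyError(
                    f"entity {entity!r} is annotated to unknown term {t!r}"
                )
        prop[entity] = dag.ancestors_of_set(terms)
    return AnnotationTable(table.entity_kind, dict(table.direct), prop)


@dataclass(frozen=True)
class ICTable:
    """Corpus-specific term frequencies and information content (nats).

    Terms never annotated in the corpus are absent: their frequency is zero
    and the IC is undefined rather than infinite, so they contribute nothing
    to common-ancestor maxima.
    """

    corpus_id: str
    frequencies: Mapping[str, float]
    ic: Mapping[str, float]

    def get(self, term: str, default=None):
        return self.ic.get(term, default)

    def __contains__(self, term: str) -> bool:
        return term in self.ic


def information_content(
    dag: OntologyDAG, annotations: AnnotationTable, corpus_id: str = "corpus"
) -> ICTable:
    """IC(t) = -ln p_t, where p_t is the fraction of annotated entities whose
    propagated term set contains t.

    Requires a propagated, non-empty annotation table.
    """
    if not annotations.is_propagated:
        raise ValueError("information_content requires a propagated AnnotationTable")
    n = len(annotations.propagated)
    if n == 0:
        raise ValueError("empty annotation corpus")
    counts: Dict[str, int] = {}
    for terms in annotations.propagated.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    freqs = {t: c / n for t, c in counts.items()}
    ic = {t: -math.log(p) for t, p in freqs.items()}
    return ICTable(corpus_id, freqs, ic)
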