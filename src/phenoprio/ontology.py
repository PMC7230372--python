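"""Phenotype ontology model: DAG queries, information content, ancestor overlap.

A phenotype ontology (e.g. the Human Phenotype Ontology) is a directed
acyclic graph of terms connected by ``is_a`` edges.  Annotating an entity
(a disease, a mouse model, ...) to a term implicitly annotates it to every
ancestor of that term, which is what makes ontology-aware similarity work:
two clinically distinct terms can still share an informative common
ancestor.

Information content (IC) of a term is ``-ln`` of the fraction of annotated
entities carrying the term or any of its descendants; rare (specific) terms
are more informative than terms near the root.
"""

from __future__ import annotations

import math
import re
from typing import Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "TermId",
    "Ontology",
    "AnnotationCorpus",
    "load_ontology",
    "ancestors",
    "information_content",
    "jaccard_similarity",
    "most_informative_common_ancestor",
]

_TERM_RE = re.compile(r"^[A-Za-z]+:\d+$")


class TermId(str):
    """An ontology term identifier such as ``HP:0000556``.

    A thin ``str`` subclass that validates the ``PREFIX:digits`` shape on
    construction; everything downstream treats term ids as plain strings.
    """

    __slots__ = ()

    def __new__(cls, value: str) -> "TermId":
        if not _TERM_RE.match(value):
            raise ValueError(f"malformed term id: {value!r} (expected PREFIX:digits)")
        return super().__new__(cls, value)


class Ontology:
    """An is_a DAG over term ids, with cached reflexive ancestor closures."""

    def __init__(
        self,
        parents: Mapping[str, Iterable[str]],
        labels: Mapping[str, str] | None = None,
    ) -> None:
        self._parents: dict[str, frozenset[str]] = {
            t: frozenset(ps) for t, ps in parents.items()
        }
        self.labels: dict[str, str] = dict(labels or {})
        missing = {
            p for ps in self._parents.values() for p in ps if p not in self._parents
        }
        if missing:
            raise ValueError(
                f"is_a target(s) not present in ontology: {sorted(missing)[:5]}"
            )
        graph = nx.DiGraph()
        graph.add_nodes_from(self._parents)
        for child, ps in self._parents.items():
            for p in ps:
                graph.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(graph):
            edge = nx.find_cycle(graph)[0]
            raise ValueError(f"ontology contains a cycle through {edge[0]} -> {edge[1]}")
        self.roots: frozenset[str] = frozenset(
            t for t, ps in self._parents.items() if not ps
        )
        self._anc_cache: dict[str, frozenset[str]] = {}

    # -- container protocol -------------------------------------------------
    def __contains__(self, term: str) -> bool:
        return term in self._parents

    def __len__(self) -> int:
        return len(self._parents)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._parents)

    def parents(self, term: str) -> frozenset[str]:
        try:
            return self._parents[term]
        except KeyError:
            raise KeyError(f"unknown term: {term}") from None

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive transitive is_a closure of *term* (includes the term)."""
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        closure = {term}
        stack = list(self.parents(term))
        while stack:
            t = stack.pop()
            if t not in closure:
                closure.add(t)
                stack.extend(self._parents[t])
        result = frozenset(closure)
        self._anc_cache[term] = result
        return result


class AnnotationCorpus:
    """Entities (diseases, organism models, ...) annotated with term profiles.

    The corpus is the IC background: term counts are propagated through the
    ontology so that an entity annotated to a term counts toward every
    ancestor of that term.
    """

    def __init__(self, entity_terms: Mapping[str, Iterable[str]]) -> None:
        self.entity_terms: dict[str, tuple[str, ...]] = {
            entity: tuple(dict.fromkeys(terms))
            for entity, terms in entity_terms.items()
        }
        if not self.entity_terms:
            raise ValueError("annotation corpus is empty")
        self._count_cache: dict[int, dict[str, int]] = {}

    @property
    def total_entities(self) -> int:
        return len(self.entity_terms)

    def term_counts(self, ontology: Ontology) -> dict[str, int]:
        """Number of entities annotated (directly or via a descendant) to each term."""
        key = id(ontology)
        cached = self._count_cache.get(key)
        if cached is not None:
            return cached
        counts: dict[str, int] = {}
        for entity, terms in self.entity_terms.items():
            closure: set[str] = set()
            for t in terms:
                if t not in ontology:
                    raise KeyError(f"entity {entity} annotated to unknown term {t}")
                closure.update(ontology.ancestors(t))
            for t in closure:
                counts[t] = counts.get(t, 0) + 1
        self._count_cache[key] = counts
        return counts

    @classmethod
    def from_tsv(cls, path) -> "AnnotationCorpus":
        """Read a 2-column TSV: entity_id, pipe-separated term ids."""
        entity_terms: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                entity, terms = line.split("\t")
                entity_terms[entity] = terms.split("|") if terms else []
        return cls(entity_terms)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for entity, terms in self.entity_terms.items():
                fh.write(f"{entity}\t{'|'.join(terms)}\n")


def load_ontology(path) -> Ontology:
    """Load an OBO(-subset) file into an :class:`Ontology`.

    Only ``[Term]`` stanzas with ``id``, ``name`` and ``is_a`` lines are
    consumed; other tags are ignored and obsolete terms are skipped.  A
    cycle, or an ``is_a`` pointing at a term with no stanza, is a hard error.
    """
    graph = obonet.read_obo(path)  # skips obsolete stanzas by default
    labels: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    for node, data in graph.nodes(data=True):
        if "name" not in data:
            raise ValueError(f"is_a target {node} has no [Term] stanza")
        labels[node] = data["name"]
        parents[node] = set()
    for child, parent, rel in graph.edges(keys=True):
        if rel == "is_a":
            parents[child].add(parent)
    return Ontology(parents, labels)


# -- module-level operation surface -----------------------------------------

def ancestors(ontology: Ontology, term: str) -> frozenset[str]:
    return ontology.ancestors(term)


def information_content(corpus: AnnotationCorpus, ontology: Ontology, term: str) -> float:
    """IC(t) = -ln(n(t) / N) in nats, with add-one smoothing on empty terms.

    ``n(t)`` counts entities annotated to *term* or any descendant; the
    ``max(n, 1)`` floor keeps IC finite on sparsely annotated fixtures.
    """
    if term not in ontology:
        raise KeyError(f"unknown term: {term}")
    counts = corpus.term_counts(ontology)
    n = max(counts.get(term, 0), 1)
    return -math.log(n / corpus.total_entities)


def jaccard_similarity(ontology: Ontology, a: str, b: str) -> float:
    """Jaccard overlap of the reflexive ancestor sets of *a* and *b*."""
    anc_a = ontology.ancestors(a)
    anc_b = ontology.ancestors(b)
    union = len(anc_a | anc_b)
    if union == 0:  # pragma: no cover - impossible for reflexive sets
        return 0.0
    return len(anc_a & anc_b) / union


def most_informative_common_ancestor(
    ontology: Ontology, corpus: AnnotationCorpus, a: str, b: str
) -> tuple[str | None, float]:
    """The common ancestor of *a* and *b* with maximal IC.

    Ties are broken by the lexicographically smallest term id; term pairs
    from different roots (no common ancestor) return ``(None, 0.0)``.
    """
    common = ontology.ancestors(a) & ontology.ancestors(b)
    if not common:
        return None, 0.0
    counts = corpus.term_counts(ontology)
    total = corpus.total_entities
    best = min(
        common,
        key=lambda t: (math.log(max(counts.get(t, 0), 1) / total), t),
    )
    return best, information_content(corpus, ontology, best)
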