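"""Ontology handling: OBO parsing, ancestor closure, closest-common-parent
distances and annotation-derived term probabilities.

The Gene Ontology is a DAG per namespace (``biological_process``,
``molecular_function``, ``cellular_component``) whose edges point from a term
to its more general parents.  Two quantities drive everything downstream:

* the *closest-common-parent* (ccp) distance between two terms — the minimum,
  over all shared ancestors ``a``, of ``hops(t1, a) + hops(t2, a)`` with hops
  counted along directed parent edges; and
* the *term probability* ``p(t)`` — the fraction of annotated genes carrying
  ``t`` after ancestor closure, the standard frequency estimate underlying
  information content ``IC(t) = -log p(t)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import IO, Mapping

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


class OboParseError(ValueError):
    """Raised for malformed OBO input; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CyclicOntologyError(ValueError):
    """Raised when is_a/part_of edges contain a directed cycle."""


class IncomparableTermsError(ValueError):
    """Raised for term pairs in different namespaces (infinite distance)."""


class UnknownTermError(KeyError):
    pass


class OntologyGraph:
    """A parsed ontology: term metadata plus the parent DAG.

    Parameters
    ----------
    graph:
        A :class:`networkx.DiGraph` with edges ``child -> parent`` and node
        attributes ``name`` and ``namespace``.
    """

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise CyclicOntologyError(f"parent edges contain a cycle: {cycle}")
        self._g = graph
        self._ancestor_hops: dict[str, dict[str, int]] = {}
        self._depth: dict[str, int] | None = None

    # -- basic accessors ---------------------------------------------------
    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def name(self, term: str) -> str:
        self._check(term)
        return self._g.nodes[term].get("name", term)

    def namespace(self, term: str) -> str:
        self._check(term)
        return self._g.nodes[term]["namespace"]

    def parents(self, term: str) -> frozenset[str]:
        self._check(term)
        return frozenset(self._g.successors(term))

    def children(self, term: str) -> frozenset[str]:
        self._check(term)
        return frozenset(self._g.predecessors(term))

    def roots(self, namespace: str | None = None) -> frozenset[str]:
        out = (
            t
            for t in self._g.nodes
            if self._g.out_degree(t) == 0
            and (namespace is None or self.namespace(t) == namespace)
        )
        return frozenset(out)

    def _check(self, term: str) -> None:
        if term not in self._g:
            raise UnknownTermError(term)

    # -- distances ---------------------------------------------------------
    def ancestor_hops(self, term: str) -> dict[str, int]:
        """Map each ancestor (self included, at 0) to its minimum hop count."""
        self._check(term)
        cached = self._ancestor_hops.get(term)
        if cached is None:
            cached = nx.single_source_shortest_path_length(self._g, term)
            self._ancestor_hops[term] = cached
        return cached

    def ancestors(self, term: str) -> frozenset[str]:
        """All transitive parents of ``term``, the term itself included."""
        return frozenset(self.ancestor_hops(term))

    def depth(self, term: str) -> int:
        """Longest directed path from a namespace root down to ``term``."""
        self._check(term)
        if self._depth is None:
            depth: dict[str, int] = {}
            for t in reversed(list(nx.topological_sort(self._g))):
                ps = list(self._g.successors(t))
                depth[t] = 0 if not ps else 1 + max(depth[p] for p in ps)
            self._depth = depth
        return self._depth[term]

    def ccp_distance(self, t1: str, t2: str) -> tuple[str, int]:
        """Closest common parent of two same-namespace terms.

        Returns ``(ancestor, hops)`` minimising ``hops(t1,a) + hops(t2,a)``
        over common ancestors ``a``; ties broken by greater depth of the
        ancestor, then lexicographic term id.
        """
        if self.namespace(t1) != self.namespace(t2):
            raise IncomparableTermsError(
                f"{t1} ({self.namespace(t1)}) vs {t2} ({self.namespace(t2)})"
            )
        h1 = self.ancestor_hops(t1)
        h2 = self.ancestor_hops(t2)
        best: tuple[int, int, str] | None = None
        for a, d1 in h1.items():
            d2 = h2.get(a)
            if d2 is None:
                continue
            key = (d1 + d2, -self.depth(a), a)
            if best is None or key < best:
                best = key
        if best is None:  # disconnected within a namespace: no shared root
            raise IncomparableTermsError(f"{t1} and {t2} share no ancestor")
        total, _negdepth, ancestor = best
        return ancestor, total


def parse_obo(stream: IO[str] | str, include_part_of: bool = False) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 document into an :class:`OntologyGraph`.

    Obsolete terms are dropped.  Only ``is_a`` edges are kept unless
    ``include_part_of`` is set, in which case ``part_of`` relationships are
    treated as additional parent edges.
    """
    if isinstance(stream, str):
        with open(stream, "rt") as fh:
            return parse_obo(fh, include_part_of=include_part_of)
    text = stream.read()
    _prescan_obo(text)
    import io as _io

    try:
        multi = obonet.read_obo(_io.StringIO(text), ignore_obsolete=True)
    except Exception as exc:  # obonet raises plain ValueError/KeyError
        raise OboParseError(str(exc)) from exc
    keep = {"is_a"} | ({"part_of"} if include_part_of else set())
    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        ns = data.get("namespace")
        if ns is None:
            raise OboParseError(f"term {node} lacks a namespace")
        g.add_node(node, name=data.get("name", node), namespace=ns)
    for child, parent, key in multi.edges(keys=True):
        if key in keep and parent in g and child in g:
            g.add_edge(child, parent)
    return OntologyGraph(g)


def _prescan_obo(text: str) -> None:
    """Cheap structural validation so malformed stanzas fail with a line number."""
    in_term = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise OboParseError("unterminated stanza header", line=lineno)
            in_term = line == "[Term]"
            continue
        if ":" not in line:
            raise OboParseError(f"expected 'tag: value', got {line!r}", line=lineno)
        if in_term:
            tag, _, value = line.partition(":")
            if tag.strip() == "id" and not value.strip():
                raise OboParseError("empty term id", line=lineno)


@dataclass(frozen=True)
class AnnotationSet:
    """Gene -> GO term assignments over a fixed background universe.

    ``universe`` is every gene of the organism (annotated or not) so that
    background frequencies mean "of all genes", matching how genome-wide
    annotation files are used.  ``propagated`` is True once term sets are
    closed under ancestors.
    """

    universe: frozenset[str]
    _terms: Mapping[str, frozenset[str]]
    graph: OntologyGraph
    propagated: bool = False
    dropped_unknown: int = 0

    def terms_of(self, gene: str) -> frozenset[str]:
        if gene not in self.universe:
            raise KeyError(gene)
        return self._terms.get(gene, frozenset())

    def terms_of_in(self, gene: str, namespace: str) -> frozenset[str]:
        g = self.graph
        return frozenset(t for t in self.terms_of(gene) if g.namespace(t) == namespace)

    @property
    def genes_with_terms(self) -> frozenset[str]:
        return frozenset(g for g, ts in self._terms.items() if ts)

    def propagate(self) -> "AnnotationSet":
        """Close every gene's term set under ancestors (idempotent)."""
        if self.propagated:
            return self
        closed = {
            g: frozenset().union(*(self.graph.ancestors(t) for t in ts))
            for g, ts in self._terms.items()
            if ts
        }
        return AnnotationSet(
            universe=self.universe,
            _terms=closed,
            graph=self.graph,
            propagated=True,
            dropped_unknown=self.dropped_unknown,
        )

    # -- term probability --------------------------------------------------
    def annotated_in(self, namespace: str) -> frozenset[str]:
        """Genes with at least one term in ``namespace`` (any closure state)."""
        return frozenset(
            g for g, ts in self._terms.items() if any(
                self.graph.namespace(t) == namespace for t in ts
            )
        )

    def term_count(self, term: str) -> int:
        return sum(1 for ts in self._terms.values() if term in ts)

    def term_probability(self, term: str) -> float:
        """Propagated annotation frequency of ``term`` among genes annotated
        in the term's namespace.  The namespace root therefore has p = 1."""
        if not self.propagated:
            raise ValueError("term_probability requires a propagated AnnotationSet")
        ns = self.graph.namespace(term)
        denom = len(self.annotated_in(ns))
        if denom == 0:
            return 0.0
        return self.term_count(term) / denom

    def information_content(self, term: str) -> float:
        """Natural-log information content ``-ln p(t)``; +inf for unused terms."""
        p = self.term_probability(term)
        return math.inf if p == 0.0 else -math.log(p)


def load_annotations(
    stream: IO[str] | str,
    graph: OntologyGraph,
    gene_column: str = "gene_id",
    go_column: str = "GO",
) -> AnnotationSet:
    """Read a tab-separated gene -> GO table (Phytozome ``annotation_info``
    dialect: one row per gene, comma-separated GO ids).

    Genes with no recognised terms stay in the universe with an empty term
    set; term ids absent from the ontology are dropped and counted.
    """
    df = pd.read_csv(stream, sep="\t", dtype=str)
    for col in (gene_column, go_column):
        if col not in df.columns:
            raise ValueError(f"annotation table lacks required column {col!r}")
    terms: dict[str, frozenset[str]] = {}
    universe: set[str] = set()
    dropped = 0
    known = graph.terms
    for gene, cell in zip(df[gene_column], df[go_column]):
        if not isinstance(gene, str) or not gene:
            raise ValueError("annotation table contains an empty gene id")
        universe.add(gene)
        ids = []
        if isinstance(cell, str) and cell.strip():
            for tid in cell.split(","):
                tid = tid.strip()
                if not tid:
                    continue
                if tid in known:
                    ids.append(tid)
                else:
                    dropped += 1
        if ids:
            terms[gene] = frozenset(terms.get(gene, frozenset()) | set(ids))
    if dropped:
        logger.warning("dropped %d annotation(s) citing unknown GO terms", dropped)
    return AnnotationSet(
        universe=frozenset(universe),
        _terms=terms,
        graph=graph,
        propagated=False,
        dropped_unknown=dropped,
    )


def ancestors(graph: OntologyGraph, term: str) -> frozenset[str]:
    """Transitive parents of ``term``, self included."""
    return graph.ancestors(term)


def ccp_distance(graph: OntologyGraph, t1: str, t2: str) -> tuple[str, int]:
    """Closest-common-parent ancestor and total hop distance (see
    :meth:`OntologyGraph.ccp_distance`)."""
    return graph.ccp_distance(t1, t2)


def term_probability(ann: AnnotationSet, term: str) -> float:
    return ann.term_probability(term)
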