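"""Cluster gene sets by GO functional similarity and name each cluster with
its descriptive *head term*.

The gene-gene distance is built on the closest-common-parent (ccp) hop
distance between annotated terms: by default the distance between two genes
is the minimum ccp distance over all cross pairs of their (unpropagated)
terms in one namespace ("best pair"); a symmetrised best-match average is
available as an alternative aggregation.  Genes are then grouped by
average-linkage agglomerative clustering cut at a hop height ``theta``.

Each cluster's head term is the most informative ontology term that is an
ancestor (after closure) of at least ``coverage_fraction`` of the member
genes — informativeness measured as information content ``-log p(t)`` from
the genome-wide annotation frequency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .ontology import AnnotationSet, OntologyGraph

logger = logging.getLogger(__name__)

INFINITE_DISTANCE = math.inf

Aggregation = Literal["best_pair", "best_match_average"]


@dataclass(frozen=True)
class GeneCluster:
    """A functional gene cluster in one ontology namespace."""

    genes: frozenset[str]
    namespace: str
    head_term: str
    head_term_name: str
    member_terms: frozenset[str]
    head_is_root: bool = False

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_terms(self) -> int:
        return len(self.member_terms)


def gene_distance(
    ann: AnnotationSet,
    graph: OntologyGraph,
    g1: str,
    g2: str,
    namespace: str,
    aggregation: Aggregation = "best_pair",
) -> float:
    """Semantic distance between two genes within one namespace.

    Uses the genes' direct (unpropagated) annotations.  Returns ``inf`` when
    either gene has no annotation in the namespace.
    """
    t1 = ann.terms_of_in(g1, namespace)
    t2 = ann.terms_of_in(g2, namespace)
    if not t1 or not t2:
        return INFINITE_DISTANCE
    return _term_set_distance(graph, t1, t2, aggregation)


def _term_set_distance(graph, t1, t2, aggregation: Aggregation) -> float:
    d = {
        (a, b): float(graph.ccp_distance(a, b)[1])
        for a in t1
        for b in t2
    }
    if aggregation == "best_pair":
        return min(d.values())
    if aggregation == "best_match_average":
        left = np.mean([min(d[(a, b)] for b in t2) for a in t1])
        right = np.mean([min(d[(a, b)] for a in t1) for b in t2])
        return float((left + right) / 2.0)
    raise ValueError(f"unknown aggregation {aggregation!r}")


def distance_matrix(
    ann: AnnotationSet,
    graph: OntologyGraph,
    genes: Sequence[str],
    namespace: str,
    aggregation: Aggregation = "best_pair",
) -> np.ndarray:
    """Symmetric gene-gene distance matrix (all genes must be annotated in
    the namespace)."""
    term_sets = [ann.terms_of_in(g, namespace) for g in genes]
    n = len(genes)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _term_set_distance(
                graph, term_sets[i], term_sets[j], aggregation
            )
    return mat


def head_term(
    genes: Iterable[str],
    ann: AnnotationSet,
    graph: OntologyGraph,
    namespace: str,
    coverage_fraction: float = 1.0,
) -> tuple[str, bool]:
    """The descriptive term of a gene cluster.

    Among terms ancestral (after closure) to at least ``coverage_fraction``
    of the member genes, returns the one with maximal information content;
    ties broken by greater term depth, then lexicographic id.  The second
    element flags the degenerate case where only a namespace root qualifies.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("head_term of an empty cluster")
    if not 0.0 < coverage_fraction <= 1.0:
        raise ValueError("coverage_fraction must be in (0, 1]")
    prop = ann.propagate()
    closures = [
        frozenset(t for t in prop.terms_of(g) if graph.namespace(t) == namespace)
        for g in genes
    ]
    if any(not c for c in closures):
        raise ValueError("head_term requires every gene annotated in the namespace")
    counts: dict[str, int] = {}
    for c in closures:
        for t in c:
            counts[t] = counts.get(t, 0) + 1
    needed = coverage_fraction * len(genes)
    candidates = [t for t, c in counts.items() if c >= needed - 1e-12]
    # ties on IC broken by greater depth, then lexicographic id
    best = sorted(
        candidates,
        key=lambda t: (-prop.information_content(t), -graph.depth(t), t),
    )[0]
    is_root = best in graph.roots(namespace)
    if is_root:
        logger.info("cluster head term fell back to namespace root %s", best)
    return best, is_root


@dataclass
class ClusteringResult:
    clusters: list[GeneCluster]
    unannotated: list[str] = field(default_factory=list)


def cluster_genes(
    ann: AnnotationSet,
    graph: OntologyGraph,
    genes: Iterable[str],
    namespace: str,
    theta: float,
    aggregation: Aggregation = "best_pair",
    coverage_fraction: float = 1.0,
) -> ClusteringResult:
    """Average-linkage agglomerative clustering of a gene set at cut height
    ``theta`` (hops).

    Genes without annotations in ``namespace`` take part in no cluster and
    are reported separately.  Output is sorted by descending cluster size,
    then head-term id — deterministic for fixed inputs.
    """
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    genes = sorted(set(genes))
    missing = [g for g in genes if g not in ann.universe]
    if missing:
        raise KeyError(f"genes outside the annotation universe: {missing[:5]}")
    annotated = [g for g in genes if ann.terms_of_in(g, namespace)]
    unannotated = [g for g in genes if g not in set(annotated)]
    clusters: list[GeneCluster] = []
    if len(annotated) == 1:
        labels = np.array([1])
    elif annotated:
        mat = distance_matrix(ann, graph, annotated, namespace, aggregation)
        condensed = squareform(mat, checks=False)
        link = hierarchy.linkage(condensed, method="average")
        labels = hierarchy.fcluster(link, t=theta, criterion="distance")
    else:
        labels = np.array([], dtype=int)
    prop = ann.propagate()
    for lab in sorted(set(labels)):
        members = [g for g, l in zip(annotated, labels) if l == lab]
        head, is_root = head_term(members, ann, graph, namespace,
                                  coverage_fraction=coverage_fraction)
        member_terms = frozenset().union(
            *(prop.terms_of(g) for g in members)
        )
        member_terms = frozenset(
            t for t in member_terms if graph.namespace(t) == namespace
        )
        clusters.append(
            GeneCluster(
                genes=frozenset(members),
                namespace=namespace,
                head_term=head,
                head_term_name=graph.name(head),
                member_terms=member_terms,
                head_is_root=is_root,
            )
        )
    clusters.sort(key=lambda c: (-c.n_genes, c.head_term, min(c.genes)))
    return ClusteringResult(clusters=clusters, unannotated=unannotated)


def write_cluster_report(result: ClusteringResult, stream) -> None:
    """Tab-separated cluster report:
    `cluster_id, namespace, head_term, head_term_name, n_genes, gene_ids, n_terms`."""
    print(
        "cluster_id\tnamespace\thead_term\thead_term_name\tn_genes\tgene_ids\tn_terms",
        file=stream,
    )
    for i, c in enumerate(result.clusters, start=1):
        gene_ids = ",".join(sorted(c.genes))
        print(
            f"C{i}\t{c.namespace}\t{c.head_term}\t{c.head_term_name}"
            f"\t{c.n_genes}\t{gene_ids}\t{c.n_terms}",
            file=stream,
        )
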