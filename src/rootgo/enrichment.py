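"""Overrepresentation scoring of functional clusters and their comparison
across time points.

For a cluster with head term *t* and a DE gene set *S* drawn from a
background universe *U*:

* overrepresentation = ``log2(f_set / f_bg)`` with ``f_set`` the fraction of
  *S* annotated (post-closure) to *t* and ``f_bg`` the genome-wide
  annotation frequency of *t*; negative infinity when no DE gene carries
  the term;
* the cluster score = ``sum_t IC(t) * n_t`` over the cluster's member
  terms, with ``IC`` the natural-log information content and ``n_t`` the
  number of member genes annotated to *t* — larger means a more specific,
  more coherent cluster;
* an exact hypergeometric upper-tail p is attached for reference (never
  used to filter or rank).

Head terms are compared across ordered time-point pairs; the increase and
decrease lists, each ranked by descending cluster score, form the final
report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .ontology import AnnotationSet
from .semantic_clustering import GeneCluster

DIRECTION_EPS = 1e-9
DEFAULT_TP_PAIRS = (("TP1", "TP3"), ("TP3", "TP7"))


@dataclass(frozen=True)
class ClusterScoreRecord:
    cluster: GeneCluster
    tp: str
    overrep: float
    hypergeom_p: float
    score: float
    term_scores: Mapping[str, float]
    is_head_at_tp: bool = True


@dataclass(frozen=True)
class TemporalComparison:
    head_term: str
    tp_pair: tuple[str, str]
    delta_overrep: float
    direction: str  # increase | decrease | unchanged
    single_tp: bool = False


def term_set_fraction(
    term: str, gene_set: Iterable[str], ann: AnnotationSet
) -> float:
    """Fraction of ``gene_set`` annotated (post-closure) to ``term``."""
    prop = ann.propagate()
    genes = list(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    k = sum(1 for g in genes if term in prop.terms_of(g))
    return k / len(genes)


def cluster_overrepresentation(
    cluster: GeneCluster, ann: AnnotationSet, gene_set: Iterable[str]
) -> float:
    """log2 frequency ratio of the head term in the DE set vs the genome
    background; ``-inf`` when the set carries no copy of the term."""
    prop = ann.propagate()
    f_bg = prop.term_probability(cluster.head_term)
    if f_bg == 0.0:
        raise ValueError(
            f"head term {cluster.head_term} has zero background frequency"
        )
    f_set = term_set_fraction(cluster.head_term, gene_set, ann)
    if f_set == 0.0:
        return -math.inf
    return math.log2(f_set / f_bg)


def hypergeometric_p(
    term: str, gene_set: Iterable[str], ann: AnnotationSet
) -> float:
    """Exact upper-tail P[X >= k]: probability of drawing at least the
    observed number of term-annotated genes in a set of this size from the
    namespace-annotated universe."""
    prop = ann.propagate()
    ns = prop.graph.namespace(term)
    background = prop.annotated_in(ns)
    M = len(background)
    K = prop.term_count(term)
    genes = [g for g in gene_set if g in background]
    N = len(genes)
    k = sum(1 for g in genes if term in prop.terms_of(g))
    return float(stats.hypergeom.sf(k - 1, M, K, N))


def cluster_score(
    cluster: GeneCluster, ann: AnnotationSet
) -> tuple[float, dict[str, float]]:
    """Sum over member terms of IC(t) x (number of member genes carrying t
    post-closure); natural-log IC, so namespace roots contribute zero."""
    prop = ann.propagate()
    term_scores: dict[str, float] = {}
    for t in sorted(cluster.member_terms):
        n_t = sum(1 for g in cluster.genes if t in prop.terms_of(g))
        term_scores[t] = prop.information_content(t) * n_t
    return sum(term_scores.values()), term_scores


def score_cluster_at_tp(
    cluster: GeneCluster,
    ann: AnnotationSet,
    gene_set: Iterable[str],
    tp: str,
    is_head_at_tp: bool = True,
) -> ClusterScoreRecord:
    total, term_scores = cluster_score(cluster, ann)
    return ClusterScoreRecord(
        cluster=cluster,
        tp=tp,
        overrep=cluster_overrepresentation(cluster, ann, gene_set),
        hypergeom_p=hypergeometric_p(cluster.head_term, gene_set, ann),
        score=total,
        term_scores=term_scores,
        is_head_at_tp=is_head_at_tp,
    )


def temporal_deltas(
    records: Sequence[ClusterScoreRecord],
    tp_pairs: Sequence[tuple[str, str]] = DEFAULT_TP_PAIRS,
    eps: float = DIRECTION_EPS,
) -> list[TemporalComparison]:
    """Overrepresentation change of each head term across ordered tp pairs.

    Head terms scored at a single time point only are emitted once, flagged
    ``single_tp`` with direction ``unchanged`` (no imputation of absent
    time points)."""
    by_term: dict[str, dict[str, ClusterScoreRecord]] = {}
    for r in records:
        by_term.setdefault(r.cluster.head_term, {})[r.tp] = r
    out: list[TemporalComparison] = []
    for term in sorted(by_term):
        tps = by_term[term]
        if len(tps) == 1:
            (tp,) = tps
            out.append(
                TemporalComparison(
                    head_term=term,
                    tp_pair=(tp, tp),
                    delta_overrep=0.0,
                    direction="unchanged",
                    single_tp=True,
                )
            )
            continue
        for earlier, later in tp_pairs:
            if earlier not in tps or later not in tps:
                continue
            delta = tps[later].overrep - tps[earlier].overrep
            if delta > eps:
                direction = "increase"
            elif delta < -eps:
                direction = "decrease"
            else:
                direction = "unchanged"
            out.append(
                TemporalComparison(
                    head_term=term,
                    tp_pair=(earlier, later),
                    delta_overrep=delta,
                    direction=direction,
                )
            )
    return out


@dataclass(frozen=True)
class RankedEntry:
    rank: int
    head_term: str
    head_term_name: str
    namespace: str
    n_genes: int
    n_terms: int
    score: float
    delta_overrep: float
    tp_pair: tuple[str, str]


@dataclass
class RankedReport:
    increase: list[RankedEntry] = field(default_factory=list)
    decrease: list[RankedEntry] = field(default_factory=list)


def rank_clusters(
    comparisons: Sequence[TemporalComparison],
    records: Sequence[ClusterScoreRecord],
    tp_pair: tuple[str, str],
    top_k: int = 5,
) -> RankedReport:
    """Increase and decrease lists for one time-point pair, each sorted by
    descending cluster score (score = the head term's maximum over time
    points where it headed a cluster); ties broken by head-term id."""
    score_of: dict[str, float] = {}
    meta: dict[str, ClusterScoreRecord] = {}
    for r in records:
        t = r.cluster.head_term
        if r.is_head_at_tp and (t not in score_of or r.score > score_of[t]):
            score_of[t] = r.score
            meta[t] = r
    report = RankedReport()
    for direction, bucket in (("increase", report.increase),
                              ("decrease", report.decrease)):
        rows = [
            c
            for c in comparisons
            if c.tp_pair == tp_pair and c.direction == direction
            and c.head_term in score_of
        ]
        rows.sort(key=lambda c: (-score_of[c.head_term], c.head_term))
        for i, c in enumerate(rows[:top_k], start=1):
            rec = meta[c.head_term]
            bucket.append(
                RankedEntry(
                    rank=i,
                    head_term=c.head_term,
                    head_term_name=rec.cluster.head_term_name,
                    namespace=rec.cluster.namespace,
                    n_genes=rec.cluster.n_genes,
                    n_terms=rec.cluster.n_terms,
                    score=score_of[c.head_term],
                    delta_overrep=c.delta_overrep,
                    tp_pair=tp_pair,
                )
            )
    return report


def write_ranked_report(
    reports: Mapping[tuple[str, str], RankedReport],
    overreps: Mapping[str, Mapping[str, float]],
    stream,
) -> None:
    """Tab-separated ranked report; one row per ranked head term and
    direction.  ``overreps`` maps head term -> tp -> overrepresentation."""
    tps = sorted({tp for m in overreps.values() for tp in m})
    header = [
        "tp_pair", "direction", "rank", "namespace", "head_term",
        "head_term_name", "n_go_terms", "n_genes", "score",
    ] + [f"overrep_{tp.lower()}" for tp in tps] + ["delta"]
    print("\t".join(header), file=stream)
    for pair in sorted(reports):
        report = reports[pair]
        for direction, entries in (("increase", report.increase),
                                   ("decrease", report.decrease)):
            for e in entries:
                cells = [
                    f"{pair[0]}->{pair[1]}", direction, str(e.rank),
                    e.namespace, e.head_term, e.head_term_name,
                    str(e.n_terms), str(e.n_genes), f"{e.score:.4f}",
                ]
                for tp in tps:
                    v = overreps.get(e.head_term, {}).get(tp)
                    cells.append("NA" if v is None else f"{v:.4f}")
                cells.append(f"{e.delta_overrep:.4f}")
                print("\t".join(cells), file=stream)
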