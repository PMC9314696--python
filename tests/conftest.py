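"""Shared fixtures: a hand-built diamond ontology with a worked annotation
table, plus independent brute-force oracles for distances and enrichment."""

import io
import math

import pandas as pd
import pytest

from rootgo.ontology import load_annotations, parse_obo

DIAMOND_OBO = """\
format-version: 1.2
ontology: test-go

[Term]
id: GO:0000001
name: bp root
namespace: biological_process

[Term]
id: GO:0000002
name: term b
namespace: biological_process
is_a: GO:0000001 ! bp root

[Term]
id: GO:0000003
name: term c
namespace: biological_process
is_a: GO:0000001 ! bp root

[Term]
id: GO:0000004
name: term d
namespace: biological_process
is_a: GO:0000002 ! term b
is_a: GO:0000003 ! term c

[Term]
id: GO:0000005
name: term e
namespace: biological_process
is_a: GO:0000002 ! term b

[Term]
id: GO:0000010
name: mf root
namespace: molecular_function

[Term]
id: GO:0000011
name: mf leaf
namespace: molecular_function
is_a: GO:0000010 ! mf root
"""

# 10 genes annotated in BP, one gene with no terms, one citing an unknown id
ANNOTATION_TSV = """\
gene_id\tGO
g1\tGO:0000004
g2\tGO:0000004
g3\tGO:0000004
g4\tGO:0000002
g5\tGO:0000003
g6\tGO:0000003
g7\tGO:0000005
g8\tGO:0000005
g9\tGO:0000003,GO:0000011
g10\tGO:0000001
g11\t
g12\tGO:9999999
"""


@pytest.fixture(scope="session")
def diamond_graph():
    return parse_obo(io.StringIO(DIAMOND_OBO))


@pytest.fixture()
def diamond_annotations(diamond_graph):
    return load_annotations(io.StringIO(ANNOTATION_TSV), diamond_graph)


@pytest.fixture(scope="session")
def paperlike_bundle():
    """One default-parameter synthetic study shared across tests."""
    from rootgo.synthetic_data import simulate_study

    return simulate_study(11)


@pytest.fixture(scope="session")
def zero_noise_bundle():
    from rootgo.synthetic_data import TruthSpec, simulate_study

    return simulate_study(12, truth_spec=TruthSpec(noise_sd=0.0))


def make_study(rows, samples):
    """Build an ExpressionStudy from {gene: [values...]} and sample tuples."""
    from rootgo.expression import ExpressionStudy

    meta = pd.DataFrame(samples, columns=["sample_id", "tissue", "tp",
                                          "replicate"])
    fpkm = pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(meta["sample_id"]))
    return ExpressionStudy(fpkm, meta)


# ---------------------------------------------------------------------------
# independent oracles (no rootgo internals)
# ---------------------------------------------------------------------------

def oracle_parent_map(graph):
    return {t: set(graph.parents(t)) for t in graph.terms}


def oracle_ancestors(parents, term):
    """Fixpoint transitive closure over an explicit parent map."""
    out = {term}
    frontier = {term}
    while frontier:
        nxt = set()
        for t in frontier:
            nxt |= parents[t] - out
        out |= nxt
        frontier = nxt
    return out

def oracle_hops(parents, term):
    """BFS hop counts from term to each ancestor, hand-rolled."""
    dist = {term: 0}
    frontier = [term]
    while frontier:
        nxt = []
        for t in frontier:
            for p in parents[t]:
                if p not in dist:
                    dist[p] = dist[t] + 1
                    nxt.append(p)
        frontier = nxt
    return dist


def oracle_ccp(parents, t1, t2):
    """Exhaustive minimisation over every common ancestor."""
    h1, h2 = oracle_hops(parents, t1), oracle_hops(parents, t2)
    common = set(h1) & set(h2)
    assert common, "no common ancestor"
    return min(h1[a] + h2[a] for a in common)


def oracle_gene_distance(parents, terms1, terms2):
    return min(oracle_ccp(parents, a, b) for a in terms1 for b in terms2)


def oracle_hypergeom_tail(k, M, K, N):
    """Exact upper tail P[X >= k] by direct enumeration with math.comb."""
    denom = math.comb(M, N)
    total = 0
    for i in range(k, min(K, N) + 1):
        total += math.comb(K, i) * math.comb(M - K, N - i)
    return total / denom
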