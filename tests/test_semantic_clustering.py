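"""Gene-gene semantic distance, agglomerative clustering and head terms."""

import io
import math

import numpy as np
import pytest

from rootgo.ontology import load_annotations
from rootgo.semantic_clustering import (
    cluster_genes,
    gene_distance,
    head_term,
    write_cluster_report,
)
from rootgo.synthetic_data import make_annotations, make_ontology

from conftest import oracle_gene_distance, oracle_parent_map

BP = "biological_process"


def _ann(diamond_graph, rows):
    body = "gene_id\tGO\n" + "".join(f"{g}\t{t}\n" for g, t in rows)
    return load_annotations(io.StringIO(body), diamond_graph)


class TestGeneDistance:
    def test_shared_term_distance_zero(self, diamond_graph):
        ann = _ann(diamond_graph, [("a", "GO:0000004"),
                                   ("b", "GO:0000004,GO:0000002")])
        assert gene_distance(ann, diamond_graph, "a", "b", BP) == 0

    def test_sibling_terms_two_hops(self, diamond_graph):
        ann = _ann(diamond_graph, [("a", "GO:0000002"), ("b", "GO:0000003")])
        assert gene_distance(ann, diamond_graph, "a", "b", BP) == 2

    def test_unannotated_gene_infinite(self, diamond_graph):
        ann = _ann(diamond_graph, [("a", "GO:0000002"), ("b", "")])
        assert math.isinf(gene_distance(ann, diamond_graph, "a", "b", BP))

    def test_symmetric_and_zero_on_self(self, diamond_graph):
        ann = _ann(diamond_graph, [("a", "GO:0000002,GO:0000004"),
                                   ("b", "GO:0000005")])
        d_ab = gene_distance(ann, diamond_graph, "a", "b", BP)
        d_ba = gene_distance(ann, diamond_graph, "b", "a", BP)
        assert d_ab == d_ba
        assert gene_distance(ann, diamond_graph, "a", "a", BP) == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_double_loop(self, seed):
        """Best-pair distance equals the exhaustive term-pair minimum."""
        graph = make_ontology(seed, n_terms=30)
        genes = [f"g{i}" for i in range(40)]
        ann, _ = make_annotations(seed, graph, genes, branch_genes=[])
        parents = oracle_parent_map(graph)
        rng = np.random.default_rng(seed)
        annotated = [g for g in genes if ann.terms_of_in(g, BP)]
        for _ in range(25):
            g1, g2 = (annotated[i]
                      for i in rng.integers(0, len(annotated), 2))
            expected = oracle_gene_distance(
                parents, ann.terms_of_in(g1, BP), ann.terms_of_in(g2, BP)
            )
            assert gene_distance(ann, graph, g1, g2, BP) == expected

    def test_best_match_average_at_least_best_pair(self, diamond_graph):
        ann = _ann(diamond_graph, [("a", "GO:0000002,GO:0000005"),
                                   ("b", "GO:0000003,GO:0000004")])
        best = gene_distance(ann, diamond_graph, "a", "b", BP)
        avg = gene_distance(ann, diamond_graph, "a", "b", BP,
                            aggregation="best_match_average")
        assert avg >= best

    def test_best_match_average_closed_form(self, diamond_graph):
        # a={b}, b={c,d}: d(b,c)=2, d(b,d)=1 -> left=min=1;
        # right=(min(2),min(1))/... = mean(2,1) applied per side
        ann = _ann(diamond_graph, [("a", "GO:0000002"),
                                   ("b", "GO:0000003,GO:0000004")])
        avg = gene_distance(ann, diamond_graph, "a", "b", BP,
                            aggregation="best_match_average")
        left = 1.0  # b's best match among {c,d} is d at 1 hop
        right = (2.0 + 1.0) / 2  # c->2 hops, d->1 hop
        assert avg == pytest.approx((left + right) / 2)


class TestClusterGenes:
    def test_theta_zero_groups_shared_term_components(self, diamond_graph):
        ann = _ann(diamond_graph, [("a", "GO:0000004"), ("b", "GO:0000004"),
                                   ("c", "GO:0000005")])
        result = cluster_genes(ann, diamond_graph, ["a", "b", "c"], BP,
                               theta=0.0)
        memberships = sorted(sorted(c.genes) for c in result.clusters)
        assert memberships == [["a", "b"], ["c"]]

    def test_theta_infinite_single_cluster(self, diamond_graph):
        ann = _ann(diamond_graph, [("a", "GO:0000002"), ("b", "GO:0000003"),
                                   ("c", "GO:0000005")])
        result = cluster_genes(ann, diamond_graph, ["a", "b", "c"], BP,
                               theta=math.inf)
        assert len(result.clusters) == 1
        assert result.clusters[0].genes == {"a", "b", "c"}

    def test_negative_theta_rejected(self, diamond_graph):
        ann = _ann(diamond_graph, [("a", "GO:0000002")])
        with pytest.raises(ValueError, match="theta"):
            cluster_genes(ann, diamond_graph, ["a"], BP, theta=-1.0)

    def test_unannotated_genes_reported_separately(self, diamond_graph):
        ann = _ann(diamond_graph, [("a", "GO:0000002"), ("b", ""),
                                   ("c", "GO:0000011")])
        result = cluster_genes(ann, diamond_graph, ["a", "b", "c"], BP,
                               theta=2.0)
        clustered = set().union(*(c.genes for c in result.clusters))
        assert clustered == {"a"}
        assert sorted(result.unannotated) == ["b", "c"]

    def test_partition_of_annotated_input(self, paperlike_bundle):
        b = paperlike_bundle
        genes = b.study.genes[:80]
        result = cluster_genes(b.annotations, b.ontology, genes, BP,
                               theta=4.0, coverage_fraction=0.8)
        seen = []
        for c in result.clusters:
            seen.extend(c.genes)
        assert len(seen) == len(set(seen))  # no gene in two clusters
        assert set(seen) | set(result.unannotated) == set(genes)

    def test_planted_two_family_fixture(self, diamond_graph):
        """Genes on two disjoint branches separate at an intermediate cut."""
        rows = [(f"d{i}", "GO:0000004") for i in range(10)]
        rows += [(f"e{i}", "GO:0000005") for i in range(10)]
        ann = _ann(diamond_graph, rows)
        # intra-family distance 0; inter-family d(GO:4, GO:5) = 2 via b
        result = cluster_genes(ann, diamond_graph,
                               [g for g, _ in rows], BP, theta=1.0)
        families = sorted(sorted(c.genes) for c in result.clusters)
        assert families == [sorted(f"d{i}" for i in range(10)),
                            sorted(f"e{i}" for i in range(10))]

    def test_deterministic_ordering(self, paperlike_bundle):
        b = paperlike_bundle
        genes = b.study.genes[100:160]
        r1 = cluster_genes(b.annotations, b.ontology, genes, BP, theta=4.0,
                           coverage_fraction=0.8)
        r2 = cluster_genes(b.annotations, b.ontology, list(reversed(genes)),
                           BP, theta=4.0, coverage_fraction=0.8)
        assert [c.genes for c in r1.clusters] == [c.genes for c in r2.clusters]
        assert [c.head_term for c in r1.clusters] == [
            c.head_term for c in r2.clusters
        ]

    def test_both_aggregations_recover_plant(self, diamond_graph):
        rows = [(f"d{i}", "GO:0000004") for i in range(5)]
        rows += [(f"e{i}", "GO:0000005") for i in range(5)]
        ann = _ann(diamond_graph, rows)
        for agg in ("best_pair", "best_match_average"):
            result = cluster_genes(ann, diamond_graph, [g for g, _ in rows],
                                   BP, theta=1.0, aggregation=agg)
            assert len(result.clusters) == 2

    def test_report_format(self, diamond_graph):
        ann = _ann(diamond_graph, [("a", "GO:0000004"), ("b", "GO:0000004")])
        result = cluster_genes(ann, diamond_graph, ["a", "b"], BP, theta=1.0)
        buf = io.StringIO()
        write_cluster_report(result, buf)
        lines = buf.getvalue().splitlines()
        assert lines[0].split("\t") == [
            "cluster_id", "namespace", "head_term", "head_term_name",
            "n_genes", "gene_ids", "n_terms",
        ]
        assert lines[1].split("\t")[4] == "2"


class TestHeadTerm:
    def test_single_shared_term_is_head(self, diamond_graph):
        ann = _ann(diamond_graph, [("a", "GO:0000004"), ("b", "GO:0000004")])
        head, is_root = head_term(["a", "b"], ann, diamond_graph, BP)
        assert head == "GO:0000004"
        assert not is_root

    def test_sibling_leaves_meet_at_parent(self, diamond_graph):
        # d and e share ancestor b (and the root); b is rarer -> head
        ann = _ann(diamond_graph, [("a", "GO:0000004"), ("b", "GO:0000005"),
                                   ("x", "GO:0000003")])
        head, is_root = head_term(["a", "b"], ann, diamond_graph, BP)
        assert head == "GO:0000002"
        assert not is_root

    def test_higher_ic_ancestor_wins_over_shallower(self, diamond_graph):
        # both genes carry d; ancestors a(root), b, c, d all cover 100%:
        # d is rarest (max IC) and wins over b and c
        ann = _ann(diamond_graph, [("a", "GO:0000004"), ("b", "GO:0000004"),
                                   ("x", "GO:0000002"), ("y", "GO:0000003")])
        head, _ = head_term(["a", "b"], ann, diamond_graph, BP)
        assert head == "GO:0000004"

    def test_root_fallback_is_flagged(self, diamond_graph):
        # d-only and e-only genes plus a c-only gene: with full coverage the
        # deepest common ancestor of {d, e, c} closures is the root
        ann = _ann(diamond_graph, [("a", "GO:0000004"), ("b", "GO:0000005"),
                                   ("c", "GO:0000003")])
        head, is_root = head_term(["a", "b", "c"], ann, diamond_graph, BP)
        assert head == "GO:0000001"
        assert is_root

    def test_lower_coverage_allows_deeper_head(self, diamond_graph):
        ann = _ann(diamond_graph, [("a", "GO:0000004"), ("b", "GO:0000005"),
                                   ("c", "GO:0000003")])
        head, is_root = head_term(["a", "b", "c"], ann, diamond_graph, BP,
                                  coverage_fraction=0.6)
        assert head != "GO:0000001"
        assert not is_root

    def test_head_ic_never_increases_with_coverage(self, diamond_graph):
        ann = _ann(diamond_graph, [("a", "GO:0000004"), ("b", "GO:0000005"),
                                   ("c", "GO:0000003")])
        prop = ann.propagate()
        ics = []
        for cov in (0.4, 0.7, 1.0):
            head, _ = head_term(["a", "b", "c"], ann, diamond_graph, BP,
                                coverage_fraction=cov)
            ics.append(prop.information_content(head))
        assert ics == sorted(ics, reverse=True)

    def test_empty_cluster_rejected(self, diamond_graph):
        ann = _ann(diamond_graph, [("a", "GO:0000004")])
        with pytest.raises(ValueError, match="empty"):
            head_term([], ann, diamond_graph, BP)
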