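"""End-to-end orchestration: load -> select -> cluster -> score -> rank ->
report, with a flat config, deterministic outputs and a run manifest.

The per-namespace enrichment flow clusters each time point's DE gene set,
then evaluates every discovered head term's overrepresentation against
every time point's DE set so temporal deltas are defined wherever a DE set
exists; head terms that never headed a cluster at a time point are marked
as derived records there and are ranked by the score of the cluster they
actually headed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .enrichment import (
    ClusterScoreRecord,
    rank_clusters,
    score_cluster_at_tp,
    temporal_deltas,
)
from .expression import (
    classify_trend,
    load_de_records,
    load_expression,
    select_de,
    select_root_specific,
)
from .ontology import load_annotations, parse_obo
from .semantic_clustering import cluster_genes, write_cluster_report

logger = logging.getLogger(__name__)

DEFAULT_NAMESPACES = ("biological_process", "molecular_function")
DEFAULT_TP_PAIRS = (("TP1", "TP3"), ("TP3", "TP7"))


@dataclass
class PipelineConfig:
    """Every knob of the analysis; defaults are the study's thresholds."""

    obo: str = ""
    annotations: str = ""
    fpkm: str = ""
    samples: str = ""
    de: str = ""
    theta: float = 4.0
    coverage_fraction: float = 0.8
    aggregation: str = "best_pair"
    alpha_de: float = 0.05
    alpha_rs: float = 0.15
    leaf_max_fpkm: float = 3.0
    root_min_fpkm: float = 5.0
    min_abs_log2fc: float = 1.0
    top_k: int = 5
    seed: int = 0
    namespaces: tuple[str, ...] = DEFAULT_NAMESPACES
    tp_pairs: tuple[tuple[str, str], ...] = DEFAULT_TP_PAIRS

    def __post_init__(self):
        for name in ("theta", "coverage_fraction", "alpha_de", "alpha_rs",
                     "leaf_max_fpkm", "root_min_fpkm", "min_abs_log2fc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        self.namespaces = tuple(self.namespaces)
        self.tp_pairs = tuple(tuple(p) for p in self.tp_pairs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["namespaces"] = list(self.namespaces)
        d["tp_pairs"] = [list(p) for p in self.tp_pairs]
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, "rt") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class NamespaceEnrichment:
    namespace: str
    clusters_by_tp: dict = field(default_factory=dict)  # tp -> ClusteringResult
    records: list = field(default_factory=list)  # ClusterScoreRecord
    comparisons: list = field(default_factory=list)
    rankings: dict = field(default_factory=dict)  # tp_pair -> RankedReport
    overrep_by_head: dict = field(default_factory=dict)  # head -> tp -> float
    empty_tps: list = field(default_factory=list)


def enrichment_analysis(
    graph,
    ann,
    de_records,
    namespace: str,
    config: PipelineConfig,
) -> NamespaceEnrichment:
    """Cluster, score and rank one namespace across time points."""
    out = NamespaceEnrichment(namespace=namespace)
    tps = sorted(
        {r.tp for r in de_records},
        key=lambda tp: (len(tp), tp),
    )
    de_sets = {tp: select_de(de_records, tp, config.alpha_de) for tp in tps}
    head_at: dict[str, dict[str, object]] = {}
    for tp in tps:
        if not de_sets[tp]:
            out.empty_tps.append(tp)
            continue
        result = cluster_genes(
            ann, graph, de_sets[tp], namespace,
            theta=config.theta,
            aggregation=config.aggregation,
            coverage_fraction=config.coverage_fraction,
        )
        out.clusters_by_tp[tp] = result
        for c in result.clusters:
            head_at.setdefault(c.head_term, {})[tp] = c
    records: list[ClusterScoreRecord] = []
    for head in sorted(head_at):
        tps_headed = head_at[head]
        representative = tps_headed[min(tps_headed)]
        for tp in tps:
            if not de_sets[tp]:
                continue
            cluster = tps_headed.get(tp, representative)
            rec = score_cluster_at_tp(
                cluster, ann, de_sets[tp], tp,
                is_head_at_tp=tp in tps_headed,
            )
            records.append(rec)
            out.overrep_by_head.setdefault(head, {})[tp] = rec.overrep
    out.records = records
    out.comparisons = temporal_deltas(records, tp_pairs=config.tp_pairs)
    for pair in config.tp_pairs:
        out.rankings[pair] = rank_clusters(
            out.comparisons, records, pair, top_k=config.top_k
        )
    return out


@dataclass
class PipelineReport:
    config: PipelineConfig
    de_sets: dict
    root_specific: set
    trend_calls: list
    enrichment: dict  # namespace -> NamespaceEnrichment
    manifest: dict


def run_pipeline(config: PipelineConfig, outdir) -> PipelineReport:
    """Run the full analysis and write the report bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        graph = parse_obo(config.obo)
        ann = load_annotations(config.annotations, graph)
    except Exception as exc:
        raise PipelineStageError("load-ontology", exc) from exc
    try:
        study = load_expression(config.fpkm, config.samples)
        de_records = load_de_records(config.de)
    except Exception as exc:
        raise PipelineStageError("load-expression", exc) from exc

    tps = sorted({r.tp for r in de_records}, key=lambda tp: (len(tp), tp))
    try:
        de_sets = {tp: select_de(de_records, tp, config.alpha_de) for tp in tps}
        root_specific = select_root_specific(
            study, de_records,
            leaf_max_fpkm=config.leaf_max_fpkm,
            root_min_fpkm=config.root_min_fpkm,
            min_abs_log2fc=config.min_abs_log2fc,
            alpha=config.alpha_rs,
        )
        trend_calls = [classify_trend(study, g) for g in sorted(root_specific)]
    except Exception as exc:
        raise PipelineStageError("select", exc) from exc

    enrichment_results = {}
    for ns in config.namespaces:
        try:
            enrichment_results[ns] = enrichment_analysis(
                graph, ann, de_records, ns, config
            )
        except Exception as exc:
            raise PipelineStageError(f"enrich[{ns}]", exc) from exc

    manifest = _write_outputs(
        outdir, config, de_sets, root_specific, trend_calls,
        enrichment_results, de_records,
    )
    return PipelineReport(
        config=config, de_sets=de_sets, root_specific=root_specific,
        trend_calls=trend_calls, enrichment=enrichment_results,
        manifest=manifest,
    )


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def _write_outputs(outdir, config, de_sets, root_specific, trend_calls,
                   enrichment_results, de_records) -> dict:
    # DE gene sets
    for tp, genes in de_sets.items():
        (outdir / f"de_genes_{tp}.txt").write_text(
            "".join(f"{g}\n" for g in sorted(genes))
        )
    # root-specific genes with trend groups
    with open(outdir / "root_specific.tsv", "wt") as fh:
        print("gene_id\tgroup\tsigned_r2_psr\tsigned_r2_pfr", file=fh)
        for call in trend_calls:
            print(
                f"{call.gene}\t{call.group}\t{_fmt(call.signed_r2_psr)}"
                f"\t{_fmt(call.signed_r2_pfr)}",
                file=fh,
            )
    # clusters + ranked reports per namespace
    log2fc = {}
    for r in de_records:
        log2fc.setdefault(r.gene, {})[r.tp] = r.log2fc
    tps = sorted({r.tp for r in de_records}, key=lambda tp: (len(tp), tp))
    for ns, res in enrichment_results.items():
        for tp, clustering in res.clusters_by_tp.items():
            with open(outdir / f"clusters_{ns}_{tp}.tsv", "wt") as fh:
                write_cluster_report(clustering, fh)
        for tp in res.empty_tps:
            (outdir / f"clusters_{ns}_{tp}.tsv").write_text(
                "# no DE genes at this time point: no clusters\n"
            )
        with open(outdir / f"ranked_{ns}.tsv", "wt") as fh:
            from .enrichment import write_ranked_report

            write_ranked_report(res.rankings, res.overrep_by_head, fh)
        # heatmap table: genes of ranked clusters x tp log2 fold changes
        with open(outdir / f"heatmap_{ns}.tsv", "wt") as fh:
            cols = "\t".join(f"log2fc_{tp.lower()}" for tp in tps)
            print(f"head_term\tgene_id\t{cols}", file=fh)
            seen = set()
            for pair in sorted(res.rankings):
                report = res.rankings[pair]
                for entry in report.increase + report.decrease:
                    head = entry.head_term
                    for tp_c, cluster in sorted(
                        res.clusters_by_tp.items()
                    ):
                        for c in cluster.clusters:
                            if c.head_term != head:
                                continue
                            for g in sorted(c.genes):
                                if (head, g) in seen:
                                    continue
                                seen.add((head, g))
                                vals = "\t".join(
                                    _fmt(log2fc.get(g, {}).get(tp, float("nan")))
                                    for tp in tps
                                )
                                print(f"{head}\t{g}\t{vals}", file=fh)
    # manifest
    cfg = config.to_dict()
    blob = json.dumps(cfg, sort_keys=True).encode()
    manifest = {
        "package": "rootgo",
        "version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "n_root_specific": len(root_specific),
        "n_de": {tp: len(v) for tp, v in sorted(de_sets.items())},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
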