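"""Synthetic study generator with planted ground truth.

Emulates the inputs of a storage-root time-course transcriptome study so the
whole pipeline runs with no external data: a two-namespace GO-like DAG, a
gene->term annotation table, an FPKM study over four tissues (SIL, SOL,
PFR_FR, PSR_SR) x four time points x three biological replicates, Welch
stand-in DE records, and a qPCR Ct table for the dual-marker root-type
classifier.  Every planted structure (root-specific genes, an enriched GO
branch switched on in PSR_SR from TP3, monotone expression trends, root
types) is recorded in a :class:`SyntheticTruth` so recovery can be scored.

Expression is lognormal: per-gene mean log2 FPKM ~ Normal(3, 1.2) with
replicate noise Normal(0, noise_sd) on the log2 scale.  At ``noise_sd=0``
every planted truth is recovered exactly by the corresponding selector.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import DERecord, ExpressionStudy, welch_de_standin
from .marker_stats import MARKER_FR, MARKER_SR, REFERENCE_GENE, QpcrTable
from .ontology import AnnotationSet, OntologyGraph

NAMESPACE_PREFIX = {"biological_process": 1, "molecular_function": 2}


@dataclass(frozen=True)
class TruthSpec:
    """Planted-structure sizes and effect parameters of one simulation."""

    n_root_specific: int = 12
    n_branch: int = 30
    trend_per_group: int = 4
    effect_size: float = 1.5  # log2 units added in PSR_SR from TP3 on
    noise_sd: float = 0.25  # replicate noise, log2 scale
    replicates: int = 3
    timepoints: tuple[str, ...] = ("TP1", "TP3", "TP5", "TP7")

    @property
    def n_planted(self) -> int:
        return self.n_root_specific + 4 * self.trend_per_group + self.n_branch


@dataclass
class SyntheticTruth:
    planted_root_specific: set[str] = field(default_factory=set)
    planted_cluster_branch: dict = field(default_factory=dict)
    planted_trend_groups: dict[str, str] = field(default_factory=dict)
    planted_root_types: dict[tuple[str, str], str] = field(default_factory=dict)
    generator_params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "planted_root_specific": sorted(self.planted_root_specific),
            "planted_cluster_branch": {
                k: (sorted(v) if isinstance(v, (set, frozenset, list)) else v)
                for k, v in self.planted_cluster_branch.items()
            },
            "planted_trend_groups": dict(sorted(self.planted_trend_groups.items())),
            "planted_root_types": {
                f"{p}/{r}": t
                for (p, r), t in sorted(self.planted_root_types.items())
            },
            "generator_params": self.generator_params,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

def make_ontology(seed: int, n_terms: int = 100, branching: int = 3) -> OntologyGraph:
    """Random rooted DAG per namespace (BP and MF), ``n_terms`` terms each.

    Terms attach to a parent with spare child capacity (about ``branching``
    children per term); 10% of non-root terms gain a second parent from a
    strictly shallower level, so the graph stays acyclic by construction.
    """
    import networkx as nx

    if n_terms < 3:
        raise ValueError("n_terms must be >= 3")
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    for ns, prefix in NAMESPACE_PREFIX.items():
        ids = [f"GO:{prefix}{i:06d}" for i in range(n_terms)]
        level = {ids[0]: 0}
        children: dict[str, int] = {ids[0]: 0}
        g.add_node(ids[0], name=f"{ns} root", namespace=ns)
        for i in range(1, n_terms):
            term = ids[i]
            if i <= branching:
                parent = ids[0]  # a few fixed top-level children, GO-like
            else:
                pool = [t for t in ids[:i] if children[t] < branching] \
                    or ids[:i]
                parent = pool[int(rng.integers(len(pool)))]
            g.add_node(term, name=f"synthetic term {ns[:2]}-{i}", namespace=ns)
            g.add_edge(term, parent)
            children[parent] += 1
            children[term] = 0
            level[term] = level[parent] + 1
            if level[term] >= 2 and rng.random() < 0.10:
                shallower = [t for t in ids[:i]
                             if level[t] < level[term] and t != parent]
                if shallower:
                    extra = shallower[int(rng.integers(len(shallower)))]
                    g.add_edge(term, extra)
    return OntologyGraph(g)


def write_obo(graph: OntologyGraph, stream) -> None:
    """Serialize an :class:`OntologyGraph` as a minimal OBO 1.2 document."""
    print("format-version: 1.2", file=stream)
    print("ontology: synthetic-go", file=stream)
    for term in sorted(graph.terms):
        print(file=stream)
        print("[Term]", file=stream)
        print(f"id: {term}", file=stream)
        print(f"name: {graph.name(term)}", file=stream)
        print(f"namespace: {graph.namespace(term)}", file=stream)
        for parent in sorted(graph.parents(term)):
            print(f"is_a: {parent} ! {graph.name(parent)}", file=stream)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def pick_branch_head(graph: OntologyGraph,
                     namespace: str = "biological_process") -> str:
    """Deterministic choice of the planted branch: the deepest term with at
    least 3 children (ties: more children, then smallest id).  Depth first
    keeps the planted subtree far from the rest of the DAG, so the branch
    is separable at realistic cut heights."""
    roots = graph.roots(namespace)
    candidates = [
        t for t in graph.terms
        if graph.namespace(t) == namespace and t not in roots
        and len(graph.children(t)) >= 3
    ]
    if not candidates:
        raise ValueError("ontology has no internal term with >=3 children")
    return sorted(
        candidates,
        key=lambda t: (-graph.depth(t), -len(graph.children(t)), t),
    )[0]


def make_annotations(
    seed: int,
    graph: OntologyGraph,
    genes: list[str],
    branch_genes: list[str],
    branch_head: str | None = None,
    unannotated_fraction: float = 0.05,
) -> tuple[AnnotationSet, str]:
    """Annotate genes against the synthetic ontology.

    Planted branch genes receive two distinct children of the branch head
    term (pairwise ccp distance <= 2 within the branch); other genes draw
    1-2 BP and 0-2 MF terms uniformly from non-root terms, with a small
    unannotated fraction.  Returns the (unpropagated) annotation set and
    the branch head term id.
    """
    rng = np.random.default_rng(seed)
    branch_set = set(branch_genes)
    if branch_head is None and branch_set:
        branch_head = pick_branch_head(graph)
    branch_children = sorted(graph.children(branch_head)) if branch_head \
        else []
    bp_terms = sorted(
        t for t in graph.terms
        if graph.namespace(t) == "biological_process"
        and t not in graph.roots("biological_process")
    )
    mf_terms = sorted(
        t for t in graph.terms
        if graph.namespace(t) == "molecular_function"
        and t not in graph.roots("molecular_function")
    )
    terms: dict[str, frozenset[str]] = {}
    for i, gene in enumerate(genes):
        if gene in branch_set:
            # round-robin pair of head-term children: every child covers
            # ~2/k of the branch genes, the head term covers all of them
            k = len(branch_children)
            picked = {branch_children[i % k], branch_children[(i + 1) % k]}
            if rng.random() < 0.5:
                picked.add(mf_terms[int(rng.integers(len(mf_terms)))])
            terms[gene] = frozenset(picked)
            continue
        if rng.random() < unannotated_fraction:
            continue
        n_bp = int(rng.integers(1, 3))
        n_mf = int(rng.integers(0, 3))
        picked = {bp_terms[int(rng.integers(len(bp_terms)))]
                  for _ in range(n_bp)}
        picked |= {mf_terms[int(rng.integers(len(mf_terms)))]
                   for _ in range(n_mf)}
        terms[gene] = frozenset(picked)
    ann = AnnotationSet(
        universe=frozenset(genes), _terms=terms, graph=graph, propagated=False
    )
    return ann, branch_head


def write_annotations(ann: AnnotationSet, stream) -> None:
    print("gene_id\tGO", file=stream)
    for gene in sorted(ann.universe):
        ts = ",".join(sorted(ann.terms_of(gene)))
        print(f"{gene}\t{ts}", file=stream)


# ---------------------------------------------------------------------------
# expression study
# ---------------------------------------------------------------------------

def _planted_gene_slices(genes: list[str], spec: TruthSpec):
    """Deterministic disjoint planted-gene assignments (front of the list)."""
    if spec.n_planted > len(genes):
        raise ValueError(
            f"{spec.n_planted} planted genes requested but only "
            f"{len(genes)} genes generated"
        )
    i = 0
    root_specific = genes[i:i + spec.n_root_specific]
    i += spec.n_root_specific
    trends: dict[str, list[str]] = {}
    for group in ("FR_UP", "SR_D", "SR_EQ", "SR_UP"):
        trends[group] = genes[i:i + spec.trend_per_group]
        i += spec.trend_per_group
    branch = genes[i:i + spec.n_branch]
    return root_specific, trends, branch


def _trend_profile(group: str, n_tp: int) -> dict[str, np.ndarray]:
    """Planted mean FPKM per tissue class across time points.

    Profiles are linear on the FPKM scale so the noiseless signed R^2 of
    the PSR_SR trend is exactly +1 (SR_UP), -1 (SR_D) or 0 (flat groups).
    """
    idx = np.arange(n_tp) / max(n_tp - 1, 1)
    flat = lambda v: np.full(n_tp, float(v))
    leaf = flat(8.0)
    if group == "FR_UP":
        return {"leaf": leaf, "PFR_FR": flat(20.0), "PSR_SR": flat(5.0)}
    if group == "SR_UP":
        return {"leaf": leaf, "PFR_FR": flat(8.0), "PSR_SR": 5.0 + 15.0 * idx}
    if group == "SR_D":
        return {"leaf": leaf, "PFR_FR": flat(8.0), "PSR_SR": 20.0 - 15.0 * idx}
    if group == "SR_EQ":
        return {"leaf": leaf, "PFR_FR": flat(8.0), "PSR_SR": flat(10.0)}
    raise ValueError(group)


def make_expression_study(
    seed: int,
    n_genes: int = 500,
    truth_spec: TruthSpec | None = None,
) -> tuple[ExpressionStudy, list[DERecord], SyntheticTruth]:
    """Generate the FPKM study, its Welch stand-in DE records and the truth.

    Planting (all disjoint): root-specific genes are near-silent in leaves
    (FPKM <= 2) and strongly expressed in roots with a >=2-fold PSR/PFR
    contrast; trend genes follow linear-in-FPKM profiles per group; branch
    genes gain ``effect_size`` log2 units in PSR_SR from TP3 onward.
    """
    spec = truth_spec or TruthSpec()
    if spec.effect_size <= 0:
        raise ValueError("effect_size must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(1, n_genes + 1)]
    root_specific, trends, branch = _planted_gene_slices(genes, spec)
    tps = list(spec.timepoints)
    n_tp = len(tps)

    # per-gene per-(tissue, tp) mean FPKM
    mean_fpkm = {
        tissue: np.zeros((n_genes, n_tp)) for tissue in
        ("SIL", "SOL", "PFR_FR", "PSR_SR")
    }
    base_log2 = rng.normal(3.0, 1.2, size=n_genes)
    for t in mean_fpkm:
        mean_fpkm[t][:, :] = 2.0 ** base_log2[:, None]

    gene_index = {g: i for i, g in enumerate(genes)}
    # branch genes: expressed in leaves (so never root-specific), boosted in
    # PSR_SR from TP3 on
    effect_from = min(1, n_tp - 1)  # index of TP3 in the default design
    for g in branch:
        i = gene_index[g]
        mu = max(base_log2[i], 2.5)
        for t in mean_fpkm:
            mean_fpkm[t][i, :] = 2.0 ** mu
        mean_fpkm["PSR_SR"][i, effect_from:] = 2.0 ** (mu + spec.effect_size)
    # trend genes
    for group, members in trends.items():
        profile = _trend_profile(group, n_tp)
        for g in members:
            i = gene_index[g]
            mean_fpkm["SIL"][i, :] = profile["leaf"]
            mean_fpkm["SOL"][i, :] = profile["leaf"]
            mean_fpkm["PFR_FR"][i, :] = profile["PFR_FR"]
            mean_fpkm["PSR_SR"][i, :] = profile["PSR_SR"]
    # root-specific genes: silent in leaves, on in roots, >=2-fold contrast
    for g in root_specific:
        i = gene_index[g]
        leaf = rng.uniform(0.1, 2.0)
        pfr = rng.uniform(5.0, 8.0)
        psr = rng.uniform(24.0, 40.0)
        mean_fpkm["SIL"][i, :] = leaf
        mean_fpkm["SOL"][i, :] = leaf
        mean_fpkm["PFR_FR"][i, :] = pfr
        mean_fpkm["PSR_SR"][i, :] = psr

    # replicate noise on the log2 scale
    columns = []
    data = []
    meta = []
    for tissue in ("SIL", "SOL", "PFR_FR", "PSR_SR"):
        for j, tp in enumerate(tps):
            for rep in range(1, spec.replicates + 1):
                sample_id = f"{tissue}_{tp}_r{rep}"
                noise = rng.normal(0.0, spec.noise_sd, size=n_genes) \
                    if spec.noise_sd > 0 else np.zeros(n_genes)
                values = mean_fpkm[tissue][:, j] * 2.0 ** noise
                columns.append(sample_id)
                data.append(values)
                meta.append((sample_id, tissue, tp, rep))
    fpkm = pd.DataFrame(
        np.column_stack(data), index=genes, columns=columns
    )
    samples = pd.DataFrame(
        meta, columns=["sample_id", "tissue", "tp", "replicate"]
    )
    study = ExpressionStudy(fpkm, samples)
    de_records: list[DERecord] = []
    for tp in tps:
        de_records.extend(welch_de_standin(study, tp))
    truth = SyntheticTruth(
        planted_root_specific=set(root_specific),
        planted_cluster_branch={"member_genes": sorted(branch)},
        planted_trend_groups={
            g: group for group, members in trends.items() for g in members
        },
        generator_params={
            "seed": seed,
            "n_genes": n_genes,
            **dataclasses.asdict(spec),
            "timepoints": list(spec.timepoints),
        },
    )
    return study, de_records, truth


# ---------------------------------------------------------------------------
# qPCR table
# ---------------------------------------------------------------------------

def make_qpcr_table(
    seed: int,
    n_plants: int = 10,
    roots_per_plant: int = 4,
    psr_fraction: float = 0.5,
    noise_sd: float = 0.3,
    tech_reps: int = 4,
    delta_per_week: float = 0.8,
) -> tuple[QpcrTable, SyntheticTruth]:
    """Ct table for the dual-marker classifier with planted root types.

    Each root is sampled at a week in 1..4 (cycling); a PSR root's SR_UP3
    Ct drops by ``delta_per_week`` x week (more transcript, earlier
    amplification), a PFR root's FR_UP1 mirrors this.  The reference gene
    is constant.  Technical replicates get Normal(0, noise_sd) Ct noise.
    """
    if not 0.0 <= psr_fraction <= 1.0:
        raise ValueError("psr_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    base_ct = {MARKER_FR: 24.0, MARKER_SR: 24.0, REFERENCE_GENE: 20.0}
    efficiency = {MARKER_FR: 1.95, MARKER_SR: 1.95, REFERENCE_GENE: 2.0}
    n_roots = n_plants * roots_per_plant
    n_psr = int(round(psr_fraction * n_roots))
    rows = []
    truth = SyntheticTruth(generator_params={
        "seed": seed, "n_plants": n_plants,
        "roots_per_plant": roots_per_plant, "psr_fraction": psr_fraction,
        "noise_sd": noise_sd, "tech_reps": tech_reps,
        "delta_per_week": delta_per_week,
    })
    idx = 0
    for p in range(1, n_plants + 1):
        plant = f"plant{p:02d}"
        for r in range(1, roots_per_plant + 1):
            root = f"root{r}"
            root_type = "PSR" if idx < n_psr else "PFR"
            week = (idx % 4) + 1
            truth.planted_root_types[(plant, root)] = root_type
            ct = dict(base_ct)
            if root_type == "PSR":
                ct[MARKER_SR] -= delta_per_week * week
            else:
                ct[MARKER_FR] -= delta_per_week * week
            for gene in (MARKER_FR, MARKER_SR, REFERENCE_GENE):
                for rep in range(1, tech_reps + 1):
                    noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                    rows.append({
                        "plant_id": plant, "root_id": root, "gene": gene,
                        "tech_rep": rep, "ct": ct[gene] + noise,
                        "efficiency": efficiency[gene],
                    })
            idx += 1
    return QpcrTable(pd.DataFrame(rows)), truth


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    ontology: OntologyGraph
    annotations: AnnotationSet
    study: ExpressionStudy
    de_records: list[DERecord]
    qpcr: QpcrTable
    truth: SyntheticTruth


def simulate_study(
    seed: int,
    n_genes: int = 500,
    n_terms: int = 100,
    branching: int = 3,
    truth_spec: TruthSpec | None = None,
    qpcr_kwargs: dict | None = None,
) -> SyntheticBundle:
    """The 'paperlike' preset: ontology + annotations + expression + qPCR.

    Sub-seeds for each component are derived deterministically from
    ``seed`` so the whole bundle is reproducible from one integer.
    """
    spec = truth_spec or TruthSpec()
    ss = np.random.SeedSequence(seed)
    s_onto, s_ann, s_expr, s_qpcr = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    )
    graph = make_ontology(s_onto, n_terms=n_terms, branching=branching)
    study, de_records, truth = make_expression_study(
        s_expr, n_genes=n_genes, truth_spec=spec
    )
    branch_genes = list(truth.planted_cluster_branch["member_genes"])
    ann, branch_head = make_annotations(
        s_ann, graph, study.genes, branch_genes
    )
    truth.planted_cluster_branch["head_term"] = branch_head
    qpcr, qpcr_truth = make_qpcr_table(s_qpcr, **(qpcr_kwargs or {}))
    truth.planted_root_types = qpcr_truth.planted_root_types
    truth.generator_params["qpcr"] = qpcr_truth.generator_params
    truth.generator_params["n_terms"] = n_terms
    truth.generator_params["branching"] = branching
    truth.generator_params["top_seed"] = seed
    return SyntheticBundle(
        ontology=graph, annotations=ann, study=study,
        de_records=de_records, qpcr=qpcr, truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    """Write every input file the analysis modules read, plus truth.json."""
    from .expression import write_de_records

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "obo": outdir / "ontology.obo",
        "annotations": outdir / "annotations.tsv",
        "fpkm": outdir / "fpkm.tsv",
        "samples": outdir / "samples.tsv",
        "de": outdir / "de.tsv",
        "qpcr": outdir / "qpcr.tsv",
        "truth": outdir / "truth.json",
    }
    with open(paths["obo"], "wt") as fh:
        write_obo(bundle.ontology, fh)
    with open(paths["annotations"], "wt") as fh:
        write_annotations(bundle.annotations, fh)
    bundle.study.to_tsv(paths["fpkm"], paths["samples"])
    with open(paths["de"], "wt") as fh:
        write_de_records(bundle.de_records, fh)
    with open(paths["qpcr"], "wt") as fh:
        bundle.qpcr.to_tsv(fh)
    paths["truth"].write_text(bundle.truth.to_json() + "\n")
    return paths
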