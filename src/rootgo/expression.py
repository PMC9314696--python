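"""FPKM expression matrices, differential-expression records and the two
gene-set selections used for storage-root transcriptome analysis.

Tissues follow the cassava storage-root study design: sink/source leaves
(``SIL``/``SOL``) and the two root classes — potential fibrous / fibrous
roots (``PFR_FR``) and potential storage / storage roots (``PSR_SR``) —
sampled at time points ``TP1``..``TP7`` in biological replicates.

Two gene sets are defined on top of a study:

* the DE set at a time point: genes with p <= alpha (default 0.05) between
  the two root classes; and
* the root-specific set: genes silent in both leaf tissues (FPKM <= 3 in
  every SIL and SOL sample), expressed in at least one root sample
  (FPKM >= 5), and fold-changed at least 2x between root classes at some
  time point at p <= 0.15.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

TISSUES = ("SIL", "SOL", "PFR_FR", "PSR_SR")
LEAF_TISSUES = ("SIL", "SOL")
ROOT_TISSUES = ("PFR_FR", "PSR_SR")
TIMEPOINTS = ("TP1", "TP3", "TP5", "TP7")

# Selection thresholds (FPKM units / log2 units / p-value bounds).
LEAF_MAX_FPKM = 3.0
ROOT_MIN_FPKM = 5.0
MIN_ABS_LOG2FC = 1.0
ALPHA_ROOT_SPECIFIC = 0.15
ALPHA_DE = 0.05

TREND_GROUPS = ("FR_UP", "SR_D", "SR_EQ", "SR_UP")
SIGNED_R2_THRESHOLD = 0.5


class StudyFormatError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class DERecord:
    """One differential-expression record: PSR_SR relative to PFR_FR."""

    gene: str
    tp: str
    log2fc: float
    p: float

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p outside [0,1]: {self.p}")


@dataclass(frozen=True)
class TrendCall:
    gene: str
    group: str
    signed_r2_psr: float
    signed_r2_pfr: float


class ExpressionStudy:
    """An FPKM matrix (genes x samples) plus per-sample metadata.

    ``samples`` must carry columns ``sample_id``, ``tissue``, ``tp`` and
    ``replicate``; the matrix columns must match ``sample_id`` exactly.
    """

    def __init__(self, fpkm: pd.DataFrame, samples: pd.DataFrame):
        samples = samples.copy()
        required = {"sample_id", "tissue", "tp", "replicate"}
        missing = required - set(samples.columns)
        if missing:
            raise StudyFormatError(f"sample sheet lacks columns: {sorted(missing)}")
        if list(fpkm.columns) != list(samples["sample_id"]):
            raise StudyFormatError("FPKM columns do not match sample sheet rows")
        if fpkm.index.duplicated().any():
            dup = fpkm.index[fpkm.index.duplicated()][0]
            raise StudyFormatError(f"duplicated gene id: {dup}")
        bad = set(samples["tissue"]) - set(TISSUES)
        if bad:
            raise StudyFormatError(f"unknown tissue label(s): {sorted(bad)}")
        values = fpkm.to_numpy(dtype=float)
        if (values < 0).any():
            raise StudyFormatError("negative FPKM value encountered")
        self.fpkm = fpkm.astype(float)
        self.samples = samples.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def timepoints(self) -> list[str]:
        present = set(self.samples["tp"])
        return [tp for tp in TIMEPOINTS if tp in present]

    def sample_ids(self, tissue: str | Iterable[str] | None = None,
                   tp: str | None = None) -> list[str]:
        sel = self.samples
        if tissue is not None:
            tissues = [tissue] if isinstance(tissue, str) else list(tissue)
            sel = sel[sel["tissue"].isin(tissues)]
        if tp is not None:
            sel = sel[sel["tp"] == tp]
        return list(sel["sample_id"])

    def values(self, tissue=None, tp=None) -> pd.DataFrame:
        return self.fpkm[self.sample_ids(tissue, tp)]

    def mean_profile(self, gene: str, tissue: str) -> pd.Series:
        """Arithmetic replicate mean per time point, ordered by time."""
        out = {}
        for tp in self.timepoints:
            cols = self.sample_ids(tissue, tp)
            if cols:
                out[tp] = float(self.fpkm.loc[gene, cols].mean())
        return pd.Series(out)

    def to_tsv(self, matrix_path, samples_path) -> None:
        self.fpkm.to_csv(matrix_path, sep="\t", index_label="gene_id",
                         float_format="%.6g")
        self.samples.to_csv(samples_path, sep="\t", index=False)


def load_expression(matrix: IO[str] | str, metadata: IO[str] | str) -> ExpressionStudy:
    """Load a tab-separated FPKM matrix (genes as rows, header = sample ids)
    and its sample sheet (`sample_id, tissue, tp, replicate`)."""
    fpkm = pd.read_csv(matrix, sep="\t", index_col=0)
    samples = pd.read_csv(metadata, sep="\t", dtype={"replicate": int})
    return ExpressionStudy(fpkm, samples)


def load_de_records(stream: IO[str] | str) -> list[DERecord]:
    """Read tab-separated DE records: `gene_id, tp, log2fc, p`."""
    df = pd.read_csv(stream, sep="\t")
    required = {"gene_id", "tp", "log2fc", "p"}
    missing = required - set(df.columns)
    if missing:
        raise StudyFormatError(f"DE table lacks columns: {sorted(missing)}")
    return [
        DERecord(gene=row.gene_id, tp=row.tp, log2fc=float(row.log2fc),
                 p=float(row.p))
        for row in df.itertuples()
    ]


def write_de_records(records: Sequence[DERecord], stream) -> None:
    df = pd.DataFrame(
        [(r.gene, r.tp, r.log2fc, r.p) for r in records],
        columns=["gene_id", "tp", "log2fc", "p"],
    )
    df.to_csv(stream, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# gene-set selections
# ---------------------------------------------------------------------------

def select_de(de: Sequence[DERecord], tp: str, alpha: float = ALPHA_DE) -> set[str]:
    """Genes differentially expressed between root classes at ``tp``:
    ``p <= alpha``, boundary included."""
    return {r.gene for r in de if r.tp == tp and r.p <= alpha}


def select_root_specific(
    study: ExpressionStudy,
    de: Sequence[DERecord],
    leaf_max_fpkm: float = LEAF_MAX_FPKM,
    root_min_fpkm: float = ROOT_MIN_FPKM,
    min_abs_log2fc: float = MIN_ABS_LOG2FC,
    alpha: float = ALPHA_ROOT_SPECIFIC,
) -> set[str]:
    """Root-specific genes.

    A gene passes iff (a) FPKM <= ``leaf_max_fpkm`` in *every* leaf sample,
    (b) FPKM >= ``root_min_fpkm`` in at least one root sample, and (c) at
    some time point |log2fc| >= ``min_abs_log2fc`` with p <= ``alpha``.
    """
    for tissue in TISSUES:
        if not study.sample_ids(tissue):
            raise StudyFormatError(f"study lacks samples for tissue {tissue}")
    leaf = study.values(LEAF_TISSUES)
    root = study.values(ROOT_TISSUES)
    cond_a = (leaf.le(leaf_max_fpkm)).all(axis=1)
    cond_b = (root.ge(root_min_fpkm)).any(axis=1)
    expressed = set(cond_a.index[cond_a & cond_b])
    passing = {
        r.gene
        for r in de
        if abs(r.log2fc) >= min_abs_log2fc and r.p <= alpha
    }
    return expressed & passing


# ---------------------------------------------------------------------------
# trend classification
# ---------------------------------------------------------------------------

def classify_trend(study: ExpressionStudy, gene: str,
                   threshold: float = SIGNED_R2_THRESHOLD) -> TrendCall:
    """Assign a gene to one of the four root expression-trend groups.

    Replicates are averaged per (tissue, time point); the signed coefficient
    of determination sign(slope) x R^2 of mean FPKM against the time-point
    index is computed separately for each root class.  The rule:

    * ``FR_UP`` — PFR_FR mean exceeds PSR_SR mean at every time point;
    * else ``SR_UP`` if signed R^2 (PSR_SR) > ``threshold``;
    * else ``SR_D`` if signed R^2 (PSR_SR) < -``threshold``;
    * else ``SR_EQ``.
    """
    from .marker_stats import trend_regression

    psr = study.mean_profile(gene, "PSR_SR")
    pfr = study.mean_profile(gene, "PFR_FR")
    if len(psr) < 3 or len(pfr) < 3:
        raise InsufficientDataError(
            f"{gene}: trend classification needs >=3 time points"
        )
    idx = np.arange(len(psr), dtype=float)
    r2_psr, _ = trend_regression(psr.to_numpy(), idx)
    r2_pfr, _ = trend_regression(pfr.to_numpy(), idx)
    if (pfr.to_numpy() > psr.to_numpy()).all():
        group = "FR_UP"
    elif r2_psr > threshold:
        group = "SR_UP"
    elif r2_psr < -threshold:
        group = "SR_D"
    else:
        group = "SR_EQ"
    return TrendCall(gene=gene, group=group,
                     signed_r2_psr=r2_psr, signed_r2_pfr=r2_pfr)


# ---------------------------------------------------------------------------
# Welch stand-in for upstream differential expression
# ---------------------------------------------------------------------------

def welch_de_standin(study: ExpressionStudy, tp: str,
                     pseudocount: float = 1.0) -> list[DERecord]:
    """Per-gene fold change and Welch p between root classes at one tp.

    Fold change is ``log2((mean PSR_SR + c) / (mean PFR_FR + c))`` on the
    FPKM scale with pseudocount ``c``; the Welch two-sample test runs on
    ``log2(FPKM + c)`` replicate values.  When both groups have zero
    variance the test is degenerate: p is 1 for equal means and 0 otherwise.
    """
    psr_cols = study.sample_ids("PSR_SR", tp)
    pfr_cols = study.sample_ids("PFR_FR", tp)
    if len(psr_cols) < 2 or len(pfr_cols) < 2:
        raise InsufficientDataError(
            f"{tp}: need >=2 replicates per root tissue, "
            f"got {len(psr_cols)} and {len(pfr_cols)}"
        )
    psr = study.fpkm[psr_cols].to_numpy(dtype=float)
    pfr = study.fpkm[pfr_cols].to_numpy(dtype=float)
    log2fc = np.log2(psr.mean(axis=1) + pseudocount) - np.log2(
        pfr.mean(axis=1) + pseudocount
    )
    a = np.log2(psr + pseudocount)
    b = np.log2(pfr + pseudocount)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-identical replicates (e.g. the zero-noise limit) trip scipy's
        # precision-loss warning; the degenerate case is handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
    return [
        DERecord(gene=g, tp=tp, log2fc=float(fc), p=float(pv))
        for g, fc, pv in zip(study.genes, log2fc, p)
    ]
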