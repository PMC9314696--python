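"""qPCR relative quantification, the dual-marker root-type classifier,
trend regression and group-comparison statistics.

Relative expression follows the efficiency-corrected ratio model

    ratio = E_target^(Ct_target,cal - Ct_target,sample)
            / E_ref^(Ct_ref,cal - Ct_ref,sample)

which reduces to the classical 2^-ddCt when both amplification efficiencies
are 2 (perfect doubling per cycle).  Technical replicates are averaged on
the Ct scale before any ratio is formed.

The root-type caller compares two marker genes of opposite behaviour —
``FR_UP1`` (up in fibrous-type roots) and ``SR_UP3`` (up in storage-type
roots) — via ``log2(relexp(FR_UP1) / relexp(SR_UP3))`` per root: positive
ratios call a potential fibrous root (PFR), negative a potential storage
root (PSR).  The reference gene cancels from this ratio; the calibrator
shifts every root by the same constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

REFERENCE_GENE = "actin"
MARKER_FR = "FR_UP1"
MARKER_SR = "SR_UP3"

QPCR_COLUMNS = ("plant_id", "root_id", "gene", "tech_rep", "ct", "efficiency")


class QpcrFormatError(ValueError):
    pass


class IncompleteDataError(ValueError):
    pass


def _mean_ct(ct) -> float:
    """Technical replicates are averaged on the Ct scale (arithmetic mean)."""
    arr = np.atleast_1d(np.asarray(ct, dtype=float))
    return float(arr.mean())


def relative_expression(
    ct_target_sample,
    ct_ref_sample,
    ct_target_calibrator,
    ct_ref_calibrator,
    e_target: float = 2.0,
    e_ref: float = 2.0,
) -> float:
    """Efficiency-corrected relative expression of a target gene versus a
    reference gene, scaled to a calibrator sample.

    Ct arguments may be scalars or sequences of technical replicates.
    Efficiencies are per-cycle amplification factors in [1, 2].
    """
    for e in (e_target, e_ref):
        if not 1.0 <= e <= 2.0:
            raise ValueError(f"amplification efficiency outside [1, 2]: {e}")
    dct_target = _mean_ct(ct_target_calibrator) - _mean_ct(ct_target_sample)
    dct_ref = _mean_ct(ct_ref_calibrator) - _mean_ct(ct_ref_sample)
    return float(e_target**dct_target / e_ref**dct_ref)


@dataclass(frozen=True)
class RootTypeCall:
    plant_id: str
    root_id: str
    log2_ratio: float
    call: str  # PFR | PSR | ambiguous


class QpcrTable:
    """Ct measurements: one row per technical replicate of one gene in one
    root of one plant, with the amplicon's efficiency."""

    def __init__(self, df: pd.DataFrame):
        missing = set(QPCR_COLUMNS) - set(df.columns)
        if missing:
            raise QpcrFormatError(f"Ct table lacks columns: {sorted(missing)}")
        df = df.copy()
        df["ct"] = df["ct"].astype(float)
        df["efficiency"] = df["efficiency"].astype(float)
        if (df["ct"] <= 0).any():
            raise QpcrFormatError("nonpositive Ct value")
        if ((df["efficiency"] < 1) | (df["efficiency"] > 2)).any():
            raise QpcrFormatError("efficiency outside [1, 2]")
        self.df = df

    @classmethod
    def read_tsv(cls, stream: IO[str] | str) -> "QpcrTable":
        return cls(pd.read_csv(stream, sep="\t"))

    def to_tsv(self, stream) -> None:
        self.df.to_csv(stream, sep="\t", index=False, float_format="%.6g")

    @property
    def roots(self) -> list[tuple[str, str]]:
        pairs = self.df[["plant_id", "root_id"]].drop_duplicates()
        return sorted(map(tuple, pairs.itertuples(index=False)))

    def genes(self) -> list[str]:
        return sorted(self.df["gene"].unique())

    def mean_ct(self, plant_id: str, root_id: str, gene: str) -> float:
        sel = self.df[
            (self.df["plant_id"] == plant_id)
            & (self.df["root_id"] == root_id)
            & (self.df["gene"] == gene)
        ]
        if sel.empty:
            raise IncompleteDataError(
                f"no Ct rows for gene {gene!r} in root {plant_id}/{root_id}"
            )
        return _mean_ct(sel["ct"].to_numpy())

    def efficiency(self, gene: str) -> float:
        sel = self.df[self.df["gene"] == gene]
        if sel.empty:
            raise IncompleteDataError(f"gene {gene!r} absent from Ct table")
        return float(sel["efficiency"].iloc[0])

    def calibrator_ct(self, gene: str,
                      roots: Iterable[tuple[str, str]] | None = None) -> float:
        """Mean of per-root mean Cts for ``gene`` over ``roots`` (default:
        every root carrying the gene)."""
        roots = list(roots) if roots is not None else [
            r for r in self.roots
            if not self.df[
                (self.df["plant_id"] == r[0])
                & (self.df["root_id"] == r[1])
                & (self.df["gene"] == gene)
            ].empty
        ]
        cts = [self.mean_ct(p, r, gene) for p, r in roots]
        if not cts:
            raise IncompleteDataError(f"no roots measured for gene {gene!r}")
        return float(np.mean(cts))


def root_type_call(
    table: QpcrTable,
    plant_id: str,
    root_id: str,
    marker_fr: str = MARKER_FR,
    marker_sr: str = MARKER_SR,
    reference: str = REFERENCE_GENE,
    tau: float = 0.0,
    calibrator: Mapping[str, float] | None = None,
) -> RootTypeCall:
    """Call one root's type from the dual-marker log ratio.

    ``calibrator`` maps gene -> calibrator Ct; by default the per-gene mean
    Ct over all roots in the table.  ``tau`` is the ambiguity half-width:
    |log2 ratio| <= tau yields ``ambiguous``.
    """
    if calibrator is None:
        calibrator = {
            g: table.calibrator_ct(g) for g in (marker_fr, marker_sr, reference)
        }
    rel = {}
    for marker in (marker_fr, marker_sr):
        rel[marker] = relative_expression(
            table.mean_ct(plant_id, root_id, marker),
            table.mean_ct(plant_id, root_id, reference),
            calibrator[marker],
            calibrator[reference],
            table.efficiency(marker),
            table.efficiency(reference),
        )
    log2_ratio = math.log2(rel[marker_fr] / rel[marker_sr])
    if log2_ratio > tau:
        call = "PFR"
    elif log2_ratio < -tau:
        call = "PSR"
    else:
        call = "ambiguous"
    return RootTypeCall(plant_id=plant_id, root_id=root_id,
                        log2_ratio=log2_ratio, call=call)


def call_all_roots(
    table: QpcrTable,
    marker_fr: str = MARKER_FR,
    marker_sr: str = MARKER_SR,
    reference: str = REFERENCE_GENE,
    tau: float = 0.0,
    calibrator: str | Mapping[str, float] = "global_mean",
) -> list[RootTypeCall]:
    """Root-type calls for every (plant, root) in the table.

    ``calibrator`` is either an explicit gene -> Ct mapping, ``"global_mean"``
    (per-gene mean Ct over all roots) or ``"pfr_mean"`` (two passes: global
    mean first, then the mean over roots provisionally called PFR)."""
    genes = (marker_fr, marker_sr, reference)
    cal: Mapping[str, float]
    if isinstance(calibrator, str):
        cal = {g: table.calibrator_ct(g) for g in genes}
        if calibrator == "pfr_mean":
            provisional = [
                root_type_call(table, p, r, marker_fr, marker_sr, reference,
                               tau, cal)
                for p, r in table.roots
            ]
            pfr_roots = [(c.plant_id, c.root_id) for c in provisional
                         if c.call == "PFR"]
            if pfr_roots:
                cal = {g: table.calibrator_ct(g, pfr_roots) for g in genes}
        elif calibrator != "global_mean":
            raise ValueError(f"unknown calibrator mode {calibrator!r}")
    else:
        cal = calibrator
    return [
        root_type_call(table, p, r, marker_fr, marker_sr, reference, tau, cal)
        for p, r in table.roots
    ]


def write_calls(calls: Sequence[RootTypeCall], stream) -> None:
    print("plant_id\troot_id\tlog2_ratio\tcall", file=stream)
    for c in calls:
        print(f"{c.plant_id}\t{c.root_id}\t{c.log2_ratio:.6g}\t{c.call}",
              file=stream)


# ---------------------------------------------------------------------------
# regression and group comparison
# ---------------------------------------------------------------------------

def trend_regression(values, timepoints) -> tuple[float, float]:
    """Signed coefficient of determination of value against time.

    Ordinary least squares of ``values`` on ``timepoints``; returns
    ``(sign(slope) * R^2, p)`` with p from the regression F test (identical
    to the slope t test for a single regressor).  A constant series has
    signed R^2 of exactly 0 (p = 1); constant *time* is degenerate.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(timepoints, dtype=float)
    if y.shape != x.shape or y.size < 3:
        raise ValueError("trend_regression needs >=3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("all time values equal: regression is degenerate")
    if np.ptp(y) == 0:
        return 0.0, 1.0
    res = stats.linregress(x, y)
    signed_r2 = float(np.sign(res.slope) * res.rvalue**2)
    return signed_r2, float(res.pvalue)


@dataclass(frozen=True)
class GroupCompareResult:
    method: str
    statistic: float
    p: float
    pairwise: pd.DataFrame | None = None


def group_compare(groups: Mapping, method: str = "welch") -> GroupCompareResult:
    """Compare labelled value groups.

    ``student``/``welch`` require exactly two groups (pooled- and
    unpooled-variance t tests).  ``tukey`` runs Tukey's HSD over all
    pairwise contrasts and reports the largest |q| with its p alongside the
    full pairwise table.  ``anova2`` expects labels that are (factor_a,
    factor_b) tuples and reports the factor_a main-effect F from a two-way
    ANOVA with interaction.
    """
    items = list(groups.items())
    if len(items) < 2:
        raise ValueError("need at least two groups")
    for label, vals in items:
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")
    if method in ("student", "welch"):
        if len(items) != 2:
            raise ValueError(f"{method} test requires exactly two groups")
        (l1, a), (l2, b) = items
        res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                              equal_var=(method == "student"))
        return GroupCompareResult(method, float(res.statistic),
                                  float(res.pvalue))
    if method == "tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate([np.asarray(v, float) for _, v in items])
        labels = np.concatenate([[str(l)] * len(v) for l, v in items])
        hsd = pairwise_tukeyhsd(values, labels)
        table = pd.DataFrame(
            hsd.summary().data[1:], columns=hsd.summary().data[0]
        )
        # std_pairs is sqrt(MSE/n), so meandiff/std_pairs is the studentized
        # range q; the most extreme contrast is the headline statistic
        q = np.abs(np.asarray(hsd.meandiffs) / np.asarray(hsd.std_pairs))
        i = int(np.argmax(q))
        return GroupCompareResult("tukey", float(q[i]),
                                  float(np.asarray(hsd.pvalues)[i]),
                                  pairwise=table)
    if method == "anova2":
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rows = []
        for label, vals in items:
            if not (isinstance(label, tuple) and len(label) == 2):
                raise ValueError("anova2 labels must be (factor_a, factor_b)")
            for v in vals:
                rows.append({"a": str(label[0]), "b": str(label[1]),
                             "y": float(v)})
        df = pd.DataFrame(rows)
        interaction = (
            df.groupby(["a", "b"]).size().min() >= 2
            and df["a"].nunique() > 1 and df["b"].nunique() > 1
        )
        formula = "y ~ C(a) * C(b)" if interaction else "y ~ C(a) + C(b)"
        model = ols(formula, data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        return GroupCompareResult(
            "anova2",
            float(table.loc["C(a)", "F"]),
            float(table.loc["C(a)", "PR(>F)"]),
            pairwise=table,
        )
    raise ValueError(f"unknown method {method!r}")
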