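"""Expression loading, the two gene-set selections, trend classification
and the Welch stand-in."""

import io

import numpy as np
import pandas as pd
import pytest

from rootgo.expression import (
    DERecord,
    InsufficientDataError,
    StudyFormatError,
    classify_trend,
    load_expression,
    select_de,
    select_root_specific,
    welch_de_standin,
)
from rootgo.synthetic_data import TruthSpec, make_expression_study

from conftest import make_study


def _samples_all_tissues(tps=("TP1", "TP3", "TP7"), reps=1):
    rows = []
    for tissue in ("SIL", "SOL", "PFR_FR", "PSR_SR"):
        for tp in tps:
            for r in range(1, reps + 1):
                rows.append((f"{tissue}_{tp}_r{r}", tissue, tp, r))
    return rows


class TestLoadExpression:
    def test_round_trip_toy_matrix(self):
        matrix = "gene_id\ts1\ts2\ns1g\t1.0\t2.0\ns2g\t0.0\t5.5\n"
        sheet = ("sample_id\ttissue\ttp\treplicate\n"
                 "s1\tSIL\tTP1\t1\ns2\tPSR_SR\tTP1\t1\n")
        study = load_expression(io.StringIO(matrix), io.StringIO(sheet))
        assert study.genes == ["s1g", "s2g"]
        assert len(study.samples) == 2

    def test_duplicate_gene_id_rejected(self):
        matrix = "gene_id\ts1\ng\t1.0\ng\t2.0\n"
        sheet = "sample_id\ttissue\ttp\treplicate\ns1\tSIL\tTP1\t1\n"
        with pytest.raises(StudyFormatError, match="duplicated"):
            load_expression(io.StringIO(matrix), io.StringIO(sheet))

    def test_missing_sheet_column_rejected(self):
        matrix = "gene_id\ts1\ng\t1.0\n"
        sheet = "sample_id\ttissue\ttp\ns1\tSIL\tTP1\n"
        with pytest.raises(StudyFormatError, match="replicate"):
            load_expression(io.StringIO(matrix), io.StringIO(sheet))

    def test_negative_fpkm_rejected(self):
        matrix = "gene_id\ts1\ng\t-1.0\n"
        sheet = "sample_id\ttissue\ttp\treplicate\ns1\tSIL\tTP1\t1\n"
        with pytest.raises(StudyFormatError, match="negative"):
            load_expression(io.StringIO(matrix), io.StringIO(sheet))

    def test_column_sheet_mismatch_rejected(self):
        matrix = "gene_id\tsX\ng\t1.0\n"
        sheet = "sample_id\ttissue\ttp\treplicate\ns1\tSIL\tTP1\t1\n"
        with pytest.raises(StudyFormatError, match="match"):
            load_expression(io.StringIO(matrix), io.StringIO(sheet))


class TestSelectDe:
    def test_boundary_p_included(self):
        de = [DERecord("a", "TP1", 1.0, 0.04),
              DERecord("b", "TP1", 1.0, 0.05),
              DERecord("c", "TP1", 1.0, 0.051)]
        assert select_de(de, "TP1") == {"a", "b"}

    def test_alpha_one_selects_everything(self):
        de = [DERecord(f"g{i}", "TP1", 0.0, p)
              for i, p in enumerate([0.0, 0.5, 1.0])]
        assert select_de(de, "TP1", alpha=1.0) == {"g0", "g1", "g2"}

    def test_alpha_zero_only_p_zero(self):
        de = [DERecord("a", "TP1", 0.0, 0.0), DERecord("b", "TP1", 0.0, 1e-9)]
        assert select_de(de, "TP1", alpha=0.0) == {"a"}

    def test_nested_in_alpha(self):
        rng = np.random.default_rng(0)
        de = [DERecord(f"g{i}", "TP1", 0.0, float(p))
              for i, p in enumerate(rng.random(50))]
        for a1, a2 in [(0.01, 0.05), (0.05, 0.2), (0.2, 1.0)]:
            assert select_de(de, "TP1", a1) <= select_de(de, "TP1", a2)

    def test_recovers_planted_de_genes_at_tiny_alpha(self):
        study, de, truth = make_expression_study(
            3, n_genes=200,
            truth_spec=TruthSpec(noise_sd=0.05, n_root_specific=12,
                                 n_branch=10, trend_per_group=0),
        )
        selected = select_de(de, "TP1", alpha=1e-3)
        # at TP1 only the root-specific contrast is planted
        assert truth.planted_root_specific <= selected


class TestSelectRootSpecific:
    samples = [
        ("SIL_TP1_r1", "SIL", "TP1", 1), ("SOL_TP1_r1", "SOL", "TP1", 1),
        ("PFR_FR_TP1_r1", "PFR_FR", "TP1", 1),
        ("PSR_SR_TP1_r1", "PSR_SR", "TP1", 1),
    ]

    def _study(self, rows):
        return make_study(rows, self.samples)

    def test_leaf_expression_above_threshold_excludes(self):
        study = self._study({"g": [1.0, 4.0, 100.0, 100.0]})
        de = [DERecord("g", "TP1", 3.0, 0.01)]
        assert select_root_specific(study, de) == set()

    def test_leaf_boundary_3_included_301_excluded(self):
        study = self._study({"in": [3.0, 0.0, 10.0, 100.0],
                             "out": [3.01, 0.0, 10.0, 100.0]})
        de = [DERecord("in", "TP1", 3.0, 0.01),
              DERecord("out", "TP1", 3.0, 0.01)]
        assert select_root_specific(study, de) == {"in"}

    def test_root_boundary_5_included_499_excluded(self):
        study = self._study({"in": [0.0, 0.0, 1.0, 5.0],
                             "out": [0.0, 0.0, 1.0, 4.99]})
        de = [DERecord("in", "TP1", 3.0, 0.01),
              DERecord("out", "TP1", 3.0, 0.01)]
        assert select_root_specific(study, de) == {"in"}

    def test_p_boundary_015_included_0151_excluded(self):
        study = self._study({"a": [0.0, 0.0, 1.0, 50.0],
                             "b": [0.0, 0.0, 1.0, 50.0]})
        de = [DERecord("a", "TP1", 3.0, 0.15),
              DERecord("b", "TP1", 3.0, 0.151)]
        assert select_root_specific(study, de) == {"a"}

    def test_fold_change_boundary_is_log2_one(self):
        study = self._study({"a": [0.0, 0.0, 1.0, 50.0],
                             "b": [0.0, 0.0, 1.0, 50.0]})
        de = [DERecord("a", "TP1", 1.0, 0.01),
              DERecord("b", "TP1", 0.99, 0.01)]
        assert select_root_specific(study, de) == {"a"}

    def test_missing_tissue_is_input_error(self):
        study = make_study(
            {"g": [1.0, 1.0]},
            [("s1", "SIL", "TP1", 1), ("s2", "PSR_SR", "TP1", 1)],
        )
        with pytest.raises(StudyFormatError, match="SOL"):
            select_root_specific(study, [DERecord("g", "TP1", 2.0, 0.01)])

    def test_zero_noise_recovery_is_exact(self, zero_noise_bundle):
        b = zero_noise_bundle
        got = select_root_specific(b.study, b.de_records)
        assert got == b.truth.planted_root_specific

    def test_adding_leaf_sample_only_shrinks(self, zero_noise_bundle):
        """Monotonicity: extra leaf evidence can only remove genes."""
        b = zero_noise_bundle
        base = select_root_specific(b.study, b.de_records)
        fpkm = b.study.fpkm.copy()
        fpkm["SIL_extra"] = 10.0  # loud leaf sample
        samples = pd.concat(
            [b.study.samples,
             pd.DataFrame([("SIL_extra", "SIL", "TP1", 9)],
                          columns=b.study.samples.columns)],
            ignore_index=True,
        )
        bigger = type(b.study)(fpkm, samples)
        assert select_root_specific(bigger, b.de_records) <= base


class TestClassifyTrend:
    def _study(self, psr, pfr, tps=("TP1", "TP3", "TP7")):
        rows = {"g": list(psr) + list(pfr) + [1.0] * 2 * len(tps)}
        samples = (
            [(f"PSR_SR_{tp}_r1", "PSR_SR", tp, 1) for tp in tps]
            + [(f"PFR_FR_{tp}_r1", "PFR_FR", tp, 1) for tp in tps]
            + [(f"SIL_{tp}_r1", "SIL", tp, 1) for tp in tps]
            + [(f"SOL_{tp}_r1", "SOL", tp, 1) for tp in tps]
        )
        return make_study(rows, samples)

    def test_linear_increase_is_sr_up(self):
        call = classify_trend(self._study([2, 5, 8], [1, 1, 1]), "g")
        assert call.group == "SR_UP"
        assert call.signed_r2_psr == pytest.approx(1.0)

    def test_near_linear_increase_is_sr_up(self):
        call = classify_trend(self._study([2, 5, 9], [1, 1, 1]), "g")
        assert call.group == "SR_UP"
        assert call.signed_r2_psr > 0.99

    def test_linear_decrease_is_sr_d(self):
        call = classify_trend(self._study([8, 5, 2], [1, 1, 1]), "g")
        assert call.group == "SR_D"
        assert call.signed_r2_psr == pytest.approx(-1.0)

    def test_flat_profile_is_sr_eq(self):
        call = classify_trend(self._study([4, 4, 4], [1, 1, 1]), "g")
        assert call.group == "SR_EQ"
        assert call.signed_r2_psr == 0.0

    def test_fr_dominant_everywhere_is_fr_up(self):
        call = classify_trend(self._study([2, 5, 8], [10, 10, 10]), "g")
        assert call.group == "FR_UP"

    def test_scaling_invariance(self):
        base = self._study([2, 5, 9], [1, 1, 1])
        scaled = self._study([20, 50, 90], [10, 10, 10])
        assert classify_trend(base, "g").group == classify_trend(
            scaled, "g"
        ).group

    def test_two_timepoints_insufficient(self):
        study = self._study([2, 5], [1, 1], tps=("TP1", "TP3"))
        with pytest.raises(InsufficientDataError):
            classify_trend(study, "g")

    def test_zero_noise_planted_groups_recovered(self, zero_noise_bundle):
        b = zero_noise_bundle
        for gene, group in b.truth.planted_trend_groups.items():
            assert classify_trend(b.study, gene).group == group


class TestWelchStandin:
    def _study(self, psr, pfr):
        rows = {"g": list(psr) + list(pfr)}
        samples = (
            [(f"PSR_SR_TP1_r{i}", "PSR_SR", "TP1", i)
             for i in range(1, len(psr) + 1)]
            + [(f"PFR_FR_TP1_r{i}", "PFR_FR", "TP1", i)
               for i in range(1, len(pfr) + 1)]
        )
        return make_study(rows, samples)

    def test_identical_groups_null(self):
        rec = welch_de_standin(self._study([4, 5, 6], [4, 5, 6]), "TP1")[0]
        assert rec.log2fc == pytest.approx(0.0)
        assert rec.p == pytest.approx(1.0)

    def test_pseudocount_fold_change_closed_form(self):
        rec = welch_de_standin(self._study([8, 8, 8], [1, 1, 1]), "TP1")[0]
        assert rec.log2fc == pytest.approx(np.log2(9 / 2))

    def test_zero_variance_unequal_means_p_zero(self):
        rec = welch_de_standin(self._study([8, 8, 8], [1, 1, 1]), "TP1")[0]
        assert rec.p == 0.0

    def test_single_replicate_rejected(self):
        with pytest.raises(InsufficientDataError):
            welch_de_standin(self._study([8], [1]), "TP1")

    def test_type_one_error_calibrated(self):
        """Null FPKM data: fraction of p <= 0.05 is ~5% (3 vs 3 replicates)."""
        rng = np.random.default_rng(42)
        n = 20000  # null genes, equivalent to many small simulations
        mu = rng.normal(3.0, 1.2, size=n)[:, None]
        vals = 2.0 ** (mu + rng.normal(0.0, 0.25, size=(n, 6)))
        rows = {f"g{i}": vals[i].tolist() for i in range(n)}
        samples = (
            [(f"PSR_SR_TP1_r{i}", "PSR_SR", "TP1", i) for i in (1, 2, 3)]
            + [(f"PFR_FR_TP1_r{i}", "PFR_FR", "TP1", i) for i in (1, 2, 3)]
        )
        study = make_study(rows, samples)
        recs = welch_de_standin(study, "TP1")
        rate = np.mean([r.p <= 0.05 for r in recs])
        assert rate == pytest.approx(0.05, abs=0.02)
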