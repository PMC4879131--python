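"""Two-stage classifier: printed-row patterns, boundaries, oracle equivalence."""

import math

import numpy as np
import pandas as pd
import pytest

from tcexpr import (
    ClassifierParams,
    SimulationConfig,
    apply_floor,
    classify_all,
    classify_enhanced,
    classify_specific,
    compute_rpkm,
    fold_changes,
    gate_expressed,
    generate_counts,
)
from tcexpr.expression import DOWN, UP, sample_label
from tests.conftest import make_expression, tissue_profile


def straight_line_oracle(expr, params):
    """Independent per-transcript re-evaluation of the classification rules.

    Works scalar-by-scalar from the floored RPKM values and expression
    flags, with none of the vectorised machinery of the implementation.
    """
    categories = {}
    tps = list(params.timepoints_considered)
    for tid in expr.rpkm.index:
        fc = {}
        for tissue in expr.tissues:
            base = expr.rpkm.at[tid, sample_label(tissue, 0)]
            for tp in tps:
                val = expr.rpkm.at[tid, sample_label(tissue, tp)]
                fc[(tissue, tp, "up")] = val / base
                fc[(tissue, tp, "down")] = base / val
        ep_ok = bool(expr.expressed.at[tid, params.focal_tissue])
        sp_ok = bool(expr.expressed.at[tid, params.reference_tissue])
        passed_up = ep_ok and any(
            fc[(params.focal_tissue, tp, "up")] >= params.focal_fc_threshold for tp in tps
        )
        passed_down = ep_ok and any(
            fc[(params.focal_tissue, tp, "down")] >= params.focal_fc_threshold for tp in tps
        )
        eliminated = sp_ok and any(
            fc[(params.reference_tissue, tp, d)] >= params.reference_fc_ceiling
            for tp in tps
            for d in ("up", "down")
        )
        if passed_up and not eliminated:
            categories[tid] = "specific_up"
            continue
        if passed_down and not eliminated:
            categories[tid] = "specific_down"
            continue
        te = params.enhanced_timepoint
        f_up = fc[(params.focal_tissue, te, "up")] if ep_ok else 1.0
        r_up = fc[(params.reference_tissue, te, "up")] if sp_ok else 1.0
        if f_up - r_up >= params.enhanced_diff_threshold:
            categories[tid] = "enhanced_up"
            continue
        f_dn = fc[(params.focal_tissue, te, "down")] if ep_ok else 1.0
        r_dn = fc[(params.reference_tissue, te, "down")] if sp_ok else 1.0
        if f_dn - r_dn >= params.enhanced_diff_threshold:
            categories[tid] = "enhanced_down"
            continue
        categories[tid] = "unclassified"
    for tid in expr.removed_ids:
        categories[tid] = "not_expressed"
    return pd.Series(categories)


class TestParams:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError, match="focal_fc_threshold"):
            ClassifierParams(focal_fc_threshold=2.0, reference_fc_ceiling=2.0)

    def test_enhanced_timepoint_must_be_considered(self):
        with pytest.raises(ValueError, match="enhanced_timepoint"):
            ClassifierParams(enhanced_timepoint=12)

    def test_exploratory_screen_is_a_parameterization(self):
        params = ClassifierParams(focal_fc_threshold=2.0, reference_fc_ceiling=1.2)
        assert params.focal_fc_threshold == 2.0


class TestSpecific:
    def test_printed_row_pattern_silent_reference(self, default_params):
        # large EP fold changes with SP silent: the canonical specific-up row
        expr = make_expression(
            {"t13378": tissue_profile([0.1, 51.2, 12.8, 6.4], [0.1, 0.1, 0.1, 0.1])}
        )
        result = classify_all(expr, default_params)
        assert result.categories["t13378"] == "specific_up"

    def test_below_threshold_everywhere_fails(self, default_params):
        expr = make_expression(
            {"a": tissue_profile([1.0, 4.9, 4.9, 4.9], [1, 1, 1, 1])}
        )
        fc_up = fold_changes(expr, UP)
        fc_down = fold_changes(expr, DOWN)
        up_ids, down_ids, _ = classify_specific(fc_up, fc_down, default_params)
        assert up_ids == [] and down_ids == []

    def test_reference_change_in_either_direction_eliminates(self, default_params):
        rows = {
            "up_in_sp": tissue_profile([1, 10, 1, 1], [1, 2.0, 1, 1]),
            "down_in_sp": tissue_profile([1, 10, 1, 1], [1, 1, 0.5, 1]),
            "small_sp": tissue_profile([1, 10, 1, 1], [1, 1.4, 0.7, 1]),
        }
        expr = make_expression(rows)
        result = classify_all(expr, default_params)
        assert result.categories["up_in_sp"] != "specific_up"
        assert result.categories["down_in_sp"] != "specific_up"
        assert result.categories["small_sp"] == "specific_up"
        assert bool(result.table.at["up_in_sp", "eliminated_by_reference"]) is True

    def test_specific_down_mirror(self, default_params):
        expr = make_expression(
            {"d": tissue_profile([8.0, 1.0, 8.0, 8.0], [1, 1, 1, 1])}
        )
        result = classify_all(expr, default_params)
        assert result.categories["d"] == "specific_down"


class TestEnhanced:
    def params(self):
        return ClassifierParams()

    def fc_tables(self, rows):
        expr = make_expression(rows)
        return fold_changes(expr, UP), fold_changes(expr, DOWN)

    def test_large_difference_with_flat_reference(self):
        # EP 3-h fold 378 vs SP 1 -> difference 377
        fc_up, fc_down = self.fc_tables(
            {"t11848": tissue_profile([1, 378, 1, 1], [1, 1, 1, 1])}
        )
        up_ids, down_ids, diffs = classify_enhanced(fc_up, fc_down, ["t11848"], self.params())
        assert up_ids == ["t11848"]
        assert diffs.at["t11848", "enhanced_diff_up"] == pytest.approx(377.0)

    def test_boundary_difference_of_25_included(self):
        # EP 27 vs SP 2 -> difference exactly 25, "25 or greater"
        fc_up, fc_down = self.fc_tables(
            {"t19791": tissue_profile([1, 27, 1, 1], [1, 2, 1, 1])}
        )
        up_ids, _, diffs = classify_enhanced(fc_up, fc_down, ["t19791"], self.params())
        assert up_ids == ["t19791"]
        assert diffs.at["t19791", "enhanced_diff_up"] == pytest.approx(25.0)

    def test_below_threshold_excluded(self):
        fc_up, fc_down = self.fc_tables(
            {"a": tissue_profile([1, 20, 1, 1], [1, 1, 1, 1])}
        )
        up_ids, down_ids, _ = classify_enhanced(fc_up, fc_down, ["a"], self.params())
        assert up_ids == [] and down_ids == []

    def test_silent_reference_counts_as_no_change(self):
        fc_up, fc_down = self.fc_tables(
            {"a": tissue_profile([1, 40, 1, 1], [0.1, 0.1, 0.1, 0.1])}
        )
        up_ids, _, diffs = classify_enhanced(fc_up, fc_down, ["a"], self.params())
        assert up_ids == ["a"]
        assert diffs.at["a", "enhanced_diff_up"] == pytest.approx(39.0)

    def test_unknown_id_errors(self):
        fc_up, fc_down = self.fc_tables(
            {"a": tissue_profile([1, 40, 1, 1], [1, 1, 1, 1])}
        )
        with pytest.raises(KeyError, match="ghost"):
            classify_enhanced(fc_up, fc_down, ["ghost"], self.params())

    def test_only_evaluated_on_exclusions(self, default_params):
        # passes the specific filter, so never reaches the enhanced stage
        expr = make_expression(
            {"s": tissue_profile([1, 100, 1, 1], [1, 1, 1, 1])}
        )
        result = classify_all(expr, default_params)
        assert result.categories["s"] == "specific_up"
        assert pd.isna(result.table.at["s", "enhanced_diff_up"])


class TestClassifyAll:
    def test_empty_matrix(self, default_params):
        expr = make_expression({})
        result = classify_all(expr, default_params)
        assert len(result.table) == 0
        assert all(v == 0 for v in result.counts().values())

    def test_partition_and_count_sum(self, default_params):
        cfg = SimulationConfig(seed=21, n_transcripts=400)
        matrix, _ = generate_counts(cfg)
        expr = apply_floor(compute_rpkm(matrix))
        expr, removed = gate_expressed(expr)
        result = classify_all(expr, default_params)
        assert len(result.table) == 400
        assert sum(result.counts().values()) == 400
        assert result.counts()["not_expressed"] == len(removed)
        assert not result.table.index.has_duplicates

    def test_monotone_in_focal_threshold(self, default_params):
        cfg = SimulationConfig(seed=22, n_transcripts=400)
        matrix, _ = generate_counts(cfg)
        expr = apply_floor(compute_rpkm(matrix))
        expr, _ = gate_expressed(expr)
        at5 = set(classify_all(expr, default_params).ids("specific_up"))
        at10 = set(classify_all(expr, ClassifierParams(focal_fc_threshold=10)).ids("specific_up"))
        assert at10 <= at5

    def test_monotone_in_reference_ceiling_and_enhanced_threshold(self):
        cfg = SimulationConfig(seed=23, n_transcripts=400)
        matrix, _ = generate_counts(cfg)
        expr = apply_floor(compute_rpkm(matrix))
        expr, _ = gate_expressed(expr)
        loose = classify_all(expr, ClassifierParams())
        tight_ref = classify_all(expr, ClassifierParams(reference_fc_ceiling=1.5))
        assert set(tight_ref.ids("specific_up")) <= set(loose.ids("specific_up"))
        tight_enh = classify_all(expr, ClassifierParams(enhanced_diff_threshold=50))
        assert set(tight_enh.ids("enhanced_up")) <= set(loose.ids("enhanced_up"))

    @pytest.mark.parametrize("seed", [31, 32, 33])
    def test_agrees_with_straight_line_oracle(self, seed, default_params):
        cfg = SimulationConfig(seed=seed, n_transcripts=300)
        matrix, _ = generate_counts(cfg)
        expr = apply_floor(compute_rpkm(matrix))
        expr, _ = gate_expressed(expr)
        result = classify_all(expr, default_params)
        expected = straight_line_oracle(expr, default_params)
        mismatch = result.categories.reindex(expected.index) != expected
        assert not mismatch.any(), expected[mismatch]

    def test_noise_free_planted_quota_recovery(self):
        quotas = {
            "specific_up": 0.10,
            "specific_down": 0.05,
            "enhanced_up": 0.05,
            "enhanced_down": 0.01,
            "unchanged": 0.69,
            "not_expressed": 0.10,
        }
        cfg = SimulationConfig(
            seed=7, n_transcripts=1000, nb_dispersion=math.inf, category_proportions=quotas
        )
        matrix, truth = generate_counts(cfg)
        expr = apply_floor(compute_rpkm(matrix))
        expr, _ = gate_expressed(expr)
        counts = classify_all(expr, ClassifierParams()).counts()
        assert counts == {
            "specific_up": 100,
            "specific_down": 50,
            "enhanced_up": 50,
            "enhanced_down": 10,
            "unclassified": 690,
            "not_expressed": 100,
        }
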