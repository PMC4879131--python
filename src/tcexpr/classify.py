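"""Two-stage tissue-contrast classification of time-course fold changes.

Stage one ("tissue-specific"): a transcript is specifically up-regulated in
the focal tissue when its fold change there reaches the focal threshold
(default 5) at one or more considered timepoints, while the reference
tissue shows less than the reference ceiling (default 2) of change — in
either direction — at every considered timepoint.  Down-regulation is the
mirror image using reciprocal (baseline/timepoint) ratios for the focal
condition.  A transcript silent in the reference tissue trivially passes
the reference filter.

Stage two ("tissue-enhanced"): among transcripts *excluded* from the
specific categories, those whose early (default 3-h) linear fold change in
the focal tissue exceeds the reference tissue's by at least the enhanced
difference threshold (default 25) are enhanced-up; analogously for
down-regulation on the reciprocal tables.  The difference is computed on
linear fold changes, with a silent tissue contributing a no-change value
of 1.

Categories partition the input: every transcript gets exactly one of
specific_up, specific_down, enhanced_up, enhanced_down, unclassified or
not_expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import DOWN, UP, ExpressionMatrix, FoldChangeTable, fold_changes

CATEGORIES = (
    "specific_up",
    "specific_down",
    "enhanced_up",
    "enhanced_down",
    "unclassified",
    "not_expressed",
)


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds and tissue roles for the two-stage classification.

    The defaults are the stringent parameterisation (5-fold focal, 2-fold
    reference ceiling, 25 enhanced difference at 3 h); the exploratory
    2-fold / 1.2-fold screen is the same filter with ``focal_fc_threshold=2,
    reference_fc_ceiling=1.2``.
    """

    focal_tissue: str = "EP"
    reference_tissue: str = "SP"
    focal_fc_threshold: float = 5.0
    reference_fc_ceiling: float = 2.0
    enhanced_diff_threshold: float = 25.0
    enhanced_timepoint: int = 3
    timepoints_considered: tuple[int, ...] = (3, 9, 24)

    def __post_init__(self) -> None:
        if not self.focal_fc_threshold > self.reference_fc_ceiling > 1:
            raise ValueError(
                "require focal_fc_threshold > reference_fc_ceiling > 1, got "
                f"{self.focal_fc_threshold} / {self.reference_fc_ceiling}"
            )
        if self.enhanced_diff_threshold <= 0:
            raise ValueError("enhanced_diff_threshold must be positive")
        if self.enhanced_timepoint not in self.timepoints_considered:
            raise ValueError(
                f"enhanced_timepoint {self.enhanced_timepoint} not among "
                f"timepoints_considered {self.timepoints_considered}"
            )
        if self.focal_tissue == self.reference_tissue:
            raise ValueError("focal and reference tissue must differ")

    def to_dict(self) -> dict:
        return {
            "focal_tissue": self.focal_tissue,
            "reference_tissue": self.reference_tissue,
            "focal_fc_threshold": self.focal_fc_threshold,
            "reference_fc_ceiling": self.reference_fc_ceiling,
            "enhanced_diff_threshold": self.enhanced_diff_threshold,
            "enhanced_timepoint": self.enhanced_timepoint,
            "timepoints_considered": list(self.timepoints_considered),
        }


@dataclass
class ClassificationResult:
    """One category per transcript plus the intermediate filter decisions.

    ``table`` columns: category, passed_focal_up, passed_focal_down,
    eliminated_by_reference, enhanced_diff_up, enhanced_diff_down (NaN where
    the enhanced stage was not evaluated).
    """

    table: pd.DataFrame
    params: ClassifierParams

    @property
    def categories(self) -> pd.Series:
        return self.table["category"]

    def ids(self, category: str) -> list[str]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return self.table.index[self.table["category"] == category].tolist()

    def counts(self) -> dict[str, int]:
        vc = self.table["category"].value_counts()
        return {c: int(vc.get(c, 0)) for c in CATEGORIES}

    def summary(self) -> dict:
        return {
            "n_transcripts": int(len(self.table)),
            "category_counts": self.counts(),
            "params": self.params.to_dict(),
        }


def _considered(fc: FoldChangeTable, params: ClassifierParams) -> list[int]:
    tps = [t for t in params.timepoints_considered if t in fc.timepoints]
    if not tps:
        raise ValueError(
            f"none of timepoints_considered {params.timepoints_considered} present "
            f"in fold-change table timepoints {fc.timepoints}"
        )
    return tps


def classify_specific(
    fc_up: FoldChangeTable,
    fc_down: FoldChangeTable,
    params: ClassifierParams,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Tissue-specific up/down lists plus the per-transcript filter decisions.

    NaN sentinels compare False throughout, which encodes both rules: a
    focal-silent transcript can never pass the focal filter, and a
    reference-silent transcript is never eliminated by the reference filter.
    """
    if fc_up.direction != UP or fc_down.direction != DOWN:
        raise ValueError("classify_specific needs (up_ratio, down_ratio) tables")
    tps = _considered(fc_up, params)
    focal, ref = params.focal_tissue, params.reference_tissue

    focal_up = fc_up.linear[focal][tps]
    focal_down = fc_down.linear[focal][tps]
    passed_up = (focal_up >= params.focal_fc_threshold).any(axis=1)
    passed_down = (focal_down >= params.focal_fc_threshold).any(axis=1)

    ref_change = pd.concat([fc_up.linear[ref][tps], fc_down.linear[ref][tps]], axis=1)
    eliminated = (ref_change >= params.reference_fc_ceiling).any(axis=1)

    decisions = pd.DataFrame(
        {
            "passed_focal_up": passed_up,
            "passed_focal_down": passed_down,
            "eliminated_by_reference": eliminated,
        }
    )
    up_ids = decisions.index[passed_up & ~eliminated].tolist()
    down_ids = decisions.index[passed_down & ~eliminated].tolist()
    return up_ids, down_ids, decisions


def classify_enhanced(
    fc_up: FoldChangeTable,
    fc_down: FoldChangeTable,
    excluded_from_specific: list[str],
    params: ClassifierParams,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Tissue-enhanced up/down lists among the specific-stage exclusions.

    The statistic is the linear fold-change difference focal − reference at
    the enhanced timepoint; a silent tissue contributes 1 (no change).
    Boundary values equal to the threshold are included.
    """
    missing = [i for i in excluded_from_specific if i not in fc_up.linear.index]
    if missing:
        raise KeyError(
            f"excluded id(s) absent from fold-change tables: {', '.join(map(str, missing[:5]))}"
        )
    tp = params.enhanced_timepoint
    focal, ref = params.focal_tissue, params.reference_tissue
    idx = pd.Index(excluded_from_specific)

    def diff(fc: FoldChangeTable) -> pd.Series:
        f = fc.linear[(focal, tp)].reindex(idx).fillna(1.0)
        r = fc.linear[(ref, tp)].reindex(idx).fillna(1.0)
        return f - r

    diff_up = diff(fc_up)
    diff_down = diff(fc_down)
    up_mask = diff_up >= params.enhanced_diff_threshold
    down_mask = (diff_down >= params.enhanced_diff_threshold) & ~up_mask
    diffs = pd.DataFrame({"enhanced_diff_up": diff_up, "enhanced_diff_down": diff_down})
    return idx[up_mask].tolist(), idx[down_mask].tolist(), diffs


def classify_all(matrix: ExpressionMatrix, params: ClassifierParams) -> ClassificationResult:
    """Run the full classification on a floored, gated expression matrix.

    Composes both fold-change directions, the specific stage, the enhanced
    stage on its exclusions, and labels the remainder: gated-out transcripts
    are ``not_expressed``, everything else left over is ``unclassified``.
    A transcript qualifying as both specific_up and specific_down (possible
    with opposite-direction peaks at different timepoints) is labelled
    specific_up.
    """
    if matrix.expressed is None:
        raise ValueError("classify_all requires a gated matrix (run gate_expressed)")
    fc_up = fold_changes(matrix, UP)
    fc_down = fold_changes(matrix, DOWN)

    up_ids, down_ids, decisions = classify_specific(fc_up, fc_down, params)
    up_set = set(up_ids)
    down_ids = [i for i in down_ids if i not in up_set]
    specific = up_set | set(down_ids)

    excluded = [i for i in fc_up.linear.index if i not in specific]
    eup_ids, edown_ids, diffs = classify_enhanced(fc_up, fc_down, excluded, params)

    category = pd.Series("unclassified", index=fc_up.linear.index, dtype=object)
    category.loc[up_ids] = "specific_up"
    category.loc[down_ids] = "specific_down"
    category.loc[eup_ids] = "enhanced_up"
    category.loc[edown_ids] = "enhanced_down"

    table = decisions.copy()
    table.insert(0, "category", category)
    table["enhanced_diff_up"] = diffs["enhanced_diff_up"].reindex(table.index)
    table["enhanced_diff_down"] = diffs["enhanced_diff_down"].reindex(table.index)

    if matrix.removed_ids:
        removed = pd.DataFrame(
            {
                "category": "not_expressed",
                "passed_focal_up": False,
                "passed_focal_down": False,
                "eliminated_by_reference": False,
                "enhanced_diff_up": np.nan,
                "enhanced_diff_down": np.nan,
            },
            index=pd.Index(matrix.removed_ids),
        )
        table = pd.concat([table, removed])

    return ClassificationResult(table=table, params=params)
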