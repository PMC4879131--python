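"""Category report tables in the layout of printed supplementary tables.

Specific categories: one row per transcript, per-timepoint log2 fold change
in the focal tissue with the reference tissue's log2 fold change in
parentheses (signed, up-ratio convention), "−" for not-expressed sentinels,
log2 values rounded to one decimal.  Down-regulated categories print the
focal column in the reciprocal (down-ratio) convention so magnitudes stay
positive.

Enhanced categories: linear 3-h fold changes of both tissues and their
difference, rounded to integers.  All reports are sorted by 3-h focal fold
change descending, ties broken by transcript id.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .classify import CATEGORIES, ClassificationResult
from .expression import DOWN, UP, FoldChangeTable
from .io import SENTINEL, AnnotationTable, _write


def _fmt_log2(value: float) -> str:
    return SENTINEL if pd.isna(value) else f"{value:.1f}"


def _fmt_int(value: float) -> str:
    return SENTINEL if pd.isna(value) else f"{value:.0f}"


def _annotation_cells(ann: AnnotationTable, tid: str) -> list[str]:
    return [ann.get(tid, col) for col in AnnotationTable.ANNOTATION_COLUMNS]


def _sort_ids(ids: list[str], sort_key: pd.Series) -> list[str]:
    key = sort_key.reindex(ids)
    frame = pd.DataFrame({"key": key, "tid": [str(i) for i in ids]}, index=ids)
    frame = frame.sort_values(["key", "tid"], ascending=[False, True], na_position="last")
    return frame.index.tolist()


def emit_report(
    result: ClassificationResult,
    fc_up: FoldChangeTable,
    fc_down: FoldChangeTable,
    annotation: AnnotationTable,
    category: str,
    path: str | Path,
    comments: list[str] | None = None,
) -> int:
    """Write the report for one category; returns the number of data rows."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category label {category!r}")
    if fc_up.direction != UP or fc_down.direction != DOWN:
        raise ValueError("emit_report needs (up_ratio, down_ratio) tables")
    params = result.params
    focal, ref = params.focal_tissue, params.reference_tissue
    ids = result.ids(category)
    ann_cols = list(AnnotationTable.ANNOTATION_COLUMNS)

    lines: list[str] = []
    if category in ("specific_up", "specific_down", "unclassified", "not_expressed"):
        focal_fc = fc_up if category != "specific_down" else fc_down
        tps = fc_up.timepoints
        header = ["transcript_id", *ann_cols]
        header += [f"log2fc_{focal}_{tp}h_({ref})" for tp in tps]
        lines.append("\t".join(header))
        ids = [i for i in ids if i in focal_fc.linear.index]  # not_expressed has no rows
        ids = _sort_ids(ids, focal_fc.linear.get((focal, params.enhanced_timepoint)))
        focal_log2, ref_log2 = focal_fc.log2, fc_up.log2
        for tid in ids:
            cells = [str(tid), *_annotation_cells(annotation, tid)]
            for tp in tps:
                f = _fmt_log2(focal_log2.at[tid, (focal, tp)])
                r = _fmt_log2(ref_log2.at[tid, (ref, tp)])
                cells.append(f"{f} ({r})")
            lines.append("\t".join(cells))
    else:  # enhanced_up / enhanced_down
        fc = fc_up if category == "enhanced_up" else fc_down
        tp = params.enhanced_timepoint
        diff_col = "enhanced_diff_up" if category == "enhanced_up" else "enhanced_diff_down"
        header = [
            "transcript_id",
            *ann_cols,
            f"fc_{focal}_{tp}h",
            f"fc_{ref}_{tp}h",
            "fold_difference",
        ]
        lines.append("\t".join(header))
        ids = _sort_ids(ids, fc.linear.get((focal, tp)))
        for tid in ids:
            f = fc.linear.at[tid, (focal, tp)]
            r = fc.linear.at[tid, (ref, tp)]
            # sentinel tissues enter the difference as no-change (1)
            f_num = 1.0 if pd.isna(f) else f
            r_num = 1.0 if pd.isna(r) else r
            diff = result.table.at[tid, diff_col]
            if pd.isna(diff):
                diff = f_num - r_num
            cells = [
                str(tid),
                *_annotation_cells(annotation, tid),
                _fmt_int(f_num),
                _fmt_int(r_num),
                _fmt_int(diff),
            ]
            lines.append("\t".join(cells))

    _write(path, comments or [], "\n".join(lines) + "\n")
    return len(lines) - 1
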