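"""Expression matrices for a two-tissue RNA-seq time course.

This module carries the quantification and pre-processing conventions used
throughout the package: RPKM computed from raw read counts, a small-value
floor that keeps ratio statistics finite, an expression gate that removes
transcripts never detected above background, and per-tissue fold-change
tables against the pre-culture (0-h) baseline.

The two conventions worth spelling out:

* The floor (default 0.1 RPKM) exists only to stabilise fold-change
  denominators.  The expression gate (default 0.5 RPKM) is evaluated on the
  *pre-floor* values, so the two rules stay independent of each other's
  parameter; with floor < gate the distinction is unobservable, but the
  contract holds for any parameterisation.
* Down-regulation fold changes are represented as the reciprocal ratio
  (baseline / timepoint) so that a single "ratio >= threshold" comparison
  expresses both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

TISSUES: tuple[str, ...] = ("EP", "SP")
TIMEPOINTS: tuple[int, ...] = (0, 3, 9, 24)

DEFAULT_FLOOR = 0.1
DEFAULT_GATE = 0.5

#: direction markers for fold-change tables
UP = "up_ratio"
DOWN = "down_ratio"


def sample_label(tissue: str, timepoint: int) -> str:
    """Canonical sample name, e.g. ``EP_3h``."""
    return f"{tissue}_{timepoint}h"


def parse_sample_label(label: str) -> tuple[str, int]:
    """Split ``EP_3h`` into ``("EP", 3)``; raise ValueError on anything else."""
    parts = label.split("_")
    if len(parts) == 2 and parts[1].endswith("h"):
        try:
            return parts[0], int(parts[1][:-1])
        except ValueError:
            pass
    raise ValueError(f"sample label {label!r} does not parse as <tissue>_<t>h")


def sample_labels(
    tissues: tuple[str, ...] = TISSUES, timepoints: tuple[int, ...] = TIMEPOINTS
) -> list[str]:
    return [sample_label(ti, tp) for ti in tissues for tp in timepoints]


@dataclass
class CountMatrix:
    """Raw read counts for transcripts across the tissue x timepoint grid.

    Parameters
    ----------
    counts
        Integer DataFrame, rows indexed by transcript id, one column per
        sample label (``EP_0h`` ... ``SP_24h``).
    lengths_bp
        Transcript length in bp, indexed like ``counts``.
    library_sizes
        Total mapped reads per sample, indexed by sample label.
    """

    counts: pd.DataFrame
    lengths_bp: pd.Series
    library_sizes: pd.Series
    tissues: tuple[str, ...] = TISSUES
    timepoints: tuple[int, ...] = TIMEPOINTS

    def __post_init__(self) -> None:
        expected = sample_labels(self.tissues, self.timepoints)
        missing = [s for s in expected if s not in self.counts.columns]
        if missing:
            raise ValueError(f"missing sample column(s): {', '.join(missing)}")
        extra = [c for c in self.counts.columns if c not in expected]
        if extra:
            raise ValueError(f"unexpected sample column(s): {', '.join(extra)}")
        self.counts = self.counts[expected]
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript id(s): {', '.join(map(str, dup))}")
        vals = self.counts.to_numpy()
        if (vals < 0).any() or not np.allclose(vals, np.rint(vals)):
            raise ValueError("counts must be non-negative integers")
        self.lengths_bp = self.lengths_bp.reindex(self.counts.index)
        if self.lengths_bp.isna().any():
            missing_len = self.lengths_bp.index[self.lengths_bp.isna()].tolist()
            raise ValueError(f"missing length for transcript(s): {missing_len[:5]}")
        self.library_sizes = self.library_sizes.reindex(expected)
        if self.library_sizes.isna().any():
            miss = self.library_sizes.index[self.library_sizes.isna()].tolist()
            raise ValueError(f"missing library size for sample(s): {miss}")

    @property
    def transcript_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def baseline(self) -> int:
        return self.timepoints[0]


@dataclass
class ExpressionMatrix:
    """RPKM values plus the floor/gate bookkeeping.

    ``rpkm`` holds the working values (floored once :func:`apply_floor` has
    run); ``prefloor`` keeps the as-computed values, which is what the
    expression gate compares against.  ``expressed`` (transcript x tissue
    booleans) is populated by :func:`gate_expressed`; ``removed_ids`` lists
    transcripts dropped by the gate.
    """

    rpkm: pd.DataFrame
    prefloor: pd.DataFrame
    floored: pd.DataFrame
    tissues: tuple[str, ...] = TISSUES
    timepoints: tuple[int, ...] = TIMEPOINTS
    expressed: pd.DataFrame | None = None
    removed_ids: tuple[str, ...] = ()
    floor: float | None = None

    @property
    def transcript_ids(self) -> pd.Index:
        return self.rpkm.index

    @property
    def baseline(self) -> int:
        return self.timepoints[0]

    def tissue_columns(self, tissue: str) -> list[str]:
        return [sample_label(tissue, tp) for tp in self.timepoints]

    @classmethod
    def from_rpkm(
        cls,
        rpkm: pd.DataFrame,
        tissues: tuple[str, ...] = TISSUES,
        timepoints: tuple[int, ...] = TIMEPOINTS,
    ) -> "ExpressionMatrix":
        """Wrap a precomputed RPKM table (no floor applied, not yet gated)."""
        expected = sample_labels(tissues, timepoints)
        missing = [s for s in expected if s not in rpkm.columns]
        if missing:
            raise ValueError(f"missing sample column(s): {', '.join(missing)}")
        rpkm = rpkm[expected].astype(float)
        if (rpkm.to_numpy() < 0).any():
            raise ValueError("RPKM values must be non-negative")
        return cls(
            rpkm=rpkm,
            prefloor=rpkm.copy(),
            floored=pd.DataFrame(False, index=rpkm.index, columns=rpkm.columns),
            tissues=tissues,
            timepoints=timepoints,
        )


def compute_rpkm(counts: CountMatrix) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    rpkm[t, s] = counts[t, s] * 1e9 / (length_bp[t] * library_size[s])
    """
    bad_len = counts.lengths_bp[counts.lengths_bp <= 0]
    if len(bad_len):
        raise ValueError(
            f"non-positive transcript length for: {', '.join(map(str, bad_len.index[:5]))}"
        )
    bad_lib = counts.library_sizes[counts.library_sizes <= 0]
    if len(bad_lib):
        raise ValueError(
            f"non-positive library size for sample(s): {', '.join(map(str, bad_lib.index))}"
        )
    rpkm = (
        counts.counts.astype(float)
        .div(counts.lengths_bp.astype(float), axis=0)
        .div(counts.library_sizes.astype(float), axis=1)
        * 1e9
    )
    return ExpressionMatrix(
        rpkm=rpkm,
        prefloor=rpkm.copy(),
        floored=pd.DataFrame(False, index=rpkm.index, columns=rpkm.columns),
        tissues=counts.tissues,
        timepoints=counts.timepoints,
    )


def apply_floor(matrix: ExpressionMatrix, floor: float = DEFAULT_FLOOR) -> ExpressionMatrix:
    """Raise every RPKM value below ``floor`` to ``floor`` (idempotent).

    Cells raised are flagged in ``floored``; values already at or above the
    floor are untouched.  ``prefloor`` is never modified.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    mask = matrix.rpkm < floor
    rpkm = matrix.rpkm.where(~mask, floor)
    return replace(
        matrix,
        rpkm=rpkm,
        floored=matrix.floored | mask,
        floor=floor,
    )


def gate_expressed(
    matrix: ExpressionMatrix, gate: float = DEFAULT_GATE
) -> tuple[ExpressionMatrix, list[str]]:
    """Apply the expression gate and drop never-expressed transcripts.

    A transcript is *expressed in a tissue* when its pre-floor RPKM reaches
    ``gate`` at one or more timepoints of that tissue.  Transcripts below
    the gate in every sample are removed; their ids are returned and also
    recorded on the matrix so downstream classification can label them.
    """
    if gate <= 0:
        raise ValueError("gate must be positive")
    expressed = pd.DataFrame(index=matrix.prefloor.index, columns=list(matrix.tissues))
    for tissue in matrix.tissues:
        cols = matrix.tissue_columns(tissue)
        expressed[tissue] = (matrix.prefloor[cols] >= gate).any(axis=1)
    expressed = expressed.astype(bool)
    keep = expressed.any(axis=1)
    removed = matrix.prefloor.index[~keep].tolist()
    gated = replace(
        matrix,
        rpkm=matrix.rpkm.loc[keep],
        prefloor=matrix.prefloor.loc[keep],
        floored=matrix.floored.loc[keep],
        expressed=expressed.loc[keep],
        removed_ids=tuple(matrix.removed_ids) + tuple(removed),
    )
    return gated, removed


@dataclass
class FoldChangeTable:
    """Per-tissue linear fold changes at each post-baseline timepoint.

    ``linear`` has a (tissue, timepoint) column MultiIndex.  Cells of a
    tissue in which the transcript is not expressed carry NaN — the
    "not expressed" sentinel, rendered "−" in reports.  ``direction`` is
    ``up_ratio`` (timepoint / baseline) or ``down_ratio`` (reciprocal).
    """

    linear: pd.DataFrame
    direction: str
    expressed: pd.DataFrame
    tissues: tuple[str, ...] = TISSUES
    timepoints: tuple[int, ...] = field(default=(3, 9, 24))

    @property
    def log2(self) -> pd.DataFrame:
        with np.errstate(divide="ignore"):
            return np.log2(self.linear)

    @property
    def transcript_ids(self) -> pd.Index:
        return self.linear.index


def fold_changes(matrix: ExpressionMatrix, direction: str = UP) -> FoldChangeTable:
    """Fold change of each post-baseline timepoint relative to 0 h, per tissue.

    Requires the floor (finite denominators) and the gate (sentinel flags)
    to have been applied.
    """
    if direction not in (UP, DOWN):
        raise ValueError(f"direction must be {UP!r} or {DOWN!r}")
    if matrix.expressed is None:
        raise ValueError("run gate_expressed before fold_changes")
    if matrix.floor is None and (matrix.rpkm.to_numpy() == 0).any():
        raise ValueError("apply_floor before fold_changes: zero RPKM present")
    post = tuple(tp for tp in matrix.timepoints if tp != matrix.baseline)
    pieces: dict[tuple[str, int], pd.Series] = {}
    for tissue in matrix.tissues:
        base = matrix.rpkm[sample_label(tissue, matrix.baseline)]
        if (base == 0).any():
            raise ValueError(f"zero baseline RPKM in tissue {tissue}; apply_floor first")
        silent = ~matrix.expressed[tissue]
        for tp in post:
            val = matrix.rpkm[sample_label(tissue, tp)]
            fc = val / base if direction == UP else base / val
            pieces[(tissue, tp)] = fc.mask(silent)
    linear = pd.DataFrame(pieces)
    linear.columns = pd.MultiIndex.from_tuples(linear.columns, names=["tissue", "timepoint"])
    return FoldChangeTable(
        linear=linear,
        direction=direction,
        expressed=matrix.expressed.copy(),
        tissues=matrix.tissues,
        timepoints=post,
    )
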