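"""TSV readers and writers for the pipeline's tabular formats.

All files are tab-separated with a header row; lines starting with ``#``
are comments (writers use them to echo the seed/provenance).  Readers
validate aggressively and report offending line numbers.  The literal
token ``NA`` is rejected on input — the only missing-value rendering in
this package is the "−" sentinel of fold-change output, which is
write-only.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import (
    CountMatrix,
    ExpressionMatrix,
    FoldChangeTable,
    TIMEPOINTS,
    TISSUES,
    sample_label,
    sample_labels,
)

SENTINEL = "−"  # U+2212, matching the "(−)" convention of printed reports


class ParseError(ValueError):
    pass


def _read_rows(path: str | Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Header fields plus (line_number, fields) for each data row."""
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            rows.append((lineno, fields))
    if header is None:
        raise ParseError(f"{path}: empty file (no header)")
    return header, rows


def _numeric(path, lineno, column, token, cast):
    if token == "NA":
        raise ParseError(
            f"{path}: line {lineno}: literal 'NA' in column {column!r} is not accepted"
        )
    try:
        return cast(token)
    except ValueError:
        raise ParseError(
            f"{path}: line {lineno}: non-numeric value {token!r} in column {column!r}"
        ) from None


def _check_duplicates(path, ids_with_lines):
    seen: dict[str, int] = {}
    for lineno, tid in ids_with_lines:
        if tid in seen:
            raise ParseError(
                f"{path}: duplicate transcript id {tid!r} on lines {seen[tid]} and {lineno}"
            )
        seen[tid] = lineno


def _read_matrix(
    path: str | Path,
    tissues: tuple[str, ...],
    timepoints: tuple[int, ...],
    cast,
) -> pd.DataFrame:
    header, rows = _read_rows(path)
    id_col, sample_cols = header[0], header[1:]
    expected = sample_labels(tissues, timepoints)
    missing = [s for s in expected if s not in sample_cols]
    if missing:
        raise ParseError(f"{path}: missing sample column(s): {', '.join(missing)}")
    _check_duplicates(path, [(lineno, fields[0]) for lineno, fields in rows])
    data = {
        fields[0]: [
            _numeric(path, lineno, col, tok, cast)
            for col, tok in zip(sample_cols, fields[1:])
        ]
        for lineno, fields in rows
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=sample_cols)
    df.index.name = id_col
    return df[expected]


def read_count_tsv(
    counts_path: str | Path,
    lengths_path: str | Path,
    library_sizes_path: str | Path,
    tissues: tuple[str, ...] = TISSUES,
    timepoints: tuple[int, ...] = TIMEPOINTS,
) -> CountMatrix:
    counts = _read_matrix(counts_path, tissues, timepoints, int)
    lengths = read_lengths_tsv(lengths_path)
    libs = read_library_sizes_tsv(library_sizes_path)
    return CountMatrix(
        counts=counts,
        lengths_bp=lengths,
        library_sizes=libs,
        tissues=tissues,
        timepoints=timepoints,
    )


def read_rpkm_tsv(
    path: str | Path,
    tissues: tuple[str, ...] = TISSUES,
    timepoints: tuple[int, ...] = TIMEPOINTS,
) -> ExpressionMatrix:
    rpkm = _read_matrix(path, tissues, timepoints, float)
    return ExpressionMatrix.from_rpkm(rpkm, tissues=tissues, timepoints=timepoints)


def read_lengths_tsv(path: str | Path) -> pd.Series:
    header, rows = _read_rows(path)
    _check_duplicates(path, [(lineno, fields[0]) for lineno, fields in rows])
    values = {
        fields[0]: _numeric(path, lineno, header[1], fields[1], int)
        for lineno, fields in rows
    }
    s = pd.Series(values, name="length_bp")
    s.index.name = header[0]
    return s


def read_library_sizes_tsv(path: str | Path) -> pd.Series:
    header, rows = _read_rows(path)
    values = {
        fields[0]: _numeric(path, lineno, header[1], fields[1], int)
        for lineno, fields in rows
    }
    s = pd.Series(values, name="total_mapped_reads")
    s.index.name = header[0]
    return s


def read_ct_tsv(path: str | Path) -> pd.DataFrame:
    """Ct table with columns gene, tissue, timepoint, replicate, ct."""
    header, rows = _read_rows(path)
    required = ["gene", "tissue", "timepoint", "replicate", "ct"]
    missing = [c for c in required if c not in header]
    if missing:
        raise ParseError(f"{path}: missing column(s): {', '.join(missing)}")
    idx = {c: header.index(c) for c in required}
    records = []
    for lineno, fields in rows:
        records.append(
            {
                "gene": fields[idx["gene"]],
                "tissue": fields[idx["tissue"]],
                "timepoint": _numeric(path, lineno, "timepoint", fields[idx["timepoint"]], int),
                "replicate": _numeric(path, lineno, "replicate", fields[idx["replicate"]], int),
                "ct": _numeric(path, lineno, "ct", fields[idx["ct"]], float),
            }
        )
    return pd.DataFrame.from_records(records)


@dataclass
class AnnotationTable:
    """Optional transcript annotation consumed (never computed) by reports.

    Columns beyond the id are all optional: gene_product, species_accession,
    evalue, ortholog, is_transcription_factor.
    """

    table: pd.DataFrame

    ANNOTATION_COLUMNS = (
        "gene_product",
        "species_accession",
        "evalue",
        "ortholog",
        "is_transcription_factor",
    )

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript id(s) in annotation: {dup[:5]}")

    def get(self, transcript_id: str, column: str) -> str:
        if transcript_id in self.table.index and column in self.table.columns:
            val = self.table.at[transcript_id, column]
            if pd.notna(val):
                return str(val)
        return ""

    @classmethod
    def empty(cls) -> "AnnotationTable":
        return cls(table=pd.DataFrame(index=pd.Index([], name="transcript_id")))


def read_annotation_tsv(path: str | Path) -> AnnotationTable:
    header, rows = _read_rows(path)
    _check_duplicates(path, [(lineno, fields[0]) for lineno, fields in rows])
    df = pd.DataFrame.from_dict(
        {fields[0]: fields[1:] for _, fields in rows}, orient="index", columns=header[1:]
    )
    df.index.name = header[0]
    return AnnotationTable(table=df)


# ---------------------------------------------------------------------------
# writers


def _write(path: str | Path, header_comments: list[str], body: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write(body)


def _matrix_body(df: pd.DataFrame, float_format: str | None = None) -> str:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", float_format=float_format)
    return buf.getvalue()


def write_counts_tsv(path: str | Path, matrix: CountMatrix, comments: list[str] | None = None):
    _write(path, comments or [], _matrix_body(matrix.counts))


def write_lengths_tsv(path: str | Path, lengths: pd.Series, comments: list[str] | None = None):
    _write(path, comments or [], _matrix_body(lengths.to_frame()))


def write_library_sizes_tsv(path: str | Path, libs: pd.Series, comments: list[str] | None = None):
    _write(path, comments or [], _matrix_body(libs.to_frame()))


def write_rpkm_tsv(path: str | Path, matrix: ExpressionMatrix, comments: list[str] | None = None):
    _write(path, comments or [], _matrix_body(matrix.rpkm, float_format="%.17g"))


def write_truth_tsv(path: str | Path, truth, comments: list[str] | None = None):
    _write(path, comments or [], _matrix_body(truth.table, float_format="%.17g"))


def write_fold_change_tsv(
    path: str | Path, fc: FoldChangeTable, comments: list[str] | None = None
) -> None:
    """Long-format fold changes: one row per transcript x tissue, with the
    "−" sentinel for tissues in which the transcript is not expressed."""
    log2 = fc.log2
    lines = []
    tps = fc.timepoints
    header = ["transcript_id", "tissue"]
    header += [f"fc{tp}" for tp in tps] + [f"log2fc{tp}" for tp in tps] + ["expressed"]
    lines.append("\t".join(header))
    for tid in fc.linear.index:
        for tissue in fc.tissues:
            expressed = bool(fc.expressed.at[tid, tissue])
            row = [str(tid), tissue]
            for tp in tps:
                v = fc.linear.at[tid, (tissue, tp)]
                row.append(f"{v:.10g}" if pd.notna(v) else SENTINEL)
            for tp in tps:
                v = log2.at[tid, (tissue, tp)]
                row.append(f"{v:.10g}" if pd.notna(v) else SENTINEL)
            row.append(str(expressed))
            lines.append("\t".join(row))
    _write(path, comments or [], "\n".join(lines) + "\n")


def write_classification_tsv(path: str | Path, result, comments: list[str] | None = None):
    df = result.table.copy()
    body = _matrix_body(df, float_format="%.10g")
    _write(path, comments or [], body)
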