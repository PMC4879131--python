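import numpy as np
import pandas as pd
import pytest

from tcexpr import (
    ClassifierParams,
    CountMatrix,
    ExpressionMatrix,
    apply_floor,
    gate_expressed,
)
from tcexpr.expression import TIMEPOINTS, TISSUES, sample_label, sample_labels


def make_count_matrix(counts, lengths, library_sizes):
    """Build a CountMatrix from plain dicts/lists keyed by sample label."""
    df = pd.DataFrame(counts)
    df.index = [f"T{i:03d}" for i in range(len(df))] if df.index.dtype == np.int64 else df.index
    df.index.name = "transcript_id"
    return CountMatrix(
        counts=df,
        lengths_bp=pd.Series(lengths, index=df.index, name="length_bp"),
        library_sizes=pd.Series(library_sizes, index=df.columns, name="total_mapped_reads"),
    )


def make_expression(rows, floor_and_gate=True):
    """ExpressionMatrix from {transcript_id: {sample_label: rpkm}} rows.

    With floor_and_gate=True (default) the floor and gate are applied so the
    matrix is ready for fold_changes/classify_all.
    """
    if rows:
        df = pd.DataFrame.from_dict(rows, orient="index")[sample_labels()]
    else:
        df = pd.DataFrame(columns=sample_labels(), dtype=float)
    df.index.name = "transcript_id"
    expr = ExpressionMatrix.from_rpkm(df.astype(float))
    if floor_and_gate:
        expr = apply_floor(expr)
        expr, _ = gate_expressed(expr)
    return expr


def tissue_profile(ep, sp):
    """Sample dict from per-tissue value sequences ordered (0, 3, 9, 24) h."""
    vals = {}
    for tissue, series in (("EP", ep), ("SP", sp)):
        for tp, v in zip(TIMEPOINTS, series):
            vals[sample_label(tissue, tp)] = v
    return vals


@pytest.fixture
def default_params():
    return ClassifierParams()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
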