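"""Relative RT-qPCR quantification by the delta-delta Ct method.

Normalized expression of a target gene in a sample is

    E ** -(dCt(sample) - dCt(calibrator)),   dCt = Ct_target - Ct_reference

with Ct values averaged over replicates before differencing, E the
amplification efficiency per cycle (2.0 = perfect doubling) and the
calibrator sample (default epidermal tissue at 0 h) scaled to 1 by
construction.  Replicate dispersion is propagated to the expression scale
first-order: SE(expr) = ln(E) * expr * SE(ddCt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("gene", "tissue", "timepoint", "replicate", "ct")


class NormalizedExpression(NamedTuple):
    value: float
    sem: float  # NaN when any contributing Ct group has a single replicate


@dataclass
class QpcrExperiment:
    """Replicated Ct readings for target and reference genes.

    ``data`` columns: gene, tissue, timepoint, replicate, ct.  The
    reference gene must be measured in every sample that has a target
    measurement; efficiency must lie in (1, 2].
    """

    data: pd.DataFrame
    reference_gene: str
    calibrator: tuple[str, int] = ("EP", 0)
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing column(s): {', '.join(missing)}")
        ct = self.data["ct"].astype(float)
        if not np.isfinite(ct).all() or (ct <= 0).any():
            raise ValueError("Ct values must be finite and positive")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError(f"efficiency must be in (1, 2], got {self.efficiency}")
        if self.reference_gene not in set(self.data["gene"]):
            raise ValueError(f"reference gene {self.reference_gene!r} has no measurements")
        ref_samples = self._samples_of(self.reference_gene)
        for gene in self.genes:
            lacking = self._samples_of(gene) - ref_samples
            if lacking:
                raise ValueError(
                    f"reference gene {self.reference_gene!r} not measured in sample(s) "
                    f"{sorted(lacking)} required by {gene!r}"
                )

    def _samples_of(self, gene: str) -> set[tuple[str, int]]:
        sub = self.data[self.data["gene"] == gene]
        return set(zip(sub["tissue"], sub["timepoint"].astype(int)))

    @property
    def genes(self) -> list[str]:
        return sorted(g for g in self.data["gene"].unique() if g != self.reference_gene)

    @property
    def samples(self) -> list[tuple[str, int]]:
        return sorted(self._samples_of(self.reference_gene))

    def _ct_stats(self, gene: str, sample: tuple[str, int]) -> tuple[float, float]:
        """Mean Ct and its squared SEM for one gene in one sample."""
        tissue, tp = sample
        sel = self.data[
            (self.data["gene"] == gene)
            & (self.data["tissue"] == tissue)
            & (self.data["timepoint"].astype(int) == int(tp))
        ]["ct"].astype(float)
        if sel.empty:
            raise ValueError(f"no Ct measurements for {gene!r} in sample {sample}")
        if len(sel) == 1:
            return float(sel.iloc[0]), float("nan")
        return float(sel.mean()), float(sel.var(ddof=1) / len(sel))

    def delta_ct(self, gene: str, sample: tuple[str, int]) -> tuple[float, float]:
        """dCt = mean Ct_target - mean Ct_reference, with its squared SEM."""
        mt, vt = self._ct_stats(gene, sample)
        mr, vr = self._ct_stats(self.reference_gene, sample)
        return mt - mr, vt + vr


def normalized_expression(
    exp: QpcrExperiment, gene: str, sample: tuple[str, int]
) -> NormalizedExpression:
    """Delta-delta Ct normalized expression of ``gene`` in ``sample``."""
    if gene == exp.reference_gene:
        raise ValueError("target gene must differ from the reference gene")
    d_s, v_s = exp.delta_ct(gene, sample)
    d_c, v_c = exp.delta_ct(gene, exp.calibrator)
    ddct = d_s - d_c
    value = exp.efficiency ** (-ddct)
    sem = math.log(exp.efficiency) * value * math.sqrt(v_s + v_c)
    return NormalizedExpression(value=value, sem=sem)


def normalized_table(exp: QpcrExperiment) -> pd.DataFrame:
    """Normalized expression (and SEM) for every target gene and sample."""
    rows = []
    for gene in exp.genes:
        for sample in sorted(exp._samples_of(gene)):
            res = normalized_expression(exp, gene, sample)
            rows.append(
                {
                    "gene": gene,
                    "tissue": sample[0],
                    "timepoint": sample[1],
                    "expression": res.value,
                    "sem": res.sem,
                }
            )
    return pd.DataFrame(rows)


def _direction(ratio: float, tol: float = 1e-9) -> int:
    if abs(ratio - 1.0) <= tol:
        return 0
    return 1 if ratio > 1.0 else -1


def concordance_report(
    qpcr_values: pd.DataFrame,
    rnaseq_rpkm: pd.DataFrame,
    baseline_timepoint: int = 0,
    compare_timepoint: int = 3,
) -> pd.DataFrame:
    """Side-by-side platform comparison with per-tissue direction agreement.

    Both inputs are long tables with columns (gene, tissue, timepoint,
    value-like); ``qpcr_values`` uses ``expression``, ``rnaseq_rpkm`` uses
    ``rpkm``.  For each gene and tissue, the baseline-to-compare-timepoint
    ratio is computed on each platform and the signs compared; exact
    no-change on both platforms counts as agreement.
    """

    def pivot(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
        return df.pivot_table(
            index=["gene", "tissue"], columns="timepoint", values=value_col, aggfunc="first"
        )

    q = pivot(qpcr_values, "expression")
    r = pivot(rnaseq_rpkm, "rpkm")
    needed = [baseline_timepoint, compare_timepoint]
    missing = []
    for name, table in (("qpcr", q), ("rnaseq", r)):
        for tp in needed:
            if tp not in table.columns:
                missing.append(f"{name}: all cells at {tp} h")
    if set(q.index) != set(r.index):
        missing.extend(f"rnaseq: {cell}" for cell in sorted(set(q.index) - set(r.index)))
        missing.extend(f"qpcr: {cell}" for cell in sorted(set(r.index) - set(q.index)))
    if missing:
        raise ValueError("platform grids differ; missing cells: " + "; ".join(missing))
    na = pd.concat([q[needed], r[needed]], axis=1).isna()
    if na.to_numpy().any():
        raise ValueError(f"incomplete grid: missing values in {q.index[na.any(axis=1)].tolist()}")

    rows = []
    for gene, tissue in q.index:
        q_fold = q.loc[(gene, tissue), compare_timepoint] / q.loc[(gene, tissue), baseline_timepoint]
        r_fold = r.loc[(gene, tissue), compare_timepoint] / r.loc[(gene, tissue), baseline_timepoint]
        agree = _direction(q_fold) == _direction(r_fold)
        rows.append(
            {
                "gene": gene,
                "tissue": tissue,
                "qpcr_fold": q_fold,
                "rnaseq_fold": r_fold,
                "direction_agreement": "agree" if agree else "disagree",
            }
        )
    return pd.DataFrame(rows).sort_values(["gene", "tissue"]).reset_index(drop=True)
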