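"""Top-level pipeline: simulate/load -> RPKM -> floor -> gate -> fold
changes -> classify -> reports (-> qPCR), with a JSON run summary.

Configuration is a YAML mapping; exactly one input mode must be selected:
``simulate`` (a SimulationConfig mapping), ``counts`` (paths to counts,
lengths and library-size TSVs) or ``rpkm`` (path to a precomputed RPKM
TSV).  Stage failures raise :class:`StageError` naming the stage;
configuration problems raise :class:`ConfigError`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as tio
from .classify import CATEGORIES, ClassifierParams, classify_all
from .expression import (
    DEFAULT_FLOOR,
    DEFAULT_GATE,
    DOWN,
    UP,
    apply_floor,
    compute_rpkm,
    fold_changes,
    gate_expressed,
)
from .qpcr import QpcrExperiment, concordance_report, normalized_table
from .report import emit_report
from .simulate import SimulationConfig, generate_counts

logger = logging.getLogger("tcexpr")

REPORT_CATEGORIES = ("specific_up", "specific_down", "enhanced_up", "enhanced_down")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    output_dir: Path
    simulate: SimulationConfig | None = None
    counts_path: Path | None = None
    lengths_path: Path | None = None
    library_sizes_path: Path | None = None
    rpkm_path: Path | None = None
    annotation_path: Path | None = None
    qpcr_ct_path: Path | None = None
    qpcr_reference_gene: str | None = None
    params: ClassifierParams = field(default_factory=ClassifierParams)
    floor: float = DEFAULT_FLOOR
    gate: float = DEFAULT_GATE
    seed: int | None = None

    def __post_init__(self) -> None:
        modes = [
            self.simulate is not None,
            self.counts_path is not None,
            self.rpkm_path is not None,
        ]
        if sum(modes) != 1:
            raise ConfigError(
                "exactly one input mode must be selected: simulate, counts or rpkm"
            )
        if self.counts_path is not None and (
            self.lengths_path is None or self.library_sizes_path is None
        ):
            raise ConfigError("counts mode needs lengths_path and library_sizes_path")
        for p in (
            self.counts_path,
            self.lengths_path,
            self.library_sizes_path,
            self.rpkm_path,
            self.annotation_path,
            self.qpcr_ct_path,
        ):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input file does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path, seed_override: int | None = None) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, seed_override=seed_override)

    @classmethod
    def from_dict(cls, raw: dict, seed_override: int | None = None) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("run config must be a mapping")
        try:
            sim = None
            seed = seed_override if seed_override is not None else raw.get("seed")
            if "simulate" in raw and raw["simulate"] is not None:
                sim_raw = dict(raw["simulate"])
                if seed is not None:
                    sim_raw["seed"] = seed
                if "seed" not in sim_raw:
                    raise ConfigError("simulate mode requires a seed")
                sim = SimulationConfig(**sim_raw)
            params = ClassifierParams(**{
                **raw.get("params", {}),
                **(
                    {"timepoints_considered": tuple(raw["params"]["timepoints_considered"])}
                    if raw.get("params", {}).get("timepoints_considered")
                    else {}
                ),
            })
            return cls(
                output_dir=Path(raw.get("output_dir", ".")),
                simulate=sim,
                counts_path=_opt_path(raw.get("counts_path")),
                lengths_path=_opt_path(raw.get("lengths_path")),
                library_sizes_path=_opt_path(raw.get("library_sizes_path")),
                rpkm_path=_opt_path(raw.get("rpkm_path")),
                annotation_path=_opt_path(raw.get("annotation_path")),
                qpcr_ct_path=_opt_path(raw.get("qpcr_ct_path")),
                qpcr_reference_gene=raw.get("qpcr_reference_gene"),
                params=params,
                floor=float(raw.get("floor", DEFAULT_FLOOR)),
                gate=float(raw.get("gate", DEFAULT_GATE)),
                seed=seed,
            )
        except ConfigError:
            raise
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc


def _opt_path(value) -> Path | None:
    return None if value is None else Path(value)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured pipeline; returns (and writes) the summary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    input_hashes: dict[str, str] = {}
    comments = [] if config.seed is None else [f"seed: {config.seed}"]

    stage = "simulate"
    try:
        if config.simulate is not None:
            matrix_counts, truth = generate_counts(config.simulate)
            logger.info("simulate: %d transcripts", len(matrix_counts.transcript_ids))
            sim_comments = [f"seed: {config.simulate.seed}"]
            tio.write_counts_tsv(out / "counts.tsv", matrix_counts, sim_comments)
            tio.write_lengths_tsv(out / "lengths.tsv", matrix_counts.lengths_bp, sim_comments)
            tio.write_library_sizes_tsv(
                out / "library_sizes.tsv", matrix_counts.library_sizes, sim_comments
            )
            tio.write_truth_tsv(out / "truth.tsv", truth, sim_comments)
        elif config.counts_path is not None:
            stage = "read_counts"
            matrix_counts = tio.read_count_tsv(
                config.counts_path, config.lengths_path, config.library_sizes_path
            )
            for name, p in (
                ("counts", config.counts_path),
                ("lengths", config.lengths_path),
                ("library_sizes", config.library_sizes_path),
            ):
                input_hashes[name] = _sha256(p)
            logger.info("read_counts: %d transcripts", len(matrix_counts.transcript_ids))
        else:
            matrix_counts = None

        stage = "rpkm"
        if matrix_counts is not None:
            expr = compute_rpkm(matrix_counts)
        else:
            expr = tio.read_rpkm_tsv(config.rpkm_path)
            input_hashes["rpkm"] = _sha256(config.rpkm_path)
        logger.info("rpkm: %d transcripts x %d samples", *expr.rpkm.shape)

        stage = "floor"
        expr = apply_floor(expr, config.floor)
        logger.info("floor: %d cells raised to %.3g", int(expr.floored.to_numpy().sum()), config.floor)

        stage = "gate"
        expr, removed = gate_expressed(expr, config.gate)
        logger.info("gate: %d transcripts removed, %d retained", len(removed), len(expr.rpkm))
        tio.write_rpkm_tsv(out / "rpkm.tsv", expr, comments)

        stage = "fold_changes"
        fc_up = fold_changes(expr, UP)
        fc_down = fold_changes(expr, DOWN)
        tio.write_fold_change_tsv(out / "fold_changes_up.tsv", fc_up, comments)
        tio.write_fold_change_tsv(out / "fold_changes_down.tsv", fc_down, comments)

        stage = "classify"
        result = classify_all(expr, config.params)
        tio.write_classification_tsv(out / "classification.tsv", result, comments)
        counts = result.counts()
        logger.info("classify: %s", counts)

        stage = "report"
        annotation = (
            tio.read_annotation_tsv(config.annotation_path)
            if config.annotation_path is not None
            else tio.AnnotationTable.empty()
        )
        if config.annotation_path is not None:
            input_hashes["annotation"] = _sha256(config.annotation_path)
        report_rows = {}
        for category in REPORT_CATEGORIES:
            n = emit_report(
                result, fc_up, fc_down, annotation, category,
                out / f"report_{category}.tsv", comments,
            )
            report_rows[category] = n
            logger.info("report %s: %d rows", category, n)

        qpcr_summary = None
        if config.qpcr_ct_path is not None:
            stage = "qpcr"
            if config.qpcr_reference_gene is None:
                raise ConfigError("qpcr_ct_path given without qpcr_reference_gene")
            ct = tio.read_ct_tsv(config.qpcr_ct_path)
            input_hashes["qpcr_ct"] = _sha256(config.qpcr_ct_path)
            exp = QpcrExperiment(data=ct, reference_gene=config.qpcr_reference_gene)
            table = normalized_table(exp)
            table.to_csv(out / "qpcr_expression.tsv", sep="\t", index=False)
            qpcr_summary = {"n_genes": len(exp.genes), "n_samples": len(exp.samples)}
            logger.info("qpcr: %d genes x %d samples", len(exp.genes), len(exp.samples))
    except ConfigError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    summary = {
        "seed": config.seed,
        "input_hashes": input_hashes,
        "floor": config.floor,
        "gate": config.gate,
        "n_input_transcripts": int(len(expr.rpkm) + len(removed)),
        "n_removed_not_expressed": len(removed),
        "category_counts": counts,
        "report_rows": report_rows,
        "params": config.params.to_dict(),
        "qpcr": qpcr_summary,
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
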