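"""Synthetic two-tissue time-course count matrices with planted truth.

Emulates the data regime of a bulk RNA-seq experiment profiling epidermal
(EP) and storage parenchyma (SP) tissue at 0, 3, 9 and 24 h of culture:
eight pooled libraries of ~45 M mapped reads each, one per tissue and
timepoint, with no within-condition replicates.  Each simulated transcript
is planted into one of six categories — specific_up, specific_down,
enhanced_up, enhanced_down, unchanged, not_expressed — whose fold-change
profiles are constructed to satisfy the corresponding classification
definitions with a guard band, so that noise-free data is recovered
perfectly and noisy data nearly so.

Generative model
----------------
* Baseline expression: log-normal RPKM (meanlog 2.0, sdlog 1.0), clamped
  from below for expressed categories so detection is not depth-limited.
* Expected RPKM per sample: baseline x planted fold change.
* Counts: negative binomial with mean = RPKM x length_kb x library_millions
  and size (shape) ``nb_dispersion``; ``nb_dispersion = inf`` is the
  noise-free limit where counts are the rounded means.

Category quotas are met exactly via largest-remainder allocation, never by
multinomial sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import TIMEPOINTS, TISSUES, CountMatrix, sample_label

CATEGORIES = (
    "specific_up",
    "specific_down",
    "enhanced_up",
    "enhanced_down",
    "unchanged",
    "not_expressed",
)

# classification definitions the planted profiles must satisfy
_FOCAL_THRESHOLD = 5.0
_REFERENCE_CEILING = 2.0
_ENHANCED_DIFF = 25.0
# guard band over the enhanced difference threshold
_ENHANCED_DIFF_MARGIN = 30.0
# minimum baseline RPKM for expressed categories (enhanced_down needs more
# headroom: the 0.1 floor must not erase the planted down-difference)
_BASELINE_MIN = 2.0
_BASELINE_MIN_ENHANCED_DOWN = 4.0
# planted "no change": log2 fc uniform in (-1/4, 1/4), well inside the 2-fold ceiling
_NOCHANGE_LOG2_HALFWIDTH = 0.25
# not_expressed baseline ceiling, kept below the 0.5 gate for noise headroom
_SILENT_BASELINE_MAX = 0.4

DEFAULT_PROPORTIONS: dict[str, float] = {
    "specific_up": 0.10,
    "specific_down": 0.05,
    "enhanced_up": 0.05,
    "enhanced_down": 0.01,
    "unchanged": 0.69,
    "not_expressed": 0.10,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic count generator.

    ``nb_dispersion`` is the negative-binomial size parameter (larger =
    less overdispersed; ``inf`` = noise-free rounding of the mean).  The
    planted focal fold-change range applies to the category-defining
    direction; the planted reference range applies to the reference-tissue
    change of enhanced transcripts (which must reach the 2-fold ceiling so
    they fail the specific filter).
    """

    seed: int
    n_transcripts: int = 2000
    category_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    baseline_rpkm_log_mean: float = 2.0
    baseline_rpkm_log_sd: float = 1.0
    nb_dispersion: float = 50.0
    planted_focal_fc_range: tuple[float, float] = (6.0, 600.0)
    planted_reference_fc_range: tuple[float, float] = (2.5, 5.0)
    library_size_per_sample: int = 45_000_000
    transcript_length_range: tuple[int, int] = (500, 3000)
    tissues: tuple[str, ...] = TISSUES
    timepoints: tuple[int, ...] = TIMEPOINTS
    focal_tissue: str = "EP"
    reference_tissue: str = "SP"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")
        unknown = set(self.category_proportions) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown category label(s): {sorted(unknown)}")
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_proportions must sum to 1, got {total!r}")
        if any(p < 0 for p in self.category_proportions.values()):
            raise ValueError("category_proportions must be non-negative")
        if self.baseline_rpkm_log_sd < 0:
            raise ValueError("baseline_rpkm_log_sd must be non-negative")
        if not self.nb_dispersion > 0:
            raise ValueError("nb_dispersion must be positive")
        for name in ("planted_focal_fc_range", "planted_reference_fc_range",
                     "transcript_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} lower bound exceeds upper bound")
        if self.transcript_length_range[0] <= 0:
            raise ValueError("transcript lengths must be positive")
        if self.library_size_per_sample <= 0:
            raise ValueError("library_size_per_sample must be positive")
        props = self.category_proportions
        if (props.get("specific_up", 0) or props.get("specific_down", 0)) and (
            self.planted_focal_fc_range[0] < _FOCAL_THRESHOLD
        ):
            raise ValueError(
                "planted_focal_fc_range lower bound "
                f"{self.planted_focal_fc_range[0]} is below the specific "
                f"fold-change threshold {_FOCAL_THRESHOLD}"
            )
        if props.get("enhanced_up", 0) or props.get("enhanced_down", 0):
            if self.planted_reference_fc_range[0] < _REFERENCE_CEILING:
                raise ValueError(
                    "planted_reference_fc_range lower bound must reach the "
                    f"reference ceiling {_REFERENCE_CEILING} so enhanced "
                    "transcripts fail the specific filter"
                )
            if (
                self.planted_focal_fc_range[1] - self.planted_reference_fc_range[0]
                < _ENHANCED_DIFF
            ):
                raise ValueError(
                    "planted fold-change ranges cannot produce an enhanced "
                    f"difference of {_ENHANCED_DIFF} or more"
                )

    def quotas(self) -> dict[str, int]:
        """Exact per-category transcript counts by largest-remainder rounding."""
        raw = {c: self.category_proportions.get(c, 0.0) * self.n_transcripts for c in CATEGORIES}
        base = {c: int(math.floor(v)) for c, v in raw.items()}
        short = self.n_transcripts - sum(base.values())
        # ties broken by category order
        by_remainder = sorted(
            CATEGORIES, key=lambda c: (-(raw[c] - base[c]), CATEGORIES.index(c))
        )
        for c in by_remainder[:short]:
            base[c] += 1
        return base


@dataclass
class SyntheticTruth:
    """Planted category and fold-change profile per simulated transcript.

    ``table`` is indexed by transcript id with a ``category`` column and one
    ``fc_<tissue>_<t>h`` column per tissue/timepoint holding the intended
    linear up-ratio fold change versus baseline.
    """

    table: pd.DataFrame

    def counts(self) -> dict[str, int]:
        vc = self.table["category"].value_counts()
        return {c: int(vc.get(c, 0)) for c in CATEGORIES}

    def ids(self, category: str) -> list[str]:
        return self.table.index[self.table["category"] == category].tolist()


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def _nochange(rng: np.random.Generator, size: int) -> np.ndarray:
    return 2.0 ** rng.uniform(-_NOCHANGE_LOG2_HALFWIDTH, _NOCHANGE_LOG2_HALFWIDTH, size)


def generate_counts(config: SimulationConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Simulate a count matrix plus its planted truth table.

    Deterministic given ``config.seed``: the same config yields bitwise
    identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts
    quotas = config.quotas()
    post = [tp for tp in config.timepoints if tp != config.timepoints[0]]
    focal, ref = config.focal_tissue, config.reference_tissue
    flo, fhi = config.planted_focal_fc_range
    rlo, rhi = config.planted_reference_fc_range

    ids = np.array([f"T{i:05d}" for i in range(n)])
    categories = np.repeat(list(CATEGORIES), [quotas[c] for c in CATEGORIES])
    order = rng.permutation(n)  # interleave categories across the index
    categories = categories[order]

    lengths = rng.integers(
        config.transcript_length_range[0], config.transcript_length_range[1] + 1, n
    )
    baseline = np.exp(
        rng.normal(config.baseline_rpkm_log_mean, config.baseline_rpkm_log_sd, n)
    )

    # planted up-ratio fold change per (tissue, post timepoint)
    fc: dict[tuple[str, int], np.ndarray] = {
        (ti, tp): np.ones(n) for ti in config.tissues for tp in post
    }

    for cat in CATEGORIES:
        mask = categories == cat
        m = int(mask.sum())
        if m == 0:
            continue
        if cat in ("specific_up", "specific_down"):
            baseline[mask] = np.maximum(baseline[mask], _BASELINE_MIN)
            peak = _loguniform(rng, flo, fhi, m)
            peak_tp = rng.choice(post, m)
            for tp in post:
                at_peak = peak_tp == tp
                other = np.exp(rng.uniform(0, np.log(peak), m))
                focal_fc = np.where(at_peak, peak, other)
                if cat == "specific_down":
                    focal_fc = 1.0 / focal_fc
                fc[(focal, tp)][mask] = focal_fc
                fc[(ref, tp)][mask] = _nochange(rng, m)
        elif cat == "enhanced_up":
            baseline[mask] = np.maximum(baseline[mask], _BASELINE_MIN)
            ref3 = _loguniform(rng, rlo, rhi, m)
            focal3 = np.maximum(_loguniform(rng, flo, fhi, m), ref3 + _ENHANCED_DIFF_MARGIN)
            fc[(focal, 3)][mask] = focal3
            fc[(ref, 3)][mask] = ref3
            for tp in post:
                if tp == 3:
                    continue
                fc[(focal, tp)][mask] = 2.0 ** rng.uniform(0, 2, m)  # decaying elevation
                fc[(ref, tp)][mask] = _nochange(rng, m)
        elif cat == "enhanced_down":
            baseline[mask] = np.maximum(baseline[mask], _BASELINE_MIN_ENHANCED_DOWN)
            ref3d = _loguniform(rng, rlo, rhi, m)
            focal3d = np.maximum(_loguniform(rng, flo, fhi, m), ref3d + _ENHANCED_DIFF_MARGIN)
            fc[(focal, 3)][mask] = 1.0 / focal3d
            fc[(ref, 3)][mask] = 1.0 / ref3d
            for tp in post:
                if tp == 3:
                    continue
                fc[(focal, tp)][mask] = 2.0 ** rng.uniform(-2, 0, m)
                fc[(ref, tp)][mask] = _nochange(rng, m)
        elif cat == "unchanged":
            baseline[mask] = np.maximum(baseline[mask], _BASELINE_MIN)
            for ti in config.tissues:
                for tp in post:
                    fc[(ti, tp)][mask] = 2.0 ** rng.uniform(-0.5, 0.5, m)
        elif cat == "not_expressed":
            baseline[mask] = rng.uniform(0.0, _SILENT_BASELINE_MAX, m)
            # flat profile of 1 everywhere

    # expected RPKM -> expected counts -> NB draw
    length_kb = lengths / 1000.0
    lib_millions = config.library_size_per_sample / 1e6
    counts = {}
    rpkm_planted = {}
    for ti in config.tissues:
        for tp in config.timepoints:
            planted = baseline if tp == config.timepoints[0] else baseline * fc[(ti, tp)]
            rpkm_planted[sample_label(ti, tp)] = planted
            mean = planted * length_kb * lib_millions
            if math.isinf(config.nb_dispersion):
                counts[sample_label(ti, tp)] = np.rint(mean).astype(np.int64)
            else:
                size = config.nb_dispersion
                p = size / (size + mean)
                counts[sample_label(ti, tp)] = rng.negative_binomial(size, p)

    index = pd.Index(ids, name="transcript_id")
    count_df = pd.DataFrame(counts, index=index)
    matrix = CountMatrix(
        counts=count_df,
        lengths_bp=pd.Series(lengths, index=index, name="length_bp"),
        library_sizes=pd.Series(
            config.library_size_per_sample,
            index=count_df.columns,
            name="total_mapped_reads",
        ),
        tissues=config.tissues,
        timepoints=config.timepoints,
    )

    truth = pd.DataFrame({"category": categories}, index=index)
    for ti in config.tissues:
        for tp in post:
            truth[f"fc_{ti}_{tp}h"] = fc[(ti, tp)]
    truth["baseline_rpkm"] = baseline
    return matrix, SyntheticTruth(table=truth)


def planted_rpkm(config: SimulationConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Expected (noise-free) RPKM per sample implied by a truth table."""
    post = [tp for tp in config.timepoints if tp != config.timepoints[0]]
    base = truth.table["baseline_rpkm"]
    cols = {}
    for ti in config.tissues:
        cols[sample_label(ti, config.timepoints[0])] = base
        for tp in post:
            cols[sample_label(ti, tp)] = base * truth.table[f"fc_{ti}_{tp}h"]
    return pd.DataFrame(cols, index=truth.table.index)
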