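# Methods

## The classification procedure

The pipeline operates on a two-tissue (focal EP, reference SP) × four
timepoint (0, 3, 9, 24 h) expression grid with one pooled library per cell
of the grid — no within-condition replicates. All decisions are threshold
rules on RPKM ratios; there is no statistical model of counting noise in
the classifier itself, which is faithful to the design it implements and
the reason the simulator (below) exists to probe its noise robustness.

Stages, in order:

1. **RPKM** from counts, transcript lengths and per-sample total mapped
   reads. Library size means total mapped reads per sample; in simulation
   the nominal library size stands in for the mapped total.
2. **Floor** (default 0.1 RPKM): values below the floor are raised to it.
   Its only purpose is finite, non-explosive ratio denominators.
3. **Gate** (default 0.5 RPKM): a transcript is expressed in a tissue if it
   reaches the gate at ≥ 1 timepoint of that tissue; below the gate in all
   eight samples it is removed (`not_expressed`). Gating compares
   *pre-floor* values so the two rules stay parameter-independent; with
   floor < gate the choice is unobservable, and a property test asserts
   floor and gate commute.
4. **Fold changes** per tissue vs 0 h, linear and log₂, in both the
   up-ratio (t/0 h) and down-ratio (0 h/t) conventions. Tissues in which a
   transcript is not expressed carry a NaN sentinel (rendered "−" in
   reports); the sentinel is data, and all threshold comparisons against it
   are defined in the classifier, not here.
5. **Specific stage**: focal FC ≥ 5 at ≥ 1 considered timepoint, and
   reference change < 2 at *all* considered timepoints. "Reference change"
   is magnitude in either direction — max(up-ratio, down-ratio) — since a
   reference tissue moving 2-fold downward is as disqualifying as upward.
   Elimination triggers at reference FC ≥ 2 exactly (retention requires
   FC < 2); the boundary is configurable via `reference_fc_ceiling`.
6. **Enhanced stage**, only on transcripts excluded from stage 5:
   difference of linear 3-h fold changes, focal − reference, ≥ 25 (ties
   included). Sentinels enter the difference as 1.0 (no change) — specified
   for the reference tissue so that reference-silent transcripts are not
   penalised for stronger specificity, and applied symmetrically to the
   focal tissue (a focal-silent transcript then never qualifies, the only
   sensible outcome). The difference is computed on linear fold changes,
   never log₂.

Tie-breaks making the output a partition: a transcript passing the focal
filter in both directions (opposite-direction peaks at different
timepoints) is labelled by the up direction first, in both the specific and
enhanced stages. This is an arbitrary but deterministic convention; the
intermediate filter booleans in `ClassificationResult.table` preserve the
full information.

### Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `focal_fc_threshold` | 5 | minimum focal fold change (log₂ 5 = 2.3) |
| `reference_fc_ceiling` | 2 | reference change that eliminates (log₂ 2 = 1) |
| `enhanced_diff_threshold` | 25 | minimum linear FC difference at 3 h |
| `enhanced_timepoint` | 3 h | early-response contrast for the enhanced stage |
| `timepoints_considered` | {3, 9, 24} h | timepoints entering stage 5 |
| floor | 0.1 RPKM | ratio-denominator floor |
| gate | 0.5 RPKM | expressed / not-expressed boundary |

The exploratory screen variant is `focal_fc_threshold=2,
reference_fc_ceiling=1.2` (log₂ 1.2 = 0.26) — a parameterisation, not a
separate code path.

## The synthetic-data generator

The generator emulates the study design end-to-end so every downstream
stage is testable without any sequencing data: eight samples, 45 M reads
each (the experiment it models reported 42–48 M), transcript lengths
uniform on [500, 3000] bp, and a planted category per transcript with
quotas met *exactly* by largest-remainder allocation (never multinomial
sampling), so truth-table counts are deterministic.

Generative model: baseline expression is log-normal RPKM (meanlog 2.0,
sdlog 1.0, median ≈ 7.4 RPKM); each sample's expected RPKM is baseline ×
planted fold change; counts are negative binomial with mean =
RPKM × length_kb × library_millions and size parameter 50 (quadratic
dispersion coefficient 0.02 — modest overdispersion appropriate for deeply
sequenced pooled libraries where no biological replicate variance enters).
`nb_dispersion = inf` is the noise-free limit: counts are the rounded
means, and the only perturbation left is integer quantization.

Planted profiles are constructed to satisfy the category definitions with
guard bands, chosen once as follows:

* *specific_up/down*: focal peak fold change log-uniform on [6, 600] at a
  random timepoint (other timepoints log-uniform between 1 and the peak);
  reference fold changes 2^U(−0.25, 0.25) — genuinely "unchanged", well
  inside the 2-fold ceiling so near-boundary noise does not eliminate them.
* *enhanced_up/down*: reference 3-h fold change log-uniform on [2.5, 5]
  (≥ 2, which is what forces exclusion from the specific category); focal
  3-h fold change at least reference + 30, a 5-unit guard band over the
  25 threshold.
* *unchanged*: all fold changes 2^U(−0.5, 0.5).
* *not_expressed*: baseline uniform on [0, 0.4] — deliberately below 0.4
  rather than the 0.5 gate, so the planted intent survives moderate noise;
  the truth label records intent, and noisy-recovery tests tolerate
  gate-boundary crossings.

Baselines of expressed categories are clamped to ≥ 2 RPKM (≈ 90 expected
counts per kb), so recovery measures the classifier, not sequencing depth.
`enhanced_down` baselines are clamped to ≥ 4 RPKM: a strongly
down-regulated transcript's 3-h value can fall below the 0.1 floor, capping
the observable down-ratio at baseline/0.1, and the planted difference of
≥ 30 must survive that cap.

What the simulator does *not* emulate: read-level artifacts (no FASTQ,
mapping, multi-mapping or assembly noise), length biases beyond the RPKM
model, between-sample composition effects, and biological replicate
variance. A passing recovery test therefore shows the classification rules
are implemented correctly and are robust to counting noise of the stated
magnitude — not that the thresholds are biologically optimal, nor that
real libraries meet the NB(size 50) noise level.

## qPCR quantification

Mean-of-Ct convention: replicate Ct values are averaged per (gene, sample)
before ΔCt is formed (the alternative mean-of-normalized-expression
convention is out of scope). Efficiency defaults to 2.0 (perfect doubling)
since primer efficiencies are typically unreported; any value in (1, 2] is
accepted. SEM propagation is first-order through the exponent:
Var(ΔCt) = SEM²(target) + SEM²(reference), Var(ΔΔCt) adds the calibrator
term, SE(expr) = ln E × expr × SE(ΔΔCt). A single-replicate group yields a
NaN SEM, never zero. The concordance report compares the sign of the
0 → 3 h change per tissue between platforms; exact no-change counts as
sign 0, so two flat profiles agree while flat-vs-up does not.

## Numerical and I/O choices

* All ratios are computed on floored linear RPKM; log₂ values are derived
  from the linear ratio, never computed independently.
* Reports round log₂ fold changes to one decimal and linear fold changes
  to integers; rows sort by 3-h focal fold change descending, ties by
  transcript id; the sentinel renders as "−". Down-regulated categories
  print the focal column in the down-ratio convention (positive
  magnitudes) with the reference column as signed up-ratio log₂.
* Readers reject duplicate ids (reporting both line numbers), missing
  sample columns (by name), non-numeric cells (by line) and the literal
  token `NA`; `#` lines are comments, used by writers to echo the seed.
* RPKM writers use 17-significant-digit formatting so write → read
  round-trips are bit-identical.
* Timepoints default to (0, 3, 9, 24) h with the first entry as baseline
  but are carried as data throughout, since nothing in the procedure is
  specific to those values.

## Problem sizes

Recovery checks use 1000 transcripts for the noise-free quota test and
20 seeds × 500 transcripts for the noisy regression (strongly planted
specific-up, peak FC ≥ 10, recovery > 95%); oracle-equivalence tests
compare the vectorised classifier against an independent straight-line
per-transcript rule evaluator on 300–500 transcripts. These sizes give
stable rates (≈ 900 strong planted transcripts in the noisy regression)
while keeping the whole suite fast.

## Known limitations

* With one library per condition the classifier cannot distinguish
  biological change from library-level noise; the thresholds are the
  design's only guard, which is exactly why the simulator reports recovery
  rates rather than error-controlled calls.
* The enhanced stage contrasts 3 h only; regulation that diverges between
  tissues later in the time course but fails the specific filter is
  reported as unclassified.
* The boundary behaviour at exactly 2-fold reference change follows the
  strict elimination reading; sources differ on this convention, so it is
  exposed as a parameter rather than hard-coded.
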