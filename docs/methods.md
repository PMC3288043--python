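# Methods

## Screen model and conventions

The screen operates on a replicate-free 2×2-factor design: four cell lines
(two HER2-positive, two HER2-negative) × {treated, control}, one array per
condition. All fold-change arithmetic is done in log2 space. The published
relative-fold-change definition subtracts "the average fold change in the
negative lines" from the positive-line fold change; we interpret both the
subtraction and the average in log2 space, so on the linear scale the RFC is
the positive-line fold change divided by the *geometric* mean of the
negative-line fold changes. Two observations force this reading: the ranked
down-regulated entries are positive ratios in (0, 1), which a linear
subtraction cannot produce, and the cross-line combined column is exactly
reproduced (to the printed 4 decimals) by the geometric mean of the two
per-line values, e.g. √(2.4300 × 3.5825) = 2.9505. One ranked entry
(combined value 2.1640) recomputes to 2.1639 from its printed 4-decimal
inputs; we attribute this to rounding of unprinted full-precision values and
treat the geometric-mean rule as exact.

Thresholds are strict (the rules say "more than"): a fold change of exactly
1.5 is *not* a response in the exclusion step, and an RFC of exactly 1.5
is not listed. The expression floor uses the "either condition" reading —
a line passes when max(treated, control) > 6 in log2 — because the rule
says "before or after" exposure; the stricter both-conditions variant is
available via `ScreenCriteria.expression_rule`. Cross-line lists admit a
miRNA whose geometric-mean RFC passes the threshold even when one per-line
RFC does not, matching the published table's structure (combined entries
exist without a second per-line entry).

Quantile normalization replaces each column rank-wise with the across-column
mean of sorted values; ties receive the mean of the tied ranks' target
values, making the result independent of tie order. Raw intensities ≤ 0
(background-subtracted medians can be negative) are clipped to ε = 1 before
log2, with the clip count logged. Replicate arrays, when present, are
averaged in log2 space before fold-change computation.

Hierarchical clustering of samples uses 1 − Pearson correlation and average
linkage; a zero-variance column (undefined correlation) is assigned distance
1 to every other column, with a warning.

## Synthetic arrays

`simulate_array` draws per-miRNA log2 baselines from N(9, 1.5²) (floored at
6.5 so "expressed" probes sit clearly above the log2-6 filter), assigns a
configurable fraction (default 0.3) baselines uniform on (2, 5) — below the
floor in all samples — and forms each sample as
2^(baseline + effect·1[treated] + N(0, σ_noise)), σ_noise = 0.1 by default.
Noise additive in log2 (log-normal linear) matches the pipeline's log2
workflow and keeps fold-change noise symmetric. Planted treatment effects
are specified per (miRNA, line) and restricted by the caller (the default
scenario plants +1.2 log2 in the HER2-positive lines only); planted miRNAs
are never assigned to the low-expression subset, since an effect on an
unexpressed probe is unmeasurable. Defaults mirror the study conditions:
4 lines × 2 treatments, n = 1 array per condition (the screen as published
is replicate-free; a replicate count is exposed as a parameter), 200 miRNAs.
The generator does not model spatial artifacts, dye bias, probe
cross-hybridization, or inter-miRNA correlation — so passing recovery tests
demonstrates correctness of the screening arithmetic under the stated noise
model, not robustness to real array artifacts.

Because quantile normalization forces every column onto the pooled empirical
distribution, a planted shift is slightly compressed (≈ 2.28 observed vs the
ideal 2^1.2 ≈ 2.30 at 200 features); tests allow for this.

All simulators derive their random streams from one integer seed via
`numpy.random.SeedSequence` with a fixed per-assay key (CRC32 of the assay
name), so outputs are bit-reproducible and adding one simulator call never
perturbs another's draws.

## Assay estimators

**ΔΔCq.** ΔCq = mean target Cq − mean over references of the per-reference
mean Cq (arithmetic averaging of reference Cq means = geometric mean of
reference quantities, the standard multi-reference rule); ratio =
E^(−ΔΔCq) with amplification efficiency E fixed at 2, since no
efficiency-corrected quantification is involved.

**WST-1.** Replicate absorbances are averaged before the treated/control
ratio is formed (the alternative — averaging per-replicate ratios — differs
only at second order for the CVs involved); inhibition = 100·(1 − ratio);
the cross-line summary is the arithmetic mean of per-line percentages
(56% and 24% average to the headline 40%).

**Cell cycle.** The proprietary histogram-deconvolution model of commercial
flow software is replaced by a stated three-component mixture: G1 ~ N(µ, σ),
G2/M ~ N(2µ, σ·b) with the G2/M mean constrained to 2µ, and S the uniform on
(µ, 2µ) convolved with N(0, σ) — the simplest bridge shape the fit can
identify. Fitting maximizes the multinomial likelihood over histogram bins
(Nelder-Mead on µ, log σ, log b and two mixing logits; fractions via
softmax). Initialization puts µ at the histogram mode with CV 5%; a second
start at half the mode guards against the mode being the G2/M peak. A
unimodal histogram is explained equally well by "all G1 at µ" and "all G2/M
at µ/2"; among optima within 2 log-likelihood units the fit takes the one
with the larger G1 weight, anchoring G1 at the observed peak (the usual
convention). Fits require ≥ 100 events and ≥ 2 occupied bins.

**Annexin-V.** The quadrant gate on two-color staining is reduced to a
single fixed intensity threshold; the estimate is the fraction of events
above it. The simulator draws positivity Bernoulli(p) with well-separated
log-normal intensity modes (medians 10 and 1000, gate at 100), so threshold
placement is not the quantity under test.

**Dual luciferase.** Normalized activity = firefly/renilla per replicate;
percent repression = 100·(1 − mean(miR)/mean(ncRNA)); the p-value is the
unpaired t-test on normalized activities. The estimator is invariant to
rescaling all renilla values by a common factor. In the simulator the two
seed sites act multiplicatively, each contributing √(1−r), so the wild-type
construct represses by r, single-site mutants by 1−√(1−r), and the double
mutant by 0; only the wild-type and double-mutant expectations are
externally constrained — the single-mutant split is a modeling choice.
Measurement noise is mean-1 log-normal with the configured CV.

**t-test.** Pooled-variance Student t (not Welch), df = n₁+n₂−2, two-sided
p from the t distribution; α = 0.05. Zero pooled variance degenerates to
t = 0, p = 1 for equal means and the p → 0 limit (flagged) otherwise.

## Seed matching

Seed = miRNA nt 2–8 (7 nt). Site types follow the canonical taxonomy: 8mer
(reverse complement of nt 2–8 followed by A opposite nt 1), 7mer-m8,
7mer-A1, 6mer. Only the sense strand is scanned (mRNA context); U and T
encodings are unified. At a locus only the maximal type is reported:
lower-grade candidates contained in an accepted higher-grade interval are
suppressed. Mutant constructs substitute 3 transversions (A↔C, G↔U fixed
map) at deterministic rng-chosen positions within the seed-pairing region,
re-drawing (bounded retries) until a rescan finds no site of any type
overlapping the disrupted locus; untouched sites are preserved. No
thermodynamic scoring, conservation, or 3′-supplementary pairing is
attempted — the module localizes candidate sites; it is not a target
predictor. Since the true reporter-construct coordinates and mutated bases
are not public, mutant semantics are exercised on synthetic two-site UTRs
(labelled `synthetic-CCNE2`).

## Problem sizes and numerical tolerances

The validation suite uses: 200 miRNAs × 8 samples × 100 seeds for screen
recovery (sensitivity ≥ 0.95, mean false positives ≤ 1 on the cross-line up
list); 50 random ≤ 10-feature instances against a brute-force straight-line
reimplementation of the four rules (set equality, RFC values to 1e-9);
10,000-event histograms for cell-cycle recovery (±0.02 per fraction, ±0.03
on the G1 shift of the 0.65→0.91 pair); 500 seeds × 3 replicates at CV 0.05
for the luciferase estimator (mean within 2 percentage points of the true
27%); 100 random 1-kb UTRs against the regex oracle; 1,000 null pairs for
t-test calibration (type-I error 0.05 ± 0.02). Published cross-line RFC
aggregates are reproduced to the printed 4 decimals from the printed
per-line pairs. These sizes keep the full suite under a few minutes on one
CPU while leaving the Monte-Carlo bounds comfortably away from their
thresholds.

## Known limitations

- The screen is threshold-based and replicate-free by design; no
  differential-expression statistics, batch correction, or background
  modeling beyond clipping are provided.
- The cell-cycle mixture is a simplification of commercial deconvolution
  models (no aggregates/debris terms, no sub-G1 population).
- The ΔΔCq estimator assumes a common amplification efficiency of 2 for all
  targets and references.
- Generator realism is limited to what the estimators assume; see the
  synthetic-arrays section.
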