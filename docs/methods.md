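# Methods

## Problem setting and assumptions

The pipeline treats cognition as a slowly varying per-subject latent
quantity observed twice (baseline and post-intervention composite z-scores)
and asks whether nocturnal physiology measured at the wrist carries
information about it. Three assumptions shape the design:

* **Short-term cognitive change is smooth and monotone.** Between two
  assessments ~10 weeks apart, change is interpolated rather than modeled;
  the default interpolant is a sigmoid (change plateaus), with linear and
  random imputation kept as comparators to measure how much the choice
  matters.
* **Only calm, resting measurement is comparable across days.** HRV
  guidance favors resting recordings; the pipeline therefore restricts to
  the contiguous 5-hour night window with the lowest pooled population mean
  HR (selected from a 21:00–09:00 candidate span on a 5-min grid, ties to
  the earliest start), rather than hard-coding clock hours.
* **Between-subject differences dominate within-subject change.** Hence the
  dual analysis: the uncentered dataset measures subject-level prediction;
  the centered dataset (features minus per-subject medians, outcomes minus
  the half-range (y0+y1)/2 of the two assessments) isolates intra-individual
  change.

## Signal processing choices

**Segmentation.** Samples are snapped to the channel's nominal-rate grid by
nearest timestamp (coincident hits averaged); 5-min windows anchor at local
midnight. Coverage is evaluated *before* gap interpolation (repair cannot
create validity), and only interior NaN runs strictly shorter than 30 s are
filled linearly; runs touching a window edge have no flank and stay missing.
Thresholds are inclusive: ≥ 50% (HR, temperature), ≥ 70% (EDA, PPG),
beat-count agreement within ≤ 10% of the HR-implied count.

**PPG beat detection.** Two-moving-average block detection: order-2
Butterworth band-pass 0.5–8 Hz (zero-phase), negative clipping, squaring;
peak window 111 ms, beat window 667 ms, threshold offset β = 0.02 of the
mean squared signal; blocks at least one peak-window wide contribute the
filtered-signal maximum as the beat. On synthetic pulse waveforms with the
default noise the detector recovers > 99% of planted beats within ±50 ms
(asserted in tests).

**HRV.** SDNN/SDSD use the sample SD (ddof = 1); pNN50/pNN20 thresholds are
strict (> 50/> 20 ms). Spectral features interpolate the tachogram cubically
to 4 Hz, detrend linearly, and use Welch PSD (120-s Hann segments, 50%
overlap) with trapezoidal band integration; LF 0.04–0.15, HF 0.15–0.40, VHF
0.40–0.50 Hz (the literature's conventional edges). Inside the Poincaré
identity SD1² + SD2² = 2·Var(NN) the variances are population variances;
SD2² is floored at zero and ratio features are reported missing when either
axis degenerates. Heart-rate-asymmetry partitions (SD1d/SD1a, SD2d/SD2a,
C1d/C1a, Guzik, Porta) use signed distances to/along the identity line;
fragmentation indices (PIP, IALS, PSS, PAS) operate on the sign sequence of
successive differences (PIP = % sign changes; IALS = inverse mean run
length; PSS = % of differences in runs shorter than 3; PAS = % in
alternation runs of length ≥ 4). Intervals outside (200, 3000) ms are
dropped before any HRV computation.

**EDA.** Denoising: order-4 Butterworth low-pass at 1 Hz. The tonic level is
a second-order *zero-phase* low-pass at 0.05 Hz realized as a first-order
Butterworth run forward-backward: the combined kernel has real poles and is
strictly positive, so the tonic estimate cannot overshoot — an order-2
filter applied the same way rings after each response and injects spurious
phasic rebounds that double-count SCRs. SCRs are phasic local maxima at
least 0.01 µS above zero and at least 0.01 µS above the preceding trough.
The sympathetic index integrates the phasic Welch PSD over 0.045–0.25 Hz
(normalized variant divides by 0–0.5 Hz total).

**Catalogue sizing.** The registry carries 45 HRV names per beat source
(PPG and IBI), 13 EDA, 14 HR (summary statistics plus band powers of the
continuous HR signal), and 6 temperature names — a superset of the grouped
counts the analysis needs, under common HRV nomenclature. Post-pruning
feature counts are emergent, data-dependent quantities, not contracts.

## Aggregation and outcomes

Pipeline order is fixed: IBI-availability filter → night window → nightly
medians (≥ 4 valid windows per night; a window wrapping midnight books to
the date it starts) → 10-day interval means → redundancy pruning (greedy,
registry order, drop at r² ≥ 0.95, zero-variance columns first). Intervals
anchor at each subject's first observed night. Pruning operates on the
interval-level matrix, keeping the analysis dataset compact and the kept
list deterministic.

The Gompertz interpolant is re-normalized to pass exactly through both
assessments, with shape parameters b = 3, c = 4 by default (midpoint
fraction g(½) ≈ 0.688 — change front-loaded then plateauing); endpoint
exactness is the property the design depends on, the shape is a knob.
Random imputation draws interior values uniformly from the closed envelope
between the two scores — a null that preserves endpoints while destroying
trajectory structure; the test suite verifies it attenuates feature–outcome
correlations relative to the sigmoid. The "dataset without imputation" used
for the concordance check consists of the first and last intervals, whose
values equal the actual assessments.

## Association and prediction

BH-FDR is applied across all outcome–feature pairs within one dataset
variant, separately per statistic; significance requires *both* adjusted
p-values strictly below 0.05. Mixed models are random-intercept fits (REML,
normal-approximation slope inference) with fixed-effect
R² = Var(βx)/(Var(βx) + σ²_subject + σ²_resid); non-converged pairs are
flagged and excluded from the FDR family.

Feature selection runs **inside each training fold** (the only leakage-free
reading of per-threshold selection); a guard raises if fold index sets
overlap, if a held-out subject/interval key appears in training rows, or if
pooled predictions do not cover each row exactly once — and a test injects
each violation to prove the guard fires. Fixed hyperparameters (no tuning):
elastic net α = 0.05, l1_ratio = 0.5 with training-fold standardization;
random forest 500 trees; gradient boosting 300 rounds, depth 3, learning
rate 0.1. Sex is encoded female = 1, male = 0. Thresholds default to
{0.05, 0.001, 0.0001, 0.00001}; the grid per outcome and scheme is 4 × 3
combined models plus the demographics baseline (and optionally
physiology-only variants). When a baseline's predictions are constant its
correlations are undefined and gains are computed against 0. Best model =
highest pooled Pearson r, ties to fewer features then the elastic net.

## The synthetic generator

The generator emulates a night-wear protocol: per wear night it renders one
beat-interval series (interval(t) = mean RR + LF·sin(2π·0.10t) +
HF·sin(2π·0.25t) + jitter) into a 64-Hz pulse waveform whose template
maximum lands on the beat time, device-style beat events from the same
series, a 1-Hz HR channel that follows the instantaneous beat rate inside
the wear block with elevated padding outside (so the calmest-window search
lands on the block), EDA with tonic drift and Poisson-timed Bateman SCRs,
and slowly varying temperature. Defaults: 17 subjects, 70 days, 2 wear
nights per 10-day interval, 4 five-min windows per night starting 01:00;
mean RR 850 ms, LF 20 ms, HF 25 ms, jitter 10 ms, tonic 1.5 µS, SCR rate
2/min, temperature 33.5 °C — resting-night values for older adults, fixed
up front. Cognitive trajectories are Gompertz sigmoids between per-subject
baseline (N(−0.8, 0.5)) and post (baseline + N(0.25, 0.35)) scores with
interior noise SD 0.05; by default the HF amplitude is linear in the latent
executive-function score with slope 12 ms per z-unit. Determinism is
hierarchical (`SeedSequence` spawning per subject/night); the same master
seed reproduces the dataset tree byte-for-byte.

What the generator does *not* emulate: motion artifacts beyond additive
noise, respiration, realistic PPG morphology changes, device-firmware
quirks, or a realistic missing-data mechanism (non-wear is whole missing
nights). Passing tests therefore demonstrate that the pipeline recovers
planted structure through its own processing chain — not that real MCI
cohorts carry signals of this strength.

## Problem sizes and numerical notes

End-to-end checks run at sizes chosen to keep the default suite fast while
preserving the statistics they assert: the headline demo uses 17 subjects ×
70 days; multi-seed coupling recovery uses 6-subject cohorts (5 seeds,
median best-combined LOSO r-gain ≥ 0.3 and median LOIO ≥ LOSO); null
cohorts keep 17 subjects (the null distribution of pooled LOSO r scales
with subject count, not row count) with one wear night per interval
(5 seeds, median over the 12 combined models' |r| < 0.25, no FDR-significant
pairs). Degenerate inputs are reported as missing with reason codes rather
than raising: constant predictions (undefined correlations), zero-variance
features, too-few beat intervals, missing HR for the consistency check.
Welch segment lengths shrink to the signal when a window is shorter than
120 s. Tie-breaks are everywhere deterministic (earliest window, registry
order, fewer features, algorithm order).

## Known limitations

Gompertz shape parameters are not identifiable from two observations and
are fixed, not fitted. The tachogram PSD ignores power above 0.5 Hz, so
total power is a band total, not the full variance, for heavily jittered
series. The mixed-model R² is the declared variance ratio above, one of
several conventions. Interval anchoring at first observation can shift a
subject's intervals by up to 9 days relative to study time when early
nights are missing.
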