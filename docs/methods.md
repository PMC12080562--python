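# Methods

This note documents the models and procedures `dyskpipe` implements, the
defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical decisions made where the underlying
experimental convention leaves the implementation open.

## Behavior

**AIM scoring.** Abnormal involuntary movements are scored on the ALO
scale: axial, limb and orofacial subscores, each an integer 0–4, summed to
a per-timepoint total of at most 12.  The package validates ranges and
aggregates; the 0–4 anchor definitions themselves are observer judgments
and out of scope.  `bin_aim` averages totals in fixed bins and reports
bins without any scored timepoint as missing (NaN).  They are never
interpolated: dyskinesia is typically scored only every other minute
during recordings, and the firing-rate correlation downstream must use
scored minutes only.

**Rotations.** `detect_rotations` smooths the unwrapped heading with a 1-s
moving average (odd-reflection padding, so linear drift at the trace ends
is preserved), then decomposes it into monotone runs.  A run of angular
extent L contributes ⌊L / 90°⌋ quarter turns in its direction — the
rotometer convention in which progress is measured from the last turning
point, so any direction reversal resets the partial count.  This makes the
counts exactly antisymmetric under time reversal (contralateral and
ipsilateral swap), a property the tests verify.  Whether commercial
video-tracking counts heading or body-axis crossings is not standardized;
the heading convention here is a documented choice, and the 1-s smoothing
window suppresses jitter turns without affecting 90° excursions at
behavioral timescales.

## In vivo unit classification

Units must have sorted spike times and no interspike interval below 1 ms
(the spike-sorting validity criterion); violating trains are rejected at
construction.

**Drug-response class.** Firing rate is averaged in 1-min bins.  The
30-min pre-injection baseline is compared to the 10–40 min post-injection
window with a two-sided Wilcoxon rank-sum (Mann–Whitney) test at
α = 0.01.  Below 20 bins per group the exact null distribution is used;
above, the normal approximation with tie correction and *without*
continuity correction — at 30 bins per group that keeps the achieved
type-I error near the nominal 1% (measured ≈ 1% on 1000 null units),
whereas the continuity-corrected version is noticeably conservative.
Direction (On vs. Off) is decided by the median difference; a significant
test with a zero median difference, and all non-significant outcomes,
yield NC.

**Waveform class.** A unit is called an interneuron only when both
features fall strictly below their thresholds (defaults: peak width
< 150 µs and peak-to-valley < 500 µs, both configurable); boundary
equality classifies as MSN.  The defaults are conventional values for
striatal extracellular recordings at 40 kHz; they matter only through the
IN/MSN split and are exposed in `WaveformThresholds`.

**PSTH and optotagging.** The laser PSTH uses 1-ms bins over
[−500, +200] ms around pulse onset.  The baseline confidence bound is
Poisson: pooled spike counts per 1-ms bin over the 500 ms before onset
give a mean count m, and the bound is the 99.5th percentile of
Poisson(m) — the upper edge of a two-sided 99% interval.  Identification
requires all three of:

1. the PSTH (after 3-ms boxcar smoothing) first exceeds the bound at a
   latency ≤ 15 ms after onset;
2. it stays above the bound for ≥ 15 consecutive ms from that crossing;
3. laser-evoked waveforms are indistinguishable from spontaneous ones.

The baseline window length and the smoothing are implementation choices:
500 ms of baseline gives a stable Poisson mean at the 1000-pulse design,
and "above threshold for at least 15 ms" is read as consecutive
milliseconds on the smoothed histogram (the raw 1-ms histogram of a
bursting unit dips below threshold in single empty bins that smoothing
bridges).  With these defaults the identified fraction on uncoupled 2-Hz
Poisson units is far below 2% — criterion 1 alone would fire on a few
percent of null units (15 chances at the 0.5% tail), and the 15-ms
duration requirement is what removes them — while synthetic tagged units
(5-ms latency, 0.9 spike probability, 20-ms evoked burst) are identified
at ≥ 95%.

**Waveform similarity (criterion 3).** Pooled spontaneous and evoked
waveforms are projected onto their first two principal axes — mirroring
the PCA space in which units are sorted — and each axis gets a Welch
two-sample test with Bonferroni correction at α = 0.01.  The unit passes
when no axis is significant.  Which statistical test the original
workflow used is not recorded; a location test on the dominant PCA axes
is the natural formalization and calibrates correctly (pass rate ≈ 1 − α
on bootstrap-null pairs).

**Dyskinesia correlation.** Ordinary least squares of the 1-min firing
rate on the 1-min AIM total, over scored minutes only (≥ 10 required).
R² > 0.30 (strict) classifies DYSK; otherwise on-unclassified.  The
classification deliberately uses the R² threshold alone, with no
additional significance test on the regression — whether the original
rule included one is ambiguous, and the output carries the R², slope and
minute count so users can re-threshold.  Zero AIM variance leaves R²
undefined and classifies ON with a warning.

## Slice electrophysiology

All sweep analyses assume uniformly sampled traces (10 kHz default,
matching 2-kHz-filtered, 10-kHz-digitized acquisition).  PSC amplitudes
are |extremum − baseline| with a 2–50 ms post-stimulus search window, a
−10 to −1 ms baseline window and a 1-ms artifact blanking period that the
search window may not enter.

**PPR.** EPSC₂/EPSC₁ per repetition, then the per-ISI PPR is the mean of
repetition ratios (5–8 repetitions recommended).  Mean-of-ratios was
chosen over ratio-of-averaged-traces because it composes with
per-repetition dropout (repetitions whose EPSC₁ is below a 3-robust-SD
noise floor are dropped and logged); the alternative convention is noted
as unresolved in the literature and differs only at second order here.
At ISIs short relative to the EPSC decay, EPSC₂ rides on the tail of
EPSC₁; the tail is fit log-linearly just before the second stimulus and
subtracted before measuring, which makes the zero-noise PPR exact at all
ISIs rather than biased by up to ~2% at 25 ms.  When the tail is within
the noise floor the correction is skipped.

**AMPA:NMDA.** Traces are averaged per holding potential; AMPA is the
peak of the averaged inward EPSC at −70 mV, NMDA the baseline-subtracted
mean of the averaged +40 mV trace over a 1-ms window centered 50 ms after
the stimulus.  A near-zero NMDA readout flags the ratio undefined (NaN)
rather than returning an unstable number.

**mEPSC detection.** No detection algorithm is standardized for this
preparation, so the detector is a deliberately auditable stand-in:
the trace is referenced to a 51-ms rolling-median baseline, the noise
scale σ is the MAD-based robust SD of the raw residual, and events are
local extrema of the 3-ms-boxcar-smoothed residual exceeding k·σ
(default k = 4) with at least half that prominence and 5 ms separation.
Thresholding the *smoothed* trace in units of the *raw* noise SD makes
baseline false events essentially impossible (the smoothed noise SD is
~5-fold smaller), and the prominence requirement prevents noise riding an
event's decay tail from double-counting; the effective detection floor is
k·σ (8 pA at 2 pA noise), well below typical 20–30 pA miniature events.
Template-matching detectors are out of scope.  Summaries apply the
≥ 500-event inclusion rule exactly and build cumulative amplitude
distributions from 500 seeded-random events.

**Excitability.** Spikes in current clamp are upward 0-mV crossings with
a 2-ms refractory — adequate for the synthetic leaky-integrate-and-fire
traces and for healthy spike waveforms; a dV/dt criterion can be
substituted via the threshold parameter.  The excitability curve counts
spikes during each 100–600 pA step (100-pA grid) and rheobase is the
smallest step with ≥ 1 spike, NaN-flagged when no step spikes.

## Connectivity

Brains qualify only when strictly less than 15% of starter cells lie
outside the striatum (15/100 fails, 14/100 passes).  Relative number is
the presynaptic count under a region divided by the number of co-infected
striatal starter cells; relative proportion divides by the total
extra-striatal presynaptic count, so proportions over a partition of
extra-striatal regions sum to 1 exactly.  Region counts aggregate upward
through a parent-child ontology; the packaged ontology is a ~25-acronym
miniature of the striatal input map (motor and somatosensory cortex,
thalamic nuclei, GPe, STN, SNc, …) sufficient for analysis and testing —
users with atlas-registered data supply their own ontology CSV in the
same schema.  Group aggregation reports mean ± SEM and n per group and
compares three conditions with Kruskal–Wallis plus post hoc Tukey HSD, or
two groups with a rank-sum test; p-values are reported, never
thresholded.

## Expression

Per-cell probe intensities are normalized in two steps: cell
normalization (intensity sum / area) and slice normalization (division by
the mean over the slice, or the slice × subregion unit), after which the
group mean is exactly 1 — an invariant asserted to machine precision.
TRAP flags come from the cell-normalized tdTomato channel against a
per-slice threshold (90th-percentile rule by default, fixed override
available; strictly-greater comparison), restricted to D1-positive cells.
D1-positivity itself is consumed as an input flag: the original
segmentation thresholds were adjusted per slice by hand and no rule is
recoverable.  TRAPed vs. unTRAPed comparisons are paired at the slice
level — the per-slice mean of each class enters a Wilcoxon signed-rank
test with n = slices, matching how such data are reported — and
subregion-level tests are Bonferroni-corrected across the three
subregions.  Slices missing one class are dropped and logged; at least 6
paired slices are required.

## Synthetic data

The generator reproduces the acquisition design: a 30-min parkinsonian
baseline, levodopa injection, 90 min of post-injection recording, AIMs
scored every other minute, and a tagging epoch of 100-ms laser pulses at
1 Hz (1000 pulses per power at 0.5/1/2/4 mW) appended after the
behavioral session.

- **Rates.** Units are inhomogeneous-Poisson with piecewise-constant
  1-min rates: 2 Hz baseline (8 Hz for interneurons, which fire faster),
  multiplied post-injection by the class gain (On ×5, Off ×0.2, NC/IN ×1).
  Baseline firing statistics of TRAPed units are not constrained by any
  reported value ("comparably low" is all that is known), so the 2-Hz
  default is a free parameter shared across classes.  The default class
  mix is 40% On / 30% Off / 25% NC / 5% IN.
- **Dyskinesia coupling.** A latent trajectory in [0, 1] rises with a
  3-min onset, decays over ~2 h and carries a 20-min sinusoidal
  fluctuation.  DYSK units (half of the On units by default; these are
  also the TRAPed/tagged units) add b·(latent − mean) to their
  post-injection rate, with b calibrated analytically by
  `coupling_for_r2` so the regression of 1-min binned rate on the latent
  has a chosen construction R² (0.6 for DYSK, 0.05 for ON) given Poisson
  counting noise.  AIM discretization noise attenuates the observed R²
  slightly below the construction target.
- **AIMs.** Each subscore is round(4 · clip(latent + ε, 0, 1)) with
  independent Gaussian ε (SD 0.05) — the cheapest monotone map onto the
  0–4 ordinal scale.
- **Tagging.** Tagged units emit, per pulse, a first spike at 5 ms latency
  with 1 ms jitter and probability 0.9, plus a Poisson burst at 150 Hz
  over the following 20 ms.  A 1-ms refractory period is enforced by
  greedy deletion (thinning) rather than a renewal process, keeping the
  rate calibration simple at these rates (≤ 0.2% of spikes removed at
  2 Hz).
- **Waveforms.** Parametric biphasic templates (MSN: ~700 µs
  peak-to-valley, ~250 µs width; IN: ~300/100 µs) plus white noise, at
  the 25-µs sample period of 40-kHz acquisition.  Extracellular waveform
  realism beyond these two features is a non-goal.
- **Tracking.** Constant-speed motion (4 cm/s) in a 25-cm arena whose
  heading drifts at a configured revolutions-per-minute bias plus white
  angular noise, radially clipped at the wall.
- **Counts and cells.** Region counts are negative-binomial (dispersion
  10; Poisson as a limit) around editable per-region means with
  multiplicative condition effects.  Cell tables draw lognormal
  intensities with per-slice staining factors (SD 0.3 in log units); the
  TRAP fraction is 10%, TRAPed cells get per-probe enrichment folds and a
  5× brighter tdTomato channel.
- **Sweeps.** PSCs are unit-peak double-exponential kernels (1 ms rise,
  8 ms decay for fast/AMPA events — placing the peak inside the 2–50 ms
  search window — and 2/50 ms for the slow +40 mV component, scaled so
  its value at 50 ms equals the configured NMDA amplitude).  Current
  steps drive a leaky integrate-and-fire neuron (rest −80 mV, threshold
  −45 mV, τ 12 ms) whose input resistance is derived from a designed
  rheobase on the 100-pA grid; lowering the threshold at fixed input
  resistance emulates a D1-agonist excitability shift.

What passing tests on these data do **not** show: robustness to rate
drift and non-Poisson firing, electrode artifacts, overlapping mEPSCs and
series-resistance changes, atlas-registration error, or segmentation
error in cell tables.  The generator's role is to verify the analysis
logic against known ground truth, not to certify performance on recorded
data.

## Problem sizes and determinism

Calibration suites use 1000 uncoupled units (1000 pulses each) for the
optotag false-positive rate, 200 tagged units for the true-positive rate,
1000 null units for the drug-response type-I error, 100 + 100 units for
DYSK/ON recovery, 200 seeded runs of 30 slices for expression power and
null calibration, and 100 random instances for each oracle-equivalence
check.  Every generator call takes a single seeded
`numpy.random.Generator`; identical configurations produce byte-identical
outputs, and `scripts/acceptance.py` derives all of its randomness from
the `--seed` argument.
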