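# Methods

This note documents the models, parameters and design choices behind
`gammacc`: what the pipeline computes, what the synthetic cohort emulates,
and what passing tests do and do not establish about real recordings.

## Montage

The packaged 10-10 layout has 64 electrodes; scalp coordinates are the
azimuthal equidistant projection of standard spherical positions, scaled
to the unit square, and are used only for the optional scalp plot.

The bipolar montage pairs immediate grid neighbors and is shipped as
versioned data (`data/bipolar_pairs.tsv`) rather than recomputed from
geometry, so the pair set can never drift between releases. The scheme:

* within-row adjacent pairs, excluding the three pairs that straddle a
  midline grid position absent from this cap (Fpz, AFz, FCz) — electrodes
  flanking an unoccupied grid site are not immediate neighbors;
* same-column pairs between adjacent coronal rows;
* sixteen nearest-diagonal pairs where an electrode has no same-column
  partner in the adjacent row.

This yields exactly 112 pairs (52 + 44 + 16) and contains the nine
analysis pairs used for band statistics, grouped left
(PO3-P1, PO3-P3, POz-PO3), right (PO4-P2, PO4-P4, POz-PO4) and midline
(Oz-POz, Oz-O1, Oz-O2). Pair names put the more posterior (between rows)
or more medial (within a row) electrode first; the signal contract is
anode minus cathode, sample-aligned. A bipolar pair is bad as soon as
either constituent electrode is bad.

## Spectral estimation

All spectra are multitaper estimates with a single Slepian taper at
time-bandwidth product 1 — the minimal-taper setting of the classic
electrophysiology toolboxes; the taper count and NW are configurable. The
500 ms analysis windows (baseline −500–0 ms, stimulus 250–750 ms re
onset) give a 2 Hz grid; the moving-window spectrogram (250 ms window,
25 ms step) gives 4 Hz. At 500 samples/s a 25 ms step is 12.5 samples, so
window starts are placed at `round(k·fs·step)`: successive spacings
alternate 24/26 ms with mean exactly 25 ms.

ΔPower sums absolute power over a band's bins (inclusive edges, which all
land on the 2 Hz grid at the default bands) separately for the stimulus
and baseline windows and takes one log-ratio. This order matters:
lower-frequency bins carry more absolute power, so the statistic is not
the mean of per-bin dB changes. Built-in bands: alpha 8–12, slow gamma
20–34, fast gamma 36–66, the "sensitive" sub-bands 26–34 and 44–56, the
combined 20–66 and the traditional 30–80 Hz band.

The baseline power law `P(f) = A·f^(−β)` is fitted over 56–84 Hz by
closed-form log-log regression followed by a Nelder-Mead simplex
refinement of the squared error in the linear power domain. The closed
form alone has the same sign and nearly the same value; the rejection
cascade can use it (`slope_refine=False`) where only the sign matters.

ERP peaks are conventional visual-ERP windows (P1: max in 75–125 ms, N1:
min in 125–200 ms, P2: max in 175–300 ms) on the baseline-corrected trial
average; windows are configurable because no canonical values exist for
this montage.

## Artifact rejection

Per electrode, a repeat is flagged when its maximum absolute amplitude or
its mean log PSD over −500–750 ms exceeds the median plus k times the
unscaled median absolute deviation across repeats (k = 6 for both
metrics). Dead (flat-zero) and NaN channel-repeats are flagged outright.
The cascade then runs in a fixed order: electrodes bad on >30% of
repeats; repeats bad on >10% of the remaining electrodes; electrodes with
negative 56–84 Hz slope (computed from baseline spectra averaged over
each electrode's surviving repeats); finally the block rule — at least
one clean bipolar pair in each of the three analysis groups, else the
block (and here the subject) is discarded. Whether the 10% rule should
count electrodes before or after slope removal is not decidable from the
sentence order alone; we fix the printed order and flag the assumption.
Impedance-based rejection enters as an input bad-electrode list.

## Eye analysis

A repeat is rejected for a fixation break when the analysis window
(−0.5–0.75 s) contains a blink (NaN run) or any sample outside the 5°
square window centered on fixation. Microsaccades are detected by the
classic velocity-threshold method: ±2-sample weighted central-difference
velocity, robust per-axis SD σ = sqrt(median(v²) − median(v)²), elliptic
threshold at λ = 6 σ, minimum duration 10 ms, events closer than 20 ms
merged. λ, the duration and the kernel are the method's canonical values
(the defaults are labelled canonical, not study-specific) and are
configurable. Detection is monocular and runs on blink-free segments.
Pupil reactivity is the coefficient of variation of pupil diameter across
time per repeat, averaged across repeats per subject.

## Synthetic cohort

The generator is a forward model of the statistical structure the
analysis assumes — not a biophysical simulation. Per channel it sums, in
µV at 500 samples/s over a −1.0–0.8 s epoch:

| component | default | notes |
|---|---|---|
| 1/f background | A = 20 µV²/Hz, β = 1.8 | exact power law on the FFT grid |
| alpha | 4 µV² variance, 8–12 Hz | amplitude ×0.5 during stimulus |
| slow / fast gamma | RMS 1.5 / 1.3 µV | zero-phase 4th-order Butterworth spectral shape, gated on 50 ms after onset with 20 ms cosine ramps |
| SSVEP | 1.5 µV at 32 Hz | counterphase trials only; per-channel fixed phases |
| evoked transient | 3 µV scale | signed Gaussians peaking at 100/170/230 ms, over by ~250 ms, group-independent |

Band-limited components are synthesized spectrally with the squared
magnitude response of the zero-phase Butterworth filter — statistically
identical to filtering white noise, cheaper, and free of edge transients.
Components are independent across channels (so bipolar derivation does
not cancel them) and scaled by a smooth occipito-parietal gain map
(floor 0.3, Gaussian around Oz, width 0.6 layout units). Case groups
(MCI/AD) scale both gamma amplitudes by `deficit_factor` (default 0.6);
alpha, SSVEP and the transient are group-neutral, so the analysis null
(alpha, SSVEP) and alternative (gamma) are simultaneously true in one
cohort. Per-subject amplitude factors are lognormal with σ = 0.25, a
moderate inter-subject variability chosen once so that a 0.6 amplitude
deficit is detectable at the study's 12-case sample size; it is a free
parameter of the generator, not an estimate from data. Gratings at 1 cpd
drive gamma at 0.7 of the 2/4 cpd amplitude, mirroring the weaker
low-spatial-frequency response; orientation has no effect, so orientation
selectivity is near zero by construction.

Eye traces: fixational drift is a low-passed (10 Hz) Ornstein-Uhlenbeck
process (SD 0.15°, τ = 0.2 s) — drift is slow, and an unfiltered OU
process would carry unphysiological high-frequency velocity that inflates
data-driven detector thresholds — plus 0.003° residual tracker noise.
Microsaccades are minimum-jerk jumps (20 ms) between fixation-offset
targets (amplitudes 0.15–1.2°, rate 0.6/s, 100 ms refractory), giving an
exactly lawful main sequence (peak velocity 1.875·A/T). Blinks are NaN
runs (rate 0.1/s, ~150 ms) shared by position and pupil; the pupil shows
a smooth stimulus-evoked constriction (8% deep, peaking at 300 ms) over a
slow noise floor.

Artifacts: with probability 0.02 per repeat, a 30 ms Gaussian transient
of 8 channel-SDs is added to one or two electrodes; a separate "rising"
mode replaces an electrode with f²-shaped noise so its fitted power-law
exponent is reliably negative and trips the slope rule.

One integer seed drives a hierarchical RNG (cohort → profiles → subject →
condition block); any subset of the cohort regenerates identically.
Cohort ages are drawn over 50–92 years and case profiles are resampled
(then, if needed, pinned to a random control's demographics) until every
case has at least one age (±1 year) / gender-matched healthy control;
requesting cases without healthy subjects raises an error, matching the
analysis-time behavior of dropping unmatched cases.

What the generator does not emulate: volume conduction and correlated
channel noise, line noise and EMG, non-stationary drift of band
amplitudes across a session, realistic ERP topographies, binocular eye
data. Passing tests therefore establish the correctness of the
*computations* under the assumed signal structure, not the robustness of
the pipeline to every failure mode of real recordings.

## Matched statistics

Cases are matched to all healthy controls within ±1 year of age and of
the same gender (an optional `limit_controls` keeps the N nearest;
synthetic data order by age distance since no recording dates exist). A
case without any match is dropped with a logged reason, never matched
loosely. Each case is compared with the mean change in power of its
controls: the controls' per-band dB values are averaged. Averaging the
controls' raw spectra instead would give the control statistic a
different null-hypothesis mean than the cases' (the log-ratio is
nonlinear in averaged power), biasing the alpha comparison; per-frequency
averaged control spectra are still attached to each matched set for
plotting.

Group tests are Kruskal-Wallis with tie correction and the standard
df = k − 1 chi-square approximation. Bootstrap medians use 10,000
resamples and report the SD of the bootstrap medians. The JZS paired
Bayes factor integrates the noncentral-t likelihood over a Cauchy(0, 1)
effect-size prior; one-tailed variants truncate the prior to a half-line
and renormalize. Interpretive bands: <1 null, 1–3 anecdotal, 3–10
substantial, >10 strong. No multiple-comparison correction is applied by
default (an optional Bonferroni/FDR helper exists). The CDR regression is
ordinary least squares in matched form (each case plus one row for its
averaged control, CDR 0, mean control age) and unmatched form (every
subject individually).

## Problem sizes

Simulation-based tests state their own sizes: generator contracts use
100–150 repeats (averaged across the ten analysis electrodes where a band
has few effective degrees of freedom per 500 ms window); the end-to-end
effect-pattern replicate runs 100 seeded cohorts per condition of 12
cases against a 74-control pool, synthesizing only the ten analysis
electrodes with the 2 and 4 cpd conditions at one orientation and 12
repeats each. Per-subject ΔPower precision is set by repeats × pairs, so
these reduced sizes leave the group-level operating characteristics
essentially unchanged while keeping a replicate under a few seconds.

## Known limitations

* The exact neighbor-pairing rule behind the original 112-pair montage is
  defined in prior work we do not re-derive; the packaged list documents
  this package's scheme, with the nine analysis pairs pinned.
* The repeat-flagging thresholds (median + 6·MAD) reproduce a "strict
  criteria, few rejections" regime but are not claimed to equal the
  original pipeline's constants.
* Band sums assume band edges on the frequency grid; at sampling rates
  whose window grids miss the printed edges, the inclusive-endpoint
  convention would need revisiting.
* SSVEP group comparisons average scalar 32 Hz dB values across controls
  (consistent with the band statistics) rather than averaging spectra.
* The reported Kruskal-Wallis degrees of freedom follow the standard
  k − 1 convention.
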