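# Methods

This note records the models, algorithms and parameter choices behind
rftkit, the points where the design was genuinely open, and what the
synthetic-data validation does and does not demonstrate.

## Conventions

Times are seconds, RR/PP intervals milliseconds, windows half-open
`[start, stop)`, sample indexing 0-based.  ECG amplitudes are mV; PPG
and respiration carry arbitrary units.  The nominal acquisition rate is
512 Hz for ECG/PPG (any fs ≥ 128 Hz works for detection) and 64 Hz for
respiration.

## Preprocessing chain

**Notch.** Second-order IIR notch at 60 Hz, Q = 30, applied
forward-backward (`filtfilt`), so the phase response is zero.  Requires
fs > 120 Hz.  The notch rings for a few hundred milliseconds at record
edges; analyses that are sensitive to edges should trim ~2 s.

**Band-pass.** Linear-phase windowed-design FIR (Hamming), edges per
channel kind: ECG 0.5–40 Hz, PPG 0.1–20 Hz, RESP 0.1–10 Hz, mirroring
the analog front end such wearables use.  The number of taps is chosen
for a 0.5 Hz transition at the low edge (≈3.3·fs/0.5, capped by record
length).  Because the kernel is symmetric, a single FFT-convolution
pass with reflection padding and group-delay trimming is exactly
zero-phase; the input mean is subtracted first so DC is removed exactly
rather than only to the stopband floor.

**3M morphological filter.** Two stages with flat structuring elements
(SE):

1. *Impulse suppression*, scale B₁:
   `y₁ = ½[close(open(x,B₁),B₁) + open(close(x,B₁),B₁)]`.  The
   open–close/close–open average removes positive and negative
   impulses narrower than B₁ symmetrically (either composition alone
   biases the baseline).
2. *Baseline correction*, scales B₂/B₃:
   `baseline = close(open(y₁,B₂),B₃)`, `y = y₁ − baseline`.  The
   opening (longer than a QRS) levels the complexes, the closing fills
   the remaining troughs, and subtraction removes drift.

Defaults: **B₁ = odd(0.01·fs)**, **B₂ = odd(0.2·fs)**,
**B₃ = odd(0.3·fs)**.  B₁ deserves comment: a flat opening preserves a
peak only down to its value half an SE away from the apex, so an SE
comparable to the QRS *duration* (e.g. 0.06 s) flattens the R wave to a
few percent of its height.  10 ms suppresses spike/contact artifacts
while keeping R-wave attenuation under ~10%, which the wander-removal
test verifies (≥ 90% of 0.3 Hz wander power removed, R amplitudes
within 10%).  Edge handling is reflection padding throughout; with all
SE lengths 1 stage 1 is the identity.

**DOM smoothing.** The named "differential operation method" of the
hardware lineage this package models has no published definition; we
implement it as a centred moving average (odd window, default 9
samples) followed by per-epoch min–max normalization to [0, 1], with
the convention that a constant epoch maps to 0.5.  It is deliberately
labelled an interpretive stand-in and is not part of the detection
path.

## Beat detection

Pan–Tompkins-style envelope: band-pass (ECG 5–15 Hz; PPG 0.5–8 Hz) →
derivative → square → 150 ms moving-window integral.  Local maxima of
the envelope at least 200 ms apart are walked in order with

- threshold `thr = 0.5 · rpe`,
- running peak estimate update `rpe ← 0.125·peak + 0.875·rpe` on each
  accepted beat (seeded from the first two seconds of envelope peaks),
- search-back: if no beat is accepted for 1.66× the running mean RR
  (last 8 intervals), the tallest rejected candidate in the gap is
  accepted if it exceeds `thr/2`,
- refinement of each candidate to the raw-signal maximum within ±50 ms
  (ECG) or ±100 ms (PPG).

Every quantity in the pipeline scales linearly or quadratically with
the input amplitude and all thresholds are relative, so detection is
invariant to positive rescaling.  On clean synthetic ECG the detector
is exact for 40–180 bpm; on a 30-minute record with broadband noise at
10 dB SNR it recovers ≥ 99.3% of beats within ±50 ms (the validation
target).  An all-zero record returns an empty series with a warning
flag rather than an error.

**Interval cleaning.** Successive differences in ms; an interval is
rejected if outside (200, 3000) ms or off the median of the
surrounding 11 intervals by > 30%.  When a sub-200 ms interval is
rejected (a spurious beat splitting one true interval in two), the
neighbour whose sum with it best reconstructs the local median is
rejected as well, provided the sum lies within the 30% band.  The
dropped count is reported; this cleaning rule is an addition of this
package, as is the respiration sign convention (rising = inspiration,
with `--invert-resp` for thermistors whose output rises on exhalation).

## Breath segmentation

1 s moving-average smoothing, then alternating local extrema with
prominence ≥ 20% of the smoothed signal's inter-quartile range and
spacing ≥ 1.5 s.  Each extremum is refined to the raw-signal extremum
within half a smoothing window, which matters for asymmetric breath
shapes (a centred average shifts the apex of an asymmetric triangle by
`(a−b)/(a+b)·w/2`).  Strict trough–peak–trough alternation is enforced
by keeping the highest peak between consecutive troughs; incomplete
first/last cycles are dropped.  Ties on plateau extrema break to the
earliest sample.

## Spectral analysis and metrics

The RR tachogram (interval against the time of its ending beat) is
cubic-interpolated onto a uniform 4 Hz grid, linearly detrended, and
its PSD estimated by Welch's method: 120 s Hann segments, 50% overlap.
Records shorter than 2 minutes are rejected.  Band powers integrate
the piecewise-linear PSD exactly over TP ≤ 0.4 Hz, LF 0.04–0.15 Hz and
HF 0.15–0.4 Hz (band edges interpolated, so a white unit-density
spectrum yields exactly 0.11/0.25).  VLF is inside TP but not reported
separately.  Welch with these settings conserves variance to well
within the 10% Parseval tolerance the tests assert.  A Lomb–Scargle
alternative was considered and not implemented; cubic resampling at
4 Hz is standard for short-term HRV and adequate for paced-breathing
records.

Normalized units are defined as percentages of LF+HF —
`LFnu = 100·LF/(LF+HF)`, `HFnu = 100 − LFnu` — the variant pinned by
published group tables in which each LF/HF pair sums exactly to 100.
`LF/HF = LF_abs/HF_abs` (+∞ flagged when HF = 0).

**Coherence ratio.** The tallest PSD value in 0.04–0.26 Hz defines the
peak; `P` integrates a 0.030 Hz window centred on it and
`CR = P/(TP − P)`.  A pure 0.1 Hz modulation scores ≫ 2; white
interval noise scores < 0.5.

## Stress assessment

SDNN bins: (50, ∞) non-stressed, [35, 50] normal, [20, 35) high,
[0, 20) very high — the printed clinical ranges overlap at 35 and 50,
resolved here by assigning the boundary to the milder category.  LF/HF:
(2.0, ∞) hyper-sympathetic, [0.5, 2.0] balanced, [0, 0.5)
hyper-parasympathetic, both bounds inside the balanced band.  The
22-item stress-response inventory scores 0–4 per item; totals strictly
greater than 56 flag a severe state ("over 56" read literally; the
threshold is an exposed constant).

A caveat the tests document explicitly: the published baseline group's
mean LF/HF of 2.19 lies above the 2.0 balanced bound, so a faithful
implementation of the printed bins classifies that group mean as
hyper-sympathetic even though the source tables treat the group as the
balanced reference.  We implement the bins as printed and keep the
discrepant check visible rather than bending either rule.

## Resonance-frequency protocol

"Maximum gain of HRV" is operationalized as **RSA amplitude**: per
complete breath (trough-to-trough), `max(RR) − min(RR)` over the
intervals ending inside the breath, averaged over breaths (≥ 5 breaths
with ≥ 3 intervals each required).  An alternative — LF peak power at
the pacing frequency — was considered; the peak-to-trough definition
matches the RSA-amplitude framing of resonance training and is robust
at the short (2 min) epochs used.  The sweep covers 4–7 breaths/min in
0.5 steps, one epoch of ≥ 2 min per frequency (the source protocol
states no epoch length; 2 min gives ≥ 8 breaths at the slowest
pacing); the resonant frequency is the argmax, ties breaking to the
lowest frequency (slower breathing preferred on equal evidence).  When
an epoch has no respiration trace, breath windows are taken from the
pacing guide.  Pacing adherence is the fraction of breaths whose
instantaneous rate is within ±0.5 breaths/min of the pacing frequency.

## Synthetic generator

RR dynamics are IPFM-style: the instantaneous trajectory
`RR(t) = mean_rr + ½·gain(f_b)·sin(2πf_b t) + ν(t)` (clipped to
300–2500 ms) is converted to a rate, integrated on a 0.125 s grid, and
a beat fires at each integer crossing — beat times and intervals stay
consistent by construction, unlike direct interval sampling.  `ν(t)` is
a band-limited Gaussian process (white knots at 0.7 Hz,
cubic-blended), which keeps its power inside the analysis band; its
delivered SD is ~0.86 of nominal, which the cohort profiles account
for.  The RSA gain curve is Gaussian in breathing frequency
(default width 0.7 breaths/min), unimodal with its maximum at the
model's resonance frequency.

ECG morphology is a Gaussian-sum P-QRS-T template (R: 1 mV, σ = 12 ms;
fixed wave offsets), PPG a single wide systolic wave per beat, and
respiration a raised-cosine cycle rising over a configurable
inspiratory fraction.  Noise options: 60 Hz powerline sine, slow
sinusoidal wander, random impulses, or broadband white noise specified
by SNR.  All generators are deterministic under a seed and return
ground-truth annotations.

The three-group study emulation (`make_cohort`) uses rest-state
profiles — baseline ~12.2 breaths/min, stressed pre-training group
breathing fast (~19.3 breaths/min) with little slow variability,
post-training ~13.5 breaths/min with restored slow oscillation — with
modulation gain and noise SD decomposed so the analysis pipeline
recovers group mean SDNN near 56/28/55 ms, and 3% between-subject
spread on the mean RR.

**What the synthetic validation does not show.** The templates contain
no ectopy, no amplitude modulation of the QRS, no electrode pops
beyond simple impulses, no apnea or sighs, and noise is stationary;
detection and segmentation performance on real wearable data will be
lower, and the stated detection rate is a property of this test
substrate, not a clinical claim.

## Study statistics

Fold changes are `b/a` (2 decimals) with percent change
`100·(b−a)/a` (1 decimal), mutually consistent before rounding.
Paired comparisons use the two-sided Student's paired t-test (identical
samples return t = 0, p = 1; non-zero constant differences have no
finite t and raise).  Group comparisons use standard one-way ANOVA
with equal-variance pairwise t-tests flagged at the
Bonferroni-corrected α = 0.05/3 (a Welch variant was considered and
left out; classical post-hoc practice pairs Bonferroni with pooled
variance).  Published F statistics of the modelled study carry
internally inconsistent degrees of freedom and are not reproduction
targets; only the printed means' arithmetic relationships are.

## File formats

CSV signals are `time_s,value` (or `value` plus an explicit rate) at
full float precision.  The EDF writer/reader is a minimal 16-bit
implementation for single-session continuous recordings; it picks a
record length that divides the signal exactly, so files round-trip to
the original length with error bounded by one quantization step of the
channel's physical range.  MNE's independent EDF reader is used as a
cross-check in the test suite.  Reports serialize to JSON (CSV/TXT
flattening available) at full precision.

## Problem sizes

The validation suite generates everything at run time: the
detection-rate check uses one 30-minute 512 Hz ECG; sweep-recovery runs
seven 2.5-minute epochs for each of seven resonance positions at the
RR level (no waveform rendering); cohort checks use 8 subjects per
group at 5 minutes each.  The full suite and the acceptance script
each complete in well under a minute of CPU apart from the 30-minute
record synthesis and detection, which takes a few seconds.
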