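# Methods

This note documents the models and procedures implemented in `audiophys`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data tests do and do not establish about real recordings.

## Design and containers

A session is an event-marked multichannel recording. The stimulus design is
five tone-train intensities (70.9–94.5 dBA) × 7 trials, each train 20 tones
of 1003 Hz (70 ms, 5 ms linear ramps) separated by 430 ms, followed by 30 s
of rest; one event row per train is the join key for all epoching. Epochs
are aligned to the sample nearest each onset with half-open `[start, end)`
windows — no sub-sample interpolation, so identical inputs give identical
rows. The default epoch geometry is −5…50 s with the −5…0 s mean
subtracted. Missing values propagate as NaN, never as zeros.

Analysis windows per metric (seconds post-onset): HR 1–3 / 3.5–5.5 / 6–8;
|PPG| 4–8; SCL 2–8; PTT 6–8 / 8–10; HRV the full 50 s; PPG spectra the
first 12 s; fNIRS 3–12 and 13–23 on −4…30 s block averages. All are
configuration fields checked for containment at validation time.

## Cardiac chain

ECG is zero-phase band-passed 0.5–35 Hz (4th-order Butterworth,
`sosfiltfilt`). QRS detection follows Pan–Tompkins: 5–15 Hz band-pass,
derivative, squaring, 150 ms moving-window integration, adaptive
signal/noise thresholds with exponential updates and a 200 ms refractory
period, then refinement to the band-passed ECG maximum within ±50 ms.
Manual ectopic-beat inspection is replaced by an automated plausibility
rule: intervals outside 300–2000 ms flag the beat that closes them, and
flagged beats are excluded from every metric.

Instantaneous HR is 60000/IBI held piecewise-constant between beats
(zero-order hold), so an interval step appears as an HR step at the beat
that defines it. RMSSD is the root mean square of successive interval
differences; SDNN uses the n−1 sample standard deviation. The interval
spectrum interpolates the tachogram with cubic splines at 2 Hz, removes
the constant level, applies a Hann window, and integrates the one-sided
FFT periodogram (window-power compensated, so Parseval holds to a few
percent) over VLF 0–0.04, LF 0.04–0.15, HF 0.15–0.5 Hz. An order-16 Burg
autoregressive spectrum is available as `method="ar"`; the FFT periodogram
is primary. A window shorter than 25 s cannot resolve the LF lower edge
and is flagged `low_resolution` rather than refused — the 50 s trial
window used here sits just above that limit.

## Vascular chain

PPG is band-passed 0.2–5 Hz. The amplitude metric rectifies the filtered
pulse (the rectified mean of a sinusoid of amplitude A is 2A/π, so a
constant-amplitude pulse train baselines to ≈0 and an amplitude drop
appears as a proportional negative deflection). The spectral metric takes
the *unfiltered* 12 s post-stimulus segment, mean-subtracts it, and
computes a Lomb–Scargle periodogram on a fixed 0.01–0.5 Hz grid
(step 0.005 Hz), scaled as a one-sided density against the mean sampling
rate; on an even grid at Fourier frequencies it equals the classical
periodogram exactly, which the tests assert to 1e-6. Normalized units
divide by LF+HF ("Task-Force" convention) and multiply by 100, making
LFnu+HFnu ≡ 100 a testable identity; division by the whole integrated
spectrum is available as `total="spectrum"`. A 12 s segment under-resolves
the 0.04 Hz band edge; rows carry a `low_resolution` flag.

Pulse transit time is the delay from each unflagged R peak to the
pulse-arrival fiducial of the following pulse, searched 100–600 ms after
the peak. The fiducial is the steepest upslope (maximum first derivative)
with sub-sample parabolic refinement of the derivative peak; pulse-peak
and pulse-foot fiducials are configuration options. The steepest-upslope
choice is robust to amplitude scaling, which matters because the injected
amplitude and transit-time effects co-occur. Beats whose best upslope is
weaker than 25 % of the across-beat median (a missing or corrupted pulse)
are flagged. Beat-wise PTT is linearly interpolated to a 10 Hz grid for
epoching; flagged beats never enter the interpolation. On noise-free
synthetic sessions the estimator's residual bias is ~1.6 ms — the
zero-phase 5 Hz low-pass slightly reshapes the upslope — which is inside
the one-sample-period (4 ms at 250 Hz) accuracy the tests require.

## Electrodermal decomposition

The conductance is modeled as tonic + (driver ⊛ Bateman kernel), the
kernel `exp(−t/τ_decay) − exp(−t/τ_rise)` normalized to unit peak.
Decomposition steps: resample to the 10 Hz driver rate (light Gaussian
anti-aliasing); initial tonic from a 20 s minimum filter, smoothed;
Tikhonov-regularized frequency-domain deconvolution of the remainder
(regularizer 0.02 relative to the kernel's peak spectral power); one tonic
refinement — the tonic is re-fit as a linear trend plus 10 s Gaussian
smooth of (signal − phasic) and the deconvolution repeated — because the
minimum-filter floor undershoots during SCR tails and would otherwise
inflate impulse areas; finally the driver's slow baseline (20th-percentile
filter over 30 s, smoothed) is returned to the tonic component, enforcing
the sparse-driver assumption. Time constants default to (0.75, 3.75) s and
are grid-searched over rise ∈ {0.5, 0.75, 1.0, 1.5} × decay ∈
{2, 3.75, 6} s minimizing negative driver mass plus 0.1× driver roughness
(sum of squared first differences) — the criterion that makes the driver
look like a nonnegative impulse train. If negative mass still exceeds half
the positive mass the result is flagged and defaults retained.

An SCR is a contiguous driver segment above max(5 % of the driver peak,
0.01 μS/s); its amplitude is the segment area in μS, which with the
unit-peak kernel equals the phasic rise the impulse produces, matching the
0.01 μS thresholding semantics. Impulses peaking in the last 5 s are
dropped (truncated tails cannot be quantified). Trial metrics in the
1–5 s post-onset window: AmpSum, nSCR, mean driver (SCR), PhasicMax, plus
the tonic mean over the trial epoch; tables export raw and z-scored.
Equivalence with the reference decomposition software is at the level of
recovered SCR structure (onsets within ±0.5 s, summed amplitudes within
10 % on constructed inputs), not bit reproduction.

## fNIRS chain

Channels are pruned when the mean raw level leaves 0.03–2.5 or the
coefficient of variation exceeds 17 %. ΔOD is −log10(I/mean I) against the
channel's whole-recording mean (the standard ΔOD convention). Motion
correction decomposes ΔOD with db3 wavelets to the level whose coarsest
detail scale exceeds 10 s and zeroes detail coefficients outside the
quartile fences `[q1 − 1.5·IQR, q3 + 1.5·IQR]` per level; spike-like
transients concentrate in those outliers while smooth physiology stays
inside the fences. The rule cannot remove spike energy that shares a scale
band with strong physiological oscillations — a known property of the
method, and the reason the spike-suppression test uses a scale-separated
background. Band-pass is 0.01–0.5 Hz; residual artifacts are masked where
the excursion within 1 s exceeds 15× the channel's 1 s-change SD or 0.7
absolute, extended 1 s each side, and any epoch containing masked samples
inside −5…20 s is excluded from averaging.

The modified Beer–Lambert law is solved per sample as a 2×2 system
`OD(λ) = (ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR) · d · DPF(λ)` with d = 3 cm,
DPF 6 (760 nm) and 5 (850 nm), and extinction coefficients (1/(mM·cm))
from the standard compiled hemoglobin spectra: 0.586/1.548 (760 nm,
HbO/HbR) and 1.058/0.691 (850 nm); the table is configuration-overridable.
Concentrations are reported in μM and ΔHbT = ΔHbO + ΔHbR holds to 1e-12
at every stage. Block averages run over −4…30 s, ROIs (left/right
auditory, visual) are unweighted channel means, and window means feed the
inference stage.

In place of short-separation channels, the visual-ROI mean time course is
regressed out of each auditory channel per chromophore over the full
filtered recording (`auditory ≈ α + β·visual`, residual returned for
re-epoching). This removes the shared global component in proportion to
how much of the visual channel's variance the global component explains:
measurement noise in the visual regressor and any stimulus-evoked
component it shares with auditory channels attenuate or bias β̂, so
suppression is strong (≥ 94 % of global-attributable variance in the test
conditions) but never total. A single-channel regressor is available as a
configuration switch.

## Inference

On univariate metrics with Euclidean distance, PERMANOVA reduces to
permutation ANOVA. One-way: pseudo-F = (SS_between/(g−1))/(SS_within/(N−g)),
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) over seeded label permutations
(default 9999 in the library, 999 in the pipeline), η² = SS_between/SS_total;
`method="exact"` enumerates all distinct labelings (p without the add-one
correction). Observations are canonicalized before permuting, so p does
not depend on input row order. Two-way: the balanced crossed decomposition
(A, B, A×B, residual) with every term tested against the same unrestricted
raw-data permutations; with a single-level second factor it reduces
exactly to the one-way result. Unrestricted permutation makes the test for
one factor mildly anticonservative when the other factor's effect is very
large; under the full null both variants hold their size (type-I error
within [0.03, 0.07] at α = 0.05 over 500 simulations). Permuting within
subject is the documented alternative.

Post hoc contrasts are paired-by-subject two-sided t-tests over all level
pairs (the design is within-subject; in single-session analyses the trial
index is the pairing unit), Benjamini–Hochberg adjusted across the
contrast family; contrasts with fewer than 3 complete pairs are reported
missing rather than dropped. Baseline tests are one-sample t-tests of
window means against zero per intensity, BH-corrected across intensities.
Contrasts are always computed; significance gating is a reporting choice.

## Synthetic sessions: what they emulate, and what they do not

Beat times come from integrating an instantaneous rate with sinusoidal
modulation at 0.095 Hz (depth 2 bpm) and 0.265 Hz (1.5 bpm) plus a smooth
random wander (SD 1 bpm, 30 s scale) around 70 bpm — the modulation
frequencies are deliberately incommensurate with the 40 s trial grid so
event-locked averages sample varying phase. Each beat places a Mexican-hat
QRS (σ = 10 ms); each pulse is a sin² wave (600 ms) positioned so its
steepest upslope sits exactly at beat time + true PTT (base 250 ms, 3 ms
beat-to-beat jitter), with amplitude 1 ± 3 %. EDA is a drifting tonic
level (~8 μS) plus Bernoulli event-locked SCRs (p = 0.3, 0.3 μS) on the
Bateman kernel and ~0.5 spontaneous SCRs/min. fNIRS channels carry local
double-gamma responses (auditory 0.10/−0.03 μM HbO/HbR, visual five times
weaker) riding on a global component — Mayer waves (0.3 μM at 0.1 Hz),
slow wander, and the intensity-conditional global response — forward-
converted through the same Beer–Lambert system to dual-wavelength
intensities with cardiac/respiratory oscillations, white OD noise, and
optional motion spikes. Intensity effects default to the highest intensity
only: HR −3 bpm (0–3 s), PPG −20 % (2–10 s), PTT −10 ms (4–12 s), global
ΔHbO −0.2 μM / ΔHbR +0.05 μM (20 s block), with 0.5 s raised-cosine ramps.
Sampling rates default to 250 Hz (ECG/PPG), 20 Hz (EDA), 4.8 Hz (fNIRS)
so the whole stack runs at desk scale; the acquisition-grade 2 kHz is a
configuration value. Everything injected is recorded as ground truth.

Passing tests on these sessions establish that each stage recovers what
its model assumes: quasi-periodic beats with known fiducials, SCRs that
truly follow the Bateman form, hemodynamics that truly satisfy the
Beer–Lambert forward model, and a global component that is exactly shared.
Real data violate all of these gracefully — variable QRS/pulse morphology,
electrode drift, sudomotor kernels that vary within subject, optode
coupling changes, and global physiology that differs across the scalp —
so synthetic recovery rates are upper bounds, not guarantees.

## Numerical choices and degenerate inputs

Band integrals are trapezoidal with interpolated band edges, so partial
grid cells contribute exactly and absolute powers are additive over
disjoint bands. Zero LF+HF yields missing normalized units; a flat ECG
yields an empty beat series with a warning; a zero-variance visual
regressor returns the auditory channel unchanged with a warning; an
all-equal PERMANOVA input is flagged degenerate with p = 1. Permutation
seeds derive from the run seed with fixed per-metric offsets, so a rerun
of the same configuration reproduces every table byte for byte.

Problem sizes in the shipped tests and acceptance script — 20 recovery
sessions, 500 calibration simulations with 999 permutations, 100–200
enumeration instances — were chosen to keep the full verification cycle
around two minutes of compute while leaving binomial noise on estimated
rates well inside the asserted bands.

## Known limitations

The Lomb LF band from 12 s segments is statistically under-resolved (and
flagged); visual-channel regression is a partial substitute for
short-separation channels, biased whenever the visual ROI carries
task-evoked activity; unrestricted two-way permutation is anticonservative
for a factor in the presence of a very large companion effect; the CDA
equivalence is structural, not a bit-reproduction of the reference
implementation; and no attempt is made at biophysically detailed ECG
morphology, acoustic playback, image reconstruction, or scalp-location
registration.
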