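# Methods

## The problem

Free-running whole-heart MRI samples k-space continuously with a 3D radial
trajectory and sorts the data into cardiac and respiratory motion states
after the fact.  The timing information comes from the data themselves: one
readout per 22-line trajectory segment is oriented along the
superior-inferior (SI) axis, and the time series of its 1D Fourier magnitude
profiles carries both respiration (0.1-0.7 Hz) and the heartbeat
(0.5-2.0 Hz).  The practical difficulty is separating the two: respiratory
sinus arrhythmia (RSA) couples heart rate to breathing, and the spatial
footprints of the two motions overlap, so the principal components of the
SI matrix are in general *mixtures* of the two physiological sources.
This package implements the full extraction-evaluation-reconstruction chain
at desk scale on synthetic data with known ground truth, so that every
claim about the method is checkable.

## Synthetic physiology (`selfgate.synth`)

`simulate_physio` produces a respiratory waveform and a cardiac trigger
train at the SI sampling rate `fs = 1/(22 * TR)`; the default TR of
2.84 ms gives `fs ≈ 16 Hz`.

**Respiratory waveform.** `sin(phi) + 0.3 sin(2 phi + 13π/8)` with
`phi = 2π f t`, `f = 0.25 Hz` by default.  The waveform was chosen by
numerically screening two-harmonic cycles for the asymmetries of tidal
breathing that the pipeline depends on: it is band-limited to `2f`
(inside the 0.7 Hz respiratory band edge), inspiration (rising phase)
occupies ~38% of the cycle, the mean amplitude during inspiration exceeds
that during expiration by ~0.25 of the unit amplitude, the signal dwells at
end-expiration longer than in mid-amplitude ranges, and the skewness is
positive.  Any time-symmetric waveform of the form `g(cos phi)` — including
a pure sine or a squared raised cosine — has *identical* inspiration and
expiration means by time-reversal symmetry and cannot exercise the sign
conventions of the conditioning stage.  Above `f = 0.35 Hz` the second
harmonic would leave the band and the waveform degrades to a pure sine.

**Heart rate and RSA.** The instantaneous rate is
`HR(t) = HR_mean + gain * flow(t) + HRV`, where `flow` is the respiratory
derivative normalised to unit maximum and `HRV` is white beat-to-beat
noise (SD `hr_sd_bpm`, default 2 bpm).  Coupling to inspiratory *flow*
rather than amplitude puts the heart-rate maximum inside inspiration,
which is the stated physiology of vagally mediated sinus arrhythmia;
amplitude coupling would peak the rate at end-inspiration and reverse the
inspiration/expiration comparison when intervals are assigned by the
respiratory derivative at their midpoint.  Trigger times accumulate beat
by beat (`interval = 60000/HR` ms), so zero gain and zero HRV give an
exact metronome.  Note one consequence of the beat-wise construction: a
metronomic 60 bpm heart phase-locks to the 4 s breathing cycle; the
default nonzero HRV is what breaks this resonance, as it does in vivo.

**SI stack.** Each (SI position, coil) channel is
`baseline + w_r * resp + w_c * cardiac + modulation + noise` in the
projection domain; the stored readouts are the inverse FFT, so the
preprocessing stage reverses the construction exactly.  The cardiac source
is a raised-cosine pulse per cycle (duty 0.35) whose upstroke coincides
with the trigger — smooth, band-limited, and with a well-defined
zero-crossing phase; the true SI cardiac waveform shape is not prescribed
by any reference, so this is a modelling choice.  The spatial weights are
Gaussian profiles with a broad floor for respiration (the whole projection
shifts with breathing) and a localised bump for the heart, *deliberately
non-orthogonal in channel space* (cross-terms of 0.3): this is the physical
reason PCA alone cannot align its components with the sources, and it is
what makes the downstream SOBI-vs-PCA comparison meaningful.  The
trajectory modulation is an additive offset keyed to the position within
the repeating 22-line segment pattern, one random 22-level pattern per
channel, scaled by `modulation_amplitude`.

**Defective ECG.** `simulate_ecg_train` applies independent per-trigger
deletions, per-interval insertions at uniform positions in the middle
60% of an interval, and Gaussian jitter, and returns the defect
bookkeeping so the cleaning rules can be scored exactly.

## Preprocessing (`selfgate.si_preproc`)

The self-gating matrix is the magnitude of the centred 1D FFT of every
readout, concatenated across coils (rows = time, columns = position x
coil).  Trajectory-related modulation is removed by subtracting, per
column, the temporal mean of each segment-position group.  This is the
minimal operator that exactly cancels a purely angle-dependent additive
term; it is idempotent, and it perturbs physiological correlations only
through the finite-sample group means (relative effect ~1e-3 on a 300 s
record, tested).

## Source separation (`selfgate.bss`)

PCA reduces the matrix to 10 components (the default simulation puts >90%
of the variance there, mirroring the behaviour reported for in vivo SI
matrices) and whitens them.  Columns are *not* z-scored by default: the
magnitude matrix weights channels by their physiological signal content,
and z-scoring inflates pure-noise channels to the same scale — with it,
the 10-component variance fraction drops to ~74%.  A `standardize` flag
exposes the alternative.

SOBI jointly diagonalises symmetrised lagged covariance matrices
(default lags 1..20 samples ≈ 1.25 s, at least one cardiac period at
16 Hz) with Jacobi-style Givens rotation sweeps using the closed-form
optimal plane rotation; the summed squared off-diagonal criterion is
non-increasing across sweeps and the 2x2 case matches an exhaustive
rotation-angle search to grid resolution.  Non-convergence after
`max_sweeps` returns the best iterate with a flag rather than raising.

FastICA (scikit-learn backend) uses the log-cosh negentropy contrast with
symmetric updates; the seed is a required part of the configuration
because the fixed-point iteration starts from a random rotation.  All
methods return unit-variance sources with sign fixed so skewness ≥ 0.

## Component selection and triggers (`selfgate.physio`)

Welch PSDs (30 s segments) are searched for local maxima inside the
physiological band; the tallest in-band peak of each component is fitted
with a Gaussian on a ±5-bin window and the component with the largest
fitted amplitude wins ("most prominent peak" made operational).  A
prominence floor of 1e-6 of the spectrum maximum rejects the numerical
ripples an out-of-band tone leaves in the band.  The respiratory component
is selected first and removed from the cardiac candidate pool.

The respiratory component is low-pass filtered at 0.7 Hz (zero-phase
4th-order Butterworth), linearly detrended, and sign-adjusted so
inspiration is high; the sign rule uses the skewness of the conditioned
signal (end-expiratory dwell below the median ⇒ positive skew when
correctly oriented).

Cardiac triggers are negative-to-positive zero crossings of the band-passed
(0.5-2.0 Hz, zero-phase) cardiac component, linearly interpolated to
sub-sample timing.  Crossings closer than 0.4x the running median interval
are suppressed.  Both polarities are evaluated and the one with the lower
interval coefficient of variation is kept; near-ties resolve to the set
whose first trigger is earlier, a rule that is itself symmetric under sign
flips.  Zero-phase filtering throughout keeps trigger timing unbiased;
the filter's edge transients do perturb the first/last few crossings of a
record (ms-scale), which the evaluation absorbs.

## Evaluation (`selfgate.triggers`)

ECG cleaning compares each interval with the median of its 40 nearest
intervals (20 per side, truncated at the edges): >1.5x flags a missing
trigger, <0.5x an extrasystolic one.  Flags are recorded per *interval*;
flagging only the closing trigger would collaterally invalidate the
following, perfectly normal interval and triple the false-flag rate.

Alignment shifts the self-gated train in 10 ms steps over ± one median
ECG interval and minimises the mean |nearest-ECG distance| with a
0.5x-median gating; ties prefer the smaller shift.  Pairing for the ISD
takes consecutive SG triggers matched to consecutive unflagged ECG
triggers.  With `d_n = |ΔS_n − ΔE_n|` and `μ = mean(d)`,
`ISD = sqrt(Σ(d_n − μ)² / (N−1))` — the sample SD of the absolute
interval differences; μ is over absolute differences, per the defining
text.

The Bonett-Seier paired dispersion test compares the mean absolute
deviations (about the sample means) of two paired samples with a z
statistic on the log MAD ratio; the variance is the delta-method
expression `(v1 + v2 − 2 c12)/n` in relative second moments, which
retains the correlation adjustment of the paired formulation.  It is
validated against a 10^4-permutation oracle (agreement within 0.02 in p).
Identical samples give z = 0, p = 0.5 by construction.  `rsa_split`
assigns each interval to inspiration/expiration by the sign of the
conditioned respiratory derivative at the interval midpoint; across
subjects the means are compared with a paired t-test.

## Binning (`selfgate.binning`)

Respiratory: four equally populated amplitude bins (quantile thresholds,
ties to the lower bin), bin 0 = end-expiration.  Cardiac:
`n_bins = round(mean interval / 50 ms)` (half away from zero, floor 1);
within each interval the bin is `floor(n_bins * phase)` with the phase
measured from that interval's own start; readouts outside the trigger span
are rejected rather than wrapped.  At 57-80 bpm this yields 15-21 bins.

## Toy reconstruction (`selfgate.recon`)

The motion-resolved compressed-sensing problem
`argmin ‖FCx − y‖² + λr|∇r x|₁ + λc|∇c x|₁` is solved at toy scale:
images ≤ 64², 2D golden-angle radial spokes, the forward map an explicit
non-uniform DFT summation, simulator-provided coil sensitivities.  The
cardiac difference operator is cyclic (heartbeats are periodic), the
respiratory one is not.  ADMM splits the two l1 terms (penalty ρ = 1,
complex soft-thresholding, warm-started CG for the x-update); with both
weights zero the solver reduces to plain CG and the fully sampled
Cartesian case reproduces the inverse transform to 1e-6.  Data are scaled
so a 5-iteration CG least-squares image has unit maximum; λr = λc = 0.001
and 10 iterations are the default configuration.  (Normalising the data
to unit l2 instead leaves image entries of order 1e-3, and λ = 0.001 then
thresholds every difference to zero — λ has no effect at all; the
λ-monotonicity test caught this.)  The ADMM objective is not strictly
monotone; on these problems it is non-increasing after two iterations to
1e-6 in unit-normalised data units.

**Binning-quality experiment.** A disk phantom contracts during the first
30% of each cardiac cycle (raised-cosine systole) and is quiescent in
diastole; 480 golden-angle spokes over 60 s of physiology are binned into
6 cardiac bins (80 spokes per bin, ~2x radial Nyquist at 24 px) twice:
with the true triggers and with triggers jittered uniformly by ±100 ms.
The headline RMSE compares the reconstructions against phase-averaged
references over the *quiescent diastolic bins* — the phase conventionally
used to judge whole-heart image quality.  With correct triggers those bins
see a static object; trigger errors leak systolic frames into them and
blur the result.  Over the systolic bins the phase-averaged reference is
itself ambiguous (a jitter-blurred reconstruction can resemble a phase
average *better*), so an all-bin RMSE flips in a minority of seeds for
reasons unrelated to binning quality; the diastolic comparison isolates
the mechanism.  Phantom k-space noise is 2% of the RMS magnitude (scaling
to the maximum would bury all high frequencies under the DC peak).

## Sharpness (`selfgate.sharpness`)

A piecewise-cubic curve (Catmull-Rom tangents in Bézier form,
interpolating every point, C1) is placed through control points along an
interface; profiles are sampled on perpendicular lines at equal arc-length
spacing by bilinear interpolation (0.5 px steps, ±10 px default) and each
is fitted with `f(x) = a2 + (a1−a2)/(1 + 10^((a0−x)s))`.  The 10-90% rise
distance is `(FOV/BR)·|f⁻¹(0.9) − f⁻¹(0.1)|`, computed both by bracketed
root finding and by the closed form `(FOV/BR)·2·log10(9)/|s|`; the two must
agree to 1e-9 or the function raises.  |s| below 1e-9 censors the
measurement at the profile window instead of returning an infinity.  The
per-image aggregate is the median over lines, robust to dropped or
non-converged fits.  Bilinear sampling at sub-pixel offsets acts as a
mild blur and biases the fitted steepness low for very sharp edges
(~2% at s = 0.3 px⁻¹, ~16% at s = 1 px⁻¹); profiles sampled on the pixel
grid are exact, which is how the generator loop-closure test is run.

## Orchestration and problem sizes

`pipeline.run_extraction` chains the stages for one simulated subject and
derives every sub-seed from the single config seed, making reports
byte-reproducible (ICA included).  The simulated study conditions used by
the tests and the acceptance script are: 300 s records at fs ≈ 16 Hz,
40 SI positions x 4 coils, channel noise SD 0.3 (0.5 where variance
coverage is probed), trajectory modulation amplitude 1.0, RSA gain 6 bpm,
HRV 2 bpm; 20 seeds for the method comparison (10 pooled subjects for the
dispersion test), 50 seeds for ECG cleaning, 20 seeds for the
reconstruction mechanism (10 in the acceptance script).  These sizes were
chosen so each Monte-Carlo estimate is stable at desk scale.

## What the synthetic data do not show

The simulator emulates the *structure* of the problem — two band-separated,
RSA-coupled sources under pseudo-periodic trajectory modulation and
additive Gaussian noise — not scanner physics.  It contains no eddy-current
dynamics, no contrast-agent or flip-angle signal evolution, no arrhythmia,
no bulk motion, and ECG defects are independent random events rather than
gradient-switching artefacts.  Passing tests therefore demonstrate the
correctness of the algorithms and the direction of the method differences
under the modelled physiology; they do not certify performance on clinical
data, where the relative ranking of the separation methods is known to
depend on the contrast regime.
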