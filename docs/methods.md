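# Methods

`efrkit` simulates the envelope following response (EFR) of a humanized
auditory-nerve (AN) population to sinusoidally amplitude-modulated (SAM)
tones, with configurable hair-cell dysfunction and cochlear synaptopathy,
and implements the matching EEG-side analysis chain used to measure EFRs in
human recordings.  This note documents the model, its assumptions, the
parameters that matter, and the choices made where the design was open.

## Stimulus

The stimulus is a SAM tone

    SAM(t) = A · sin(2π f_c t) · (1 + m · sin(2π f_m t)) / 2

with carrier `f_c = 2005 Hz` (labelled 2 kHz in band names), modulation
frequency `f_m = 93 Hz`, and modulation depth `m ∈ {0.85, 0.25}` ("deep" /
"shallow").  `A` is calibrated against the realized digital RMS so that the
waveform RMS equals `20 µPa · 10^(L/20)` for a requested level `L` in
dB SPL; the round-trip is exact to well under 0.01 dB for any duration.
Simulated stimuli are 1.2 s long and unramped — the analysis uses only the
steady state, so onset transients are irrelevant; a raised-cosine ramp is
available for exported audio.  Two level schedules are shipped: the
recording schedule (ten levels, 34–87 dB SPL, presentation times of
5.5–10 min chosen to reach a statistically significant EFR) and the
simulation schedule (10–100 dB SPL in 5-dB steps).

## Fiber population

Characteristic frequencies (CFs) sit at 200 equally spaced positions on the
basilar membrane, mapped to 0.2–20 kHz through the human Greenwood map
`F(x) = 165.4 · (10^(2.1x) − 0.88)` with normalized place `x` (endpoints
solved exactly).  32,000 synapses are distributed over the grid — uniformly
(160 per CF) by default, or following a piecewise-linear approximation of
the human innervation-density curve (peak near 2–4 kHz) — and split
61 % / 23 % / 16 % into high-, medium- and low-spontaneous-rate (SR)
classes, the proportions reported for cat.  All integerization uses
deterministic largest-remainder rounding (ties by index), so grand totals
are exact and runs are reproducible: a 160-synapse channel splits into
(98, 37, 25).

Synaptopathy profiles are percent-loss tables anchored at a few
frequencies, with optional flat extensions to the grid edges, interpolated
on a log2-frequency axis with a shape-preserving piecewise cubic Hermite
polynomial (PCHIP).  Shape preservation guarantees the interpolant never
leaves [0, 100].  Two named presets approximate the patterns fitted to the
representative listeners: `NH09` (85 % loss concentrated in the octave
around 4 kHz, graded shoulders at 2.7–2.9 and 5.65–5.75 kHz, zero
elsewhere) and `HI04` (20 % loss up to 2 kHz grading to 85 % at and above
2.5 kHz).  The printed source table for these anchors is typographically
damaged; the shipped parse reproduces its digit strings and the prose
description, but anchor tables are plain data and can be overridden.
Applying a profile rounds each count to `count · (1 − loss/100)` per CF and
selected class and reports the realized total loss.  On the uniform-density
population the NH09 preset removes ≈ 14.6 % of all synapses and HI04
≈ 52.6 %; published totals computed with a non-uniform human innervation
density (17.8 % and 57.3 %) are not reproducible from tabulated data and
are deliberately not hard-coded.

## Surrogate periphery

The full phenomenological inner-ear model this package stands in for
(basilar-membrane control path, power-law synaptic adaptation, fractional
noise) is replaced by an envelope-driven rate surrogate.  The design
premise is that the population-EFR phenomena of interest rest on four
mechanisms, each implemented and tested separately:

1. **Instantaneous level.**  A narrowband SAM tone carries the level
   trajectory `L(t) = L_rms + 20·log10(env(t)/env_rms)` with
   `env(t) = (1 + m sin 2π f_m t)/2`.
2. **Tip/tail tuning.**  Channel `cf` sees the carrier attenuated by
   `A(cf, f_c)`: zero at the tip, 120 dB/oct on the high-frequency flank
   (carrier above CF), 60 dB/oct on the low-frequency flank, bounded on the
   low side by a *tail*: a 45-dB plateau from 0.75 octaves of separation,
   rising gently at 12 dB/oct with further separation.  The shallow tail
   ramp spreads the recruitment of basal channels over ~30 dB of stimulus
   level; a perfectly flat tail would recruit half the population at one
   level and make the summed response non-monotonic.
3. **Hair-cell dysfunction asymmetry.**  An audiogram is interpolated to
   the grid (monotone cubic in log frequency; thresholds beyond 8 kHz
   either flat or sloping at 50 dB/oct; negative hearing levels clamped to
   zero) and split into outer-hair-cell (OHC) and inner-hair-cell (IHC)
   components — 2/3 : 1/3 by default, or all-OHC / all-IHC.  The OHC shift
   raises only the tip branch of `A` (the tail, i.e. off-frequency
   response, is invariant); the IHC shift subtracts from the drive
   everywhere.  This reproduces the characteristic result that pure OHC
   dysfunction leaves the EFR level function essentially unchanged while
   IHC dysfunction attenuates it broadly.
4. **Saturating rate per SR class.**  The drive maps to an instantaneous
   rate `r = SR + (Rmax − SR)·σ((drive − θ)/DR)` with a logistic σ scaled
   so σ(0) = 0.05 and σ(1) = 0.95.  Modulation is transmitted on the rising
   part of σ and collapses in saturation, so each (class, channel) traces a
   single-peaked synchrony-level function whose peak level grows with
   `A(cf)` — bells that shift basal-ward with level, as in single-unit
   data.

The population PSTH is the count-weighted sum `counts[cf, class] · r(t)` at
1-ms resolution ("analytic" mode, deterministic); a "spiking" mode draws
seeded inhomogeneous-Poisson counts per bin around the same mean.  A 0.1-s
settling margin is discarded before analysis — the surrogate is memoryless,
so this serves only to decouple window placement from stimulus onset.

### Class parameters and their calibration

| class  | SR (sp/s) | θ (dB) | DR (dB) | Rmax (sp/s) |
|--------|-----------|--------|---------|-------------|
| high   | 60        | 0      | 45      | 250         |
| medium | 5         | 12     | 45      | 45          |
| low    | 0.1       | 25     | 45      | 35          |

These are *effective* parameters, not physiological measurements.  `DR` is
the width of the envelope-coding region, set near the 30–50-dB widths of
measured synchrony-level functions rather than the ~20-dB spike-count
dynamic range of real fibers: in real fibers (and in power-law-adaptation
models) envelope synchrony survives well past rate saturation, and a
memoryless sigmoid can only mimic that with a wide transition.  `Rmax` for
the medium/low classes is likewise an effective synchronized-rate ceiling,
set well below the high-SR ceiling so that the population EFR is dominated
by high-SR fibers at every level — the behaviour reported for the full
population model and attributed to the higher driven rates of high-SR
fibers.  The calibration targets were qualitative and fixed before the
test suite: per-class synchrony bells, monotonic summed growth over
35–90 dB SPL, high-SR dominance (medium+low removal ≤ 1.5 dB), off-band
dominance at high level, and the confinement of the NH09-pattern reduction
to 55–85 dB SPL.  All constants are config-overridable per run.

## Simulated EFR

The simulated EFR is the amplitude of the `f_m` component of the summed
PSTH: mean removed, rectangular-window FFT over a 1-s steady-state window
(93 cycles at 93 Hz — `f_m` falls exactly on a bin, enforced), 2/N scaling.
Magnitude-level functions evaluate this per stimulus level and modulation
depth; 1/3-octave band selections (half-open upper edge) and SR-class
selections decompose it.  Because every channel's rate rises with the same
envelope through monotone nonlinearities, all `f_m` components add in
phase; removing fibers can only reduce the magnitude, which makes the
dose-response of synaptopathy monotone by construction.  Simulated
magnitudes are in arbitrary units; `normalize_to_reference` applies one
additive dB offset (anchoring the deep-modulation healthy curve at a chosen
level to a recorded value in dB re 1 µV) to every curve of a run, leaving
all between-condition differences intact.

## EEG analysis chain

Epochs (1 s at 2048 Hz, µV) pass through:

1. **Band-pass** 60–400 Hz, 4th-order Butterworth applied forward and
   backward (`sosfiltfilt`): zero phase, squared magnitude response.
2. **Artifact rejection**: epochs whose absolute amplitude exceeds 80 µV
   are dropped ("exceeds" is strict — an 80.0-µV peak survives); the
   boolean mask is returned for audit.
3. **Trial formation**: 16 consecutive accepted epochs concatenate into a
   16-s trial (spectral resolution 1/16 Hz); leftovers are dropped.
4. **Weighted averaging**: trials are ensemble-averaged with
   inverse-variance weights computed per 1-s epoch *after* filtering (the
   source description does not say before or after; after is chosen so
   weights reflect the noise actually entering the spectrum).  Equal
   variances reduce exactly to the arithmetic mean.  Zero-variance epochs
   (a synthetic-data corner case) have weights capped at 10⁶ × the median.
5. **Spectral F-test**: the power at the `f_m` bin is divided by the mean
   power of all bins within ±3 Hz (96 bins at 1/16-Hz resolution).  The
   p-value is the upper tail of F(2, dfd).

**Degrees-of-freedom convention.**  The denominator dof is selectable.  The
default `dfd = 96` (number of averaged noise bins) matches the printed
critical value of 4.8333 and the SNR bound 10·log10(F_crit − 1) = 5.84 dB;
the alternative `dfd = 192` (two dof per complex noise bin, the exact
sampling distribution of the ratio under Gaussian noise, critical value
4.717) is also available because the two conventions are quoted
inconsistently in the source literature.  With the default, the detector is
very slightly conservative: the measured type-I error on signal-free
synthetic EEG is ≈ 0.0098 at a nominal 0.01.

## Synthetic EEG generator

The generator produces what the pipeline's estimators rely on, not
biophysically realistic EEG: a sinusoid of known amplitude and phase at
`f_m`, phase-continuous across epochs (as in looped stimulus presentation);
white Gaussian noise (default SD 1 µV per sample, a plausible magnitude for
band-limited scalp EEG) plus 1/f-shaped noise of equal RMS (spectral
shaping, exponent 1); optional square-pulse artifacts (200 µV, 50 ms,
per-epoch probability) that reliably survive the band-pass above the 80-µV
rejection threshold; and an optional heteroscedastic mode (log-normal
per-epoch noise SD, log-SD 0.4) to exercise inverse-variance weighting.
Everything derives from a single seed and reproduces bit-identically.

What passing tests on this generator do show: the chain's type-I error is
calibrated, amplitude recovery is unbiased to < 5 % at realistic SNR,
weighting strictly improves the noise floor under heteroscedasticity, and
artifacts are excised exactly.  What they do not show: robustness to
non-stationary or non-Gaussian EEG noise, line interference, electrode
drift, or multi-channel referencing effects — real recordings need those
checks separately.

## Numerical choices and degenerate inputs

- `f_m` must fall exactly on an FFT bin (integer cycles per window); both
  the simulation and the F-test raise otherwise rather than leak.
- Largest-remainder rounding resolves fractional-part ties by index after
  rounding away float noise at 1e-9.
- The noise-free amplitude recovered through the full chain equals the
  injected amplitude times the two-pass filter gain at 93 Hz (0.9958), a
  0.4 % droop inherent to the published filter — tests assert against the
  independently computed gain.
- Empty populations, all-rejected epoch sets, out-of-range anchors, off-bin
  modulation frequencies, mismatched grids and invalid modes raise
  `ValueError` with actionable messages; borderline-but-legal inputs
  (totals below the channel count, negative hearing levels) warn and
  proceed with the documented behaviour.

## Problem sizes

Defaults used throughout the tests and the reproduction script: 200 CFs ×
3 classes × 1.2 s at 1-ms bins per simulation (a full 19-level, two-depth
sweep takes well under a second); 5000 noise-only recordings of 16 epochs
for the type-I calibration; 200 recordings of 960 epochs for the
recovery-bias estimate.  These sizes give binomial/Monte-Carlo intervals
tight enough for the asserted tolerances while keeping the whole suite in
the low minutes.

## Known limitations

- The surrogate is memoryless: no adaptation, refractoriness, two-tone
  suppression, or medial-olivocochlear effects; synchrony persistence
  beyond saturation is emulated by wide effective dynamic ranges rather
  than mechanism.
- All channels modulate in phase, so population magnitudes add
  constructively; real cochlear phase dispersion partially cancels and can
  reshape level functions.
- Level-dependent filter broadening is omitted; upward spread of excitation
  is carried entirely by the tuning-curve tail.
- The tail's "modest hypersensitivity" under OHC loss is ignored.
- Scalp-potential generation (unitary-response convolution) is out of
  scope: simulated magnitudes are AN-level quantities in arbitrary units
  and are only anchored to recorded values by a single normalization
  offset.
- The human innervation-density curve is approximate; quantitative
  total-loss percentages depend on it and should not be over-interpreted.
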