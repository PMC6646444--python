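# efrkit

Auditory-nerve population simulation of **envelope following responses
(EFR)** with configurable hair-cell dysfunction and cochlear synaptopathy,
plus the matching EEG-side EFR detection pipeline.

## What problem this addresses

Cochlear synaptopathy — the loss of synapses between inner hair cells and
auditory-nerve (AN) fibers without hair-cell damage — elevates no audiogram
and is invisible to standard clinical tests ("hidden" hearing loss).  The
EFR, a scalp potential phase-locked to the envelope of a modulated tone,
has been proposed as a non-invasive marker: its growth with stimulus level
should change when AN fibers are missing.  Testing that proposal requires
(a) a population model of the AN that can be lesioned synapse-by-synapse
and per fiber class, and (b) a rigorous detection pipeline for the
microvolt-scale EFR in EEG.  `efrkit` provides both, for researchers in
auditory electrophysiology and computational hearing science.

## The model in brief

The stimulus is a SAM tone, `SAM(t) = A·sin(2πf_c t)·(1 + m·sin(2πf_m t))/2`
(f_c = 2005 Hz, f_m = 93 Hz, m ∈ {0.85, 0.25}), calibrated in dB SPL.
The AN is 32,000 synapses on 200 characteristic frequencies (CFs) placed by
the human Greenwood map over 0.2–20 kHz and split 61/23/16 % into high-,
medium- and low-spontaneous-rate fibers.  Each channel sees the stimulus
envelope through a tip/tail tuning attenuation (OHC dysfunction raises the
tip only; IHC dysfunction attenuates everywhere) and each fiber class maps
that drive to an instantaneous rate through a saturating nonlinearity, so
every (channel, class) has a single-peaked synchrony-level function.  The
simulated EFR is the f_m-component amplitude of the count-weighted PSTH
sum; synaptopathy profiles (anchor tables, PCHIP-interpolated over log
frequency) remove synapses per CF and class.  The EEG chain implements
60–400-Hz zero-phase Butterworth filtering, 80-µV artifact rejection,
16×1-s trial concatenation, inverse-variance weighted averaging, and a
spectral F-test (power at f_m vs the mean of 96 flanking bins; p ≤ 0.01,
critical F = 4.8333, SNR bound 5.84 dB).  Details and rationale:
[docs/methods.md](docs/methods.md).

## Worked example

Simulate magnitude-level functions for a healthy ear, an ear missing every
medium- and low-SR fiber, and an ear with the "NH09" synaptopathy pattern
(85 % loss in the octave around 4 kHz):

```bash
python examples/03_magnitude_level_functions.py
```

```
level   healthy   no med/low   NH09 CS   (EFR dB a.u., m = 0.85)
   35    100.76    100.35    100.03
   50    104.58    103.93    102.10
   65    108.71    108.07    103.93
   80    112.67    112.02    109.25
   90    113.29    112.45    111.34

max |change| from removing all med+low-SR fibers: 0.84 dB
NH09 reduction peaks at 65 dB SPL (4.77 dB), edges 0.73 / 1.95 dB
```

Read: the healthy summed response grows monotonically; removing *all*
medium- and low-SR fibers moves it by less than 1 dB (high-SR fibers
dominate the population EFR at every level), whereas a band of loss that
includes high-SR fibers carves a several-dB dip confined to medium-to-high
levels — the signature that makes the EFR level function a candidate
synaptopathy marker.

Detect a 0.1-µV EFR in synthetic EEG through the full analysis chain:

```bash
python examples/05_eeg_detection.py
```

```
recovered amplitude  : 0.0970 uV (injected 0.1000 uV)
F-ratio              : 679.95 over 96 noise bins
p-value              : 2.08e-57  -> significant: True
SNR                  : 28.32 dB (detection bound 5.84 dB)
```

The other examples cover stimulus calibration (`01`), population building
and lesioning (`02`), CF-band × fiber-type decomposition (`04`), and the
detector's false-positive calibration (`06`).  Scenario bundles (audiogram
+ hair-cell mode + synaptopathy preset) are available programmatically:

```python
from efrkit import run_scenario, list_scenarios
tables = run_scenario("nh09_synaptopathy")   # tidy DataFrames, CSV-ready
```

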