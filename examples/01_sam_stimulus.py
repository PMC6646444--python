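"""Generate and calibrate a SAM-tone stimulus.

Builds the canonical stimulus (2005-Hz carrier, 93-Hz modulation, deep
depth m = 0.85) at 80 dB SPL, verifies the calibration and the sideband
structure, and prints the level/duration schedules.
"""

import numpy as np

from efrkit import stimuli

stim = stimuli.make_sam(
    carrier_freq=2005.0, mod_freq=93.0, mod_index=0.85,
    level_db_spl=80.0, duration=1.0, sample_rate=48000.0,
)

rms = np.sqrt(np.mean(stim.waveform**2))
print(f"waveform RMS           : {rms:.6f} Pa (80 dB SPL = 0.2 Pa re 20 uPa)")
print(f"realized level         : {20*np.log10(rms/stimuli.P_REF):.3f} dB SPL")

amps = 2.0 / len(stim.waveform) * np.abs(np.fft.rfft(stim.waveform))
print(f"sideband/carrier ratio : {amps[2005-93]/amps[2005]:.4f} (theory m/2 = 0.4250)")

print("\nrecording schedule (level dB SPL -> minutes):")
for lv, dur_s in stimuli.level_schedule("recorded"):
    print(f"  {lv:4.0f} -> {dur_s/60:.1f}")
sim = stimuli.level_schedule("simulated")
print(f"\nsimulation schedule: {len(sim)} levels, "
      f"{sim[0][0]:.0f}-{sim[-1][0]:.0f} dB SPL in 5-dB steps, each {sim[0][1]} s")
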