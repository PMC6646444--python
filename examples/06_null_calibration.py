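"""Check the detector's false-positive rate on signal-free synthetic EEG.

Runs the complete chain on several hundred noise-only recordings; with the
p <= 0.01 criterion about 1 % of them should be flagged significant.  (The
test suite repeats this at 5000 runs against the exact binomial interval.)
"""

from efrkit import eeg, synth

n_runs = 400
hits = 0
for i in range(n_runs):
    spec = synth.SynthSpec(efr_amplitude=0.0, pink_scale=0.0, white_sd=1.0,
                           n_epochs=16, seed=100_000 + i)
    epochs, _ = synth.generate_epochs(spec)
    hits += eeg.analyze_epochs(epochs, fm=93.0).significant

print(f"false positives: {hits}/{n_runs} = {hits/n_runs:.4f} (target alpha = 0.01)")
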