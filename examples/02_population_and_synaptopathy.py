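"""Build the auditory-nerve population and apply a synaptopathy pattern.

Creates the 200-channel Greenwood grid with 32,000 synapses (61/23/16 %
high/medium/low spontaneous-rate fibers), then removes fibers according to
the NH09 pattern (up to 85 % loss around 4 kHz) and reports the result.
"""

import numpy as np

from efrkit import population

grid = population.build_cf_grid(n_cf=200, f_min=200.0, f_max=20000.0)
pop = population.allocate_fibers(grid, total=32000, density="uniform")

print(f"CF grid    : {grid.n_cf} channels, {grid.cf[0]:.0f}-{grid.cf[-1]:.0f} Hz")
print(f"population : {pop.total} synapses, {pop.counts.sum(axis=1)[0]} per CF")
print("SR classes :", {c: pop.class_total(c) for c in population.SR_CLASSES})
print("one CF     : high/medium/low =", tuple(int(c) for c in pop.counts[0]))

profile = population.interpolate_loss("NH09", grid)
pruned, realized = population.apply_synaptopathy(pop, profile)
print(f"\nNH09 pattern: realized total loss {realized:.1f} % of all synapses")
for f_khz in (1.0, 2.5, 3.0, 4.0, 5.0, 8.0):
    i = np.argmin(np.abs(grid.cf - 1000 * f_khz))
    before = tuple(int(c) for c in pop.counts[i])
    after = tuple(int(c) for c in pruned.counts[i])
    print(f"  loss at ~{f_khz:3.1f} kHz: {profile.per_cf_loss[i]:5.1f} %  "
          f"(counts {before} -> {after})")
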