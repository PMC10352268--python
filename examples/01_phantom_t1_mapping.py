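"""Simulate a multi-tube phantom at 64 mT and fit a voxelwise T1 map.

Builds a one-slice phantom of 15.7 nm iron oxide nanoparticles at four
concentrations, simulates the inversion-recovery series at SNR 50, fits the
magnitude IR model per voxel, and compares each tube's median T1 against the
value implied by the linear relaxivity relation.
"""

import numpy as np

from lowfield_relax import (
    build_default_agents,
    circular_tube_layout,
    default_protocol,
    map_volume,
    simulate_phantom_series,
    true_rates,
)

agents = {a.name: a for a in build_default_agents()}
agent = agents["D"]
concs = [0.0, 0.03, 0.06, 0.12]

layout = circular_tube_layout(agent.name, concs, shape=(40, 40, 1), tube_radius=3.0)
protocol = default_protocol(0.064, "inversion_recovery", noise_sigma=0.02, seed=42)
series = simulate_phantom_series(layout, protocol, [agent])
t1_map = map_volume(series, noise_sigma=0.02)

print(f"{agent.name} ({agent.core_diameter_nm} nm cores) at 64 mT, SNR 50")
print(f"{'conc (mmol/L)':>14} {'true T1 (ms)':>13} {'fitted T1 (ms)':>15}")
for i, c in enumerate(concs):
    r1, _ = true_rates(agent, c, 0.064, layout.background_rates)
    tube = layout.tube_mask(i) & t1_map.converged
    fitted = float(np.median(t1_map.T_ms[tube]))
    print(f"{c:>14g} {1000.0 / r1:>13.0f} {fitted:>15.0f}")
# The doped tubes track the ground truth to a few percent.  The blank
# (0 mmol/L) tube is the least constrained: its T1 (~2860 ms) exceeds the
# longest inversion time (2500 ms), so its estimate scatters by ~10-15 %;
# the relaxivity fit absorbs this in the intercept.
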