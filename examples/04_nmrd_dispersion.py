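"""NMRD dispersion profiles: peak structure and model fitting.

Shows where the superparamagnetic dispersion peak sits for each particle
size, then simulates a fast-field-cycling profile of the 15.7 nm particles
at the instrument's 1 % error level, fits the heuristic superparamagnetic
model, and interpolates r1 at the 64 mT proton Larmor frequency (2.72 MHz).
"""

import numpy as np

from lowfield_relax import (
    SPMParams,
    build_default_agents,
    fit_nmrd,
    peak_frequency,
    r1_at_field,
    simulate_nmrd_profile,
    spm_params_for_agent,
)

agents = {a.name: a for a in build_default_agents()}

print("dispersion peak vs particle size (D = 2.3e-9 m²/s, 21.5 °C):")
for name in ("A", "B", "C", "D"):
    p = spm_params_for_agent(agents[name], 21.5)
    print(f"  {agents[name].core_diameter_nm:>5.1f} nm -> "
          f"peak at {peak_frequency(p):.1f} MHz")

truth = spm_params_for_agent(agents["D"], 21.5)
profile = simulate_nmrd_profile("spm", truth, rel_noise=0.01, seed=11, label="D")
init = SPMParams(**{**truth.__dict__, "d_nm": 10.0, "tau_N": 1e-9,
                    "K_scale": float(np.max(profile.r1))})
fit = fit_nmrd(profile, model="spm", init=init)

print(f"\nfit of the 15.7 nm profile (converged={fit.success}):")
print(f"  d      = {fit.params.d_nm:.2f} nm   (truth {truth.d_nm})")
print(f"  tau_N  = {fit.params.tau_N:.2e} s  (truth {truth.tau_N:.0e})")
print(f"  r1 @ 64 mT = {r1_at_field(fit, 0.064):.1f} L/mmol/s "
      f"(truth {agents['D'].nmrd_r1_true[21.5]})")
# The peak moves to lower frequency as the cores grow (slower diffusion past
# a larger sphere), and for the largest particles it sits close to 2.72 MHz —
# which is why they perform so well at this imaging field.
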