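"""Langevin analysis of a magnetization curve.

Simulates M(B) for the 15.7 nm particles over 0-7 T at 21.5 °C with 1 %
instrument noise, fits a single Langevin function, and reports the
saturation magnetization, the effective magnetic diameter, the fraction of
saturation already reached at 64 mT, and the comparison with bulk magnetite.
"""

from lowfield_relax import (
    build_default_agents,
    fit_langevin,
    saturation_fraction,
    simulate_magnetization_curve,
)
from lowfield_relax.constants import BULK_MAGNETITE_MS

agent = {a.name: a for a in build_default_agents()}["D"]
curve = simulate_magnetization_curve(agent, rel_noise=0.01, seed=7)
fit = fit_langevin(curve)

print(f"agent {agent.name}: physical core diameter {agent.core_diameter_nm} nm")
print(f"Ms = {fit.Ms:.1f} ± {fit.Ms_se:.1f} A·m²/kg "
      f"(truth {agent.mass_saturation_magnetization})")
print(f"per-particle moment mu = {fit.mu:.3e} J/T")
print(f"effective magnetic diameter = {fit.magnetic_diameter_nm:.1f} nm")
print(f"fraction of saturation at 64 mT = "
      f"{100 * saturation_fraction(fit, 0.064, curve.temperature_K):.0f}%")
print(f"Ms as % of bulk magnetite (92 A·m²/kg) = "
      f"{100 * fit.Ms / BULK_MAGNETITE_MS:.0f}%")
# The magnetic diameter is smaller than the physical core (surface disorder);
# these particles sit at ~40-50 % of saturation already at the imaging field.
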