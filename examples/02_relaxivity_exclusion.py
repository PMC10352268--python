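"""Relaxivity estimation with the first-inversion-time exclusion rule.

Computes ground-truth T1 values for each concentration of every agent at
64 mT, applies the rule (fitted T1 below the first inversion time of 100 ms
is unmeasurable and removed from all fits for that agent), then fits r1 on
exact rates to show the slope recovery and the excluded concentrations.
"""

import numpy as np

from lowfield_relax import (
    ConcentrationSeries,
    apply_exclusion_rule,
    build_default_agents,
    fit_relaxivity,
    true_rates,
)
from lowfield_relax.synthetic import DEFAULT_BACKGROUND_RATES, default_concentrations

bg = DEFAULT_BACKGROUND_RATES[0.064]
concs = default_concentrations(0.064)
nonzero = concs[concs > 0]

total_excluded = 0
print(f"{'agent':>12} {'r1 fit':>7} {'excluded concs (mmol/L)':>25}")
for agent in build_default_agents():
    rates = np.array([true_rates(agent, c, 0.064, bg)[0] for c in concs])
    t1_ms = 1000.0 / rates
    _, reasons = apply_exclusion_rule(t1_ms, first_ti_ms=100.0)
    included = np.array([i not in reasons for i in range(len(concs))])
    series = ConcentrationSeries(
        agent=agent.name, field_T=0.064, channel="R1",
        conc_nominal_mM=concs, conc_actual_mM=concs,
        rate_s=rates, included=included,
    )
    fit = fit_relaxivity(series)
    excl = [f"{concs[i]:g}" for i in sorted(reasons)]
    total_excluded += sum(c > 0 for c in (concs[i] for i in reasons))
    print(f"{agent.name:>12} {fit.r:>7.1f} {';'.join(excl) or '—':>25}")

print(f"\nexcluded datasets: {total_excluded} of {len(nonzero) * 7}")
# On exact linear rates the slope equals the tabulated relaxivity; the rule
# removes 11 of the 42 nonzero-concentration datasets — the fast-relaxing
# large particles at high concentration.
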