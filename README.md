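# lowfield-relax

Simulation and analysis of MRI contrast-agent relaxometry at low magnetic
field (64 mT), with a 3 T clinical-field comparison arm.

Point-of-care MRI scanners operating at tens of millitesla need their own
contrast agents: the Gd chelates that dominate clinical imaging lose most of
their advantage there, while superparamagnetic iron oxide nanoparticles
(SPIONs) — T2 agents at clinical fields — turn into excellent *positive* T1
agents at low field, with longitudinal relaxivities an order of magnitude
above their 3 T values and r2/r1 ratios near 1. This package implements the
full quantitative workflow used to characterize such agents, driven by a
synthetic-data generator with known ground truth so every estimator can be
validated end to end:

* **Phantom simulation** — multi-tube agarose phantoms imaged as magnitude
  inversion-recovery and multi-echo series at 64 mT and 3 T, with Rician
  noise and seeded reproducibility (`lowfield_relax.synthetic`).
* **Voxelwise T1/T2 mapping** — magnitude signal models
  `S = S0·|1 − (1+d)e^(−TI/T1) + e^(−TR/T1)|` and `S = S0·e^(−TE/T2)`,
  fitted by bounded multi-start nonlinear least squares
  (`lowfield_relax.mapping`).
* **Relaxivity analysis** — the linear relation `1/T = 1/T' + r·[CM]`
  fitted over a metal-concentration series, with ICP-OES concentration
  rescaling, the first-inversion-time exclusion rule (fitted T1 < first TI
  is unmeasurable and removed from *all* fits for that agent), r2/r1 ratios
  and fold enhancements (`lowfield_relax.relaxivity`).
* **Langevin magnetometry** — `M(B) = Ms·L(μB/kBT)` fits yielding the
  saturation magnetization, per-particle moment, effective magnetic
  diameter, and fraction of saturation at the imaging field
  (`lowfield_relax.magnetometry`).
* **NMRD dispersion modelling** — r1 versus proton Larmor frequency over
  0.01–40 MHz: a heuristic superparamagnetic model built from Langevin
  weights with Ayant (Curie term) and Freed (fluctuating term) spectral
  densities, and Solomon–Bloembergen–Morgan theory for Gd chelates, with
  weighted fitting and interpolation of r1 at 2.72 MHz
  (`lowfield_relax.nmrd`).
* **Pipeline** — a seeded, configured, manifest-checked orchestration of all
  stages (`lowfield_relax.pipeline`), plus a thin `lowfield-relax` CLI.

The built-in agent table covers seven agents: four monodisperse
carboxylic-acid-coated SPION sizes (4.9, 8.5, 12.9, 15.7 nm), the clinical
multi-core agents ferumoxytol and ferumoxides, and the Gd chelate Gd-BOPTA
(gadobenate dimeglumine), with published core diameters, saturation
magnetizations and relaxivities as simulation ground truth.

## Worked example

`examples/` contains one short script per capability. For instance,
Langevin magnetometry (`python examples/03_magnetometry_langevin.py`):

```
agent D: physical core diameter 15.7 nm
Ms = 42.3 ± 0.1 A·m²/kg (truth 42.4)
per-particle moment mu = 1.109e-19 J/T
effective magnetic diameter = 9.9 nm
fraction of saturation at 64 mT = 49%
Ms as % of bulk magnetite (92 A·m²/kg) = 46%
```

The fit recovers the generating saturation magnetization from a 1 %-noise
curve; the magnetic diameter is smaller than the physical core (surface
spin disorder), and at 64 mT these particles already sit at ~half of
saturation — the key to their strong low-field T1 performance.

NMRD dispersion (`python examples/04_nmrd_dispersion.py`):

```
dispersion peak vs particle size (D = 2.3e-9 m²/s, 21.5 °C):
    4.9 nm -> peak at 12.0 MHz
    8.5 nm -> peak at 7.8 MHz
   12.9 nm -> peak at 5.6 MHz
   15.7 nm -> peak at 4.5 MHz

fit of the 15.7 nm profile (converged=True):
  d      = 15.75 nm   (truth 15.7)
  tau_N  = 2.02e-09 s  (truth 2e-09)
  r1 @ 64 mT = 61.3 L/mmol/s (truth 61.5)
```

The dispersion peak shifts to lower frequency as the cores grow (the
translational-diffusion correlation time τ_D = d²/D lengthens), and for the
largest particles it lands close to the 64 mT proton Larmor frequency of
2.72 MHz. `examples/05_full_pipeline.py` runs the complete synthetic study
(all agents, both fields, SNR 50) in about a minute and prints the fitted
relaxivity table and fold enhancements over Gd-BOPTA.

## Layout

```
src/lowfield_relax/   library (synthetic, mapping, relaxivity,
                      magnetometry, nmrd, pipeline, io, cli)
examples/             one narrative script per capability
tests/                pytest suite
scripts/acceptance.py headline-quantity reproduction
docs/methods.md       models, assumptions, parameter choices, limitations
```
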