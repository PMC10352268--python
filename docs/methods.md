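# Methods

This note records the models implemented in `lowfield_relax`, the
assumptions behind them, the default parameter choices and why, and what the
synthetic-data generator does and does not emulate.

## Signal models and T1/T2 mapping

Magnitude inversion-recovery data are fitted with

    S(TI) = S0 · |1 − (1 + d)·e^(−TI/T1) + e^(−TR/T1)|

where d is the inversion-efficiency scale factor (d = 1 for a perfect 180°
pulse) and the absolute value reflects that magnitude images never recover
signal polarity. Multi-echo data follow S(TE) = S0·e^(−TE/T2). We fit the
absolute-value model directly rather than attempting polarity restoration;
this matches how the magnitude data are actually distributed but makes the
objective non-convex around the signal null. The voxel fitter therefore
multi-starts a bounded trust-region least-squares solve from a coarse T1
grid {50, 200, 800, 2000} ms and keeps the lowest-cost solution. Bounds:
T1 ∈ [1 ms, 20 s], T2 ∈ [1 ms, 5 s], d ∈ [0, 1.2]. The inversion factor is
fitted per voxel by default (it can be frozen); on noiseless synthetic data
both T1 and d are recovered to better than 0.1 %.

Two identifiability guards: voxels whose maximum signal is below 5× the
background noise estimate (a Rayleigh estimate from the image border) are
not fitted at all, and a fit whose best-fit curve is constant across the TI
range (e.g. a constant input signal, exactly representable by any
sufficiently short T1) is flagged `converged = False` rather than reported
as a confident estimate.

Default acquisition timings follow the two scanners being emulated:
15 inversion times from 100 to 2500 ms with TR = 3000 ms and ten echo times
from 37 to 702 ms at 64 mT; eleven inversion times from 50 to 6000 ms with
TR = 10000 ms and five echo times from 14 to 224 ms at 3 T.

## Relaxivity analysis

Relaxivity is the slope of rate against metal concentration,
1/T = 1/T′ + r·[CM], estimated per tube from the ROI median of the voxel
map and fitted by unweighted ordinary least squares (a weighted option uses
the per-rate standard errors). Nominal concentrations are rescaled by the
assayed/nominal stock ratio before fitting, and the generator applies the
same rescaling, so the analysis is exercised against consistent ground
truth.

Exclusion rule: a fitted T1 below the first inversion time of the protocol
(100 ms at 64 mT, 50 ms at 3 T — read from the protocol, not hard-coded)
cannot be measured and that concentration is excluded; for consistency the
same concentration is then removed from all four (field × channel) fits of
that agent. With the default agent table and background rates this removes
exactly 11 of the 42 nonzero-concentration datasets — the large particles at
0.25–1 mmol/L — a census that is insensitive to the (unpublished) agarose
background rate over roughly 0.2–0.8 s⁻¹.

Derived metrics (r2/r1 with quadrature errors, fold enhancement over a
reference agent, predicted T1 at a concentration) are computed from the
unrounded fits; rounding (half-up, one decimal) is applied only for report
tables.

## Langevin magnetometry

A monodisperse superparamagnet follows M(B) = Ms·L(μB/kBT) with
L(x) = coth x − 1/x. The Langevin function switches to its Taylor series
below |x| = 10⁻³, where the direct formula loses ~10⁻¹² absolute accuracy to
cancellation. Fits start from the curve itself (Ms from the plateau, μ from
the low-field slope Ms·μ/3kBT) and require fields reaching well into the
plateau (the default grid spans 0–7 T, 71 points). The effective magnetic
diameter follows d = (6μ/π·Ms_vol)^(1/3) with the volumetric Ms taken as
mass-Ms × 5180 kg/m³ (magnetite density; configurable — the true core
density of partially oxidized particles is unknown). Saturation-
magnetization uncertainties combine the magnetometry and elemental-assay
relative errors in quadrature. Only a single-population Langevin is
implemented; no moment-distribution (log-normal) fitting, and no ZFC/FC or
hysteresis analysis (the particles are superparamagnetic, with zero
remanence).

Default per-particle moments: the fitted magnetic diameters of the real
particles are not available, so each SPION's default μ is calibrated once so
that L(μB/kBT) at 64 mT and 294.65 K lies in the 40–50 % band that
characterizes these agents (Langevin arguments x between 1.45 and 1.75
across the seven agents). This makes the defaults physically coherent at the
imaging field while leaving the moment magnitudes nominal.

## NMRD dispersion models

An NMRD profile is r1 versus proton Larmor frequency ν = γ_I·B0/2π
(42.577478 MHz/T), measured by fast-field cycling over 0.01–40 MHz with
relative rate errors below 1 % — the default fit weights. Raw rates are
converted to relaxivity by subtracting the agent-free (diamagnetic agarose)
profile and dividing by the assayed metal concentration; negative residual
values are kept but flagged.

### Superparamagnetic (heuristic) model

For SPIONs, water-proton relaxation is dominated by translational diffusion
past the particle moment. The moment contributes both a static (Curie) part
— its thermal average, growing with field through the Langevin factor — and
a fluctuating part modulated by Néel reversal. The implemented form is

    r1(ν) = K · [ 3·L(x)²·J_A(ω, τ_D)
                  + 3·(1 − L(x)² − 2L(x)/x)·J_F(ω, τ_D, τ_N)
                  + (7/2)·(2L(x)/x)·J_F(ω, τ_D, τ_N) ]

with x = μB0/kBT, ω = 2πν, τ_D = d²/D the diffusion correlation time for
distance of closest approach d and solvent diffusion coefficient D, τ_N the
Néel time, J_A the Ayant spectral density (static moment under diffusion)
and J_F the Freed spectral density (diffusion with an exchange/Néel cut-off,
z = sqrt(iωτ_D + τ_D/τ_N)). The x → 0 limits of the weights (L² → 0,
2L/x → 2/3) are evaluated analytically, so the model is smooth through zero
field. The weight constants (3, 7/2) are a documented transcription choice
exposed in `SPMParams`; K is a fitted amplitude absorbing particle number
density, moment magnitude and unit conventions — standard practice when the
stoichiometric prefactors are uncertain. Validation of this model is
structural (zero-frequency limits, peak window and ordering, parameter
round-trips), never literature-constant-exact.

The model reproduces the characteristic SPION dispersion shape: a low-field
plateau set by the Freed terms, a rise as L(x)² grows, and a peak followed
by the diffusive cut-off. With D = 2.3·10⁻⁹ m²/s the peaks for 8.5–15.7 nm
cores fall between 2 and 10 MHz and shift monotonically to lower frequency
with increasing size. Two caveats discovered during validation and worth
recording: the peak position is co-determined by the Langevin-weight rise,
which is anchored to the field axis and does not move with d or D, so the
peak does *not* scale as 1/τ_D; in the saturated-moment regime the Ayant
small-u expansion puts it on a τ_D^(−1/3) drift instead (verified to ~6 %
over d ∈ [5, 20] nm). And when profiles are recomputed for media with
different diffusion coefficients, the dipolar outer-sphere amplitude's
1/(d·D) proportionality must be carried along (K rescaled by D_ref/D);
rescaling τ_D alone would wrongly *suppress* relaxivity in slow media
through the Freed τ_D/τ_N ratio. With the amplitude carried, slower media
shift the peak down-frequency and enhance r1 at the imaging field, the
behaviour expected for tissue environments.

Per-temperature parameters are fitted independently (no Arrhenius coupling);
the water diffusion coefficient is frozen at the temperature-appropriate
bulk value (2.3·10⁻⁹ m²/s near room temperature, 3.0·10⁻⁹ at 37 °C) rather
than fitted. Correlation times are fitted as log10 values — their natural
scale spans decades and linear-scale steps stall the optimizer.

### Solomon–Bloembergen–Morgan model

Gd chelates are fitted with inner-sphere SBM: r1_IS = (q/55500)/(T_1M + τ_M)
with the dipolar rate

    1/T_1M = (2/15)(μ0/4π)²γ_I²g²μ_B²S(S+1)/r_GdH⁶ ·
             [3τ_c1/(1+ω_I²τ_c1²) + 7τ_c2/(1+ω_S²τ_c2²)]

1/τ_ci = 1/τ_R + 1/τ_M + 1/T_ie, electron relaxation from the transient
zero-field-splitting (Δ², τ_V) expressions, ω_S = 658.2·ω_I, S = 7/2, plus
an optional hard-sphere outer-sphere term with Freed densities (electron
relaxation is slow against τ_D for Gd at these fields, so pure translational
modulation is used there). Defaults are typical chelate values (q = 1,
r_GdH = 3.0 Å, τ_M = 160 ns, τ_R = 80 ps, τ_V = 20 ps, Δ² = 4·10¹⁹ s⁻²,
with faster exchange/rotation at 37 °C); an overall `scale` amplitude
absorbs speciation and second-sphere contributions.

### Amplitude anchoring of synthetic profiles

The synthetic generator anchors each agent's forward-model amplitude so that
the model evaluated at 2.72 MHz (the 64 mT proton frequency) equals the
agent's tabulated dispersion relaxivity at that temperature. Structural
parameters (d, τ_N, μ) stay at their ground-truth values, so fits recover
them nontrivially while the profile heights remain realistic.

## Synthetic data: what it emulates, what it does not

The generator emulates: multi-tube agarose phantoms (circular tubes on an
axial slice, 0-based (row, col, slice) voxel indices) with per-tube rates
from the linear relaxivity relation; magnitude images with Rician noise (two
Gaussian channels then the modulus; SD expressed as a fraction of S0 = 1,
SNR 50 by default); magnetization curves over 0–7 T at 294.65 K (Langevin
for SPIONs, linear χB for the chelate, χ = 0.15 A·m²/kg/T so the chelate
stays far below the SPION curves); NMRD profiles on a 0.01–40 MHz log grid
with 1 % multiplicative noise; and the 0, 0.03, 0.06, 0.12, 0.25, 0.5,
1 mmol/L concentration ladder (the 3 T series omits the blank — that sample
holder takes one fewer tube). All generators are bit-reproducible under a
fixed seed, and with noise off they equal the analytic forward models
exactly.

It does **not** emulate: k-space acquisition, coil sensitivities, fast-spin-
echo echo-train artifacts, B0/B1 inhomogeneity, image registration error,
partial-volume effects at tube edges, polydisperse core sizes, particle
clustering in the multi-core agents, or colloidal instability. Eq-level
signal models are treated as exact voxel physics. Passing recovery tests
therefore demonstrates the correctness and noise robustness of the
estimators, not the fidelity of any scanner. The agarose background rates
(R1′ = 0.35 s⁻¹, R2′ = 1.5 s⁻¹ at 64 mT; 0.40/2.0 s⁻¹ at 3 T) are
placeholder defaults — blank-gel values are rarely published — and are
configurable; the relaxivity slope estimates are insensitive to them. The
multi-core agents carry nominal effective NMRD diameters (ferumoxytol
6.5 nm, ferumoxides 5.0 nm) because no physical core diameter is defined for
a clustered agent.

## Numerical choices

* Voxel fits use `scipy.optimize.least_squares` (trust-region reflective)
  for throughput; curve-level NMRD fits use lmfit; relaxivity lines use
  `scipy.stats.linregress`.
* The Langevin function and the SPM weight functions switch to series
  expansions below |x| = 10⁻³ and 10⁻⁶ respectively.
* ROI summaries use the median over converged voxels for rates (robust to
  the occasional null-point misfit) and mean ± sample SD for intensities.
* Ties/degenerate inputs: empty ROIs, all-zero signals, fewer than 4 TIs /
  3 TEs, fewer than 2 included concentrations, overlapping tubes and
  non-monotone TI/TE lists all raise explicit errors; non-converged fits are
  flagged and propagated, never silently dropped.
* Problem sizes used by the default study: 48×48×1 phantom grids with
  7 tubes of radius 3 voxels per agent/field, 71-point magnetization curves,
  25-point NMRD grids, 50-repeat noise ensembles. These sizes put every
  Monte-Carlo bound well away from its threshold while keeping a full run
  around a minute.

## Known limitations

* The SPM weight set is one documented transcription of the
  superparamagnetic relaxation literature; other weight conventions rescale
  K and the term balance. Fitted d and τ_N should be read as effective
  parameters of this form.
* SBM electron-relaxation here is the transient-ZFS approximation; static
  ZFS and spin-dynamics corrections relevant below ~1 MHz for some chelates
  are out of scope.
* The exclusion rule operates on fitted T1 only (as defined); very short T2
  at 3 T for the largest particles is handled implicitly because the same
  concentrations are excluded for consistency.
* Magnetometry assumes a single moment population; polydispersity biases μ
  toward the volume-weighted mean and makes the magnetic diameter an
  effective, not literal, size.
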