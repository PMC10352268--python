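"""Physical constants and field-specific reference values.

CODATA values; units are SI unless a name says otherwise.
"""

# Fundamental constants
BOLTZMANN = 1.380649e-23            # J/K
BOHR_MAGNETON = 9.2740100783e-24    # J/T
MU0_OVER_4PI = 1.0e-7               # T·m/A
AVOGADRO = 6.02214076e23            # 1/mol
G_ELECTRON = 2.0                    # electron g-factor used in dipolar prefactors

# Proton gyromagnetic ratio
GAMMA_PROTON = 2.6752218744e8       # rad s^-1 T^-1
GAMMA_PROTON_MHZ_PER_T = 42.577478  # MHz/T (gamma / 2 pi)

# Electron/proton Larmor frequency ratio (gamma_S / gamma_I)
OMEGA_S_OVER_OMEGA_I = 658.2

# Reference material properties
BULK_MAGNETITE_MS = 92.0            # A·m²/kg, bulk Fe3O4 at room temperature
MAGNETITE_DENSITY_KG_M3 = 5180.0    # kg/m³, used to convert mass Ms to volumetric Ms

# Self-diffusion coefficient of water, m²/s, by temperature in °C.
# 2.3e-9 is the conventional room-temperature value used for outer-sphere
# relaxation modelling; 3.0e-9 approximates 37 °C.
WATER_DIFFUSION = {
    15.0: 1.77e-9,
    21.5: 2.3e-9,
    25.0: 2.3e-9,
    37.0: 3.0e-9,
}

ROOM_TEMPERATURE_K = 294.65         # 21.5 °C, the magnetometry/MRI lab temperature
BODY_TEMPERATURE_K = 310.15         # 37 °C


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


def water_diffusion_coefficient(temperature_c: float) -> float:
    """Water self-diffusion coefficient (m²/s) at the nearest tabulated temperature."""
    key = min(WATER_DIFFUSION, key=lambda t: abs(t - temperature_c))
    return WATER_DIFFUSION[key]
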