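"""Physical constants and the package's unit conventions.

Internal unit system: lengths in nm, times in microseconds, energies in
units of k_B*T, potentials in volts, rates in 1/s (kinetics) or 1/us
(rotational diffusion).  All conversions between SI and internal units
live here so that no other module hard-codes a conversion factor.
"""

# CODATA 2018 exact values
BOLTZMANN_J_PER_K = 1.380649e-23
ELEMENTARY_CHARGE_C = 1.602176634e-19

# unit conversions
NM_PER_M = 1e9
M_PER_NM = 1e-9
US_PER_S = 1e6
S_PER_US = 1e-6

# defaults for aqueous buffer at 25 C
DEFAULT_TEMPERATURE_K = 298.15
DEFAULT_VISCOSITY_PA_S = 0.89e-3
DEFAULT_IONIC_STRENGTH_MM = 50.0

# Debye length of a monovalent electrolyte in water at 298 K:
# lambda_D [nm] = DEBYE_PREFACTOR_NM / sqrt(I [mol/L])
DEBYE_PREFACTOR_NM = 0.304


def thermal_energy_J(T: float) -> float:
    """k_B*T in joules at temperature T (kelvin)."""
    return BOLTZMANN_J_PER_K * T


def thermal_voltage_V(T: float) -> float:
    """k_B*T/e in volts: converts e*Phi energies to k_B*T units."""
    return BOLTZMANN_J_PER_K * T / ELEMENTARY_CHARGE_C


def debye_length_nm(ionic_strength_mM: float) -> float:
    """Debye screening length (nm) of a monovalent salt solution at 298 K."""
    if ionic_strength_mM <= 0:
        raise ValueError("ionic strength must be positive")
    return DEBYE_PREFACTOR_NM / (ionic_strength_mM * 1e-3) ** 0.5
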