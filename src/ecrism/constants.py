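"""Physical constants and unit conversions.

Internal unit system: lengths in Angstrom, energies in kcal/mol, charges in
units of the elementary charge e, temperatures in K, magnetic fields in mT,
frequencies in MHz.  Spin densities are accepted in atomic units (a0^-3),
the convention in which quantum-chemistry codes print them.
"""

from __future__ import annotations

import scipy.constants as _C

#: Coulomb constant e^2/(4 pi eps0) in kcal*A/(mol*e^2).
COULOMB_KCAL = _C.e**2 / (4 * _C.pi * _C.epsilon_0) * _C.N_A / (4184.0 * 1e-10)

#: Boltzmann constant in kcal/(mol*K).
KB_KCAL = _C.k * _C.N_A / 4184.0

#: Free-electron g-factor (positive magnitude convention).
G_ELECTRON = abs(_C.value("electron g factor"))

#: Bohr magneton, J/T.
MU_B = _C.value("Bohr magneton")

#: Nuclear magneton, J/T.
MU_N = _C.value("nuclear magneton")

#: Planck constant, J*s.
PLANCK_H = _C.h

#: Bohr radius in Angstrom.
BOHR_A = _C.value("Bohr radius") * 1e10


def beta_kcal(temperature: float) -> float:
    """Inverse temperature 1/(kB*T) in mol/kcal."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return 1.0 / (KB_KCAL * temperature)


def fermi_contact_prefactor() -> float:
    """Fermi-contact conversion factor in MHz per (g_N * a0^-3) at S=1/2.

    A_iso = prefactor * g_N * rho(R_N) / (2S), with the spin density rho in
    atomic units.  Built from CODATA constants:
    (2 mu0 / 3) * g_e * mu_B * mu_N / h / a0^3.
    """
    a0 = _C.value("Bohr radius")
    return (2 * _C.mu_0 / 3) * G_ELECTRON * MU_B * MU_N / _C.h / a0**3 / 1e6


def field_per_mhz(g_value: float) -> float:
    """Hyperfine splitting in field units: mT of field per MHz of coupling.

    a_field = A_iso * h / (g * mu_B); at g ~ 2 this is ~0.0357 mT/MHz.
    """
    return _C.h / (g_value * MU_B) * 1e6 * 1e3


def resonance_field_mt(frequency_ghz: float, g_value: float) -> float:
    """Center field B0 = h*nu/(g*mu_B) in mT."""
    return _C.h * frequency_ghz * 1e9 / (g_value * MU_B) * 1e3
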