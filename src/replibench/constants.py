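"""Frozen physical constants and unit-conversion factors.

Internal units throughout the package: energy kJ/mol, length Å, temperature K,
pressure kPa, mass g/mol, time ps.  Every conversion anywhere in the package
goes through the constants below; none of them is configurable, because the
whole point of the provenance machinery is that printed parameter conversions
must be reproducible bit-for-bit.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """2019 SI exact values (CODATA)."""

    boltzmann: float = 1.380649e-23  # J/K
    avogadro: float = 6.02214076e23  # 1/mol
    calorie: float = 4.184           # J per thermochemical calorie

    @property
    def gas_constant_kj(self) -> float:
        """k_B * N_A in kJ/(mol K)."""
        return self.boltzmann * self.avogadro / 1000.0


CONSTANTS = PhysicalConstants()

#: k_B N_A in kJ/(mol K)
R_KJ = CONSTANTS.gas_constant_kj

#: elementary charge (C) and vacuum permittivity (F/m), CODATA 2018
ELEMENTARY_CHARGE = 1.602176634e-19
VACUUM_PERMITTIVITY = 8.8541878128e-12

#: Coulomb prefactor q_i q_j / r with q in e and r in Å -> kJ/mol
import math as _math

COULOMB_KJ_A = (
    CONSTANTS.avogadro
    * ELEMENTARY_CHARGE**2
    / (4.0 * _math.pi * VACUUM_PERMITTIVITY * 1.0e-10)
    / 1000.0
)

#: 1 (kJ/mol)/Å^3 expressed in kPa
KJMOL_A3_TO_KPA = 1.0e30 / CONSTANTS.avogadro

#: p[kPa] * V[Å^3] expressed in kJ/mol
KPA_A3_TO_KJMOL = 1.0 / KJMOL_A3_TO_KPA

#: mass density: rho[kg/m^3] = DENSITY_FACTOR * M_total[g/mol] / V[Å^3]
DENSITY_FACTOR = 1.0e27 / CONSTANTS.avogadro

#: kinetic energy: 1 (g/mol)(Å/ps)^2 = 0.01 kJ/mol
KE_FACTOR = 0.01
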