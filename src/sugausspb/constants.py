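"""Physical constants and unit conversions.

All internal work happens in the natural units of grid Poisson-Boltzmann
solvers: lengths in angstrom, charges in units of the elementary charge,
potentials in kT/e.  Conversion to kcal/mol happens only when an energy is
reported.  Everything here is derived from CODATA values at run time; no
pre-multiplied magic constants appear in the formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

# CODATA 2018 exact/recommended values (SI)
ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
CALORIE = 4.184  # J

ANGSTROM = 1e-10  # m


def coulomb_prefactor(temperature: float) -> float:
    """e^2 / (4 pi eps0 kB T * 1 A): Coulomb energy of two unit charges 1 A
    apart in vacuum, in kT units.

    Multiplying ``q1*q2/(eps_rel * d_A)`` by this gives an interaction in kT;
    equivalently the potential of a unit charge in kT/e.  ~557 at 300 K.
    """
    e2 = ELEMENTARY_CHARGE**2
    return e2 / (4.0 * math.pi * VACUUM_PERMITTIVITY * BOLTZMANN * temperature * ANGSTROM)


def kt_kcal_mol(temperature: float) -> float:
    """kB*T in kcal/mol (0.59616 at 300 K)."""
    return BOLTZMANN * temperature * AVOGADRO / (CALORIE * 1000.0)


def coulomb_kcal_mol() -> float:
    """The Coulomb constant in kcal*A/(mol*e^2), ~332.06."""
    e2 = ELEMENTARY_CHARGE**2
    joule = e2 / (4.0 * math.pi * VACUUM_PERMITTIVITY * ANGSTROM)
    return joule * AVOGADRO / (CALORIE * 1000.0)


def compute_kappa2(salt_molar: float, temperature: float) -> float:
    """Debye-Huckel screening coefficient kappa^2 in 1/A^2 for a 1:1 salt.

    Defined on the eps=1 basis so that it enters the linearized PB operator
    as ``[1-S] kappa^2 phi`` next to the relative dielectric: the far-field
    decay in a solvent of dielectric ``eps_out`` is exp(-r*sqrt(kappa^2/
    eps_out)), i.e. the standard Debye length.  kappa^2 is linear in the
    ionic strength I (mol/L) and inversely proportional to T.  Zero at I=0.
    """
    if salt_molar < 0:
        raise ValueError("salt concentration must be >= 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if salt_molar == 0.0:
        return 0.0
    # number density of each ion species: (mol/L) * NA / (1e27 A^3/L)
    n = AVOGADRO * salt_molar * 1e-27
    bjerrum = coulomb_prefactor(temperature)  # = Bjerrum length at eps=1, in A
    return 8.0 * math.pi * bjerrum * n


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of the run-time constants a solve needs.

    Attributes
    ----------
    coulomb_prefactor : e^2/(kB T 4 pi eps0 A) in kT*A/e^2 (relative-eps basis).
    kT_kcal_mol : kB*T in kcal/mol.
    kappa2 : Debye-Huckel coefficient, 1/A^2 (0 for salt-free solvent).
    temperature : K.
    """

    coulomb_prefactor: float
    kT_kcal_mol: float
    kappa2: float
    temperature: float

    @classmethod
    def at(cls, temperature: float = 300.0, salt_molar: float = 0.0) -> "PhysicalConstants":
        return cls(
            coulomb_prefactor=coulomb_prefactor(temperature),
            kT_kcal_mol=kt_kcal_mol(temperature),
            kappa2=compute_kappa2(salt_molar, temperature),
            temperature=temperature,
        )
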