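"""Units convention used throughout the package.

All public APIs work in a single, fixed unit system:

=============  =====================
quantity       unit
=============  =====================
energy         kcal mol⁻¹
length         Å
time           ps
temperature    K
mass           amu
=============  =====================

Velocities are therefore Å ps⁻¹ and forces kcal mol⁻¹ Å⁻¹.  Because
kinetic energy in amu Å² ps⁻² is not directly a kcal mol⁻¹ figure, masses
entering the equations of motion are converted once with
:data:`MASS_TO_KCAL`, so that ``0.5 * m_eff * v**2`` is a kcal mol⁻¹
kinetic energy and ``F = m_eff * a`` holds in the working units.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant, kcal mol⁻¹ K⁻¹.
KB = 1.9872041e-3

#: 1 amu Å² ps⁻² expressed in kcal mol⁻¹ (= 10 J mol⁻¹ / 4184 J kcal⁻¹).
MASS_TO_KCAL = 10.0 / 4184.0

#: Standard atomic masses (amu) for the elements the toy systems and the
#: minimal PDB reader care about.  Anything unknown falls back to carbon.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
}

DEFAULT_MASS = 12.011


def kt(temperature: float) -> float:
    """Thermal energy k_B·T in kcal mol⁻¹ for a temperature in K."""
    return KB * temperature


def mass_of(element: str) -> float:
    """Atomic mass (amu) for an element symbol, case-insensitive."""
    return ATOMIC_MASSES.get(element.capitalize(), DEFAULT_MASS)


@dataclass(frozen=True)
class UnitsConvention:
    """Immutable record of the package-wide unit system."""

    energy: str = "kcal/mol"
    length: str = "angstrom"
    time: str = "ps"
    temperature: str = "K"
    mass: str = "amu"
    kB: float = KB


UNITS = UnitsConvention()
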