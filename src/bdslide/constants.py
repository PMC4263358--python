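"""Physical constants and unit conventions.

Internal units: lengths in Å, energies in kcal/mol, times in ns (time steps
are specified in ps and converted), charges in units of the elementary
charge e, temperatures in K, viscosities in cP (mPa·s).

Diffusion coefficients are in Å²/ns; note 1 Å²/ns = 1e-7 cm²/s.
"""

import numpy as np

#: Boltzmann constant in kcal/mol/K (thermochemical calorie).
KB = 1.987204259e-3

#: Default simulation temperature, K.
T_DEFAULT = 298.0

#: kB*T at the default temperature, kcal/mol.
KBT = 0.59248

#: Electrostatic conversion e^2/(4 pi eps0) in kcal·Å/mol.
C_ELEC = 332.06

#: Default solvent viscosity, cP (water at room temperature).
ETA_DEFAULT = 0.89

#: Boltzmann constant, J/K (SI, for hydrodynamic mobilities).
KB_SI = 1.380649e-23

#: Avogadro number, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Vacuum permittivity, F/m.
EPS0_SI = 8.8541878128e-12

#: Elementary charge, C.
E_CHARGE_SI = 1.602176634e-19


def kbt(temperature: float = T_DEFAULT) -> float:
    """kB*T in kcal/mol.

    At the default temperature this returns the conventional room-temperature
    value 0.59248 kcal/mol exactly, so that force constants defined as
    multiples of kB*T (the DNA bond table) reproduce their printed values.
    """
    if temperature == T_DEFAULT:
        return KBT
    return KB * temperature


def mobility_scale(temperature: float = T_DEFAULT, eta: float = ETA_DEFAULT) -> float:
    """kB*T / (6 pi eta) in Å³/ns.

    This is the numerator of the Stokes–Einstein relation: the translational
    diffusion coefficient of a sphere of Stokes radius a (Å) is
    ``mobility_scale()/a`` in Å²/ns.  At the defaults (298 K, 0.89 cP) the
    value is ~245.4 Å³/ns.
    """
    kbt_si = kbt(temperature) * 4184.0 / N_AVOGADRO  # J
    return kbt_si / (6.0 * np.pi * eta * 1e-3) * 1e21


def rotational_mobility_scale(temperature: float = T_DEFAULT,
                              eta: float = ETA_DEFAULT) -> float:
    """kB*T / (8 pi eta) in Å³/ns (rotational Stokes–Einstein numerator)."""
    return mobility_scale(temperature, eta) * 6.0 / 8.0
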