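"""Physical constants and the reduced unit system.

The model works in reduced units anchored by the solvent-mediated contact
energy ``EPSILON_KCAL = 0.6 kcal/mol``: energies are reported in units of
epsilon, lengths in Angstrom, masses in units of a bead mass, and time in
``tau_L = sigma * sqrt(m / epsilon)``.  Electrostatics is the one place
physical constants enter; the screened-Coulomb energy is evaluated in
kcal/mol and divided by ``EPSILON_KCAL`` on the way out.
"""

import math

# Energy unit of the coarse-grained Hamiltonian.
EPSILON_KCAL = 0.6  # kcal/mol

# CODATA 2018.
ELEMENTARY_CHARGE = 1.602176634e-19  # C
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
BOLTZMANN_SI = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol

# Gas constant in the units the thermal-unfolding fits use.
R_KCAL = 1.98720425864083e-3  # kcal/(mol K)

# e^2 N_A / (4 pi eps0) expressed in kcal * Angstrom / mol: the Coulomb
# prefactor so that V = COULOMB_KCAL_ANG * Z_i Z_j / (eps_r * r[A]).
COULOMB_KCAL_ANG = (
    ELEMENTARY_CHARGE**2
    * AVOGADRO
    / (4.0 * math.pi * VACUUM_PERMITTIVITY)
    / 4184.0
    / 1.0e-10
)

# Default vdW diameter of a backbone (C-alpha) bead, Angstrom.
SIGMA_BACKBONE = 3.8
# Calcium bead vdW diameter, Angstrom (ionic diameter scale).
SIGMA_CALCIUM = 2.0
# Ficoll 70 crowder: hard-sphere radius 55 A -> vdW diameter 110 A.
CROWDER_RADIUS = 55.0
SIGMA_CROWDER = 2.0 * CROWDER_RADIUS

# Steric scaling factor of the repulsive term, f in sigma_bar = f(s_i+s_j)/2.
STERIC_SCALING = 0.9

# Spring constants of the bonded terms, in epsilon units.
K_BOND = 100.0
K_ANGLE = 20.0


def bjerrum_length(eps_r: float = 80.0, temperature_K: float = 298.0) -> float:
    """Distance at which two unit charges interact with 1 k_BT, in Angstrom."""
    kT_kcal = R_KCAL * temperature_K
    return COULOMB_KCAL_ANG / (eps_r * kT_kcal)


def debye_kappa(
    ionic_strength_M: float, eps_r: float = 80.0, temperature_K: float = 298.0
) -> float:
    """Inverse Debye screening length, 1/Angstrom.

    kappa^2 = 2 N_A e^2 I*10^3 / (eps0 eps_r k_B T) with I in mol/L.
    """
    if ionic_strength_M < 0:
        raise ValueError("ionic strength must be >= 0")
    if ionic_strength_M == 0:
        return 0.0
    kappa_sq_si = (
        2.0
        * AVOGADRO
        * ELEMENTARY_CHARGE**2
        * ionic_strength_M
        * 1.0e3
        / (VACUUM_PERMITTIVITY * eps_r * BOLTZMANN_SI * temperature_K)
    )
    return math.sqrt(kappa_sq_si) * 1.0e-10  # 1/m -> 1/A


def debye_length(
    ionic_strength_M: float, eps_r: float = 80.0, temperature_K: float = 298.0
) -> float:
    """Debye screening length, Angstrom (inf at I = 0)."""
    kappa = debye_kappa(ionic_strength_M, eps_r, temperature_K)
    return math.inf if kappa == 0.0 else 1.0 / kappa
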