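"""Core-shell ferrofluid composition from elemental analysis.

A gold-coated magnetite (Fe3O4@Au) ferrofluid generally contains both coated
and bare magnetite particles.  Direct current plasma atomic emission
spectroscopy (DCP-AES) yields two atom-count ratios: iron-to-gold over the
whole fluid, N_Fe(T)/N_Au, and iron-to-gold within the coated particles,
N_Fe(C)/N_Au.  From these two numbers this module derives

* the fraction of uncoated magnetite particles in the fluid,
* the gold-to-iron atomic ratio AR = N_Au / (3 N_Fe(C))  (each Fe3O4 formula
  unit carries three iron atoms), and
* the mean gold-shell thickness of a spherical core-shell particle, by
  inverting the mass balance between the shell volume and the core volume.

All lengths are accepted in nanometres and densities in g/cm^3 (the units in
which such measurements are reported) and converted to SI once at the
constructor boundary; internal arithmetic is SI throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "AtomRatioSpec",
    "CoreShellGeometry",
    "uncoated_fraction",
    "gold_iron_atomic_ratio",
    "gold_iron_atomic_ratio_from_masses",
    "core_mass",
    "shell_mass",
    "shell_thickness",
    "atomic_ratio_from_geometry",
    "composition_summary",
]

# Default molar masses (g/mol)
M_FE3O4 = 231.5326
M_AU = 196.9666


@dataclass(frozen=True)
class AtomRatioSpec:
    """DCP-AES atom-count ratios of a partially coated ferrofluid.

    Parameters
    ----------
    r_total : float
        N_Fe(T)/N_Au — iron atoms in the whole fluid per gold atom.
    r_coated : float
        N_Fe(C)/N_Au — iron atoms inside coated particles per gold atom.
    """

    r_total: float
    r_coated: float

    def __post_init__(self):
        if self.r_total <= 0 or self.r_coated <= 0:
            raise ValueError("atom-count ratios must be strictly positive")
        if self.r_coated > self.r_total:
            raise ValueError(
                "r_coated > r_total would imply a negative uncoated fraction"
            )


@dataclass(frozen=True)
class CoreShellGeometry:
    """Spherical core-shell particle geometry and material constants.

    Lengths in nm, densities in g/cm^3, molar masses in g/mol; converted to
    SI on access through the ``*_si`` properties.
    """

    D_core: float  # core diameter (nm)
    d_shell: float = 0.0  # shell thickness (nm)
    rho_core: float = 5.196  # g/cm^3 (magnetite)
    rho_shell: float = 19.3  # g/cm^3 (gold)
    M_core: float = M_FE3O4  # g/mol
    M_shell: float = M_AU  # g/mol

    def __post_init__(self):
        if self.D_core <= 0:
            raise ValueError("core diameter must be positive")
        if self.d_shell < 0:
            raise ValueError("shell thickness cannot be negative")
        for name in ("rho_core", "rho_shell", "M_core", "M_shell"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def D_core_si(self) -> float:
        """Core diameter in metres."""
        return self.D_core * 1e-9

    @property
    def d_shell_si(self) -> float:
        return self.d_shell * 1e-9

    @property
    def rho_core_si(self) -> float:
        """Core density in kg/m^3."""
        return self.rho_core * 1e3

    @property
    def rho_shell_si(self) -> float:
        return self.rho_shell * 1e3


def uncoated_fraction(ratios: AtomRatioSpec) -> float:
    """Fraction of bare (uncoated) magnetite particles in the ferrofluid.

    N_Fe(U)/N_Fe(T) = 1 - N_Fe(C)/N_Fe(T) = 1 - r_coated/r_total.
    """
    return 1.0 - ratios.r_coated / ratios.r_total


def gold_iron_atomic_ratio(r_coated: float) -> float:
    """Gold-to-iron atomic ratio AR = N_Au/(3 N_Fe(C)) of coated particles."""
    if r_coated <= 0:
        raise ValueError("r_coated must be strictly positive")
    return 1.0 / (3.0 * r_coated)


def gold_iron_atomic_ratio_from_masses(
    m_shell: float, m_core: float, M_shell: float = M_AU, M_core: float = M_FE3O4
) -> float:
    """AR from component masses: (m_Au/M_Au) / (3 m_Fe3O4/M_Fe3O4).

    Mole-count form of the same ratio; agrees with the atom-count form when
    the masses come from the same particle population.
    """
    if m_core <= 0:
        raise ValueError("core mass must be positive")
    return (m_shell / M_shell) / (3.0 * m_core / M_core)


def core_mass(geom: CoreShellGeometry) -> float:
    """Mass of the magnetite core (kg): (pi/6) D^3 rho."""
    return math.pi / 6.0 * geom.D_core_si**3 * geom.rho_core_si


def shell_mass(geom: CoreShellGeometry) -> float:
    """Mass of the gold shell (kg): (pi/6) [(D + 2 d)^3 - D^3] rho."""
    D, d = geom.D_core_si, geom.d_shell_si
    return math.pi / 6.0 * ((D + 2.0 * d) ** 3 - D**3) * geom.rho_shell_si


def atomic_ratio_from_geometry(geom: CoreShellGeometry) -> float:
    """AR implied by a given core-shell geometry (forward mass balance)."""
    return gold_iron_atomic_ratio_from_masses(
        shell_mass(geom), core_mass(geom), geom.M_shell, geom.M_core
    )


def shell_thickness(AR: float, geom: CoreShellGeometry) -> float:
    """Gold-shell thickness (nm) from the atomic ratio, by cube-root inversion.

    d_shell = (D_core/2) [ (1 + 3 AR (rho_core/rho_shell)(M_shell/M_core))^(1/3) - 1 ]

    Inverse of :func:`atomic_ratio_from_geometry`; the round trip recovers AR
    to ~1e-12 relative.
    """
    if AR < 0:
        raise ValueError("atomic ratio cannot be negative")
    factor = 1.0 + 3.0 * AR * (geom.rho_core / geom.rho_shell) * (
        geom.M_shell / geom.M_core
    )
    return 0.5 * geom.D_core * (factor ** (1.0 / 3.0) - 1.0)


def composition_summary(
    ratios: AtomRatioSpec, geom: CoreShellGeometry
) -> dict[str, float]:
    """Full composition chain as a flat record (CLI / reporting surface)."""
    AR = gold_iron_atomic_ratio(ratios.r_coated)
    d_shell = shell_thickness(AR, geom)
    resolved = CoreShellGeometry(
        D_core=geom.D_core,
        d_shell=d_shell,
        rho_core=geom.rho_core,
        rho_shell=geom.rho_shell,
        M_core=geom.M_core,
        M_shell=geom.M_shell,
    )
    return {
        "uncoated_fraction": uncoated_fraction(ratios),
        "atomic_ratio": AR,
        "d_shell_nm": d_shell,
        "core_mass_kg": core_mass(resolved),
        "shell_mass_kg": shell_mass(resolved),
    }
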