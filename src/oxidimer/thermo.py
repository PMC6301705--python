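"""Species-level thermochemistry: free-energy composition and constants.

All energies are kept in kcal/mol internally.  Hartree input is accepted at
the registry boundary and converted once (factor 627.509474).  The Gibbs free
energy of a species is composed from the electronic (or solution-phase total)
energy and the harmonic thermal correction::

    G = E_T + G_corr

with an enthalpy variant ``H = E_T + H_corr`` used for bond-dissociation
*enthalpies*.  The bare proton is special-cased: its free energy is an
empirical literature value per phase, and no value exists for heptane.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from types import MappingProxyType
from typing import Mapping, Optional

from .errors import HeptaneProtonError, MissingDataError

__all__ = [
    "Phase",
    "Compound",
    "Constants",
    "CONSTANTS",
    "ThermoRecord",
    "HARTREE_TO_KCAL",
    "hartree_to_kcal",
    "kcal_to_hartree",
    "free_energy",
    "enthalpy",
    "proton_free_energy",
]

HARTREE_TO_KCAL = 627.509474


class Phase(str, Enum):
    """Solvation environment of a single-point calculation."""

    GAS = "gas"
    HEPTANE = "heptane"
    WATER = "water"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Compound(str, Enum):
    """Monomer families; ``SHARED`` marks phase-wide small species (H*, O2...)."""

    AP2 = "2AP"
    L3HOK = "L3HOK"
    HAA3 = "3HAA"
    HAA3I = "3HAAi"
    SHARED = "shared"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The four monomer families the network applies to.
COMPOUNDS = (Compound.AP2, Compound.L3HOK, Compound.HAA3, Compound.HAA3I)


@dataclass(frozen=True)
class Constants:
    """Physical constants and unit conventions.

    ``std_state_factor`` (1 atm -> 1 M standard-state conversion) and
    ``wigner_coeff`` (cm*K) are kept at the literature-printed 24.3 and 1.44
    by default so that printed rate tables are reproduced bit-for-bit; the
    physically exact alternatives (24.465 at 298.15 K, hc/kB = 1.43877 cm*K)
    may be passed explicitly and shift rates by ~0.2-1%.
    """

    T: float = 298.15  # K
    kB: float = 1.380649e-23  # J/K
    h: float = 6.62607015e-34  # J*s
    R_cal: float = 1.987204  # cal mol^-1 K^-1
    std_state_factor: float = 24.3
    wigner_coeff: float = 1.44  # cm*K
    hartree_to_kcal: float = HARTREE_TO_KCAL
    #: literature proton free energies, kcal/mol; heptane deliberately absent
    G_proton: Mapping[Phase, float] = field(
        default_factory=lambda: MappingProxyType(
            {Phase.GAS: -6.28, Phase.WATER: -272.18}
        )
    )

    def __post_init__(self) -> None:
        for name in ("T", "kB", "h", "R_cal", "std_state_factor", "wigner_coeff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name} must be positive")


CONSTANTS = Constants()


@dataclass(frozen=True)
class ThermoRecord:
    """One species in one phase.

    ``E_T`` is the single-point total energy (gas) or total free energy in
    solution; ``G_corr`` the thermal correction to the Gibbs energy;
    ``H_corr`` the optional thermal enthalpy correction.  ``optimized_in``
    records where the geometry/Hessian came from (ion-radicals unstable in
    the gas phase are optimized in water), which is bookkeeping only: energy
    differences are always taken as plain G differences.
    """

    species_id: str
    compound: Compound
    form: str
    phase: Phase
    E_T: float  # kcal/mol
    G_corr: Optional[float] = None  # kcal/mol
    H_corr: Optional[float] = None  # kcal/mol
    charge: int = 0
    multiplicity: int = 1
    optimized_in: str = "gas"
    level: str = "III"

    def __post_init__(self) -> None:
        if not math.isfinite(self.E_T):
            raise MissingDataError(f"{self.species_id} [{self.phase}]: non-finite E_T")
        if self.G_corr is not None and not math.isfinite(self.G_corr):
            raise MissingDataError(f"{self.species_id} [{self.phase}]: non-finite G_corr")
        if self.multiplicity < 1:
            raise ValueError(f"{self.species_id}: multiplicity must be >= 1")

    @property
    def key(self) -> tuple:
        return (self.species_id, self.phase, self.level)

    def in_kcal(self, units: str) -> "ThermoRecord":
        """Return a copy converted to kcal/mol from the declared units."""
        if units == "kcal_per_mol":
            return self
        if units != "hartree":
            raise ValueError(f"unknown units {units!r}")
        return replace(
            self,
            E_T=hartree_to_kcal(self.E_T),
            G_corr=None if self.G_corr is None else hartree_to_kcal(self.G_corr),
            H_corr=None if self.H_corr is None else hartree_to_kcal(self.H_corr),
        )


def hartree_to_kcal(x: float) -> float:
    return x * HARTREE_TO_KCAL


def kcal_to_hartree(x: float) -> float:
    return x / HARTREE_TO_KCAL


def free_energy(record: ThermoRecord) -> float:
    """G = E_T + G_corr, kcal/mol."""
    if record.G_corr is None:
        raise MissingDataError(
            f"species {record.species_id!r} in phase {record.phase.value!r}: "
            "G_corr is missing; cannot compose a free energy"
        )
    return record.E_T + record.G_corr


def enthalpy(record: ThermoRecord) -> float:
    """H = E_T + H_corr, kcal/mol (used for bond-dissociation enthalpies)."""
    if record.H_corr is None:
        raise MissingDataError(
            f"species {record.species_id!r} in phase {record.phase.value!r}: "
            "H_corr is missing; cannot compose an enthalpy"
        )
    return record.E_T + record.H_corr


def proton_free_energy(phase: Phase, constants: Constants = CONSTANTS) -> float:
    """Empirical free energy of the bare proton in a given phase, kcal/mol.

    Raises :class:`HeptaneProtonError` for heptane, where no literature value
    exists; protonation/deprotonation stage pairs must be summed instead so
    the proton cancels.
    """
    phase = Phase(phase)
    try:
        return constants.G_proton[phase]
    except KeyError:
        raise HeptaneProtonError(
            f"proton free energy unavailable in {phase.value}; "
            "use paired-stage summaries (the proton cancels in N7+N8 / N13+N14)"
        ) from None
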