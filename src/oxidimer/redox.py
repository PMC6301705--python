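"""Adiabatic redox descriptors: IP, EA and Mulliken electronegativity.

IP = G(cation) − G(neutral), EA = G(neutral) − G(anion), χ = (IP + EA)/2,
all in kcal/mol from separately optimized ions (adiabatic values; there is
no vertical mode).  Ion geometries that were only stable in water carry a
provenance flag; their descriptors are still plain G differences, with a
warning about the mixed provenance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import pandas as pd

from .errors import OxidimerError
from .io import FixtureSet
from .thermo import Compound, Phase, ThermoRecord, free_energy

logger = logging.getLogger("oxidimer")

__all__ = ["RedoxRecord", "ionization_potential", "electron_affinity",
           "electronegativity", "rank_species", "redox_table"]


@dataclass(frozen=True)
class RedoxRecord:
    species_id: str
    compound: Compound
    phase: Phase
    IP: Optional[float] = None
    EA: Optional[float] = None
    cation_optimized_in: str = "gas"
    anion_optimized_in: str = "gas"

    @property
    def chi(self) -> Optional[float]:
        if self.IP is None or self.EA is None:
            return None
        return electronegativity(self.IP, self.EA)


def _check_pair(neutral: ThermoRecord, ion: ThermoRecord, allow_phase_mismatch: bool) -> None:
    if neutral.phase != ion.phase and not allow_phase_mismatch:
        raise OxidimerError(
            f"phase mismatch: neutral {neutral.species_id} in {neutral.phase.value}, "
            f"ion {ion.species_id} in {ion.phase.value} (pass allow_phase_mismatch=True "
            "to override)")
    if neutral.optimized_in != ion.optimized_in:
        logger.warning(
            "mixed provenance for %s: neutral optimized in %s, ion in %s "
            "(value is still a plain G difference)",
            neutral.species_id, neutral.optimized_in, ion.optimized_in)


def ionization_potential(neutral: ThermoRecord, cation: ThermoRecord,
                         allow_phase_mismatch: bool = False) -> float:
    """Adiabatic IP = G(cation) − G(neutral), kcal/mol."""
    _check_pair(neutral, cation, allow_phase_mismatch)
    return free_energy(cation) - free_energy(neutral)


def electron_affinity(neutral: ThermoRecord, anion: ThermoRecord,
                      allow_phase_mismatch: bool = False) -> float:
    """Adiabatic EA = G(neutral) − G(anion), kcal/mol (positive when electron
    attachment is downhill)."""
    _check_pair(neutral, anion, allow_phase_mismatch)
    return free_energy(neutral) - free_energy(anion)


def electronegativity(IP: float, EA: float) -> float:
    """Mulliken electronegativity χ = (IP + EA)/2, kcal/mol."""
    return (IP + EA) / 2.0


def rank_species(records: Sequence[RedoxRecord], by: str = "IP",
                 ascending: bool = True) -> List[RedoxRecord]:
    """Stable sort of redox records by IP, EA or chi; ties break on species_id."""
    if by not in {"IP", "EA", "chi"}:
        raise ValueError(f"rank key must be IP, EA or chi, got {by!r}")
    if not records:
        raise OxidimerError("cannot rank an empty record list")
    keyed = sorted(records, key=lambda r: (getattr(r, by), r.species_id))
    return keyed if ascending else keyed[::-1]


def redox_table(fixtures: FixtureSet, phase: Union[Phase, str],
                compound: Union[Compound, str, None] = None) -> List[RedoxRecord]:
    """Build redox records from the packaged IP/EA tables for one phase."""
    phase = Phase(phase)
    ip, ea = fixtures.ip, fixtures.ea
    ip = ip[ip.phase == phase.value]
    ea = ea[ea.phase == phase.value]
    if compound is not None:
        comp = Compound(compound).value
        ip, ea = ip[ip.compound == comp], ea[ea.compound == comp]
    ea_idx = {(r["form"], r.compound): r for _, r in ea.iterrows()}
    out: List[RedoxRecord] = []
    for _, r in ip.iterrows():
        e = ea_idx.get((r["form"], r.compound))
        out.append(RedoxRecord(
            species_id=f"{r.compound}:{r['form']}",
            compound=Compound(r.compound), phase=phase,
            IP=float(r.value), EA=None if e is None else float(e.value),
            cation_optimized_in="water" if r.ion_optimized_in_water else "gas",
            anion_optimized_in=("water" if (e is not None and e.ion_optimized_in_water)
                                else "gas"),
        ))
    return out


def redox_frame(records: Sequence[RedoxRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"species_id": r.species_id, "compound": r.compound.value,
         "phase": r.phase.value, "IP": r.IP, "EA": r.EA, "chi": r.chi,
         "cation_optimized_in": r.cation_optimized_in,
         "anion_optimized_in": r.anion_optimized_in}
        for r in records])
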