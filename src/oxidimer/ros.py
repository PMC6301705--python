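"""Coupling oxidation half-reactions with O₂ reduction: which ROS can form.

Each H-abstraction stage of the dimerization network releases H-atoms that
molecular oxygen can accept.  Summing the oxidation half-reaction ΔG with the
matching O₂ reduction half-reaction ΔG (full reduction to water, two-H
reduction to H₂O₂, one-H reduction to HO₂*, or pure electron transfer to
superoxide) classifies which combinations are exergonic — i.e. which ROS the
non-enzymatic chemistry can produce in each phase.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple, Union

from .errors import StoichiometryError
from .io import FixtureSet
from .network import (H_ABSTRACTION_STAGES, get_reaction, pathway_sum, resolve_stage,
                      ENZYMATIC_ROUTE)
from .thermo import COMPOUNDS, Compound, Phase

__all__ = ["O2ReductionSet", "CouplingResult", "couple_h_abstraction",
           "classify_all", "electron_transfer_feasibility", "superoxide_discrepancies",
           "H_DEMAND", "H2O2_PAIR_CANDIDATES"]

#: H* demanded by each O2 reduction channel.
H_DEMAND = {"HO2": 1, "H2O2": 2, "full": 6}

#: Candidate paired H-abstractions for H2O2 (hydroxyl+amine H oriented toward
#: O2), plus the two-H xanthommatin stage N26 for L-3HOK.
H2O2_PAIR_CANDIDATES: Tuple[Tuple[str, ...], ...] = (
    ("N1", "N2"), ("N5", "N6"), ("N11", "N12"), ("N19", "N22"), ("N26",))

#: margin (kcal/mol) within which a superoxide call is tagged "marginal"
MARGINAL_BAND = 0.5


@dataclass(frozen=True)
class O2ReductionSet:
    """O₂ reduction half-reaction free energies for one phase, kcal/mol."""

    phase: Phase
    dG_full: float       # 1.5 O2 + 6 H* -> 3 H2O
    dG_H2O2: float       # O2 + 2 H* -> H2O2
    dG_HO2: float        # O2 + H* -> HO2*
    dG_superoxide: float  # O2 + e- -> O2*-

    @classmethod
    def from_fixtures(cls, fixtures: FixtureSet, phase: Union[Phase, str]) -> "O2ReductionSet":
        phase = Phase(phase)
        df = fixtures.o2_reduction
        sel = df[df.phase == phase.value].set_index("reduction").dG
        return cls(phase=phase, dG_full=float(sel["full"]), dG_H2O2=float(sel["H2O2"]),
                   dG_HO2=float(sel["HO2"]), dG_superoxide=float(sel["superoxide"]))

    def for_channel(self, reduction: str) -> float:
        return {"full": self.dG_full, "H2O2": self.dG_H2O2, "HO2": self.dG_HO2,
                "superoxide": self.dG_superoxide}[reduction]


@dataclass(frozen=True)
class CouplingResult:
    stages: Tuple[str, ...]
    compound: Compound
    phase: Phase
    reduction: str
    dG_oxidation: float
    dG_reduction: float
    dG_total: float
    feasible: bool


def couple_h_abstraction(stages: Sequence[str], compound: Union[Compound, str],
                         phase: Union[Phase, str], reduction: str,
                         source, reduction_set: O2ReductionSet = None,
                         fixtures: FixtureSet = None) -> CouplingResult:
    """Couple one or more H-abstraction stages with an O₂ reduction channel.

    The number of H* the stages release must equal the channel's demand
    (1 for HO₂*, 2 for H₂O₂, 6 for full reduction to water).
    """
    compound, phase = Compound(compound), Phase(phase)
    if reduction not in H_DEMAND:
        raise ValueError(f"unknown reduction channel {reduction!r}")
    released = sum(get_reaction(s).h_star_yield() for s in stages)
    if released != H_DEMAND[reduction]:
        raise StoichiometryError(
            f"stages {list(stages)} release {released} H*, but the {reduction} "
            f"channel demands {H_DEMAND[reduction]}")
    if reduction_set is None:
        reduction_set = O2ReductionSet.from_fixtures(fixtures or source, phase)
    ox = sum(resolve_stage(s, compound, phase, source).dG for s in stages)
    red = reduction_set.for_channel(reduction)
    total = ox + red
    return CouplingResult(stages=tuple(stages), compound=compound, phase=phase,
                          reduction=reduction, dG_oxidation=ox, dG_reduction=red,
                          dG_total=total, feasible=total < 0)


@dataclass(frozen=True)
class SuperoxideCall:
    form: str
    compound: Compound
    dG: float
    feasible: bool
    marginal: bool


def electron_transfer_feasibility(IP: float, phase: Union[Phase, str],
                                  reduction_set: O2ReductionSet) -> Tuple[float, bool, bool]:
    """Electron transfer to O₂: ΔG = IP + ΔG(O₂ → O₂*⁻); feasible iff ΔG < 0.

    Also returns a "marginal" tag for calls within ±0.5 kcal/mol of zero.
    """
    dG = IP + reduction_set.dG_superoxide
    return dG, dG < 0, abs(dG) <= MARGINAL_BAND


def classify_all(fixtures: FixtureSet, phase: Union[Phase, str]) -> Dict[str, List[Tuple[str, Tuple[str, ...]]]]:
    """Thermodynamic ROS-formation classification for one phase.

    Returns a map reduction channel -> list of (stage-combo, tuple of
    feasible compounds).  HO₂* scans every single H-abstraction stage;
    H₂O₂ scans the fixed candidate pairs (+N26 for L-3HOK, ammonium
    variant); the full channel couples each compound's complete pathway SUM;
    superoxide scans the IP table (species-level, see
    :func:`superoxide_discrepancies` for the comparison with print).
    """
    phase = Phase(phase)
    red = O2ReductionSet.from_fixtures(fixtures, phase)
    out: Dict[str, List[Tuple[str, Tuple[str, ...]]]] = {}

    # full reduction: pathway SUM + dG_full
    full_members = []
    for comp in COMPOUNDS:
        total = pathway_sum(ENZYMATIC_ROUTE, comp, phase, fixtures).total
        if total + red.dG_full < 0:
            full_members.append(comp.value)
    out["full"] = [("SUM", tuple(full_members))] if full_members else []

    # HO2*: every single H-abstraction stage
    ho2: List[Tuple[str, Tuple[str, ...]]] = []
    for stage in H_ABSTRACTION_STAGES:
        members = tuple(
            c.value for c in COMPOUNDS
            if c in get_reaction(stage).compounds
            and couple_h_abstraction([stage], c, phase, "HO2", fixtures,
                                     reduction_set=red).feasible)
        if members:
            ho2.append((stage, members))
    out["HO2"] = ho2

    # H2O2: the fixed candidate pairs
    h2o2: List[Tuple[str, Tuple[str, ...]]] = []
    for combo in H2O2_PAIR_CANDIDATES:
        label = "+".join(s.lstrip("N") for s in combo)
        label = "N" + label
        members = tuple(
            c.value for c in COMPOUNDS
            if all(c in get_reaction(s).compounds for s in combo)
            and couple_h_abstraction(combo, c, phase, "H2O2", fixtures,
                                     reduction_set=red).feasible)
        if members:
            h2o2.append((label, members))
    out["H2O2"] = h2o2

    # superoxide: species-level electron transfer from the IP table
    sup: List[Tuple[str, Tuple[str, ...]]] = []
    ip = fixtures.ip[fixtures.ip.phase == phase.value]
    for form in ip["form"].unique():
        sub = ip[ip["form"] == form]
        members = tuple(
            r.compound for _, r in sub.iterrows()
            if electron_transfer_feasibility(float(r.value), phase, red)[1])
        if members:
            sup.append((form, members))
    out["superoxide"] = sup
    return out


@dataclass(frozen=True)
class Discrepancy:
    """A cell where the computed superoxide feasibility disagrees with the
    printed donor list (neither source is suppressed)."""

    phase: Phase
    compound: Compound
    form: str
    printed: bool
    computed: bool
    dG: float


def superoxide_discrepancies(fixtures: FixtureSet, phase: Union[Phase, str]) -> List[Discrepancy]:
    """Compare computed superoxide donors against the printed donor list.

    Known outcome: in the gas phase the printed list contains 3HAAi-D4
    although IP + ΔG(O₂→O₂*⁻) = +6.475 > 0, and omits 3HAAi-D6 although its
    transfer is exergonic (−1.471); both cells are reported, not resolved.
    """
    phase = Phase(phase)
    red = O2ReductionSet.from_fixtures(fixtures, phase)
    printed: Dict[Tuple[str, str], bool] = {}
    for _, row in fixtures.superoxide_donors.iterrows():
        if row.phase != phase.value:
            continue
        forms = [] if not isinstance(row.forms, str) or row.forms == "" else row.forms.split("|")
        for form in forms:
            printed[(row.compound, form)] = True
    out: List[Discrepancy] = []
    ip = fixtures.ip[fixtures.ip.phase == phase.value]
    for _, r in ip.iterrows():
        dG, feasible, _ = electron_transfer_feasibility(float(r.value), phase, red)
        was_printed = printed.get((r.compound, r["form"]), False)
        if feasible != was_printed:
            out.append(Discrepancy(phase=phase, compound=Compound(r.compound),
                                   form=r["form"], printed=was_printed,
                                   computed=feasible, dG=dG))
    return out
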