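"""The 26-stage dimerization reaction network.

Two monomers of a 2-aminophenol-type compound are oxidized to a phenoxazinone
(D10) by six H-atom abstractions, either along the "classic" enzyme-assisted
route (stages N1-N14) or along redundant non-enzymatic routes (N15-N25, plus
the final xanthommatin stage N26 for L-3HOK).  This module computes stage free
energies from a species registry (Hess's law: ΔG = ΣG(products) − ΣG(reactants)),
multiplicity-weighted pathway sums, route-independence (Hess) checks, summary
statistics over the H-abstraction bond-dissociation free energies (BDG), and
BSSE-adjusted stage energies.

Protonation/deprotonation stages in heptane are only available as summed
pairs (N7+8, N13+14): the bare-proton free energy is undefined there and
cancels in the pair.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import yaml
from scipy import stats as _sps

from .errors import (DoubleCorrectionError, HeptaneProtonError, MissingSpeciesError,
                     StoichiometryError)
from .io import FixtureSet, SpeciesTable
from .thermo import CONSTANTS, Compound, Constants, Phase, free_energy, proton_free_energy

__all__ = [
    "Reaction", "StageEnergy", "PathwayResult", "BsseCorrection", "BdgSummary",
    "load_reactions", "stage_free_energy", "pathway_sum", "hess_check",
    "bdg_summary", "apply_bsse", "net_stoichiometry", "h_star_released",
    "ENZYMATIC_ROUTE", "NONENZYMATIC_ROUTE", "BDG_STAGES", "H_ABSTRACTION_STAGES",
]

_PROTON_FORM = "Hp"
_H_ATOM_FORM = "Hs"

#: H-abstraction stages entering the BDG summary (N24 is excluded: it is a
#: spin-forbidden biradical collapse, not an H abstraction; N26 is the
#: xanthommatin special case restricted to L-3HOK).
BDG_STAGES = ("N1", "N2", "N5", "N6", "N11", "N12", "N16", "N17", "N19", "N21", "N22")

#: All single-H* releasing stages (used for hydroperoxyl coupling).
H_ABSTRACTION_STAGES = BDG_STAGES

#: The classic route, one pass through N1..N14 (its net stoichiometry is
#: 2 M -> D10 + 6 H*: N3 consumes the second monomer).
ENZYMATIC_ROUTE: Tuple[Tuple[str, int], ...] = tuple((f"N{i}", 1) for i in range(1, 15))

#: The redundant route via quinoneimine self-conjugation.
NONENZYMATIC_ROUTE: Tuple[Tuple[str, int], ...] = (
    ("N1", 2), ("N2", 2), ("N15", 1), ("N16", 1), ("N17", 1))


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric half-reaction of the network."""

    id: str
    rclass: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    compounds: Tuple[Compound, ...]
    variant: str = ""

    def h_star_yield(self) -> int:
        return self.products.get(_H_ATOM_FORM, 0) - self.reactants.get(_H_ATOM_FORM, 0)


_RCLASSES = {"H_ABSTRACTION", "CONJUGATION", "TAUTOMERIZATION", "PROTONATION",
             "DEPROTONATION", "CYCLIZATION"}

_PAIRS = {"N7+8": ("N7", "N8"), "N13+14": ("N13", "N14")}


def load_reactions() -> Dict[Tuple[str, str], Reaction]:
    """Load the packaged stage registry, keyed by (stage id, variant)."""
    ref = resources.files("oxidimer") / "data" / "reactions.yaml"
    doc = yaml.safe_load(ref.read_text())
    registry: Dict[Tuple[str, str], Reaction] = {}
    for entry in doc["reactions"]:
        rclass = entry["rclass"]
        if rclass not in _RCLASSES:
            raise ValueError(f"unknown reaction class {rclass!r} for {entry['id']}")
        comps = tuple(Compound(c) for c in entry.get("compounds",
                      ["2AP", "L3HOK", "3HAA", "3HAAi"]))
        rxn = Reaction(
            id=entry["id"], rclass=rclass,
            reactants=dict(entry["reactants"]), products=dict(entry["products"]),
            compounds=comps, variant=entry.get("variant", ""),
        )
        if rclass == "H_ABSTRACTION":
            expected = 2 if rxn.id == "N26" else 1
            if rxn.h_star_yield() != expected:
                raise ValueError(f"{rxn.id}: H-abstraction must release {expected} H*")
        registry[(rxn.id, rxn.variant)] = rxn
    return registry


_REACTIONS: Optional[Dict[Tuple[str, str], Reaction]] = None


def _reactions() -> Dict[Tuple[str, str], Reaction]:
    global _REACTIONS
    if _REACTIONS is None:
        _REACTIONS = load_reactions()
    return _REACTIONS


def get_reaction(stage: str, variant: str = "") -> Reaction:
    reg = _reactions()
    if (stage, variant) in reg:
        return reg[(stage, variant)]
    if variant == "" and (stage, "NH4") in reg:  # N26 default: ammonium variant
        return reg[(stage, "NH4")]
    raise KeyError(f"unknown stage {stage!r} (variant {variant!r})")


@dataclass(frozen=True)
class StageEnergy:
    """ΔG of one stage for one compound in one phase."""

    stage: str
    compound: Compound
    phase: Phase
    dG: float  # kcal/mol
    source: str  # from_species | from_fixture
    components: Mapping[str, float] = field(default_factory=dict)
    bsse_applied: Optional[float] = None
    variant: str = ""


@dataclass(frozen=True)
class BsseCorrection:
    """A counterpoise correction for one stage, stored with the printed
    (negative) sign.  Applying it makes dimerization less favorable and
    X-H bond dissociation less costly."""

    stage: str
    compound: Compound
    value: float  # kcal/mol, negative by convention


def apply_bsse(stage_energy: StageEnergy, correction: BsseCorrection) -> StageEnergy:
    """Return a BSSE-adjusted copy of a stage energy (at most once).

    The correction removes spurious basis-set stabilization of the composite
    side of the reaction: for conjugation (dimer product) ΔG is raised by
    |c|; for H abstraction (composite on the reactant side) ΔG is lowered.
    """
    if correction.stage != stage_energy.stage:
        raise ValueError(
            f"correction targets stage {correction.stage!r}, energy is for "
            f"{stage_energy.stage!r}")
    if stage_energy.bsse_applied is not None:
        raise DoubleCorrectionError(
            f"BSSE correction already applied to {stage_energy.stage} "
            f"({stage_energy.compound.value}, {stage_energy.phase.value})")
    rclass = get_reaction(stage_energy.stage).rclass
    # printed corrections are negative; |c| destabilizes the composite species
    shift = -correction.value if rclass == "CONJUGATION" else correction.value
    return replace(stage_energy, dG=stage_energy.dG + shift,
                   bsse_applied=correction.value)


def stage_free_energy(stage: str, compound: Union[Compound, str], phase: Union[Phase, str],
                      registry: SpeciesTable, variant: str = "",
                      constants: Constants = CONSTANTS) -> StageEnergy:
    """Stage ΔG from species free energies: ΣG(products) − ΣG(reactants).

    Handles the bracketed pair stages ("N7+8", "N13+14") by summing their
    members symbolically so the proton cancels, which is the only way the
    protonation stages are defined in heptane.
    """
    compound, phase = Compound(compound), Phase(phase)
    if stage in _PAIRS:
        a, b = _PAIRS[stage]
        ra, rb = get_reaction(a), get_reaction(b)
        net_r = Counter(ra.reactants) + Counter(rb.reactants)
        net_p = Counter(ra.products) + Counter(rb.products)
        cancel = net_r & net_p  # the proton (and any other common species)
        net_r -= cancel
        net_p -= cancel
        rxn = Reaction(id=stage, rclass="PROTONATION", reactants=dict(net_r),
                       products=dict(net_p), compounds=ra.compounds)
    else:
        rxn = get_reaction(stage, variant)
    if compound not in rxn.compounds:
        raise MissingSpeciesError(f"stage {stage} is not defined for {compound.value}")
    if phase is Phase.HEPTANE and (_PROTON_FORM in rxn.reactants
                                   or _PROTON_FORM in rxn.products):
        raise HeptaneProtonError(
            f"stage {stage} involves a bare proton; in heptane request the "
            "paired stage ('N7+8' or 'N13+14') instead")

    components: Dict[str, float] = {}

    def g_of(form: str) -> float:
        if form == _PROTON_FORM:
            if phase is Phase.HEPTANE:
                raise HeptaneProtonError(
                    f"stage {stage} involves a bare proton; in heptane request the "
                    "paired stage ('N7+8' or 'N13+14') instead")
            g = proton_free_energy(phase, constants)
        else:
            g = free_energy(registry.lookup(compound, form, phase))
        components[form] = g
        return g

    dG = 0.0
    for form, count in rxn.products.items():
        dG += count * g_of(form)
    for form, count in rxn.reactants.items():
        dG -= count * g_of(form)
    return StageEnergy(stage=stage, compound=compound, phase=phase, dG=dG,
                       source="from_species", components=components,
                       variant=rxn.variant)


def _fixture_stage(fixtures: FixtureSet, stage: str, compound: Compound,
                   phase: Phase, variant: str = "") -> StageEnergy:
    if stage == "N26" and variant == "":
        variant = "NH4"
    dG = fixtures.stage(stage, compound, phase, variant)
    return StageEnergy(stage=stage, compound=compound, phase=phase, dG=dG,
                       source="from_fixture", variant=variant)


def resolve_stage(stage: str, compound: Union[Compound, str], phase: Union[Phase, str],
                  source: Union[FixtureSet, SpeciesTable], variant: str = "") -> StageEnergy:
    """Stage ΔG from either a fixture set or a species registry."""
    compound, phase = Compound(compound), Phase(phase)
    if isinstance(source, FixtureSet):
        return _fixture_stage(source, stage, compound, phase, variant)
    return stage_free_energy(stage, compound, phase, source, variant)


@dataclass(frozen=True)
class PathwayResult:
    """A multiplicity-weighted sum over stages."""

    stages: Tuple[Tuple[str, int, float], ...]  # (stage, multiplicity, dG)
    compound: Compound
    phase: Phase
    total: float
    pair_summaries_used: bool

    def to_frame(self):
        import pandas as pd
        rows = [{"stage": s, "multiplicity": m, "dG": g} for s, m, g in self.stages]
        rows.append({"stage": "SUM", "multiplicity": 1, "dG": self.total})
        return pd.DataFrame(rows)


def _normalize_route(stages: Sequence[Union[str, Tuple[str, int]]],
                     phase: Phase) -> Tuple[List[Tuple[str, int]], bool]:
    """Expand a route spec, substituting pair summaries for the
    protonation/deprotonation stages in heptane."""
    out: List[Tuple[str, int]] = []
    for item in stages:
        stage, mult = item if isinstance(item, tuple) else (item, 1)
        out.append((stage, mult))
    pairs_used = False
    if phase is Phase.HEPTANE:
        merged: List[Tuple[str, int]] = []
        skip_next: Dict[str, int] = {}
        singles = {m: p for p, ms in _PAIRS.items() for m in ms}
        i = 0
        names = [s for s, _ in out]
        while i < len(out):
            stage, mult = out[i]
            partner = None
            if stage in singles:
                pair = singles[stage]
                a, b = _PAIRS[pair]
                other = b if stage == a else a
                if i + 1 < len(out) and out[i + 1][0] == other and out[i + 1][1] == mult:
                    merged.append((pair, mult))
                    pairs_used = True
                    i += 2
                    continue
                raise HeptaneProtonError(
                    f"stage {stage} cannot be evaluated singly in heptane; "
                    f"supply the pair {pair!r} (proton free energy undefined)")
            merged.append((stage, mult))
            i += 1
        out = merged
    return out, pairs_used


def pathway_sum(stages: Sequence[Union[str, Tuple[str, int]]],
                compound: Union[Compound, str], phase: Union[Phase, str],
                source: Union[FixtureSet, SpeciesTable]) -> PathwayResult:
    """Multiplicity-weighted ΔG sum along an ordered stage list.

    In heptane, adjacent N7/N8 (N13/N14) entries are automatically collapsed
    to their bracketed pair summaries; pair stages may also be named
    explicitly ("N7+8", "N13+14") in any phase.
    """
    compound, phase = Compound(compound), Phase(phase)
    route, pairs_used = _normalize_route(stages, phase)
    resolved: List[Tuple[str, int, float]] = []
    total = 0.0
    for stage, mult in route:
        se = resolve_stage(stage, compound, phase, source)
        resolved.append((stage, mult, se.dG))
        total += mult * se.dG
        pairs_used = pairs_used or stage in _PAIRS
    return PathwayResult(stages=tuple(resolved), compound=compound, phase=phase,
                         total=total, pair_summaries_used=pairs_used)


def net_stoichiometry(stages: Sequence[Union[str, Tuple[str, int]]]) -> Counter:
    """Net species multiset of a route (products positive, reactants negative).

    Pair stages count as their members; the proton cancels by construction.
    """
    net: Counter = Counter()
    for item in stages:
        stage, mult = item if isinstance(item, tuple) else (item, 1)
        members = _PAIRS.get(stage, (stage,))
        for name in members:
            rxn = get_reaction(name)
            for form, count in rxn.products.items():
                net[form] += mult * count
            for form, count in rxn.reactants.items():
                net[form] -= mult * count
    return Counter({k: v for k, v in net.items() if v != 0})


def h_star_released(stages: Sequence[Union[str, Tuple[str, int]]]) -> int:
    """Total H* released along a route (six for any complete 2 M -> D10 route)."""
    return net_stoichiometry(stages).get(_H_ATOM_FORM, 0)


@dataclass(frozen=True)
class HessResult:
    delta: float
    passed: bool
    total_a: float
    total_b: float
    tolerance: float


def hess_check(route_a: Sequence[Union[str, Tuple[str, int]]],
               route_b: Sequence[Union[str, Tuple[str, int]]],
               compound: Union[Compound, str], phase: Union[Phase, str],
               source: Union[FixtureSet, SpeciesTable],
               tolerance: Optional[float] = None) -> HessResult:
    """Route-independence check: two routes with identical net stoichiometry
    must have identical total ΔG.

    Default tolerance: 1e-6 kcal/mol for species-derived energies (exact up
    to float roundoff), 0.01 kcal/mol against printed (rounded) fixtures.
    """
    net_a, net_b = net_stoichiometry(route_a), net_stoichiometry(route_b)
    if net_a != net_b:
        diff = Counter(net_a)
        diff.subtract(net_b)
        diff = {k: v for k, v in diff.items() if v != 0}
        raise StoichiometryError(
            f"routes have different net stoichiometry; imbalance: {diff}")
    if tolerance is None:
        tolerance = 0.01 if isinstance(source, FixtureSet) else 1e-6
    ta = pathway_sum(route_a, compound, phase, source).total
    tb = pathway_sum(route_b, compound, phase, source).total
    delta = abs(ta - tb)
    return HessResult(delta=delta, passed=delta <= tolerance,
                      total_a=ta, total_b=tb, tolerance=tolerance)


@dataclass(frozen=True)
class BdgSummary:
    """Summary of the homolytic X-H bond-dissociation free energies.

    The printed "±" of the source study is a t-based 95% CI half-width
    (verified numerically for the gas phase); the sample SD is reported
    alongside.
    """

    phase: Phase
    mean: float
    sd: float
    ci95: float
    n: int


def bdg_summary(phase: Union[Phase, str], source: Union[FixtureSet, SpeciesTable],
                compounds: Sequence[Union[Compound, str]] = ("2AP", "L3HOK", "3HAA", "3HAAi"),
                stages: Sequence[str] = BDG_STAGES) -> BdgSummary:
    """Mean / SD / 95% CI over the 44 H-abstraction stage ΔG values
    (11 stages x 4 compounds; N24 and N26 excluded).  With fewer than two
    values the spread statistics are NaN (CI undefined)."""
    phase = Phase(phase)
    values: List[float] = []
    missing: List[str] = []
    for stage in stages:
        for comp in compounds:
            try:
                values.append(resolve_stage(stage, comp, phase, source).dG)
            except MissingSpeciesError:
                missing.append(f"{stage}/{Compound(comp).value}")
    if missing:
        raise MissingSpeciesError(
            f"BDG summary in {phase.value}: missing stage values: {missing}")
    arr = np.asarray(values, dtype=float)
    n = arr.size
    mean = float(arr.mean())
    if n < 2:
        return BdgSummary(phase=phase, mean=mean, sd=float("nan"),
                          ci95=float("nan"), n=n)
    sd = float(arr.std(ddof=1))
    ci = float(_sps.t.ppf(0.975, n - 1) * sd / math.sqrt(n))
    return BdgSummary(phase=phase, mean=mean, sd=sd, ci95=ci, n=n)
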