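"""Self-consistent synthetic inputs for pipeline testing.

The generator emulates the *summary output* of a quantum-thermochemistry
study — species free energies over three phases, transition-state barrier /
imaginary-frequency pairs, and energies at two linearly related theory
levels — without any molecular structure.  Species free energies are built
constructively: the monomer G is sampled, then every dimer/ion/radical G is
placed so that each network stage hits a sampled (or pinned) target ΔG.
Hess route-independence therefore holds *exactly* by construction, which is
what makes the synthetic world a valid oracle for the network code.

What it does NOT emulate: real electronic-structure error (basis-set and
functional bias, solvation-model artifacts), conformational multiplicity,
or any correlation between a species' energy and its structure.  A green
test on synthetic data establishes the bookkeeping, not the chemistry.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .io import SpeciesTable
from .kinetics import TSRecord, rate_pair
from .stats import PairedSeries
from .thermo import COMPOUNDS, CONSTANTS, Compound, Phase, ThermoRecord

__all__ = ["SynthConfig", "GeneratedTS", "generate_registry", "generate_ts_records",
           "generate_two_level", "generate_groups"]

# doublet radicals / triplets in the network (bookkeeping only)
_MULT = {"Mstar": 2, "D3": 2, "D8": 2, "D3p": 2, "D5p": 2, "D6p": 3,
         "Hs": 2, "HO2": 2, "O2m": 2, "O2": 3}


@dataclass(frozen=True)
class SynthConfig:
    """Stated world of the generator.

    Stage ΔG ranges are read off the observed spread of the printed network
    tables (H abstraction 19-77 kcal/mol etc.); barriers and imaginary
    frequencies span the printed kinetics table.  ``pinned`` fixes chosen
    stage targets (keyed ``(stage, compound, phase)``, stage "N26:NH3" for
    the variant) to exact values, letting fixture-derived and
    species-derived pipelines be cross-validated.
    """

    seed: int
    compounds: Tuple[Compound, ...] = COMPOUNDS
    phases: Tuple[Phase, ...] = (Phase.GAS, Phase.HEPTANE, Phase.WATER)
    class_dg_ranges: Mapping[str, Tuple[float, float]] = field(default_factory=lambda: {
        "H_ABSTRACTION": (19.0, 77.0),
        "CONJUGATION": (-5.0, 58.0),
        "TAUTOMERIZATION": (-17.0, 7.0),
        "CYCLIZATION": (2.0, 37.0),
        "PAIR": (-16.0, 7.0),           # summed protonation+deprotonation
        "N26": (76.0, 145.0),           # two-H xanthommatin stage
    })
    protonation_ranges: Mapping[Phase, Tuple[float, float]] = field(default_factory=lambda: {
        Phase.GAS: (-250.0, -225.0), Phase.WATER: (-20.0, 5.0)})
    ip_range: Tuple[float, float] = (75.0, 230.0)
    ea_range: Tuple[float, float] = (-20.0, 110.0)
    barrier_range: Tuple[float, float] = (5.0, 40.0)
    nu_i_range: Tuple[float, float] = (1000.0, 2500.0)
    reverse_offset_range: Tuple[float, float] = (-14.0, 16.0)  # dG_P_R spread
    # two-level relation: level III = slope * level II + intercept + N(0, sigma)
    two_level_slope: float = 0.977
    two_level_intercept: float = -0.916
    two_level_sigma: float = 1.0
    two_level_n: int = 36
    two_level_range: Tuple[float, float] = (30.0, 80.0)  # X-H dissociation energies
    group_effect: float = 1.0
    group_sigma: float = 1.0
    group_n: int = 6
    pinned: Mapping[Tuple[str, str, str], float] = field(default_factory=dict)


def _compound_charge(comp: Compound) -> int:
    return -1 if comp is Compound.HAA3I else 0


_STAGE_CLASS = {
    "N1": "H_ABSTRACTION", "N2": "H_ABSTRACTION", "N3": "CONJUGATION",
    "N4": "TAUTOMERIZATION", "N5": "H_ABSTRACTION", "N6": "H_ABSTRACTION",
    "N9": "CYCLIZATION", "N10": "TAUTOMERIZATION", "N11": "H_ABSTRACTION",
    "N12": "H_ABSTRACTION", "N15": "CONJUGATION", "N18": "TAUTOMERIZATION",
    "N19": "H_ABSTRACTION", "N20": "CYCLIZATION", "N22": "H_ABSTRACTION",
    "N23": "CYCLIZATION", "N7+8": "PAIR", "N13+14": "PAIR",
    "N26:NH3": "N26", "N26:NH4": "N26",
}


def generate_registry(config: SynthConfig) -> SpeciesTable:
    """Build a Hess-consistent species registry.

    The returned table's ``metadata["stage_targets"]`` maps
    ``(stage, compound, phase)`` to the ΔG each *independent* stage was
    given; dependent stages (N8, N14, N16, N17, N21, N24, N25) follow from
    the construction and can be recovered with
    :func:`oxidimer.network.stage_free_energy`.
    """
    rng = np.random.default_rng(config.seed)
    table = SpeciesTable(metadata={"seed": config.seed})
    targets: Dict[Tuple[str, str, str], float] = {}

    def sample(stage: str, comp: Compound, phase: Phase) -> float:
        key = (stage, comp.value, phase.value)
        if key in config.pinned:
            val = float(config.pinned[key])
        elif stage == "N7" or stage == "N13":
            lo, hi = config.protonation_ranges[phase]
            val = float(rng.uniform(lo, hi))
        else:
            lo, hi = config.class_dg_ranges[_STAGE_CLASS[stage]]
            val = float(rng.uniform(lo, hi))
        targets[key] = val
        return val

    def add(comp: Compound, form: str, phase: Phase, G: float, charge: int) -> None:
        g_corr = float(rng.uniform(60.0, 130.0))
        table.add(ThermoRecord(
            species_id=f"{comp.value}:{form}", compound=comp, form=form, phase=phase,
            E_T=G - g_corr, G_corr=g_corr, H_corr=g_corr + float(rng.uniform(3.0, 8.0)),
            charge=charge, multiplicity=_MULT.get(form, 1),
            optimized_in="water" if (comp is Compound.HAA3I and form.endswith(("+", "-")))
            else "gas"))

    shared_g: Dict[Tuple[str, Phase], float] = {}
    for phase in config.phases:
        # small shared species
        g_h = -313.5 + float(rng.normal(0.0, 0.5))
        g_o2 = -94200.0 + float(rng.normal(0.0, 5.0))
        t_ho2 = float(rng.uniform(-42.0, -37.0))
        t_h2o2 = float(rng.uniform(-112.0, -105.0))
        t_full = float(rng.uniform(-432.0, -415.0))
        t_sup = float(rng.uniform(-90.0, -13.0))
        g_nh3 = -35400.0 + float(rng.normal(0.0, 2.0))
        g_nh4 = g_nh3 - 200.0 + float(rng.normal(0.0, 2.0))
        small = {
            "Hs": (g_h, 0), "O2": (g_o2, 0),
            "HO2": (g_o2 + g_h + t_ho2, 0),
            "H2O2": (g_o2 + 2 * g_h + t_h2o2, 0),
            "H2O": ((t_full + 1.5 * g_o2 + 6 * g_h) / 3.0, 0),
            "O2m": (g_o2 + t_sup, -1),
            "NH3": (g_nh3, 0), "NH4p": (g_nh4, 1),
        }
        for form, (G, q) in small.items():
            add(Compound.SHARED, form, phase, G, q)
            shared_g[(form, phase)] = G

        for comp in config.compounds:
            c = _compound_charge(comp)
            g: Dict[str, float] = {}
            g["M"] = -345000.0 + float(rng.uniform(-1000.0, 1000.0))
            g["Mstar"] = g["M"] + sample("N1", comp, phase) - g_h
            g["Mq"] = g["Mstar"] + sample("N2", comp, phase) - g_h
            g["D1"] = g["M"] + g["Mq"] + sample("N3", comp, phase)
            g["D2"] = g["D1"] + sample("N4", comp, phase)
            g["D3"] = g["D2"] + sample("N5", comp, phase) - g_h
            g["D4"] = g["D3"] + sample("N6", comp, phase) - g_h
            g["D5"] = g["D4"] + sample("N7+8", comp, phase)
            g["D6"] = g["D5"] + sample("N9", comp, phase)
            g["D7"] = g["D6"] + sample("N10", comp, phase)
            g["D8"] = g["D7"] + sample("N11", comp, phase) - g_h
            g["D9"] = g["D8"] + sample("N12", comp, phase) - g_h
            g["D10"] = g["D9"] + sample("N13+14", comp, phase)
            if phase is not Phase.HEPTANE:
                g_hp = CONSTANTS.G_proton[phase]
                g["D4H"] = g["D4"] + g_hp + sample("N7", comp, phase)
                g["D9H"] = g["D9"] + g_hp + sample("N13", comp, phase)
            g["D1p"] = 2 * g["Mq"] + sample("N15", comp, phase)
            g["D2p"] = g["D1p"] + sample("N18", comp, phase)
            g["D3p"] = g["D2p"] + sample("N19", comp, phase) - g_h
            g["D5p"] = g["D3p"] + sample("N20", comp, phase)
            g["D4p"] = g["D3p"] + sample("N22", comp, phase) - g_h
            g["D6p"] = g["D4p"] + sample("N23", comp, phase)
            if comp is Compound.L3HOK:
                g["XAN"] = (g["D10"] - shared_g[("NH3", phase)] - 2 * g_h
                            + sample("N26:NH3", comp, phase))
                g["XANi"] = (g["D10"] - shared_g[("NH4p", phase)] - 2 * g_h
                             + sample("N26:NH4", comp, phase))
            for form, G in g.items():
                charge = 2 * c if form.startswith("D") else c
                if form in ("D4H", "D9H"):
                    charge = 2 * c + 1
                if form == "XAN":
                    charge = 0
                if form == "XANi":
                    charge = -1
                add(comp, form, phase, G, charge)
            # separately optimized ions for the redox module
            for form in ("M", "Mq", "D2", "D7"):
                ip = float(rng.uniform(*config.ip_range))
                ea = float(rng.uniform(*config.ea_range))
                targets[(f"IP:{form}", comp.value, phase.value)] = ip
                targets[(f"EA:{form}", comp.value, phase.value)] = ea
                base_q = 2 * c if form.startswith("D") else c
                add(comp, f"{form}+", phase, g[form] + ip, base_q + 1)
                add(comp, f"{form}-", phase, g[form] - ea, base_q - 1)
    table.metadata["stage_targets"] = targets
    return table


@dataclass(frozen=True)
class GeneratedTS:
    """Synthetic TS records plus the ground-truth rates they were built with."""

    records: Tuple[TSRecord, ...]
    true_rates: Mapping[str, Tuple[float, float]]  # label -> (k_forward, k_reverse)


def generate_ts_records(config: SynthConfig, n_per_compound: int = 3) -> GeneratedTS:
    """Barrier/frequency pairs in the printed table's ranges, with rates
    precomputed by the same TST+Wigner formula for oracle comparison."""
    rng = np.random.default_rng(config.seed + 1)
    records: List[TSRecord] = []
    truth: Dict[str, Tuple[float, float]] = {}
    for comp in config.compounds:
        for i in range(n_per_compound):
            for phase in config.phases:
                fwd = float(rng.uniform(*config.barrier_range))
                rev = fwd - float(rng.uniform(*config.reverse_offset_range))
                rev = max(rev, 0.5)
                nu = float(rng.uniform(*config.nu_i_range))
                rec = TSRecord(label=f"{comp.value}-TS{i + 1}-{phase.value}",
                               compound=comp, phase=phase, dG_TS_R=fwd,
                               dG_TS_P=rev, nu_i=nu)
                res = rate_pair(rec)
                records.append(rec)
                truth[rec.label] = (res.k_forward, res.k_reverse)
    return GeneratedTS(records=tuple(records), true_rates=truth)


def generate_two_level(config: SynthConfig) -> PairedSeries:
    """Level-II energies uniform over a dissociation-energy range; level-III
    linearly related with Gaussian noise."""
    rng = np.random.default_rng(config.seed + 2)
    x = rng.uniform(*config.two_level_range, size=config.two_level_n)
    noise = rng.normal(0.0, config.two_level_sigma, size=config.two_level_n)
    y = config.two_level_slope * x + config.two_level_intercept + noise
    labels = [f"XH{i + 1}" for i in range(config.two_level_n)]
    return PairedSeries(x=x, y=y, labels=labels)


def generate_groups(config: SynthConfig, effect: Optional[float] = None,
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Two Gaussian groups separated by the configured effect size (assay
    comparison stand-in)."""
    rng = np.random.default_rng(config.seed + 3)
    eff = config.group_effect if effect is None else effect
    a = rng.normal(0.0, config.group_sigma, size=config.group_n)
    b = rng.normal(eff, config.group_sigma, size=config.group_n)
    return a, b
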