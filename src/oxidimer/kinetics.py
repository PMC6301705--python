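"""Transition-state-theory rates with Wigner tunneling.

For the H-transfer of a dimer to molecular oxygen the bimolecular rate is

    k(T) = I * (kB*T/h) * exp(-ΔG‡ / RT) * f_std * A(T)

where I is the reaction-path degeneracy, f_std (default 24.3) converts the
1 atm ideal-gas standard state to 1 M, and A(T) is the Wigner tunneling
factor computed from the magnitude of the transition state's imaginary
frequency ν_i (cm⁻¹):

    A(T) = 1 + (1/24) * (c * ν_i / T)²      with c = 1.44 cm*K by default.

Forward rates use the reactant-side barrier ΔG‡_R = G_TS − G_R, reverse
rates the product-side barrier ΔG‡_P = G_TS − G_P; their difference is the
reaction free energy ΔG_P−R, so detailed balance
k_f/k_r = exp(−ΔG_P−R/RT) holds exactly (degeneracy, standard-state and
tunneling factors cancel).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Union

import pandas as pd

from .errors import MissingDataError
from .io import FixtureSet
from .thermo import CONSTANTS, Compound, Constants, Phase

logger = logging.getLogger("oxidimer")

__all__ = ["TSRecord", "RateResult", "wigner_factor", "tst_rate", "rate_pair",
           "rates_from_fixtures"]


@dataclass(frozen=True)
class TSRecord:
    """A transition-state record: barrier pair + imaginary frequency."""

    label: str
    compound: Compound
    phase: Phase
    dG_TS_R: float  # kcal/mol, G_TS - G_R
    dG_TS_P: float  # kcal/mol, G_TS - G_P
    nu_i: float     # cm^-1, magnitude of the imaginary frequency
    degeneracy: int = 1
    T: float = 298.15
    G_TS: Optional[float] = None
    G_R: Optional[float] = None
    G_P: Optional[float] = None

    def __post_init__(self) -> None:
        if self.nu_i < 0:
            raise ValueError(f"{self.label}: nu_i is a magnitude, must be >= 0")
        if self.degeneracy < 1:
            raise ValueError(f"{self.label}: degeneracy must be a positive integer")
        if self.G_TS is not None and self.G_R is not None:
            if abs((self.G_TS - self.G_R) - self.dG_TS_R) > 1e-9:
                raise ValueError(f"{self.label}: dG_TS_R inconsistent with raw G values")
        if self.G_TS is not None and self.G_P is not None:
            if abs((self.G_TS - self.G_P) - self.dG_TS_P) > 1e-9:
                raise ValueError(f"{self.label}: dG_TS_P inconsistent with raw G values")

    @property
    def dG_P_R(self) -> float:
        """Reaction free energy: ΔG_P−R = ΔG‡_R − ΔG‡_P."""
        return self.dG_TS_R - self.dG_TS_P


@dataclass(frozen=True)
class RateResult:
    record: TSRecord
    k_forward: float  # M^-1 s^-1
    k_reverse: float
    wigner_A: float
    K_eq_direction: str  # products_favored | reactants_favored


def wigner_factor(nu_i: float, T: float = CONSTANTS.T,
                  constants: Constants = CONSTANTS) -> float:
    """Wigner tunneling factor A(T) = 1 + (1/24)(c·ν_i/T)²; A ≥ 1."""
    if nu_i < 0:
        raise ValueError("nu_i must be a non-negative magnitude")
    if T <= 0:
        raise ValueError("T must be positive")
    return 1.0 + (constants.wigner_coeff * nu_i / T) ** 2 / 24.0


def tst_rate(dG_barrier: float, nu_i: float, degeneracy: int = 1,
             T: Optional[float] = None, constants: Constants = CONSTANTS) -> float:
    """TST rate constant in M⁻¹s⁻¹ for a barrier in kcal/mol.

    Negative barriers are allowed (barrierless limit) but logged.
    """
    T = constants.T if T is None else T
    if not math.isfinite(dG_barrier):
        raise MissingDataError("barrier is not finite")
    if dG_barrier < 0:
        logger.warning("negative barrier %.3f kcal/mol: treating as barrierless",
                       dG_barrier)
    prefactor = degeneracy * constants.kB * T / constants.h
    boltz = math.exp(-dG_barrier * 1000.0 / (constants.R_cal * T))
    return prefactor * boltz * constants.std_state_factor * wigner_factor(nu_i, T, constants)


def rate_pair(ts: TSRecord, constants: Constants = CONSTANTS) -> RateResult:
    """Forward/reverse rates for a barrier pair; direction from sign of ΔG_P−R."""
    kf = tst_rate(ts.dG_TS_R, ts.nu_i, ts.degeneracy, ts.T, constants)
    kr = tst_rate(ts.dG_TS_P, ts.nu_i, ts.degeneracy, ts.T, constants)
    direction = "products_favored" if ts.dG_P_R < 0 else "reactants_favored"
    return RateResult(record=ts, k_forward=kf, k_reverse=kr,
                      wigner_A=wigner_factor(ts.nu_i, ts.T, constants),
                      K_eq_direction=direction)


def ts_records_from_fixtures(fixtures: FixtureSet,
                             phase: Union[Phase, str, None] = None) -> List[TSRecord]:
    """Transition-state records from the packaged printed table.

    The 3HAAi D2'/D5' rows are genuinely absent (no stable TS was found for
    them), not zero.
    """
    df = fixtures.ts
    if phase is not None:
        df = df[df.phase == Phase(phase).value]
    return [
        TSRecord(label=f"{r.compound}-{r['form']}", compound=Compound(r.compound),
                 phase=Phase(r.phase), dG_TS_R=float(r.dG_TS_R),
                 dG_TS_P=float(r.dG_TS_P), nu_i=float(r.nu_i))
        for _, r in df.iterrows()]


def rates_from_fixtures(fixtures: FixtureSet, phase: Union[Phase, str, None] = None,
                        constants: Constants = CONSTANTS) -> pd.DataFrame:
    """Recompute the full printed rate table; returns a tidy frame with the
    printed rates alongside for comparison."""
    rows = []
    df = fixtures.ts
    if phase is not None:
        df = df[df.phase == Phase(phase).value]
    for _, r in df.iterrows():
        ts = TSRecord(label=f"{r.compound}-{r['form']}", compound=Compound(r.compound),
                      phase=Phase(r.phase), dG_TS_R=float(r.dG_TS_R),
                      dG_TS_P=float(r.dG_TS_P), nu_i=float(r.nu_i))
        res = rate_pair(ts, constants)
        rows.append({
            "compound": r.compound, "form": r["form"], "phase": r.phase,
            "nu_i": ts.nu_i, "dG_TS_R": ts.dG_TS_R, "dG_TS_P": ts.dG_TS_P,
            "dG_P_R": ts.dG_P_R, "wigner_A": res.wigner_A,
            "k_forward": res.k_forward, "k_reverse": res.k_reverse,
            "k_fwd_printed": float(r.k_fwd_printed),
            "k_rev_printed": float(r.k_rev_printed),
            "direction": res.K_eq_direction,
        })
    return pd.DataFrame(rows)
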