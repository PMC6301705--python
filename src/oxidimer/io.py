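"""Registry and fixture I/O.

Species registries, reaction registries and transition-state tables travel as
delimited text (comma or tab) with documented headers; the printed reference
tables of the source study ship with the package as CSV fixtures and are
loaded into long-format :class:`pandas.DataFrame` objects.

Decimal commas (a European-locale artifact of one printed table) are
normalized to decimal points with a logged warning.
"""
from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

import pandas as pd

from .errors import DuplicateRecordError, MissingSpeciesError, RegistryFormatError
from .thermo import Compound, Phase, ThermoRecord

logger = logging.getLogger("oxidimer")

__all__ = ["SpeciesTable", "FixtureSet", "read_species_table", "write_species_table",
           "load_fixtures", "write_report"]

_DECIMAL_COMMA = re.compile(r"^\s*(-?\d+),(\d+)\s*$")

_SPECIES_COLUMNS = ["species_id", "compound", "form", "phase", "E_T", "G_CORR",
                    "H_CORR", "charge", "multiplicity", "optimized_in", "level"]


@dataclass
class SpeciesTable:
    """A validated collection of :class:`ThermoRecord`, unique on
    (species_id, phase, level).  Records are stored in kcal/mol."""

    records: List[ThermoRecord] = field(default_factory=list)
    units: str = "kcal_per_mol"
    metadata: Dict[str, object] = field(default_factory=dict)
    _index: Dict[tuple, ThermoRecord] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.key in self._index:
                raise DuplicateRecordError(f"duplicate registry key {rec.key}")
            self._index[rec.key] = rec

    def __len__(self) -> int:
        return len(self.records)

    def add(self, rec: ThermoRecord) -> None:
        if rec.key in self._index:
            raise DuplicateRecordError(f"duplicate registry key {rec.key}")
        self.records.append(rec)
        self._index[rec.key] = rec

    def get(self, species_id: str, phase: Phase, level: str = "III") -> ThermoRecord:
        try:
            return self._index[(species_id, Phase(phase), level)]
        except KeyError:
            raise MissingSpeciesError(
                f"species {species_id!r} not in registry for phase "
                f"{Phase(phase).value!r} (level {level!r})"
            ) from None

    def lookup(self, compound: Union[Compound, str], form: str, phase: Phase,
               level: str = "III") -> ThermoRecord:
        """Address a record by (compound, form, phase); shared species fall
        back to the ``shared`` pseudo-compound."""
        comp = Compound(compound)
        for cid in (comp, Compound.SHARED):
            key = (f"{cid.value}:{form}", Phase(phase), level)
            if key in self._index:
                return self._index[key]
        raise MissingSpeciesError(
            f"species form {form!r} for compound {comp.value!r} not in registry "
            f"for phase {Phase(phase).value!r}"
        )

    def has(self, compound: Union[Compound, str], form: str, phase: Phase,
            level: str = "III") -> bool:
        try:
            self.lookup(compound, form, phase, level)
            return True
        except MissingSpeciesError:
            return False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "species_id": r.species_id, "compound": r.compound.value,
                "form": r.form, "phase": r.phase.value, "E_T": r.E_T,
                "G_CORR": r.G_corr, "H_CORR": r.H_corr, "charge": r.charge,
                "multiplicity": r.multiplicity, "optimized_in": r.optimized_in,
                "level": r.level,
            })
        return pd.DataFrame(rows, columns=_SPECIES_COLUMNS)


def _coerce_number(value: object, context: str) -> Optional[float]:
    """Parse a numeric cell, normalizing decimal commas with a warning."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip().replace("−", "-")  # unicode minus
    if text == "":
        return None
    m = _DECIMAL_COMMA.match(text)
    if m:
        text = f"{m.group(1)}.{m.group(2)}"
        logger.warning("decimal comma normalized in %s: %r -> %s", context, value, text)
    try:
        return float(text)
    except ValueError:
        raise RegistryFormatError(f"non-numeric value {value!r} in {context}") from None


def read_species_table(path: Union[str, Path], units: str = "kcal_per_mol") -> SpeciesTable:
    """Read a species registry from delimited text (comma or tab separated).

    The header must name the documented columns; ``H_CORR``, ``charge``,
    ``multiplicity``, ``optimized_in`` and ``level`` are optional.  Energies
    may be declared in hartree and are converted on read.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = {"species_id", "compound", "form", "phase", "E_T", "G_CORR"} - set(df.columns)
    if missing:
        raise RegistryFormatError(f"{path}: missing required columns {sorted(missing)}")
    table = SpeciesTable(units="kcal_per_mol", metadata={"source": str(path)})
    bad_rows: List[str] = []
    for i, row in df.iterrows():
        ctx = f"{path.name} row {i + 2}"
        try:
            phase = Phase(str(row["phase"]).strip())
        except ValueError:
            bad_rows.append(f"{ctx}: unknown phase {row['phase']!r}")
            continue
        try:
            rec = ThermoRecord(
                species_id=str(row["species_id"]).strip(),
                compound=Compound(str(row["compound"]).strip()),
                form=str(row["form"]).strip(),
                phase=phase,
                E_T=_coerce_number(row["E_T"], ctx),
                G_corr=_coerce_number(row.get("G_CORR"), ctx),
                H_corr=_coerce_number(row.get("H_CORR"), ctx),
                charge=int(_coerce_number(row.get("charge"), ctx) or 0),
                multiplicity=int(_coerce_number(row.get("multiplicity"), ctx) or 1),
                optimized_in=str(row.get("optimized_in", "gas") or "gas").strip(),
                level=str(row.get("level", "III") or "III").strip(),
            ).in_kcal(units)
        except (RegistryFormatError, ValueError, TypeError) as exc:
            bad_rows.append(f"{ctx}: {exc}")
            continue
        try:
            table.add(rec)
        except DuplicateRecordError as exc:
            bad_rows.append(f"{ctx}: {exc}")
    if bad_rows:
        raise RegistryFormatError(
            f"{path}: {len(bad_rows)} invalid row(s):\n  " + "\n  ".join(bad_rows)
        )
    return table


def write_species_table(table: SpeciesTable, path: Union[str, Path]) -> None:
    table.to_frame().to_csv(path, index=False, float_format="%.9f")


@dataclass
class FixtureSet:
    """The packaged transcriptions of the study's printed tables.

    Every frame carries a ``table`` column naming the printed table of
    origin.  ``stage_dg`` is long-format (stage x compound x phase), with
    ``pair=1`` marking the bracketed protonation/deprotonation pair
    summaries and ``variant`` distinguishing the two printed product
    variants of the final xanthommatin stage.
    """

    stage_dg: pd.DataFrame
    pathway_sums: pd.DataFrame
    o2_reduction: pd.DataFrame
    ros_membership: pd.DataFrame
    superoxide_donors: pd.DataFrame
    ip: pd.DataFrame
    ea: pd.DataFrame
    ts: pd.DataFrame

    def stage(self, stage: str, compound: Union[Compound, str], phase: Union[Phase, str],
              variant: str = "") -> float:
        """ΔG of one stage (or bracketed pair) for a compound/phase, kcal/mol."""
        df = self.stage_dg
        sel = df[(df.stage == stage)
                 & (df.compound == Compound(compound).value)
                 & (df.phase == Phase(phase).value)
                 & (df.variant.fillna("") == variant)]
        if len(sel) != 1:
            raise MissingSpeciesError(
                f"fixture has {len(sel)} entries for stage {stage!r}, "
                f"compound {Compound(compound).value!r}, phase {Phase(phase).value!r}, "
                f"variant {variant!r}"
            )
        return float(sel.dG.iloc[0])

    def redox_value(self, which: str, form: str, compound: Union[Compound, str],
                    phase: Union[Phase, str]) -> float:
        df = {"IP": self.ip, "EA": self.ea}[which]
        sel = df[(df["form"] == form)
                 & (df.compound == Compound(compound).value)
                 & (df.phase == Phase(phase).value)]
        if len(sel) != 1:
            raise MissingSpeciesError(
                f"fixture {which} table has {len(sel)} entries for "
                f"({form}, {Compound(compound).value}, {Phase(phase).value})"
            )
        return float(sel.value.iloc[0])


_EXPECTED_SHAPES = {
    # file -> (rows, key columns); guards against a silently truncated fixture
    "stage_dg.csv": (314, {"stage", "compound", "phase", "dG"}),
    "pathway_sums.csv": (12, {"compound", "phase", "sum"}),
    "o2_reduction.csv": (12, {"phase", "reduction", "dG"}),
    "ros_membership.csv": (23, {"phase", "reduction", "combo", "compounds"}),
    "superoxide_donors.csv": (3, {"phase", "compound", "forms"}),
    "ip.csv": (183, {"form", "compound", "phase", "value"}),
    "ea.csv": (183, {"form", "compound", "phase", "value"}),
    "ts.csv": (30, {"compound", "form", "nu_i", "phase", "dG_TS_R", "dG_TS_P"}),
}


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("oxidimer") / "fixtures" / name
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, keep_default_na=False, na_values=[""])
    n, cols = _EXPECTED_SHAPES[name]
    if len(df) != n or not cols <= set(df.columns):
        raise RegistryFormatError(
            f"fixture {name}: shape mismatch (got {len(df)} rows, columns {list(df.columns)})"
        )
    return df


def load_fixtures() -> FixtureSet:
    """Load the packaged printed-table fixtures, shape-checked."""
    fx = FixtureSet(
        stage_dg=_read_fixture("stage_dg.csv"),
        pathway_sums=_read_fixture("pathway_sums.csv"),
        o2_reduction=_read_fixture("o2_reduction.csv"),
        ros_membership=_read_fixture("ros_membership.csv"),
        superoxide_donors=_read_fixture("superoxide_donors.csv"),
        ip=_read_fixture("ip.csv"),
        ea=_read_fixture("ea.csv"),
        ts=_read_fixture("ts.csv"),
    )
    fx.stage_dg["variant"] = fx.stage_dg["variant"].fillna("")
    return fx


def write_report(result: object, path: Union[str, Path], format: str = "csv") -> None:
    """Write a pipeline result as CSV (DataFrame-shaped) or JSON.

    Accepts a DataFrame, a dataclass-like object with ``to_frame``/``to_dict``,
    a mapping, or an iterable of mappings.  Column order is stable and the
    CSV round-trips numerically at 1e-9.
    """
    path = Path(path)
    if hasattr(result, "to_frame"):
        result = result.to_frame()
    if format == "json":
        if isinstance(result, pd.DataFrame):
            payload = result.to_dict(orient="records")
        elif hasattr(result, "to_dict"):
            payload = result.to_dict()
        else:
            payload = result
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        return
    if format != "csv":
        raise ValueError(f"unknown report format {format!r}")
    if isinstance(result, dict):
        result = pd.DataFrame([result])
    elif not isinstance(result, pd.DataFrame):
        result = pd.DataFrame(list(result))
    result.to_csv(path, index=False, float_format="%.9f")
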