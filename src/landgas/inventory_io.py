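"""Reading, validation and unit normalisation of state-year inventory tables.

The pipeline's primary inputs are three CSV tables:

* ``waste.csv`` — one row per (state, year): municipal solid waste generated,
  in metric tons per day (MT/day), optionally with waste-composition mass
  fractions (paper/cardboard/rags, leaves/straw/others, fruit/vegetable,
  wood).
* ``econ.csv`` — one row per (state, year): gross state domestic product
  (GSDP) in crore (10^7 INR).  A blank/NA cell marks GSDP as missing, which
  is distinct from zero.
* ``population.csv`` — decennial census year and national population in
  millions.

All tables are UTF-8 CSV with a header row; heterogeneous source layouts are
accommodated through a column-name mapping (``dialect``) rather than extra
parsers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

#: inclusive calendar-year window accepted for inventory records
DEFAULT_YEAR_RANGE = (1900, 2100)

#: canonical composition column names (mass fractions, dimensionless)
COMPOSITION_COLUMNS = ("paper_frac", "green_frac", "food_frac", "wood_frac")

_FRACTION_SUM_TOL = 1e-9


@dataclass(frozen=True)
class CompositionProfile:
    """Mass fractions of the degradable waste streams.

    ``paper_frac`` covers paper, cardboard and rags; ``green_frac`` leaves,
    straw and other garden waste; ``food_frac`` fruit and vegetable waste;
    ``wood_frac`` wood.  ``other_frac`` is the inert remainder (earth, ash,
    plastics, glass, metals) and absorbs whatever the four degradable
    fractions leave.
    """

    paper_frac: float
    green_frac: float
    food_frac: float
    wood_frac: float = 0.0
    other_frac: float | None = None

    def __post_init__(self) -> None:
        degradable = (self.paper_frac, self.green_frac, self.food_frac, self.wood_frac)
        for name, value in zip(COMPOSITION_COLUMNS, degradable):
            if not (0.0 <= value <= 1.0):
                raise ValidationError(f"{name}={value!r} outside [0, 1]")
        total = sum(degradable)
        if total > 1.0 + _FRACTION_SUM_TOL:
            raise ValidationError(
                f"degradable fractions sum to {total:.6f} > 1"
            )
        if self.other_frac is None:
            object.__setattr__(self, "other_frac", max(0.0, 1.0 - total))
        elif not (0.0 <= self.other_frac <= 1.0):
            raise ValidationError(f"other_frac={self.other_frac!r} outside [0, 1]")
        if total + self.other_frac > 1.0 + 1e-6:
            raise ValidationError(
                f"fractions sum to {total + self.other_frac:.6f} > 1"
            )


@dataclass(frozen=True)
class WasteRecord:
    """MSW generated by one state in one inventory year, MT/day.

    Inventory years are labelled by their starting calendar year
    ("1999-2000" is year 1999).
    """

    state: str
    year: int
    msw_tpd: float
    composition: CompositionProfile | None = None

    def __post_init__(self) -> None:
        if self.msw_tpd < 0:
            raise ValidationError(
                f"negative waste tonnage {self.msw_tpd} for {self.state}/{self.year}"
            )
        lo, hi = DEFAULT_YEAR_RANGE
        if not (lo <= self.year <= hi):
            raise ValidationError(
                f"year {self.year} outside inventory range {DEFAULT_YEAR_RANGE}"
            )


@dataclass(frozen=True)
class EconRecord:
    """Gross state domestic product for one state-year, crore (10^7 INR).

    ``gsdp`` is ``None`` when the source prints NA; missing is never zero.
    """

    state: str
    year: int
    gsdp: float | None

    def __post_init__(self) -> None:
        if self.gsdp is not None and self.gsdp <= 0:
            raise ValidationError(
                f"non-positive GSDP {self.gsdp} for {self.state}/{self.year}"
            )

    @property
    def missing(self) -> bool:
        return self.gsdp is None


@dataclass(frozen=True)
class PopulationRecord:
    """National population at one decennial census, millions."""

    census_year: int
    population_millions: float

    def __post_init__(self) -> None:
        if self.population_millions <= 0:
            raise ValidationError(
                f"non-positive population {self.population_millions}"
            )


@dataclass
class InventoryPanel:
    """The full state-year panel: waste, GSDP and census population."""

    waste: list[WasteRecord] = field(default_factory=list)
    econ: list[EconRecord] = field(default_factory=list)
    population: list[PopulationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique([(w.state, w.year) for w in self.waste], "waste")
        _check_unique([(e.state, e.year) for e in self.econ], "econ")
        _check_unique([p.census_year for p in self.population], "population")
        years = [p.census_year for p in self.population]
        if years != sorted(years):
            raise ValidationError("census years must be strictly increasing")
        for a, b in zip(years, years[1:]):
            if b - a != 10:
                raise ValidationError(
                    f"census years {a} and {b} are not 10 years apart"
                )

    def waste_by_state(self, year: int) -> dict[str, WasteRecord]:
        return {w.state: w for w in self.waste if w.year == year}

    def gsdp_by_state(self, year: int) -> dict[str, float | None]:
        return {e.state: e.gsdp for e in self.econ if e.year == year}

    @property
    def waste_years(self) -> list[int]:
        return sorted({w.year for w in self.waste})

    @property
    def states(self) -> list[str]:
        return sorted({w.state for w in self.waste} | {e.state for e in self.econ})


def _check_unique(keys: Sequence, table: str) -> None:
    seen = set()
    for k in keys:
        if k in seen:
            raise ValidationError(f"duplicate key {k!r} in {table} table")
        seen.add(k)


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

def tpd_to_gg_per_year(msw_tpd):
    """Convert a waste flow in metric tons/day to Gg/yr (1 Gg = 1000 t).

    A 365-day inventory year is used throughout (no leap-year handling).
    Accepts scalars or numpy arrays; negative input is a domain error.
    """
    arr = np.asarray(msw_tpd, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("waste flow must be non-negative")
    out = arr * 365.0 / 1000.0
    return float(out) if np.isscalar(msw_tpd) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _remap(df: pd.DataFrame, dialect: Mapping[str, str] | None) -> pd.DataFrame:
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    return df


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)} (use a column mapping if the header differs)"
        )


def read_waste_csv(path, dialect: Mapping[str, str] | None = None) -> list[WasteRecord]:
    """Read a waste CSV into records.

    ``dialect`` maps canonical column names (``state``, ``year``,
    ``msw_tpd``, composition columns) to the names actually present.
    Malformed rows raise with the offending row index and key.
    """
    df = _remap(pd.read_csv(path), dialect)
    _require_columns(df, ("state", "year", "msw_tpd"), path)
    has_composition = all(c in df.columns for c in COMPOSITION_COLUMNS[:3])
    records = []
    for idx, row in df.iterrows():
        try:
            composition = None
            if has_composition and not math.isnan(float(row["paper_frac"])):
                composition = CompositionProfile(
                    paper_frac=float(row["paper_frac"]),
                    green_frac=float(row["green_frac"]),
                    food_frac=float(row["food_frac"]),
                    wood_frac=float(row.get("wood_frac", 0.0) or 0.0),
                )
            records.append(
                WasteRecord(
                    state=str(row["state"]),
                    year=int(row["year"]),
                    msw_tpd=float(row["msw_tpd"]),
                    composition=composition,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from exc
    _check_unique([(r.state, r.year) for r in records], f"{path}")
    return records


def read_econ_csv(path, dialect: Mapping[str, str] | None = None) -> list[EconRecord]:
    """Read a GSDP CSV; blank or 'NA' cells become missing values."""
    df = _remap(pd.read_csv(path), dialect)
    _require_columns(df, ("state", "year", "gsdp_crore"), path)
    records = []
    for idx, row in df.iterrows():
        raw = row["gsdp_crore"]
        gsdp = None if pd.isna(raw) or str(raw).strip().upper() == "NA" else float(raw)
        try:
            records.append(EconRecord(str(row["state"]), int(row["year"]), gsdp))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from exc
    _check_unique([(r.state, r.year) for r in records], f"{path}")
    return records


def read_population_csv(path, dialect: Mapping[str, str] | None = None) -> list[PopulationRecord]:
    df = _remap(pd.read_csv(path), dialect)
    _require_columns(df, ("census_year", "population_millions"), path)
    return [
        PopulationRecord(int(r["census_year"]), float(r["population_millions"]))
        for _, r in df.iterrows()
    ]


def write_waste_csv(records: Sequence[WasteRecord], path) -> None:
    rows = []
    for r in records:
        row = {"state": r.state, "year": r.year, "msw_tpd": r.msw_tpd}
        if r.composition is not None:
            c = r.composition
            row.update(
                paper_frac=c.paper_frac, green_frac=c.green_frac,
                food_frac=c.food_frac, wood_frac=c.wood_frac,
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_econ_csv(records: Sequence[EconRecord], path) -> None:
    pd.DataFrame(
        [{"state": r.state, "year": r.year, "gsdp_crore": r.gsdp} for r in records]
    ).to_csv(path, index=False)


def write_population_csv(records: Sequence[PopulationRecord], path) -> None:
    pd.DataFrame(
        [
            {"census_year": r.census_year, "population_millions": r.population_millions}
            for r in records
        ]
    ).to_csv(path, index=False)


def read_panel(
    waste_path,
    econ_path=None,
    population_path=None,
    dialects: Mapping[str, Mapping[str, str]] | None = None,
) -> InventoryPanel:
    """Assemble an :class:`InventoryPanel` from the three CSV tables."""
    dialects = dialects or {}
    return InventoryPanel(
        waste=read_waste_csv(waste_path, dialects.get("waste")),
        econ=read_econ_csv(econ_path, dialects.get("econ")) if econ_path else [],
        population=(
            read_population_csv(population_path, dialects.get("population"))
            if population_path
            else []
        ),
    )


# ---------------------------------------------------------------------------
# panel validation (report-only, never mutates)
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Cross-table completeness report for a panel.

    ``econ_missing`` lists (state, year) pairs whose GSDP is absent or NA;
    ``waste_missing`` pairs that have GSDP but no waste record.  A recorded
    zero is complete data, not missing.
    """

    n_waste: int
    n_econ: int
    n_population: int
    econ_missing: list[tuple[str, int]] = field(default_factory=list)
    waste_missing: list[tuple[str, int]] = field(default_factory=list)

    @property
    def empty_panel(self) -> bool:
        return self.n_waste == 0 and self.n_econ == 0

    @property
    def clean(self) -> bool:
        return not self.empty_panel and not self.econ_missing and not self.waste_missing


def validate_panel(panel: InventoryPanel) -> ValidationReport:
    """Report missing waste/GSDP coverage per state-year; never raises."""
    waste_keys = {(w.state, w.year) for w in panel.waste}
    econ_present = {(e.state, e.year) for e in panel.econ if not e.missing}
    econ_na = {(e.state, e.year) for e in panel.econ if e.missing}
    report = ValidationReport(
        n_waste=len(panel.waste),
        n_econ=len(panel.econ),
        n_population=len(panel.population),
    )
    report.econ_missing = sorted(econ_na | (waste_keys - econ_present - econ_na))
    report.waste_missing = sorted(econ_present - waste_keys)
    return report


def drop_records(
    panel: InventoryPanel,
    waste_keys: Iterable[tuple[str, int]] = (),
    econ_keys: Iterable[tuple[str, int]] = (),
) -> InventoryPanel:
    """Return a copy of the panel without the named state-year records."""
    waste_keys, econ_keys = set(waste_keys), set(econ_keys)
    return InventoryPanel(
        waste=[w for w in panel.waste if (w.state, w.year) not in waste_keys],
        econ=[e for e in panel.econ if (e.state, e.year) not in econ_keys],
        population=list(panel.population),
    )
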