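"""National aggregation, percent-change reporting and the GSDP-CH4 link.

Percent figures follow inventory-report usage: a "245% increase from 1999
to 2011" is the *ratio* 100*E_2011/E_1999 truncated to an integer, not a
delta percentage.  The GSDP association is the R^2 of an ordinary
least-squares fit of state CH4 emissions on state GSDP within one inventory
year; states with missing GSDP are dropped pairwise, never imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError
from .inventory_io import PopulationRecord

logger = logging.getLogger(__name__)


@dataclass
class TrendReport:
    """Aggregated pipeline results.

    national_series
        (method, inventory year) -> national total, Gg/yr.
    percent_changes
        (year_a, year_b) -> 100*E_b/E_a, full precision (truncate on report).
    r2_by_year
        inventory year -> (n paired states, R^2 of CH4 on GSDP).
    growth_rates
        census year -> decadal population growth, percent.
    """

    national_series: dict[tuple[str, int], float] = field(default_factory=dict)
    percent_changes: dict[tuple[int, int], float] = field(default_factory=dict)
    r2_by_year: dict[int, tuple[int, float]] = field(default_factory=dict)
    growth_rates: dict[int, float] = field(default_factory=dict)

    def national_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"method": m, "year": y, "national_gg": v}
                for (m, y), v in sorted(self.national_series.items())
            ]
        )


def national_total(per_state: Mapping[str, float]) -> float:
    """Sum state emissions (Gg/yr) into a national total."""
    values = list(per_state.values())
    if any(v < 0 for v in values):
        raise ValidationError("state emissions must be non-negative")
    return float(sum(values))


def percent_ratio(value_b: float, value_a: float, mode: str = "truncate"):
    """100 * value_b / value_a, the ratio-as-percent used in reports.

    ``mode``: ``truncate`` (floor to integer, the report default), ``round``
    (nearest integer) or ``exact`` (full-precision float).
    """
    if value_a <= 0:
        raise ValidationError(f"baseline must be positive, got {value_a}")
    ratio = 100.0 * value_b / value_a
    if mode == "exact":
        return ratio
    if mode == "truncate":
        return int(math.floor(ratio))
    if mode == "round":
        return int(round(ratio))
    raise ValidationError(f"unknown percent mode {mode!r}")


def decadal_growth(earlier: PopulationRecord, later: PopulationRecord) -> float:
    """Decadal population growth rate, percent, rounded to 2 decimals."""
    if later.census_year - earlier.census_year != 10:
        raise ValidationError(
            f"census years {earlier.census_year}/{later.census_year} are not consecutive"
        )
    p1, p2 = earlier.population_millions, later.population_millions
    return round(100.0 * (p2 - p1) / p1, 2)


def growth_series(population: Sequence[PopulationRecord]) -> dict[int, float]:
    """Decadal growth for each census year after the first."""
    ordered = sorted(population, key=lambda p: p.census_year)
    return {
        b.census_year: decadal_growth(a, b) for a, b in zip(ordered, ordered[1:])
    }


def ols_r2(
    x: Mapping[str, float | None],
    y: Mapping[str, float],
    log_log: bool = False,
) -> tuple[int, float]:
    """R^2 of the OLS fit y = a + b*x over states present in both maps.

    ``x`` is GSDP by state (None = missing, dropped pairwise and logged);
    ``y`` is CH4 by state.  ``log_log`` fits log(y) on log(x) instead.
    Returns (number of states used, R^2).  Requires >= 3 complete pairs and
    non-constant x.
    """
    keys = sorted(set(x) & set(y))
    dropped = sorted(k for k in keys if x[k] is None or _isnan(x[k]) or _isnan(y[k]))
    if dropped:
        logger.info("ols_r2: dropping states with missing values: %s", dropped)
    keys = [k for k in keys if k not in dropped]
    if len(keys) < 3:
        raise ValidationError(f"need >= 3 complete (GSDP, CH4) pairs, have {len(keys)}")
    xv = np.array([float(x[k]) for k in keys])
    yv = np.array([float(y[k]) for k in keys])
    if log_log:
        if np.any(xv <= 0) or np.any(yv <= 0):
            raise ValidationError("log-log fit requires strictly positive values")
        xv, yv = np.log(xv), np.log(yv)
    if np.ptp(xv) == 0:
        raise ValidationError("GSDP is constant across states; the fit is undefined")
    model = sm.OLS(yv, sm.add_constant(xv)).fit()
    return len(keys), float(model.rsquared)


def _isnan(v) -> bool:
    try:
        return math.isnan(float(v))
    except (TypeError, ValueError):
        return True


def write_trend_csvs(report: TrendReport, out_dir) -> None:
    """Write trends.csv, r2.csv and growth.csv under ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.national_frame().to_csv(out / "trends.csv", index=False)
    pd.DataFrame(
        [
            {"year": y, "n_states": n, "r2": r2}
            for y, (n, r2) in sorted(report.r2_by_year.items())
        ]
    ).to_csv(out / "r2.csv", index=False)
    pd.DataFrame(
        [
            {"census_year": y, "percent": g}
            for y, g in sorted(report.growth_rates.items())
        ]
    ).to_csv(out / "growth.csv", index=False)
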