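"""The three landfill-CH4 estimators and their shared parameterisation.

Three estimators over a state-year waste panel:

* **DM** — the IPCC default (mass-balance) method.  All methane potential of
  a year's landfilled waste is attributed to that same year:

  ``E = (MSW_T * MSW_F) * MCF * DOC * DOC_F * F * (16/12 - R) * (1 - OX)``

* **MTM** — the modified triangular method.  Each deposition cohort emits
  along a triangular rate profile: zero until one year after deposition, a
  linear rise to a peak 6 years after deposition, then a linear fall to zero
  16 years after deposition.  The cohort's lifetime yield is
  ``G = 1.87 * A_t * C0`` where ``A_t`` is the mass landfilled in year ``t``
  and ``C0`` the methane generation potential per unit waste.

* **FOD** — first-order decay.  Degradable carbon decays exponentially with
  rate ``k = ln 2 / t_half``; a cohort deposited in year ``t`` releases the
  fraction ``e^{-(T-1)k} - e^{-Tk}`` of its lifetime yield in the year at
  offset ``T >= 1``.

A year's emission under MTM/FOD is the superposition over all past cohorts.
All masses are Gg (1 Gg = 1000 t); emissions are Gg CH4 per year.

The methane recovery term ``R`` is applied exactly where the mass-balance
formula places it (subtracted from the 16/12 carbon-to-methane ratio), which
is dimensionally odd but inert at the default ``R = 0``; set
``strict_ipcc_recovery`` to subtract recovered methane in Gg from the final
total instead (the IPCC 1996 convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, MissingHistoryError, ValidationError
from .inventory_io import CompositionProfile

#: stoichiometric mass ratio CH4/C (16 g CH4 per 12 g C)
C_TO_CH4 = 16.0 / 12.0

_DOC_COEFFS = {"paper_frac": 0.40, "green_frac": 0.17, "food_frac": 0.15, "wood_frac": 0.30}


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmissionParams:
    """Scalars of the mass-balance formula.

    msw_f
        Fraction of generated MSW that reaches a landfill (0.7: Indian
        collection efficiency; the rest is recycled, reused or lost).
    mcf
        Methane correction factor for the landfill management category
        (0.6: uncategorised sites).
    doc
        Degradable organic carbon, g C per g waste (0.114 for the national
        composition; superseded per state when composition data exist).
    doc_f
        Fraction of DOC actually dissimilated to gas (0.77 at 35 degC).
    f
        Fraction of methane in landfill gas (0.5).
    r
        Recovered methane term (0: no recovery infrastructure).
    ox
        Oxidation factor for the aerobic top layer (0: default).
    """

    msw_f: float = 0.7
    mcf: float = 0.6
    doc: float = 0.114
    doc_f: float = 0.77
    f: float = 0.5
    r: float = 0.0
    ox: float = 0.0
    strict_ipcc_recovery: bool = False

    #: stoichiometric CH4/C mass ratio; fixed
    c_to_ch4: float = C_TO_CH4

    def __post_init__(self) -> None:
        for name in ("msw_f", "mcf", "doc", "doc_f", "f", "r", "ox"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValidationError(f"{name}={value!r} outside [0, 1]")
        if self.c_to_ch4 != C_TO_CH4:
            raise ValidationError("c_to_ch4 is stoichiometric and fixed at 16/12")


@dataclass(frozen=True)
class DecayParams:
    """First-order decay kinetics: half-life in years, rate k = ln2/t_half."""

    t_half: float = 7.0
    k: float | None = None

    def __post_init__(self) -> None:
        if self.t_half <= 0:
            raise ValidationError(f"half-life must be positive, got {self.t_half}")
        implied = math.log(2.0) / self.t_half
        if self.k is None:
            object.__setattr__(self, "k", implied)
        elif abs(self.k - implied) > 1e-12 * implied:
            raise ValidationError(
                f"k={self.k} inconsistent with ln2/t_half={implied}"
            )

    @classmethod
    def from_k(cls, k: float) -> "DecayParams":
        if k <= 0:
            raise ValidationError(f"rate constant must be positive, got {k}")
        return cls(t_half=math.log(2.0) / k)


@dataclass(frozen=True)
class MTMParams:
    """Triangular-profile geometry and the lifetime relation G = coeff*A_t*C0.

    ``c0`` is the methane generation potential per unit waste; when ``None``
    it is resolved at use time to ``lifetime_yield(1)/coefficient`` so that
    MTM and DM agree on lifetime yield (see :func:`default_c0`).
    """

    c0: float | None = None
    coefficient: float = 1.87
    lag_years: int = 1
    peak_year: int = 6
    end_year: int = 16

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ConfigurationError(f"coefficient must be positive, got {self.coefficient}")
        if not (self.lag_years < self.peak_year < self.end_year):
            raise ConfigurationError(
                f"need lag < peak < end, got {self.lag_years}/{self.peak_year}/{self.end_year}"
            )
        if self.c0 is not None and self.c0 < 0:
            raise ConfigurationError(f"c0 must be non-negative, got {self.c0}")


def default_c0(
    params: EmissionParams, mtm: MTMParams | None = None, doc: float | None = None
) -> float:
    """C0 making the MTM lifetime yield of a unit deposit equal the DM one."""
    coefficient = mtm.coefficient if mtm is not None else 1.87
    return lifetime_yield(1.0, params, doc=doc) / coefficient


# ---------------------------------------------------------------------------
# series containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepositionSeries:
    """Annual mass landfilled, Gg per year, over contiguous years.

    Masses are *landfilled* quantities (generation already multiplied by
    MSW_F).  ``history_complete`` asserts that no waste was deposited before
    ``start_year``; series built from observed records alone leave it False
    until a backcast extends them, and the superposition estimators refuse
    to treat unknown history as zero.
    """

    start_year: int
    masses: np.ndarray
    history_complete: bool = True

    def __post_init__(self) -> None:
        arr = np.atleast_1d(np.asarray(self.masses, dtype=float))
        if arr.ndim != 1 or arr.size == 0:
            raise ValidationError("deposition series must be a non-empty 1-d array")
        if np.any(arr < 0):
            raise ValidationError("deposited masses must be non-negative")
        object.__setattr__(self, "masses", arr)

    @classmethod
    def from_mapping(
        cls, deposits: Mapping[int, float], history_complete: bool = True
    ) -> "DepositionSeries":
        years = sorted(deposits)
        if years != list(range(years[0], years[-1] + 1)):
            raise ValidationError(f"deposition years {years} are not contiguous")
        return cls(years[0], np.array([deposits[y] for y in years]), history_complete)

    @property
    def end_year(self) -> int:
        return self.start_year + self.masses.size - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    def mass_in(self, year: int) -> float:
        """Mass deposited in ``year``; 0 outside the series only where the
        history is known complete."""
        if year < self.start_year:
            if not self.history_complete:
                raise MissingHistoryError(
                    f"deposition history before {self.start_year} is unknown"
                )
            return 0.0
        if year > self.end_year:
            return 0.0
        return float(self.masses[year - self.start_year])

    def backcast(
        self, mode: str = "geometric", growth: float = 0.05, years: int = 25
    ) -> "DepositionSeries":
        """Extend the series ``years`` further into the past.

        ``geometric`` de-grows the first observed mass at ``growth`` per
        year; ``constant`` repeats it; ``zero`` prepends zeros.  The result
        is marked history-complete.
        """
        if years < 0:
            raise ConfigurationError(f"backcast years must be >= 0, got {years}")
        first = float(self.masses[0])
        offsets = np.arange(years, 0, -1)
        if mode == "geometric":
            if growth <= -1:
                raise ConfigurationError(f"growth must exceed -1, got {growth}")
            prefix = first / (1.0 + growth) ** offsets
        elif mode == "constant":
            prefix = np.full(years, first)
        elif mode == "zero":
            prefix = np.zeros(years)
        else:
            raise ConfigurationError(f"unknown backcast mode {mode!r}")
        return DepositionSeries(
            self.start_year - years,
            np.concatenate([prefix, self.masses]),
            history_complete=True,
        )


@dataclass(frozen=True)
class EmissionSeries:
    """Annual CH4 emissions, Gg/yr, labelled by estimator (DM | MTM | FOD)."""

    method: str
    start_year: int
    emissions: np.ndarray

    def __post_init__(self) -> None:
        arr = np.atleast_1d(np.asarray(self.emissions, dtype=float))
        if np.any(arr < -1e-12):
            raise ValidationError("emissions must be non-negative")
        object.__setattr__(self, "emissions", arr)

    def as_dict(self) -> dict[int, float]:
        return {
            int(self.start_year + i): float(v) for i, v in enumerate(self.emissions)
        }


# ---------------------------------------------------------------------------
# DOC composition model
# ---------------------------------------------------------------------------

def compute_doc(profile: CompositionProfile) -> float:
    """Degradable organic carbon from waste composition.

    ``DOC = 0.4*A + 0.17*B + 0.15*C + 0.3*D`` with A = paper/cardboard/rags,
    B = leaves/straw/others, C = fruit/vegetable waste, D = wood; all mass
    fractions.  Result lies in [0, 0.4].
    """
    return (
        _DOC_COEFFS["paper_frac"] * profile.paper_frac
        + _DOC_COEFFS["green_frac"] * profile.green_frac
        + _DOC_COEFFS["food_frac"] * profile.food_frac
        + _DOC_COEFFS["wood_frac"] * profile.wood_frac
    )


def doc_for(profile: CompositionProfile | None, params: EmissionParams) -> float:
    """Per-state DOC: composition model when data exist, else the scalar."""
    return params.doc if profile is None else compute_doc(profile)


# ---------------------------------------------------------------------------
# DM — mass-balance default method
# ---------------------------------------------------------------------------

def dm_emission(msw_t: float, params: EmissionParams, doc: float | None = None) -> float:
    """Mass-balance CH4 for one year, Gg/yr.

    ``msw_t`` is total waste *generated* that year (Gg/yr); the landfilled
    share is taken via ``params.msw_f``.  ``doc`` overrides the scalar DOC
    (per-state composition).
    """
    if msw_t < 0:
        raise ValidationError(f"waste mass must be non-negative, got {msw_t}")
    doc = params.doc if doc is None else doc
    stoich = C_TO_CH4 - params.r
    if stoich < 0:
        raise ValidationError(
            f"recovery term r={params.r} exceeds the 16/12 stoichiometric ratio"
        )
    base = msw_t * params.msw_f * params.mcf * doc * params.doc_f * params.f
    if params.strict_ipcc_recovery:
        return max(0.0, base * C_TO_CH4 * (1.0 - params.ox) - params.r)
    return base * stoich * (1.0 - params.ox)


def lifetime_yield(a: float, params: EmissionParams, doc: float | None = None) -> float:
    """Total CH4 ever generated by ``a`` Gg of *landfilled* waste, Gg.

    ``a * MCF * DOC * DOC_F * F * 16/12`` — the common normaliser tying the
    MTM and FOD cohort totals to the mass-balance factors (MSW_F excluded:
    the mass is already landfilled; R/OX excluded: generation, not net
    release).
    """
    if a < 0:
        raise ValidationError(f"deposited mass must be non-negative, got {a}")
    doc = params.doc if doc is None else doc
    return a * params.mcf * doc * params.doc_f * params.f * C_TO_CH4


# ---------------------------------------------------------------------------
# MTM — modified triangular method
# ---------------------------------------------------------------------------

def mtm_profile(a_t: float, params: MTMParams) -> np.ndarray:
    """Annual emissions of one cohort, Gg/yr, for offsets 0..end_year.

    The instantaneous rate is triangular: zero until ``lag_years`` after
    deposition, linear up to the peak at ``peak_year``, linear down to zero
    at ``end_year``.  Entry ``i`` is the exact integral of that rate over
    the one-year slice [i, i+1); the profile therefore sums to
    ``G = coefficient * a_t * c0`` by construction.
    """
    if a_t < 0:
        raise ValidationError(f"deposited mass must be non-negative, got {a_t}")
    if params.c0 is None:
        raise ConfigurationError(
            "MTMParams.c0 unresolved; set it or use default_c0()"
        )
    g = params.coefficient * a_t * params.c0
    lag, peak, end = float(params.lag_years), float(params.peak_year), float(params.end_year)
    height = 2.0 * g / (end - lag)

    def rate(t: float) -> float:
        if t <= lag or t >= end:
            return 0.0
        if t <= peak:
            return height * (t - lag) / (peak - lag)
        return height * (end - t) / (end - peak)

    profile = np.zeros(params.end_year + 1)
    for i in range(params.end_year + 1):
        # exact trapezoid over the linear pieces inside [i, i+1)
        pts = sorted({float(i), float(i + 1)} | {b for b in (lag, peak, end) if i < b < i + 1})
        profile[i] = sum(
            (b - a) * 0.5 * (rate(a) + rate(b)) for a, b in zip(pts, pts[1:])
        )
    return profile


def mtm_emission(
    deposits: DepositionSeries, inventory_year: int, params: MTMParams
) -> float:
    """CH4 in ``inventory_year`` as the superposition of cohort triangles."""
    unit = mtm_profile(1.0, params)
    total = 0.0
    for offset in range(params.end_year + 1):
        total += unit[offset] * deposits.mass_in(inventory_year - offset)
    return total


# ---------------------------------------------------------------------------
# FOD — first-order decay
# ---------------------------------------------------------------------------

def fod_rate_constant(t_half: float) -> float:
    """First-order rate constant k = ln2 / t_half, 1/yr."""
    if t_half <= 0:
        raise ValidationError(f"half-life must be positive, got {t_half}")
    return math.log(2.0) / t_half


def fod_fraction(offset_t, k: float):
    """Fraction of a cohort's lifetime yield released at offset T >= 1.

    ``e^{-(T-1)k} - e^{-Tk}``: strictly positive, strictly decreasing in T,
    telescoping to 1 over T = 1..inf.  Vectorised over ``offset_t``.
    """
    if k <= 0:
        raise ValidationError(f"rate constant must be positive, got {k}")
    t = np.asarray(offset_t)
    if np.any(t < 1):
        raise ValidationError("offset must be >= 1 (release starts one year after deposition)")
    out = np.exp(-(t - 1.0) * k) - np.exp(-t * k)
    return float(out) if np.isscalar(offset_t) else out


def fod_emission(
    deposits: DepositionSeries,
    inventory_year: int,
    params: EmissionParams,
    decay: DecayParams,
    doc: float | None = None,
    min_history: int | None = None,
) -> float:
    """CH4 in ``inventory_year`` from exponentially decaying cohorts, Gg/yr.

    Each past cohort contributes ``fod_fraction(offset) * lifetime factors``;
    the recovery term is subtracted per existing summand (as the formula
    places it) unless ``params.strict_ipcc_recovery``, and ``(1 - OX)``
    scales the sum.

    Exponential release never truncates, so a series whose pre-start history
    is unknown cannot be evaluated exactly: it is accepted only when it
    reaches at least ``min_history`` years before ``inventory_year`` (the
    older tail is then below ``e^{-min_history * k}`` of lifetime yield).
    """
    if not deposits.history_complete:
        if min_history is None:
            raise MissingHistoryError(
                f"deposition history before {deposits.start_year} is unknown; "
                "backcast the series or pass min_history"
            )
        if deposits.start_year > inventory_year - min_history:
            raise MissingHistoryError(
                f"series starts {deposits.start_year}, needs coverage back to "
                f"{inventory_year - min_history}"
            )
    doc = params.doc if doc is None else doc
    last = min(inventory_year - 1, deposits.end_year)
    first = deposits.start_year
    total = 0.0
    if last >= first:
        years = np.arange(first, last + 1)
        offsets = inventory_year - years
        masses = deposits.masses[years - deposits.start_year]
        fracs = fod_fraction(offsets, decay.k)
        per_cohort = fracs * masses * params.mcf * doc * params.doc_f * params.f * C_TO_CH4
        if params.strict_ipcc_recovery:
            total = float(per_cohort.sum())
        else:
            total = float((per_cohort - params.r * (masses > 0)).sum())
    if params.strict_ipcc_recovery:
        return max(0.0, total * (1.0 - params.ox) - params.r)
    return total * (1.0 - params.ox)


def emission_series(
    deposits: DepositionSeries,
    years: range | list[int],
    method: str,
    params: EmissionParams,
    decay: DecayParams | None = None,
    mtm: MTMParams | None = None,
    doc: float | None = None,
) -> EmissionSeries:
    """Evaluate one estimator over a span of inventory years."""
    years = list(years)
    if method == "MTM":
        mtm = mtm or MTMParams()
        if mtm.c0 is None:
            mtm = replace(mtm, c0=default_c0(params, mtm, doc=doc))
        values = [mtm_emission(deposits, y, mtm) for y in years]
    elif method == "FOD":
        decay = decay or DecayParams()
        values = [fod_emission(deposits, y, params, decay, doc=doc) for y in years]
    else:
        raise ConfigurationError(f"unknown cohort method {method!r}")
    return EmissionSeries(method, years[0], np.array(values))
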