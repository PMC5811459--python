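"""Synthetic state-year panels with known ground truth.

Real Indian MSW inventories come from pollution-board compendia that are
not machine-readable; this module emulates their statistical shape so every
pipeline stage is testable end to end:

* state GSDP is lognormal across states and grows multiplicatively;
* waste generation follows a power law in GSDP with lognormal noise,
  ``msw_tpd = scale * gsdp^elasticity * exp(eps)``, the one-knob mechanism
  behind the positive, heteroscedastic GSDP-CH4 scatter seen in real
  inventories;
* the scale is calibrated so the base-year national total hits a target
  (default 52125 MT/day, the published 1999-2000 national figure);
* waste composition is drawn uniformly inside the ranges reported for
  Indian cities: organics 40-60% (split between garden and food waste),
  paper 3-6%, wood 0-2%, the inert remainder (earth/ash 30-40%, plastics/
  glass/metals ~1% each) absorbed by ``other_frac``.

``generate_panel`` returns the panel together with the ground truth
(scale, elasticity, per-state DOC) so tests can do parameter recovery.
A single seed drives everything through deterministic per-state substreams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .inventory_io import (
    CompositionProfile,
    EconRecord,
    InventoryPanel,
    PopulationRecord,
    WasteRecord,
    write_econ_csv,
    write_population_csv,
    write_waste_csv,
)
from .emission_models import compute_doc

#: decennial national census populations (millions), bundled as the default
#: population fixture
INDIA_CENSUS = (
    (1911, 252.09), (1921, 251.32), (1931, 278.98), (1941, 318.66),
    (1951, 361.09), (1961, 439.23), (1971, 548.16), (1981, 683.33),
    (1991, 846.30), (2001, 1028.61), (2011, 1210.19),
)

#: uniform draw bounds for composition fractions
DEFAULT_COMPOSITION_RANGES = {
    "organic": (0.40, 0.60),
    "paper": (0.03, 0.06),
    "wood": (0.00, 0.02),
}

#: share of the organic draw assigned to leaves/straw/others (the rest is
#: fruit/vegetable waste)
DEFAULT_ORGANIC_SPLIT = 0.6


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults reproduce the published study scale.

    ``noise_sd`` is the standard deviation of the lognormal waste noise; the
    default is calibrated so that with 25 states the base-year GSDP-CH4
    R^2 averages ~0.8 across seeds, the strength of association the real
    inventories show.
    """

    n_states: int = 25
    year_start: int = 1999
    year_end: int = 2015
    seed: int = 0
    gsdp_log_mean: float = 11.9
    gsdp_log_sd: float = 0.8
    waste_elasticity: float = 1.0
    noise_sd: float = 0.35
    growth_rate: float = 0.05
    composition_ranges: dict = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION_RANGES)
    )
    organic_split: float = DEFAULT_ORGANIC_SPLIT
    national_tpd_target: float | None = 52125.0

    def __post_init__(self) -> None:
        if self.n_states < 3:
            raise ConfigurationError(f"need >= 3 states, got {self.n_states}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.year_end < self.year_start:
            raise ConfigurationError("year_end precedes year_start")
        if not (0.0 <= self.organic_split <= 1.0):
            raise ConfigurationError("organic_split must lie in [0, 1]")
        hi = sum(b for _, b in (self.composition_ranges[k] for k in ("organic", "paper", "wood")))
        if hi > 1.0:
            raise ConfigurationError(
                f"composition upper bounds sum to {hi} > 1; inerts cannot absorb the remainder"
            )


@dataclass
class GroundTruth:
    """What the generator actually used, for parameter-recovery tests."""

    seed: int
    scale: float
    elasticity: float
    growth_rate: float
    doc_by_state: dict[str, float]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _state_names(n: int) -> list[str]:
    return [f"State{i + 1:02d}" for i in range(n)]


def generate_panel(config: SyntheticConfig) -> tuple[InventoryPanel, GroundTruth]:
    """Draw a full panel (waste + GSDP + census population) and its truth."""
    root = np.random.SeedSequence(config.seed)
    state_seqs = root.spawn(config.n_states)
    states = _state_names(config.n_states)
    years = list(range(config.year_start, config.year_end + 1))
    n_years = len(years)

    base_gsdp = np.empty(config.n_states)
    noise = np.empty((config.n_states, n_years))
    compositions: list[CompositionProfile] = []
    o_lo, o_hi = config.composition_ranges["organic"]
    p_lo, p_hi = config.composition_ranges["paper"]
    w_lo, w_hi = config.composition_ranges["wood"]
    for i, seq in enumerate(state_seqs):
        rng = np.random.default_rng(seq)
        base_gsdp[i] = np.exp(rng.normal(config.gsdp_log_mean, config.gsdp_log_sd))
        noise[i] = rng.normal(0.0, config.noise_sd, size=n_years) if config.noise_sd else 0.0
        organic = rng.uniform(o_lo, o_hi)
        compositions.append(
            CompositionProfile(
                paper_frac=rng.uniform(p_lo, p_hi),
                green_frac=config.organic_split * organic,
                food_frac=(1.0 - config.organic_split) * organic,
                wood_frac=rng.uniform(w_lo, w_hi),
            )
        )

    growth = (1.0 + config.growth_rate) ** np.arange(n_years)
    gsdp = base_gsdp[:, None] * growth[None, :]  # states x years, crore

    raw = gsdp ** config.waste_elasticity * np.exp(noise)
    if config.national_tpd_target is not None:
        scale = config.national_tpd_target / raw[:, 0].sum()
    else:
        scale = 1.0
    msw_tpd = scale * raw

    waste, econ = [], []
    doc_by_state = {}
    for i, state in enumerate(states):
        doc_by_state[state] = compute_doc(compositions[i])
        for j, year in enumerate(years):
            waste.append(
                WasteRecord(state, year, float(msw_tpd[i, j]), compositions[i])
            )
            econ.append(EconRecord(state, year, float(gsdp[i, j])))

    panel = InventoryPanel(
        waste=waste,
        econ=econ,
        population=[PopulationRecord(y, p) for y, p in INDIA_CENSUS],
    )
    truth = GroundTruth(
        seed=config.seed,
        scale=float(scale),
        elasticity=config.waste_elasticity,
        growth_rate=config.growth_rate,
        doc_by_state=doc_by_state,
    )
    return panel, truth


def perturb_panel(
    panel: InventoryPanel,
    missing: list[tuple[str, int | None, str]],
    seed: int | None = None,
) -> InventoryPanel:
    """Knock out records to emulate incomplete real-world coverage.

    ``missing`` entries are ``(state, year or None, field)`` with field one
    of ``waste``, ``econ`` or ``both``; ``year=None`` drops every year for
    that state.  ``seed`` is accepted for API symmetry with the generator
    (removal itself is deterministic).
    """
    known = {w.state for w in panel.waste} | {e.state for e in panel.econ}
    waste_keys, econ_keys = set(), set()
    for state, year, which in missing:
        if state not in known:
            raise ConfigurationError(f"unknown state {state!r}")
        if which not in ("waste", "econ", "both"):
            raise ConfigurationError(f"unknown field {which!r}")
        w_years = [w.year for w in panel.waste if w.state == state]
        e_years = [e.year for e in panel.econ if e.state == state]
        years_w = w_years if year is None else [year]
        years_e = e_years if year is None else [year]
        if which in ("waste", "both"):
            waste_keys.update((state, y) for y in years_w)
        if which in ("econ", "both"):
            econ_keys.update((state, y) for y in years_e)
    from .inventory_io import drop_records

    return drop_records(panel, waste_keys, econ_keys)


def write_panel(panel: InventoryPanel, truth: GroundTruth | None, out_dir) -> None:
    """Write waste.csv, econ.csv, population.csv (and truth.json) to a dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_waste_csv(panel.waste, out / "waste.csv")
    write_econ_csv(panel.econ, out / "econ.csv")
    write_population_csv(panel.population, out / "population.csv")
    if truth is not None:
        truth.to_json(out / "truth.json")
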