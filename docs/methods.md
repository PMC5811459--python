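# Methods

## Scope and model structure

`landgas` estimates annual methane emissions from landfilled municipal
solid waste over a state × year panel, using three estimators that share
one parameterisation and differ only in how they distribute a waste
cohort's methane potential over time:

* **DM (mass balance)** attributes a cohort's entire potential to its
  deposition year. It needs no history and is the method of choice when
  only annual generation totals exist; on a growing waste stream it
  overestimates current-year emissions relative to the cohort methods.
* **MTM (modified triangular)** spreads the potential over a triangular
  rate profile: onset one year after deposition, peak at year 6, zero at
  year 16. It suits regions whose waste characterisation is too coarse
  for full kinetics.
* **FOD (first-order decay)** releases potential exponentially at
  `k = ln 2 / t½`; the year at offset `T ≥ 1` gets
  `e^{−(T−1)k} − e^{−Tk}` of the lifetime yield, which telescopes to 1
  over an infinite horizon.

All three are tied together by the same lifetime normaliser: a
landfilled mass `a` can ever generate
`a · MCF · DOC · DOC_F · F · 16/12` Gg of CH₄. With the default
MTM generation potential `C₀ = lifetime_yield(1)/1.87`, all three
methods agree on lifetime yield, and both cohort methods converge to the
DM annual value on a constant deposition stream (exactly for MTM once
the 16-year window fills; within the exponential truncation for FOD).
This equivalence is the suite's principal cross-check, alongside a naive
double-loop superposition oracle.

## Parameters, units, defaults

| parameter | meaning | default | basis |
|---|---|---|---|
| `msw_f` | fraction of generated MSW landfilled | 0.7 | Indian average collection efficiency |
| `mcf` | methane correction factor | 0.6 | uncategorised/shallow sites class |
| `doc` | degradable organic carbon (g C/g waste) | 0.114 | national composition; per-state value from the composition model when fractions are supplied |
| `doc_f` | dissimilated DOC fraction | 0.77 | anaerobic decomposition at 35 °C |
| `f` | CH₄ fraction of landfill gas | 0.5 | standard landfill gas mixture |
| `r`, `ox` | recovery, oxidation | 0, 0 | no recovery infrastructure; default oxidation |
| `t_half` | FOD half-life (yr) | 7 | mid-range for mixed MSW in warm, wet climates |
| `coefficient` | MTM lifetime multiplier | 1.87 | the triangular method's standard lifetime relation |
| `c0` | MTM generation potential | `lifetime_yield(1)/1.87` | ties MTM to the mass balance; override for measured potentials |
| backcast | mode/growth/years | geometric / 0.05 / 25 | 5 %/yr ≈ the national MSW growth implied by 52125→139566 MT/day over 16 yr |

`mcf` and `t_half` are genuinely open choices in this setting — the
source inventories do not publish them — so they are configurable,
logged in every run manifest, and never silently assumed beyond these
documented defaults.

The recovery term `R` sits inside the printed mass-balance bracket
`(16/12 − R)`, which mixes a dimensionless ratio with a recovered
quantity. We implement it exactly as written (it is inert at the default
`R = 0`) and provide `strict_ipcc_recovery` to subtract recovered
methane in Gg from the final total instead. In the FOD sum the per-term
`− R` is applied only to cohorts that exist, so zero-mass backcast years
do not each subtract it.

The second exponential of the FOD release fraction is implemented as
`e^{−Tk}`; with a positive exponent the bracket would be negative for
every `T`, so the negative sign is the only reading consistent with a
telescoping, mass-conserving decay model.

## Numerical choices

* **Units**: MT/day → Gg/yr via × 365/1000; a fixed 365-day year
  (inventory convention, < 0.3 % effect). Inventory years are labelled
  by their starting calendar year ("1999–2000" → 1999).
* **MTM discretisation**: annual values are exact integrals of the
  piecewise-linear rate over `[offset, offset+1)` (trapezoids split at
  the lag/peak/end breakpoints), not midpoint samples — this makes the
  17-slice sum equal `1.87 · A_t · C₀` to floating-point accuracy and
  the conservation test exact rather than approximate.
* **Missing history**: cohort methods refuse to evaluate a series whose
  pre-observation history is unknown (`MissingHistoryError`), rather
  than zero-filling. A backcast (geometric, constant or zero) extends
  the series and marks it complete; `fod_emission` alternatively accepts
  an explicit `min_history` horizon, with truncation error below
  `e^{−min_history·k}` of lifetime yield.
* **Missing data**: states with absent records are dropped from national
  totals and logged, never imputed; state-years with GSDP printed as NA
  are dropped pairwise from the R² fit. A recorded zero is data, not
  missingness.
* **Percent reporting**: percent changes are ratio-as-percent
  (`100·E_b/E_a`) truncated to integers in reports — matching how such
  inventories print "245 %" for a ratio of 245.05 — with full precision
  retained internally. Decadal census growth is a delta percentage
  rounded to 2 decimals.
* **R² fit**: linear OLS of state CH₄ on state GSDP (statsmodels), per
  inventory year, matching how the association is usually presented; a
  log-log option exists but is off by default. R² requires ≥ 3 complete
  pairs and non-constant GSDP.

## Synthetic data generator

Real CPCB/CSO source tables are not machine-readable or public, so the
generator emulates their statistical shape with known ground truth:

* GSDP lognormal across states (`gsdp_log_mean = 11.9`,
  `gsdp_log_sd = 0.8`, i.e. median ≈ 1.5 × 10⁵ crore at the 1999 scale)
  growing 5 %/yr.
* Waste is a power law in GSDP with lognormal noise:
  `msw_tpd = scale · GSDP^elasticity · e^ε`, elasticity 1 by default.
  The scale is set so the base-year national total equals 52125 MT/day,
  the benchmark 1999–2000 national figure.
* Composition per state drawn uniformly inside the reported ranges
  (organics 40–60 % split 60/40 between garden and food waste, paper
  3–6 %, wood 0–2 %), inerts absorbing the remainder; the implied DOC
  lands in [0.07, 0.17].
* `noise_sd = 0.35` was calibrated once by Monte-Carlo (50 seeds,
  25 states) so that the mean base-year GSDP–CH₄ R² is ≈ 0.80, the
  strength of association real state inventories show; the realised
  mean in that calibration was 0.805 (sd 0.12).
* One root seed; per-state substreams are spawned deterministically, so
  panels are bit-reproducible.

What the generator does **not** emulate: real state identities and their
relative magnitudes, within-state composition trends over time,
reporting gaps and revisions between compendium editions, or any serial
correlation in the waste noise. Passing tests therefore demonstrate that
the estimators, aggregation and correlation machinery are correct and
internally consistent — not that any particular national total is
reproduced. Reproducing published national totals requires the
unpublished state-level tonnage and the compiler's exact MCF/t½/C₀
choices; with those CSVs in hand the same pipeline applies unchanged.

The noise-free proportionality check (R² exactly 1) applies the uniform
national DOC, since per-state composition DOC is itself a (deliberate)
source of scatter in the generated panels.

## Known limitations

* Tier-1 structure throughout: no waste-category-resolved FOD, no
  LandGEM-style site modelling, no CO₂/N₂O accounting, no gas-recovery
  economics.
* The backcast is a modelling convenience; where pre-observation
  deposition is known, supply it instead.
* The GSDP–CH₄ association is cross-sectional and descriptive — no
  causal or time-series claims.
* Problem sizes in the test suite (panels of 5–25 states × up to 17
  years, 100-series conservation sweeps, 500-year horizons) were chosen
  as the smallest sizes at which the asserted tolerances are meaningful;
  all are package defaults, and everything runs in seconds.
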