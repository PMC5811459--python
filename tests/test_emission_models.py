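import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from landgas import (
    C_TO_CH4,
    CompositionProfile,
    DecayParams,
    DepositionSeries,
    EmissionParams,
    MTMParams,
    MissingHistoryError,
    ValidationError,
    compute_doc,
    default_c0,
    dm_emission,
    fod_emission,
    fod_fraction,
    fod_rate_constant,
    lifetime_yield,
    mtm_emission,
    mtm_profile,
)
from landgas.errors import ConfigurationError

from conftest import random_deposit_series


# ---------------------------------------------------------------------------
# independent oracles: naive double-loop cohort superposition
# ---------------------------------------------------------------------------

def brute_mtm(deposits: dict[int, float], year: int, mtm: MTMParams) -> float:
    total = 0.0
    for t, a in deposits.items():
        profile = mtm_profile(a, mtm)
        offset = year - t
        if 0 <= offset < len(profile):
            total += profile[offset]
    return total


def brute_fod(
    deposits: dict[int, float], year: int, p: EmissionParams, k: float
) -> float:
    total = 0.0
    for t, a in deposits.items():
        offset = year - t
        if offset >= 1:
            frac = math.exp(-(offset - 1) * k) - math.exp(-offset * k)
            total += frac * a * p.mcf * p.doc * p.doc_f * p.f * C_TO_CH4
    return total


class TestDocModel:
    @pytest.mark.parametrize(
        "a,b,c,d,expected",
        [
            (0, 0, 0, 0, 0.0),
            (1, 0, 0, 0, 0.4),
            (0.05, 0.45, 0.15, 0.01, 0.1220),
        ],
    )
    def test_composition_weighting(self, a, b, c, d, expected):
        profile = CompositionProfile(paper_frac=a, green_frac=b, food_frac=c, wood_frac=d)
        assert compute_doc(profile) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValidationError):
            CompositionProfile(paper_frac=-0.1, green_frac=0, food_frac=0)


class TestMassBalance:
    def test_zero_waste(self, params):
        assert dm_emission(0.0, params) == 0.0

    def test_pure_stoichiometry(self):
        p = EmissionParams(msw_f=1, mcf=1, doc=1, doc_f=1, f=1, r=0, ox=0)
        assert dm_emission(100.0, p) == pytest.approx(400.0 / 3.0, rel=1e-12)

    def test_national_1999_tonnage(self, params):
        # 52125 MT/day -> 19025.625 Gg/yr through the default factor chain
        assert dm_emission(19025.625, params) == pytest.approx(467.62, abs=0.005)

    def test_recovery_term_bounded(self):
        # r is a [0,1] fraction as printed, so it can never exceed 16/12
        with pytest.raises(ValidationError):
            EmissionParams(r=1.5)

    @given(
        msw=st.floats(0, 1e5),
        alpha=st.floats(0, 10),
    )
    def test_homogeneity(self, msw, alpha):
        p = EmissionParams()
        assert dm_emission(alpha * msw, p) == pytest.approx(
            alpha * dm_emission(msw, p), rel=1e-9, abs=1e-9
        )

    def test_additive_over_states(self, params):
        parts = [100.0, 250.5, 7.25, 0.0]
        assert dm_emission(sum(parts), params) == pytest.approx(
            sum(dm_emission(x, params) for x in parts), rel=1e-9
        )

    @pytest.mark.parametrize("field", ["msw_f", "mcf", "doc", "doc_f", "f"])
    def test_monotone_increasing_factors(self, field):
        lo = dm_emission(100.0, EmissionParams(**{field: 0.3}))
        hi = dm_emission(100.0, EmissionParams(**{field: 0.6}))
        assert hi > lo

    @pytest.mark.parametrize("field", ["r", "ox"])
    def test_monotone_decreasing_factors(self, field):
        lo = dm_emission(100.0, EmissionParams(**{field: 0.0}))
        hi = dm_emission(100.0, EmissionParams(**{field: 0.5}))
        assert hi < lo

    def test_lifetime_yield_hand_product(self, params):
        assert lifetime_yield(100.0, params) == pytest.approx(3.5112, abs=5e-4)
        assert lifetime_yield(0.0, params) == 0.0
        assert lifetime_yield(1.0, EmissionParams(msw_f=1, mcf=1, doc=1, doc_f=1, f=1)) == pytest.approx(4.0 / 3.0)


class TestTriangularProfile:
    def test_zero_deposit_gives_zero_profile(self, unit_mtm):
        assert not mtm_profile(0.0, unit_mtm).any()

    def test_lifetime_sum_is_coefficient(self, unit_mtm):
        profile = mtm_profile(1.0, unit_mtm)
        assert profile.shape == (17,)
        assert profile.sum() == pytest.approx(1.87, rel=1e-9)

    def test_lag_and_tail_are_dark(self, unit_mtm):
        profile = mtm_profile(1.0, unit_mtm)
        assert profile[0] == 0.0  # release starts one year post-deposition
        assert profile[16] == 0.0  # rate hits zero at the 16th year

    def test_peak_rate_geometry(self, unit_mtm):
        # triangle area identity: peak instantaneous rate = 2G/(end - lag)
        g = 1.87
        height = 2 * g / (16 - 1)
        assert height == pytest.approx(0.24933, abs=5e-6)
        profile = mtm_profile(1.0, unit_mtm)
        # the largest one-year slice starts at the peak (offset 6) and
        # integrates the first year of the fall: mean of h and h*9/10
        assert profile.argmax() == 6
        assert profile[6] == pytest.approx(height * (1 + 9 / 10) / 2, rel=1e-9)

    def test_slices_match_numerical_integration(self, unit_mtm):
        lag, peak, end, g = 1.0, 6.0, 16.0, 1.87
        height = 2 * g / (end - lag)

        def rate(t):
            if t <= lag or t >= end:
                return 0.0
            if t <= peak:
                return height * (t - lag) / (peak - lag)
            return height * (end - t) / (end - peak)

        profile = mtm_profile(1.0, unit_mtm)
        ts = np.linspace(0, 17, 170001)
        vals = np.array([rate(t) for t in ts])
        for i in range(17):
            sel = (ts >= i) & (ts <= i + 1)
            numeric = np.trapezoid(vals[sel], ts[sel])
            assert profile[i] == pytest.approx(numeric, abs=1e-7)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            MTMParams(c0=1.0, lag_years=6, peak_year=6, end_year=16)

    def test_unresolved_c0_rejected(self):
        with pytest.raises(ConfigurationError):
            mtm_profile(1.0, MTMParams())


class TestTriangularSuperposition:
    def test_same_year_deposit_emits_nothing(self, unit_mtm):
        deposits = DepositionSeries.from_mapping({2000: 5.0})
        assert mtm_emission(deposits, 2000, unit_mtm) == 0.0

    def test_profile_is_exhausted_after_end_year(self, unit_mtm):
        deposits = DepositionSeries.from_mapping({2000: 5.0})
        assert mtm_emission(deposits, 2020, unit_mtm) == 0.0

    def test_steady_state_equals_lifetime_yield_rate(self, unit_mtm):
        a = 12.5
        deposits = DepositionSeries.from_mapping({y: a for y in range(2000, 2017)})
        assert mtm_emission(deposits, 2016, unit_mtm) == pytest.approx(
            1.87 * a * 1.0, rel=1e-9
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed, unit_mtm):
        start, masses = random_deposit_series(seed)
        deposits = DepositionSeries(start, masses)
        mapping = dict(zip(range(start, start + len(masses)), masses))
        for year in range(start, start + len(masses) + 20, 3):
            expected = brute_mtm(mapping, year, unit_mtm)
            got = mtm_emission(deposits, year, unit_mtm)
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_unknown_history_raises(self, unit_mtm):
        deposits = DepositionSeries(2000, np.array([5.0, 5.0]), history_complete=False)
        with pytest.raises(MissingHistoryError):
            mtm_emission(deposits, 2001, unit_mtm)

    def test_backcast_makes_history_usable(self, unit_mtm):
        observed = DepositionSeries(2000, np.array([5.0, 5.0]), history_complete=False)
        extended = observed.backcast(mode="geometric", growth=0.05, years=25)
        assert extended.history_complete
        assert mtm_emission(extended, 2001, unit_mtm) > 0

    @pytest.mark.parametrize("mode,expected_first", [
        ("geometric", 5.0 / 1.05**3), ("constant", 5.0), ("zero", 0.0),
    ])
    def test_backcast_modes(self, mode, expected_first):
        observed = DepositionSeries(2000, np.array([5.0]), history_complete=False)
        ext = observed.backcast(mode=mode, growth=0.05, years=3)
        assert ext.start_year == 1997
        assert ext.masses[0] == pytest.approx(expected_first, rel=1e-12)


class TestFirstOrderDecay:
    def test_rate_constant_identity(self):
        assert fod_rate_constant(math.log(2.0)) == pytest.approx(1.0, rel=1e-12)
        assert fod_rate_constant(7.0) == pytest.approx(0.09902, abs=5e-6)
        assert fod_rate_constant(1e9) == pytest.approx(0.0, abs=1e-8)
        with pytest.raises(ValidationError):
            fod_rate_constant(0.0)

    def test_decay_params_consistency_enforced(self):
        with pytest.raises(ValidationError):
            DecayParams(t_half=7.0, k=0.2)
        p = DecayParams(t_half=7.0)
        assert p.k == pytest.approx(math.log(2) / 7, rel=1e-12)
        assert DecayParams.from_k(0.1).t_half == pytest.approx(math.log(2) / 0.1)

    def test_first_year_fraction(self):
        k = 0.09902
        assert fod_fraction(1, k) == pytest.approx(1 - math.exp(-k), rel=1e-12)
        assert fod_fraction(1, k) == pytest.approx(0.09428, abs=5e-6)

    def test_fractions_telescope_to_one(self):
        k = 0.25
        total = fod_fraction(np.arange(1, 2001), k).sum()
        assert total == pytest.approx(1.0, rel=1e-12)

    @given(k=st.floats(1e-3, 2.0), t=st.integers(1, 200))
    def test_strictly_decreasing_in_offset(self, k, t):
        assert fod_fraction(t + 1, k) < fod_fraction(t, k)

    def test_offset_below_one_rejected(self):
        with pytest.raises(ValidationError):
            fod_fraction(0, 0.1)

    def test_no_deposits_no_emission(self, params, decay):
        deposits = DepositionSeries.from_mapping({2000: 0.0})
        assert fod_emission(deposits, 2001, params, decay) == 0.0

    def test_single_cohort_conserves_lifetime_yield(self, params, decay):
        deposits = DepositionSeries.from_mapping({2000: 1.0})
        total = sum(
            fod_emission(deposits, y, params, decay) for y in range(2001, 2501)
        )
        assert total == pytest.approx(lifetime_yield(1.0, params), rel=1e-6)

    def test_steady_state_approaches_mass_balance(self, params, decay):
        a = 20.0
        years = {y: a for y in range(1900, 2001)}
        deposits = DepositionSeries.from_mapping(years)
        annual = fod_emission(deposits, 2000, params, decay)
        assert annual == pytest.approx(lifetime_yield(a, params), rel=1e-3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed, params, decay):
        start, masses = random_deposit_series(seed)
        deposits = DepositionSeries(start, masses)
        mapping = dict(zip(range(start, start + len(masses)), masses))
        for year in range(start + 1, start + len(masses) + 15, 3):
            expected = brute_fod(mapping, year, params, decay.k)
            got = fod_emission(deposits, year, params, decay)
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_unknown_history_raises(self, params, decay):
        deposits = DepositionSeries(2000, np.array([5.0]), history_complete=False)
        with pytest.raises(MissingHistoryError):
            fod_emission(deposits, 2001, params, decay)
        # an explicit horizon waives the requirement once coverage is deep enough
        long = DepositionSeries(1950, np.full(60, 5.0), history_complete=False)
        assert fod_emission(long, 2005, params, decay, min_history=50) > 0


class TestMethodAgreement:
    def test_default_c0_ties_mtm_to_mass_balance(self, params):
        c0 = default_c0(params)
        mtm = MTMParams(c0=c0)
        a = 33.0
        deposits = DepositionSeries.from_mapping({y: a for y in range(2000, 2017)})
        steady = mtm_emission(deposits, 2016, mtm)
        assert steady == pytest.approx(lifetime_yield(a, params), rel=1e-6)
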