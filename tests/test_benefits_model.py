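import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialpool.benefits_model import (
    DiseaseEpiParams,
    averted_outcomes,
    build_trajectory,
    cases_averted,
    coverage_with_product,
    dalys_averted,
    deaths_averted,
    incidence_with_vaccine,
    treatment_costs_averted,
    yld_averted,
    yld_per_treated_case,
    yld_per_untreated_case,
    yll_averted,
    yll_per_death,
)


def make_params(**overrides):
    base = dict(
        disease="x",
        age_groups=("all",),
        incidence=np.array([1000.0]),
        deaths=np.array([100.0]),
        life_expectancy=np.array([30.0]),
        dw_untreated=np.array([0.2]),
        dw_treated=np.array([0.1]),
        dur_untreated=np.array([1.0]),
        dur_treated=np.array([0.5]),
        cfr_untreated=0.1,
        cfr_treated=0.05,
        coverage_baseline=0.2,
        cost_per_case=50.0,
    )
    base.update(overrides)
    return DiseaseEpiParams(**base)


class TestPerCaseRates:
    def test_yll_single_group(self):
        assert yll_per_death(make_params()) == 30.0

    def test_yll_two_groups(self):
        p = make_params(
            age_groups=("young", "old"),
            incidence=np.array([500.0, 500.0]),
            deaths=np.array([100.0, 300.0]),
            life_expectancy=np.array([40.0, 20.0]),
            dw_untreated=np.array([0.2, 0.2]),
            dw_treated=np.array([0.1, 0.1]),
            dur_untreated=np.array([1.0, 1.0]),
            dur_treated=np.array([0.5, 0.5]),
        )
        assert yll_per_death(p) == pytest.approx((100 * 40 + 300 * 20) / 400)
        assert yll_per_death(p) == 25.0

    def test_yll_zero_deaths_raises(self):
        p = make_params(deaths=np.array([0.0]))
        with pytest.raises(ValueError):
            yll_per_death(p)

    def test_yld_untreated_hand_value(self):
        p = make_params(dur_untreated=np.array([0.5]), dw_untreated=np.array([0.2]))
        assert yld_per_untreated_case(p) == pytest.approx(0.1)

    def test_yld_zero_weight(self):
        p = make_params(dw_untreated=np.array([0.0]), dw_treated=np.array([0.0]))
        assert yld_per_untreated_case(p) == 0.0

    def test_yld_zero_incidence_raises(self):
        p = make_params(incidence=np.array([0.0]))
        with pytest.raises(ValueError):
            yld_per_untreated_case(p)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_treated_yld_never_exceeds_untreated(self, seed):
        rng = np.random.default_rng(seed)
        dw_u = rng.uniform(0.05, 0.8, 3)
        dur_u = rng.uniform(0.2, 3.0, 3)
        p = make_params(
            age_groups=("a", "b", "c"),
            incidence=rng.uniform(10, 1e5, 3),
            deaths=rng.uniform(1, 1e3, 3),
            life_expectancy=rng.uniform(5, 70, 3),
            dw_untreated=dw_u,
            dw_treated=dw_u * rng.uniform(0, 1, 3),
            dur_untreated=dur_u,
            dur_treated=dur_u * rng.uniform(0, 1, 3),
        )
        assert yld_per_treated_case(p) <= yld_per_untreated_case(p) + 1e-12

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            make_params(cfr_treated=0.2)  # exceeds untreated 0.1
        with pytest.raises(ValueError):
            make_params(dw_treated=np.array([0.3]))  # exceeds untreated 0.2
        with pytest.raises(ValueError):
            make_params(incidence=np.array([-1.0]))


class TestIncidenceRamp:
    YEARS = pd.RangeIndex(2024, 2045, name="year")

    def test_stepwise_reduction_and_floor(self):
        ib = pd.Series(1000.0, index=self.YEARS)
        iv = incidence_with_vaccine(ib, market_entry_year=2024)
        expected_head = [900.0, 800.0, 700.0, 600.0, 500.0, 400.0, 300.0, 200.0, 100.0]
        assert list(iv.iloc[:9]) == expected_head
        # floor from year 9 of the ramp onwards
        assert (iv.iloc[8:] == 100.0).all()

    def test_before_entry_unchanged(self):
        ib = pd.Series(1000.0, index=self.YEARS)
        iv = incidence_with_vaccine(ib, market_entry_year=2030)
        assert (iv.loc[:2029] == 1000.0).all()

    def test_cap_binds_long_after_entry(self):
        ib = pd.Series(1000.0, index=pd.RangeIndex(2040, 2045))
        iv = incidence_with_vaccine(ib, market_entry_year=2020)
        assert (iv == 100.0).all()

    def test_no_entry(self):
        ib = pd.Series(1000.0, index=self.YEARS)
        assert incidence_with_vaccine(ib, None).equals(ib)

    def test_reduction_never_exceeds_90pct(self):
        ib = pd.Series(1000.0, index=pd.RangeIndex(2019, 2101))
        iv = incidence_with_vaccine(ib, market_entry_year=2019)
        assert (iv >= 0.1 * ib - 1e-12).all()


class TestCoverageRamp:
    def test_second_ramp_year(self):
        assert coverage_with_product(0.5, 2024, 2025) == pytest.approx(0.7)

    def test_high_baseline_never_reduced(self):
        assert coverage_with_product(0.95, 2024, 2030) == 0.95

    def test_cap_binds(self):
        assert coverage_with_product(0.2, 2024, 2033) == pytest.approx(0.9)

    def test_before_entry(self):
        assert coverage_with_product(0.5, 2024, 2023) == 0.5

    def test_invalid_baseline(self):
        with pytest.raises(ValueError):
            coverage_with_product(1.2, 2024, 2025)


class TestAvertedFormulas:
    def single_year_traj(self, ib, cb, iv, cd):
        idx = pd.RangeIndex(2025, 2026, name="year")
        return pd.DataFrame(
            {"IB": [ib], "IV": [iv], "CB": [cb], "CD": [cd]}, index=idx
        )

    def test_deaths_averted_hand_value(self):
        traj = self.single_year_traj(1000.0, 0.2, 900.0, 0.3)
        assert deaths_averted(traj, make_params()) == pytest.approx(13.5, abs=1e-9)

    def test_cases_averted_hand_value(self):
        idx = pd.RangeIndex(2025, 2028, name="year")
        traj = pd.DataFrame(
            {"IB": 1000.0, "IV": [900.0, 800.0, 700.0], "CB": 0.2, "CD": 0.2}, index=idx
        )
        assert cases_averted(traj) == pytest.approx(600.0, abs=1e-9)

    def test_treatment_costs_averted_hand_value(self):
        traj = self.single_year_traj(1000.0, 0.2, 900.0, 0.3)
        value = treatment_costs_averted(traj, make_params(), cases=pd.Series([100.0], index=traj.index))
        assert value == pytest.approx(1500.0, abs=1e-9)

    def test_no_product_all_zero(self):
        table = averted_outcomes(make_params(), None, None)
        assert (table.to_numpy() == 0.0).all()

    def test_zero_before_market_entry(self):
        table = averted_outcomes(make_params(), vaccine_entry_year=2027, treatment_entry_year=2028)
        assert (table.loc[:2026].to_numpy() == 0.0).all()
        assert (table.loc[2027:].abs().to_numpy().sum()) > 0

    def test_dalys_additivity_exact(self):
        table = averted_outcomes(make_params(), vaccine_entry_year=2024, treatment_entry_year=2026)
        assert (table["dalys"] == table["yll"] + table["yld"]).all()
        assert dalys_averted(2.0, 3.0) == 5.0

    def test_negative_input_rejected(self):
        traj = self.single_year_traj(-1.0, 0.2, 900.0, 0.3)
        with pytest.raises(ValueError):
            cases_averted(traj)

    def test_trajectory_invariants(self):
        traj = build_trajectory(make_params(), vaccine_entry_year=2022, treatment_entry_year=2023)
        assert (traj["IV"] <= traj["IB"] + 1e-12).all()
        assert (traj["IV"] >= 0.1 * traj["IB"] - 1e-12).all()
        assert (traj["CD"] >= traj["CB"] - 1e-12).all()
        assert (traj["CD"] <= 0.9 + 1e-12).all()

    @settings(max_examples=50, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        v_entry=st.one_of(st.none(), st.integers(2020, 2035)),
        t_entry=st.one_of(st.none(), st.integers(2020, 2035)),
    )
    def test_averted_series_nonnegative(self, seed, v_entry, t_entry):
        rng = np.random.default_rng(seed)
        cfr_u = rng.uniform(0.01, 0.5)
        dw_u = rng.uniform(0.05, 0.9, 1)
        dur_u = rng.uniform(0.1, 3.0, 1)
        p = make_params(
            incidence=rng.uniform(10, 1e6, 1),
            deaths=rng.uniform(1, 1e4, 1),
            cfr_untreated=cfr_u,
            cfr_treated=cfr_u * rng.uniform(0, 1),
            dw_untreated=dw_u,
            dw_treated=dw_u * rng.uniform(0, 1, 1),
            dur_untreated=dur_u,
            dur_treated=dur_u * rng.uniform(0, 1, 1),
            coverage_baseline=rng.uniform(0, 0.9),
            cost_per_case=rng.uniform(1, 500),
        )
        table = averted_outcomes(p, v_entry, t_entry)
        for col in ("cases", "deaths", "yll", "yld", "dalys"):
            assert (table[col] >= -1e-9).all(), col


def naive_averted(params, vaccine_entry, treatment_entry, start_year=2019, end_year=2035):
    """Brute-force oracle: plain year-by-year, age-group-by-age-group loops."""
    total_i = sum(params.incidence)
    total_d = sum(params.deaths)
    yll_rate = sum(d * l for d, l in zip(params.deaths, params.life_expectancy)) / total_d
    yld_u = sum(
        i * t * w for i, t, w in zip(params.incidence, params.dur_untreated, params.dw_untreated)
    ) / total_i
    yld_t = sum(
        i * t * w for i, t, w in zip(params.incidence, params.dur_treated, params.dw_treated)
    ) / total_i
    rows = {}
    for year in range(start_year, end_year + 1):
        ib = total_i
        if vaccine_entry is not None and year >= vaccine_entry:
            red = min(0.1 * (year - vaccine_entry + 1), 0.9)
        else:
            red = 0.0
        iv = ib * (1 - red)
        cb = params.coverage_baseline
        if treatment_entry is not None and year >= treatment_entry:
            cd = min(cb + 0.1 * (year - treatment_entry + 1), max(0.9, cb))
        else:
            cd = cb
        cases = ib - iv
        deaths = (
            ib * (1 - cb) * params.cfr_untreated + ib * cb * params.cfr_treated
        ) - (iv * (1 - cd) * params.cfr_untreated + iv * cd * params.cfr_treated)
        yll = deaths * yll_rate
        yld = (ib * (1 - cb) * yld_u + ib * cb * yld_t) - (
            iv * (1 - cd) * yld_u + iv * cd * yld_t
        )
        costs = cases * params.cost_per_case - (iv * cd - ib * cb) * params.cost_per_case
        rows[year] = (cases, deaths, yll, yld, yll + yld, costs)
    return rows


class TestOracleEquivalence:
    @settings(max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        v_entry=st.one_of(st.none(), st.integers(2020, 2034)),
        t_entry=st.one_of(st.none(), st.integers(2020, 2034)),
    )
    def test_matches_naive_loops(self, seed, v_entry, t_entry):
        rng = np.random.default_rng(seed)
        n = 4
        cfr_u = rng.uniform(0.01, 0.5)
        dw_u = rng.uniform(0.05, 0.9, n)
        dur_u = rng.uniform(0.1, 3.0, n)
        p = make_params(
            age_groups=tuple(f"g{i}" for i in range(n)),
            incidence=rng.uniform(10, 1e6, n),
            deaths=rng.uniform(1, 1e4, n),
            life_expectancy=rng.uniform(2, 80, n),
            cfr_untreated=cfr_u,
            cfr_treated=cfr_u * rng.uniform(0, 1),
            dw_untreated=dw_u,
            dw_treated=dw_u * rng.uniform(0, 1, n),
            dur_untreated=dur_u,
            dur_treated=dur_u * rng.uniform(0, 1, n),
            coverage_baseline=rng.uniform(0, 0.95),
            cost_per_case=rng.uniform(1, 500),
        )
        table = averted_outcomes(p, v_entry, t_entry)
        oracle = naive_averted(p, v_entry, t_entry)
        for year, expected in oracle.items():
            got = table.loc[year]
            for value, col in zip(expected, table.columns):
                assert got[col] == pytest.approx(value, abs=1e-9, rel=1e-9), (year, col)
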