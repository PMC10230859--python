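"""Health and economic benefits of product launches.

Given per-disease epidemiology and the market-entry years of new
products, this module computes yearly cases, deaths, years of life lost
(YLL), years lived with disability (YLD), DALYs and treatment costs
averted from market entry through 2035.

Product impact is modelled with two ramps:

* a new **vaccine** cuts base-case incidence by 10 percentage points of
  the base level in its first market year and a further 10 points each
  subsequent year, capped at a 90% reduction;
* a new **therapeutic or diagnostic** raises treatment coverage by 10
  percentage points per market year, capped at 90% coverage (baseline
  coverage already above the cap is left untouched).

Both ramps are additive in percentage points, which is the only reading
under which the stated 90% limits are attained exactly.  Averted
outcomes are the difference between the base-case burden (no launch) and
the with-product burden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DiseaseEpiParams",
    "yll_per_death",
    "yld_per_untreated_case",
    "yld_per_treated_case",
    "incidence_with_vaccine",
    "coverage_with_product",
    "coverage_series",
    "build_trajectory",
    "cases_averted",
    "deaths_averted",
    "yll_averted",
    "yld_averted",
    "dalys_averted",
    "treatment_costs_averted",
    "averted_outcomes",
    "AVERTED_COLUMNS",
]

MAX_INCIDENCE_REDUCTION = 0.9
MAX_COVERAGE = 0.9
RAMP_STEP = 0.1
BENEFITS_END_YEAR = 2035

AVERTED_COLUMNS = ("cases", "deaths", "yll", "yld", "dalys", "treatment_costs")


@dataclass(frozen=True)
class DiseaseEpiParams:
    """Epidemiological and cost parameters for one disease.

    Per-age-group arrays: annual incidence and deaths, residual life
    expectancy, disability weights and illness durations with/without
    treatment.  Scalars: case fatality with/without treatment, baseline
    treatment coverage, and treatment cost per case (2020 USD).
    """

    disease: str
    age_groups: Tuple[str, ...]
    incidence: np.ndarray
    deaths: np.ndarray
    life_expectancy: np.ndarray
    dw_untreated: np.ndarray
    dw_treated: np.ndarray
    dur_untreated: np.ndarray
    dur_treated: np.ndarray
    cfr_untreated: float
    cfr_treated: float
    coverage_baseline: float
    cost_per_case: float

    def __post_init__(self) -> None:
        n = len(self.age_groups)
        for name in (
            "incidence",
            "deaths",
            "life_expectancy",
            "dw_untreated",
            "dw_treated",
            "dur_untreated",
            "dur_treated",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per age group")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative values")
        for name in ("dw_untreated", "dw_treated"):
            if np.any(getattr(self, name) > 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(self.dw_treated > self.dw_untreated + 1e-12):
            raise ValueError("treated disability weight exceeds untreated")
        for name in ("cfr_untreated", "cfr_treated", "coverage_baseline"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cfr_treated > self.cfr_untreated + 1e-12:
            raise ValueError("treated case fatality exceeds untreated")
        if self.cost_per_case < 0:
            raise ValueError("cost_per_case must be >= 0")

    @property
    def total_incidence(self) -> float:
        return float(self.incidence.sum())

    @property
    def total_deaths(self) -> float:
        return float(self.deaths.sum())


def yll_per_death(params: DiseaseEpiParams) -> float:
    """Death-weighted mean residual life expectancy, in years per death."""
    total = params.total_deaths
    if total <= 0:
        raise ValueError("YLL per death is undefined with zero total deaths")
    return float((params.deaths * params.life_expectancy).sum() / total)


def _yld_per_case(params: DiseaseEpiParams, duration: np.ndarray, weight: np.ndarray) -> float:
    total = params.total_incidence
    if total <= 0:
        raise ValueError("YLD per case is undefined with zero total incidence")
    return float((params.incidence * duration * weight).sum() / total)


def yld_per_untreated_case(params: DiseaseEpiParams) -> float:
    """Incidence-weighted disability years per case without treatment."""
    return _yld_per_case(params, params.dur_untreated, params.dw_untreated)


def yld_per_treated_case(params: DiseaseEpiParams) -> float:
    """Incidence-weighted disability years per case with treatment."""
    return _yld_per_case(params, params.dur_treated, params.dw_treated)


def incidence_with_vaccine(
    ib_series: pd.Series, market_entry_year: Optional[int]
) -> pd.Series:
    """With-vaccine incidence under the additive reduction ramp.

    For years at or after market entry, base incidence is cut by
    ``0.1 * (years since entry + 1)``, capped at 90%.  Before entry (or
    with no entry at all) incidence equals the base series.
    """
    ib = ib_series.astype(float)
    if market_entry_year is None:
        return ib.copy()
    years = ib.index.to_numpy()
    # integer tenths keep the ramp exact: year 9 hits the 90% cap precisely
    steps = np.clip(years - market_entry_year + 1, 0, 9)
    return ib * ((10 - steps) / 10.0)


def coverage_with_product(
    cb: float, market_entry_year: Optional[int], year: int
) -> float:
    """Treatment coverage in ``year`` under the additive coverage ramp.

    Coverage climbs 10 percentage points per market year and is capped at
    90%; a baseline already above the cap is never reduced.
    """
    if not 0.0 <= cb <= 1.0:
        raise ValueError("baseline coverage must lie in [0, 1]")
    if market_entry_year is None or year < market_entry_year:
        return cb
    return min(cb + RAMP_STEP * (year - market_entry_year + 1), max(MAX_COVERAGE, cb))


def coverage_series(
    cb: float, market_entry_year: Optional[int], years: Iterable[int]
) -> pd.Series:
    years = list(years)
    return pd.Series(
        [coverage_with_product(cb, market_entry_year, y) for y in years],
        index=years,
        dtype=float,
    )


def build_trajectory(
    params: DiseaseEpiParams,
    vaccine_entry_year: Optional[int] = None,
    treatment_entry_year: Optional[int] = None,
    start_year: int = 2019,
    end_year: int = BENEFITS_END_YEAR,
) -> pd.DataFrame:
    """Yearly base-case vs with-product series for one disease.

    Returns a year-indexed frame with columns ``IB`` (base incidence,
    held at the input level for every projection year), ``IV``
    (with-vaccine incidence), ``CB``/``CD`` (base and with-product
    coverage) and ``DB``/``DT`` (base and with-product deaths derived
    from incidence, coverage and the two case-fatality rates).
    """
    if end_year < start_year:
        raise ValueError("end_year precedes start_year")
    years = pd.RangeIndex(start_year, end_year + 1, name="year")
    ib = pd.Series(params.total_incidence, index=years, dtype=float)
    iv = incidence_with_vaccine(ib, vaccine_entry_year)
    cb = pd.Series(params.coverage_baseline, index=years, dtype=float)
    cd = coverage_series(params.coverage_baseline, treatment_entry_year, years)
    cfr, cfrt = params.cfr_untreated, params.cfr_treated
    db = ib * (1.0 - cb) * cfr + ib * cb * cfrt
    dt = iv * (1.0 - cd) * cfr + iv * cd * cfrt
    return pd.DataFrame({"IB": ib, "IV": iv, "CB": cb, "CD": cd, "DB": db, "DT": dt})


def _check_trajectory(traj: pd.DataFrame) -> None:
    for col in ("IB", "IV", "CB", "CD"):
        if col not in traj.columns:
            raise ValueError(f"trajectory missing column {col!r}")
        if (traj[col] < 0).any():
            raise ValueError(f"trajectory column {col!r} contains negative values")


def cases_averted(traj: pd.DataFrame) -> float:
    """Total cases averted: sum over years of base minus with-vaccine incidence."""
    _check_trajectory(traj)
    return float((traj["IB"] - traj["IV"]).sum())


def _deaths_averted_series(traj: pd.DataFrame, params: DiseaseEpiParams) -> pd.Series:
    cfr, cfrt = params.cfr_untreated, params.cfr_treated
    base = traj["IB"] * (1.0 - traj["CB"]) * cfr + traj["IB"] * traj["CB"] * cfrt
    with_product = traj["IV"] * (1.0 - traj["CD"]) * cfr + traj["IV"] * traj["CD"] * cfrt
    return base - with_product


def deaths_averted(traj: pd.DataFrame, params: DiseaseEpiParams) -> float:
    """Total deaths averted via the coverage-weighted case-fatality mix."""
    _check_trajectory(traj)
    return float(_deaths_averted_series(traj, params).sum())


def yll_averted(traj: pd.DataFrame, params: DiseaseEpiParams) -> float:
    """Total years of life lost averted: deaths averted x YLL per death."""
    _check_trajectory(traj)
    return float(_deaths_averted_series(traj, params).sum() * yll_per_death(params))


def _yld_averted_series(traj: pd.DataFrame, params: DiseaseEpiParams) -> pd.Series:
    yld_u = yld_per_untreated_case(params)
    yld_t = yld_per_treated_case(params)
    base = traj["IB"] * (1.0 - traj["CB"]) * yld_u + traj["IB"] * traj["CB"] * yld_t
    with_product = traj["IV"] * (1.0 - traj["CD"]) * yld_u + traj["IV"] * traj["CD"] * yld_t
    return base - with_product


def yld_averted(traj: pd.DataFrame, params: DiseaseEpiParams) -> float:
    """Total years lived with disability averted."""
    _check_trajectory(traj)
    return float(_yld_averted_series(traj, params).sum())


def dalys_averted(yll, yld):
    """DALYs averted are exactly YLL plus YLD averted (scalar or series)."""
    return yll + yld


def treatment_costs_averted(
    traj: pd.DataFrame, params: DiseaseEpiParams, cases: Optional[pd.Series] = None
) -> float:
    """Total treatment costs averted, in the same USD units as
    ``params.cost_per_case``.

    Cases no longer occurring save their full per-case cost, offset by
    the change in the number of *treated* cases (with-product coverage
    applies to the reduced caseload).
    """
    _check_trajectory(traj)
    k = params.cost_per_case
    n = traj["IB"] - traj["IV"] if cases is None else cases
    extra_treated = traj["IV"] * traj["CD"] - traj["IB"] * traj["CB"]
    return float((n * k - extra_treated * k).sum())


def averted_outcomes(
    params: DiseaseEpiParams,
    vaccine_entry_year: Optional[int] = None,
    treatment_entry_year: Optional[int] = None,
    start_year: int = 2019,
    end_year: int = BENEFITS_END_YEAR,
) -> pd.DataFrame:
    """Yearly averted-outcome table for one disease.

    Columns: cases, deaths, yll, yld, dalys, treatment_costs.  All rows
    before the earliest market entry are exactly zero, and the whole
    table is exactly zero when no product enters at all.
    """
    years = pd.RangeIndex(start_year, end_year + 1, name="year")
    if vaccine_entry_year is None and treatment_entry_year is None:
        return pd.DataFrame(0.0, index=years, columns=list(AVERTED_COLUMNS))
    traj = build_trajectory(
        params, vaccine_entry_year, treatment_entry_year, start_year, end_year
    )
    cases = traj["IB"] - traj["IV"]
    deaths = _deaths_averted_series(traj, params)
    yll = deaths * yll_per_death(params)
    yld = _yld_averted_series(traj, params)
    extra_treated = traj["IV"] * traj["CD"] - traj["IB"] * traj["CB"]
    costs = cases * params.cost_per_case - extra_treated * params.cost_per_case
    out = pd.DataFrame(
        {
            "cases": cases,
            "deaths": deaths,
            "yll": yll,
            "yld": yld,
            "dalys": dalys_averted(yll, yld),
            "treatment_costs": costs,
        }
    )
    out.index = years
    return out
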