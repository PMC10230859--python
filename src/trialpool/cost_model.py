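"""Cost side of the evaluation.

Assembles yearly cost schedules, all in **2020 USD millions**: mechanism
operating costs (with a one-time start-up surcharge and, for the larger
design options, five years of health system strengthening investment),
phase III trial spend from the pipeline simulation, and vaccine
procurement priced per averted case scaled by vaccine efficacy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

import pandas as pd

__all__ = [
    "OPS_COST",
    "HSS_COST",
    "STARTUP_FRACTION",
    "MechanismCostParams",
    "VaccineParams",
    "mechanism_cost_schedule",
    "procurement_costs",
    "total_cost_schedule",
    "PERSPECTIVES",
]

#: Annual operating cost by design option, USD millions.
OPS_COST: Dict[int, float] = {1: 25.0, 2: 40.0, 3: 60.0}
#: Annual health system strengthening investment by option, USD millions.
HSS_COST: Dict[int, float] = {1: 0.0, 2: 100.0, 3: 250.0}
STARTUP_FRACTION = 0.45

PERSPECTIVES = ("societal", "altruistic")


@dataclass(frozen=True)
class MechanismCostParams:
    annual_ops: float  # USD millions per operating year
    hss_annual: float  # USD millions per year, first hss_years only
    startup_fraction: float = STARTUP_FRACTION
    ops_start: int = 2019
    ops_end: int = 2030
    hss_years: int = 5

    def __post_init__(self) -> None:
        if min(self.annual_ops, self.hss_annual, self.startup_fraction) < 0:
            raise ValueError("cost parameters must be >= 0")
        if self.ops_end < self.ops_start:
            raise ValueError("operating window ends before it starts")

    @classmethod
    def for_option(cls, option_id: int, **overrides) -> "MechanismCostParams":
        if option_id not in OPS_COST:
            raise ValueError(f"unknown design option: {option_id!r}")
        return cls(
            annual_ops=OPS_COST[option_id], hss_annual=HSS_COST[option_id], **overrides
        )


@dataclass(frozen=True)
class VaccineParams:
    efficacy: float = 0.75
    price_per_dose: float = 10.0  # USD

    def __post_init__(self) -> None:
        if not 0.0 < self.efficacy <= 1.0:
            raise ValueError("efficacy must lie in (0, 1]")
        if self.price_per_dose < 0:
            raise ValueError("price_per_dose must be >= 0")


def mechanism_cost_schedule(params: MechanismCostParams) -> pd.Series:
    """Yearly mechanism costs, USD millions.

    Start-up (45% of annual operations by default) is booked in the first
    operating year; operations recur every operating year; health system
    strengthening runs for the first ``hss_years`` years only.
    """
    years = range(params.ops_start, params.ops_end + 1)
    sched = pd.Series(params.annual_ops, index=pd.Index(years, name="year"), dtype=float)
    sched.iloc[0] += params.startup_fraction * params.annual_ops
    hss_end = params.ops_start + params.hss_years
    sched.loc[sched.index < hss_end] += params.hss_annual
    return sched


def procurement_costs(
    cases_averted_by_year: pd.Series, params: VaccineParams = VaccineParams()
) -> pd.Series:
    """Vaccine procurement, USD millions per year.

    Doses are averted cases divided by efficacy, priced per dose.
    Scales linearly in the price and inversely in efficacy.
    """
    cases = cases_averted_by_year.astype(float)
    return cases / params.efficacy * params.price_per_dose / 1e6


def total_cost_schedule(
    perspective: str,
    mech_costs: pd.Series,
    phase3_spend: pd.Series,
    procurement: pd.Series,
    include_mechanism_in_altruistic: bool = True,
) -> pd.Series:
    """Combine cost components for one analysis perspective (USD millions).

    The societal perspective sums everything; the altruistic-investor
    perspective drops vaccine procurement (assumed borne by countries or
    pooled-procurement entities).  ``include_mechanism_in_altruistic``
    keeps or drops operating/start-up/HSS costs from the altruistic
    total -- published headline figures are ambiguous on this point, so
    both variants are available.
    """
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective: {perspective!r}")
    parts = [phase3_spend]
    if perspective == "societal":
        parts += [mech_costs, procurement]
    elif include_mechanism_in_altruistic:
        parts.append(mech_costs)
    total = pd.concat(parts, axis=1).fillna(0.0).sum(axis=1)
    total.index.name = "year"
    return total.sort_index()
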