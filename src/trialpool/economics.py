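"""Discounting and headline economics.

Net costs, net benefits (treatment costs averted), benefit-cost ratios,
cost per DALY / per death averted, and incremental cost-effectiveness
ratios between design options.  Everything is discounted to a common
base year at a 3% annual rate by default; health outcomes are discounted
alongside costs, with a toggle to leave them undiscounted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Union

import pandas as pd

__all__ = [
    "DISCOUNT_RATE",
    "BASE_YEAR",
    "EconomicSummary",
    "discount",
    "bcr",
    "cost_per_outcome",
    "icer",
    "summarize",
]

DISCOUNT_RATE = 0.03
BASE_YEAR = 2019

Series = Union[pd.Series, Mapping[int, float]]


def discount(yearly_series: Series, rate: float = DISCOUNT_RATE, base_year: int = BASE_YEAR) -> float:
    """Present value of a year-indexed series at ``base_year``.

    ``sum(value_x / (1 + rate) ** (x - base_year))``; a zero rate gives
    the plain sum.
    """
    if rate <= -1.0:
        raise ValueError("rate must exceed -1")
    if not isinstance(yearly_series, pd.Series):
        yearly_series = pd.Series(dict(yearly_series), dtype=float)
    if yearly_series.empty:
        return 0.0
    years = yearly_series.index.to_numpy(dtype=float)
    return float((yearly_series.to_numpy(dtype=float) / (1.0 + rate) ** (years - base_year)).sum())


def bcr(net_benefit: float, net_cost: float) -> float:
    """Benefit-cost ratio: total monetary benefits over total monetary costs."""
    if net_cost <= 0:
        raise ValueError("BCR requires a positive net cost")
    return net_benefit / net_cost


def cost_per_outcome(net_cost: float, outcomes: float) -> float:
    """Net cost per unit health outcome (DALY or death averted)."""
    if outcomes <= 0:
        raise ValueError("cost per outcome requires positive outcomes")
    return net_cost / outcomes


@dataclass(frozen=True)
class EconomicSummary:
    """Headline economics of one design option under one perspective.

    ``net_cost`` and ``net_benefit`` are present-value 2020 USD;
    ``net_benefit`` is treatment costs averted, the only monetary
    benefit counted.  The ratio fields are derived from the other fields
    and stay self-consistent by construction.
    """

    option_id: int
    perspective: str
    net_cost: float
    net_benefit: float
    dalys_averted: float
    deaths_averted: float
    discount_rate: float = DISCOUNT_RATE
    cost_per_daly: float = field(init=False)
    cost_per_death: float = field(init=False)
    bcr: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cost_per_daly", cost_per_outcome(self.net_cost, self.dalys_averted))
        object.__setattr__(self, "cost_per_death", cost_per_outcome(self.net_cost, self.deaths_averted))
        object.__setattr__(self, "bcr", bcr(self.net_benefit, self.net_cost))

    def to_dict(self) -> dict:
        return {
            "option_id": self.option_id,
            "perspective": self.perspective,
            "net_cost": self.net_cost,
            "net_benefit": self.net_benefit,
            "dalys_averted": self.dalys_averted,
            "deaths_averted": self.deaths_averted,
            "cost_per_daly": self.cost_per_daly,
            "cost_per_death": self.cost_per_death,
            "bcr": self.bcr,
            "discount_rate": self.discount_rate,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EconomicSummary":
        return cls(
            option_id=int(d["option_id"]),
            perspective=str(d["perspective"]),
            net_cost=float(d["net_cost"]),
            net_benefit=float(d["net_benefit"]),
            dalys_averted=float(d["dalys_averted"]),
            deaths_averted=float(d["deaths_averted"]),
            discount_rate=float(d.get("discount_rate", DISCOUNT_RATE)),
        )


def icer(option_hi: EconomicSummary, option_lo: EconomicSummary) -> float:
    """Incremental cost-effectiveness ratio between two options, USD/DALY.

    Difference in net costs over difference in DALYs averted.  Raises on
    equal effectiveness; warns when the higher-cost comparison is
    dominated (cheaper *and* more effective option exists).
    """
    d_daly = option_hi.dalys_averted - option_lo.dalys_averted
    if d_daly == 0:
        raise ValueError("ICER undefined: options avert identical DALYs")
    d_cost = option_hi.net_cost - option_lo.net_cost
    if (d_cost < 0) == (d_daly > 0):
        warnings.warn("one option dominates: negative ICER", stacklevel=2)
    return d_cost / d_daly


def summarize(
    option_id: int,
    perspective: str,
    cost_schedule_musd: pd.Series,
    treatment_costs_averted_usd: Series,
    dalys_by_year: Series,
    deaths_by_year: Series,
    rate: float = DISCOUNT_RATE,
    base_year: int = BASE_YEAR,
    discount_outcomes: bool = True,
) -> EconomicSummary:
    """Discount all streams and assemble an :class:`EconomicSummary`.

    ``cost_schedule_musd`` is in USD millions (converted to USD here);
    the benefit stream is in plain USD.
    """
    outcome_rate = rate if discount_outcomes else 0.0
    return EconomicSummary(
        option_id=option_id,
        perspective=perspective,
        net_cost=discount(cost_schedule_musd, rate, base_year) * 1e6,
        net_benefit=discount(treatment_costs_averted_usd, rate, base_year),
        dalys_averted=discount(dalys_by_year, outcome_rate, base_year),
        deaths_averted=discount(deaths_by_year, outcome_rate, base_year),
        discount_rate=rate,
    )
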