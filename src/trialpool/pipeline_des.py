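"""Discrete-event simulation of a product R&D pipeline.

Product candidates move through up to four trial phases (preclinical,
phase I, phase II, phase III) over a 2019--2030 horizon.  Each candidate
carries its archetype's per-phase cost (2020 USD millions), duration
(years) and probability of success.  On completing a phase, a Bernoulli
draw decides whether the candidate advances; survivors of their final
active phase are recorded as launches and enter the market one calendar
year later.  Phase servers have unlimited capacity, so candidates never
queue: trajectories are independent given their random draws.

The module ships a built-in base parameter table for ten product
archetypes (simple/complex vaccines, new chemical entities, repurposed
drugs, biologics, and two diagnostic development tracks), plus the two
scenario transforms used throughout the analysis:

* :func:`apply_sensitivity` -- inflate phase III costs and all phase
  durations by given factors.
* :func:`apply_efficiency` -- adaptive-trial efficiencies: a duration cut
  of up to 6 months per phase and a phase III cost cut of up to 15%.

Some archetypes have phases with no data at all ("NA" cells); those
phases are skipped outright, so e.g. a simple repurposed drug starts life
in phase II and an assay-development diagnostic launches on completing
phase II.  A phase with a cost or success probability but no duration is
run as an instantaneous stage; a phase with a duration but no cost and no
probability is run as a free, certain-success stage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "ARCHETYPES",
    "PRODUCT_CLASS",
    "PhaseCell",
    "PhaseParams",
    "base_phase_params",
    "active_phases",
    "expected_launch_probability",
    "apply_sensitivity",
    "apply_efficiency",
    "Candidate",
    "LaunchRecord",
    "SimConfig",
    "SimulationResult",
    "MonteCarloSummary",
    "replenish",
    "simulate_once",
    "run_monte_carlo",
]

PHASES: Tuple[str, ...] = ("preclinical", "phase1", "phase2", "phase3")

ARCHETYPES: Tuple[str, ...] = (
    "vaccine-simple",
    "vaccine-complex",
    "nce-simple",
    "nce-complex",
    "repurposed-simple",
    "repurposed-complex",
    "biologic-simple",
    "biologic-complex",
    "dx-assay",
    "dx-platform",
)

#: Broad product class of each archetype, used for benefit attribution
#: (vaccines shift incidence; therapeutics and diagnostics shift coverage).
PRODUCT_CLASS: Dict[str, str] = {
    "vaccine-simple": "vaccine",
    "vaccine-complex": "vaccine",
    "nce-simple": "therapeutic",
    "nce-complex": "therapeutic",
    "repurposed-simple": "therapeutic",
    "repurposed-complex": "therapeutic",
    "biologic-simple": "therapeutic",
    "biologic-complex": "therapeutic",
    "dx-assay": "diagnostic",
    "dx-platform": "diagnostic",
}


@dataclass(frozen=True)
class PhaseCell:
    """Parameters of one archetype x phase cell.

    ``None`` marks an absent value.  A cell with all three values absent
    is *inactive*: the phase does not exist for that archetype.
    """

    cost: Optional[float] = None  # 2020 USD millions
    length: Optional[float] = None  # years
    p_success: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cost is not None and self.cost < 0:
            raise ValueError(f"negative phase cost: {self.cost}")
        if self.length is not None and self.length < 0:
            raise ValueError(f"negative phase length: {self.length}")
        if self.p_success is not None and not 0.0 <= self.p_success <= 1.0:
            raise ValueError(f"success probability outside [0, 1]: {self.p_success}")

    @property
    def active(self) -> bool:
        return not (self.cost is None and self.length is None and self.p_success is None)


#: Mapping from (archetype, phase) to :class:`PhaseCell`.
PhaseParams = Dict[Tuple[str, str], PhaseCell]

# Base table, one tuple entry per archetype in ARCHETYPES order.
_BASE_COST = {
    "preclinical": (6.66, 16.63, 5.00, 10.00, None, 5.00, 10.79, 21.59, 3.00, None),
    "phase1": (2.25, 2.47, 2.21, 7.44, None, 2.21, 2.41, 7.65, 2.00, 100.00),
    "phase2": (13.22, 13.88, 5.81, 6.39, 5.81, 5.81, 7.53, 8.28, 3.50, 3.50),
    "phase3": (111.10, 133.32, 32.82, 36.10, 17.61, 17.61, 54.12, 59.53, None, None),
}
_BASE_LENGTH = {
    "preclinical": (3.36, 3.33, 2.49, 2.87, None, None, 3.29, 3.24, 1.00, None),
    "phase1": (1.57, 1.97, 1.80, 1.93, None, None, 1.62, 1.49, 1.25, None),
    "phase2": (2.23, 3.71, 3.38, 3.51, 2.14, 2.14, 2.47, 4.16, 1.33, 2.50),
    "phase3": (2.33, 3.50, 3.18, 2.80, 2.14, 2.14, 2.10, 3.38, None, 2.00),
}
_BASE_PSUCCESS = {
    "preclinical": (0.410, 0.410, 0.650, 0.550, None, 0.750, 0.750, 0.770, 0.500, None),
    "phase1": (0.684, 0.500, 0.597, 0.572, None, 0.585, 0.662, 0.696, 1.000, 0.750),
    "phase2": (0.459, 0.216, 0.388, 0.197, 0.457, 0.457, 0.443, 0.322, 1.000, 1.000),
    "phase3": (0.708, 0.636, 0.691, 0.403, 0.681, 0.681, 0.709, 0.625, None, None),
}


def base_phase_params() -> PhaseParams:
    """Return a fresh copy of the base archetype x phase parameter table."""
    params: PhaseParams = {}
    for phase in PHASES:
        for j, arch in enumerate(ARCHETYPES):
            params[(arch, phase)] = PhaseCell(
                cost=_BASE_COST[phase][j],
                length=_BASE_LENGTH[phase][j],
                p_success=_BASE_PSUCCESS[phase][j],
            )
    return params


def active_phases(
    archetype: str, params: Mapping[Tuple[str, str], PhaseCell], from_phase: Optional[str] = None
) -> Tuple[str, ...]:
    """Active phases of ``archetype`` in order, optionally starting at ``from_phase``.

    Raises ``ValueError`` if ``from_phase`` is not an active phase of the
    archetype.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype: {archetype!r}")
    actives = tuple(ph for ph in PHASES if params[(archetype, ph)].active)
    if from_phase is None:
        return actives
    if from_phase not in actives:
        raise ValueError(f"{archetype} has no active phase {from_phase!r}")
    return actives[actives.index(from_phase):]


def expected_launch_probability(
    archetype: str, starting_phase: str, params: Mapping[Tuple[str, str], PhaseCell]
) -> float:
    """Analytic launch probability: product of success probabilities from
    ``starting_phase`` through the archetype's last active phase.

    Cells with an absent probability count as certain success.  This is
    the closed-form oracle used to check Monte Carlo output when the
    horizon is non-binding.
    """
    prob = 1.0
    for phase in active_phases(archetype, params, from_phase=starting_phase):
        p = params[(archetype, phase)].p_success
        prob *= 1.0 if p is None else p
    return prob


def _scaled(value: Optional[float], factor: float) -> Optional[float]:
    return None if value is None else value * factor


def apply_sensitivity(
    params: Mapping[Tuple[str, str], PhaseCell], cost_factor: float, length_factor: float
) -> PhaseParams:
    """Inflate phase III costs by ``(1 + cost_factor)`` and every phase
    duration by ``(1 + length_factor)``.

    Success probabilities and absent cells are untouched.  Costs of
    phases other than phase III are untouched: only late-stage trial
    costs are stressed.
    """
    if cost_factor < 0 or length_factor < 0:
        raise ValueError("sensitivity factors must be >= 0")
    out: PhaseParams = {}
    for (arch, phase), cell in params.items():
        cost = _scaled(cell.cost, 1.0 + cost_factor) if phase == "phase3" else cell.cost
        out[(arch, phase)] = PhaseCell(
            cost=cost,
            length=_scaled(cell.length, 1.0 + length_factor),
            p_success=cell.p_success,
        )
    return out


def apply_efficiency(
    params: Mapping[Tuple[str, str], PhaseCell],
    adaptive_share: float,
    min_length: float = 0.01,
) -> PhaseParams:
    """Apply adaptive-trial efficiencies for a given share of trials.

    At ``adaptive_share=1.0`` every phase duration drops by 6 months and
    phase III costs by 15%; at ``0.5`` the cuts are 3 months and 7.5%.
    Other shares in [0, 1] interpolate linearly (flagged with a warning,
    since only the two anchor scenarios are empirically grounded).
    Durations are floored at ``min_length`` years.
    """
    if not 0.0 <= adaptive_share <= 1.0:
        raise ValueError("adaptive_share must lie in [0, 1]")
    if adaptive_share not in (0.0, 0.5, 1.0):
        warnings.warn(
            "adaptive_share outside the anchored scenarios {0.5, 1.0}; "
            "interpolating linearly",
            stacklevel=2,
        )
    length_cut = 0.5 * adaptive_share  # years
    cost_factor = 1.0 - 0.15 * adaptive_share
    out: PhaseParams = {}
    for (arch, phase), cell in params.items():
        length = cell.length
        if length is not None:
            length = max(length - length_cut, min_length)
        cost = _scaled(cell.cost, cost_factor) if phase == "phase3" else cell.cost
        out[(arch, phase)] = PhaseCell(cost=cost, length=length, p_success=cell.p_success)
    return out


@dataclass(frozen=True)
class Candidate:
    """One pipeline entity.

    ``entry_time`` is in decimal years since the simulation start year
    (0.0 = start of 2019 under the default horizon).
    """

    id: str
    archetype: str
    disease: str
    phase_at_entry: str
    entry_time: float = 0.0


@dataclass(frozen=True)
class LaunchRecord:
    candidate_id: str
    disease: str
    archetype: str
    launch_time: float  # decimal years since start year
    launch_year: int
    market_entry_year: int  # launch_year + 1


@dataclass(frozen=True)
class SimConfig:
    """Horizon and replenishment settings for one simulation scenario."""

    start_year: int = 2019
    end_year: int = 2030
    archetypes: Tuple[str, ...] = ()
    diseases: Tuple[str, ...] = ()
    replenishment: bool = True
    replenishment_rate: int = 10
    replenishment_years: int = 5

    @property
    def span(self) -> float:
        """Horizon length in years (end year inclusive)."""
        return float(self.end_year - self.start_year + 1)


@dataclass
class SimulationResult:
    launches: List[LaunchRecord]
    phase3_spend_by_year: Dict[int, float]  # calendar year -> USD millions
    phase3_entrants: int
    # (candidate_id, archetype, phase III start time) per entrant
    phase3_entries: List[Tuple[str, str, float]] = field(default_factory=list)

    @property
    def total_phase3_spend(self) -> float:
        return float(sum(self.phase3_spend_by_year.values()))


@dataclass
class MonteCarloSummary:
    """Across-run aggregates of repeated simulations."""

    launches_mean: pd.DataFrame  # index: archetype, columns: launch year
    launches_sd: pd.DataFrame
    spend_mean: pd.Series  # calendar year -> mean USD millions
    total_launches_mean: float
    total_launches_sd: float
    phase3_entrants_mean: float
    n_runs: int
    runs: Optional[List[SimulationResult]] = None


def replenish(
    config: SimConfig,
    year: int,
    phase_params: Optional[Mapping[Tuple[str, str], PhaseCell]] = None,
) -> List[Candidate]:
    """New entrants injected at the start of ``year``.

    For each of the first ``replenishment_years`` years of the horizon,
    ``replenishment_rate`` fresh candidates per archetype enter at the
    earliest phase the archetype runs (preclinical for most archetypes).
    Diseases are assigned round-robin over the configured disease list so
    the injection is deterministic.
    """
    if not config.replenishment:
        return []
    if not config.start_year <= year < config.start_year + config.replenishment_years:
        return []
    if phase_params is None:
        phase_params = base_phase_params()
    diseases = config.diseases or ("unspecified",)
    out: List[Candidate] = []
    for arch in config.archetypes:
        entry_phase = active_phases(arch, phase_params)[0]
        for k in range(config.replenishment_rate):
            out.append(
                Candidate(
                    id=f"repl-{year}-{arch}-{k}",
                    archetype=arch,
                    disease=diseases[k % len(diseases)],
                    phase_at_entry=entry_phase,
                    entry_time=float(year - config.start_year),
                )
            )
    return out


def _book_spend(
    spend: Dict[int, float], cost: float, t0: float, length: float, start_year: int
) -> None:
    """Spread ``cost`` uniformly over the calendar years [t0, t0+length)."""
    if cost <= 0.0:
        return
    if length <= 0.0:
        year = start_year + int(math.floor(t0))
        spend[year] = spend.get(year, 0.0) + cost
        return
    t1 = t0 + length
    for y in range(int(math.floor(t0)), int(math.ceil(t1))):
        overlap = min(t1, y + 1.0) - max(t0, float(y))
        if overlap > 0.0:
            year = start_year + y
            spend[year] = spend.get(year, 0.0) + cost * overlap / length

def simulate_once(
    candidates: Sequence[Candidate],
    phase_params: Mapping[Tuple[str, str], PhaseCell],
    config: SimConfig,
    seed: int,
) -> SimulationResult:
    """Run one pipeline trajectory for every candidate.

    Each candidate advances through its archetype's active phases from its
    entry phase.  Phase success is decided at phase *end* (a failed
    phase III still books its full cost), with one uniform draw per
    candidate per phase taken from a pre-drawn matrix so that results are
    deterministic given ``seed`` and, crucially, invariant to duration
    changes: lengthening phases can only push launches past the horizon,
    never create new ones.

    A launch is recorded when a candidate succeeds in its last active
    phase before the horizon ends.  Phase III spend is booked (spread
    over the calendar years the phase spans) for every candidate whose
    phase III starts inside the horizon, successful or not.
    """
    if config.end_year < config.start_year:
        raise ValueError("horizon end precedes horizon start")
    all_cands: List[Candidate] = list(candidates)
    if config.replenishment:
        for year in range(config.start_year, config.end_year + 1):
            all_cands.extend(replenish(config, year, phase_params))
    for cand in all_cands:
        # raises if the entry phase is not active for the archetype
        active_phases(cand.archetype, phase_params, from_phase=cand.phase_at_entry)

    rng = np.random.default_rng(seed)
    draws = rng.random((len(all_cands), len(PHASES)))

    span = config.span
    launches: List[LaunchRecord] = []
    spend: Dict[int, float] = {}
    entries: List[Tuple[str, str, float]] = []

    for i, cand in enumerate(all_cands):
        t = cand.entry_time
        ok = True
        for phase in active_phases(cand.archetype, phase_params, from_phase=cand.phase_at_entry):
            cell = phase_params[(cand.archetype, phase)]
            length = cell.length or 0.0
            if phase == "phase3" and t < span:
                entries.append((cand.id, cand.archetype, t))
                _book_spend(spend, cell.cost or 0.0, t, length, config.start_year)
            t += length
            p = 1.0 if cell.p_success is None else cell.p_success
            if draws[i, PHASES.index(phase)] >= p:
                ok = False
                break
        if ok and t < span:
            launch_year = config.start_year + int(math.floor(t))
            launches.append(
                LaunchRecord(
                    candidate_id=cand.id,
                    disease=cand.disease,
                    archetype=cand.archetype,
                    launch_time=t,
                    launch_year=launch_year,
                    market_entry_year=launch_year + 1,
                )
            )

    return SimulationResult(
        launches=launches,
        phase3_spend_by_year=spend,
        phase3_entrants=len(entries),
        phase3_entries=entries,
    )


def run_seed(base_seed: int, run_index: int) -> int:
    """Seed for run ``run_index``: ``base_seed + run_index``.

    Kept as a named function so a single run from a Monte Carlo batch can
    be reproduced in isolation.
    """
    return base_seed + run_index


def summarize_runs(
    results: Sequence[SimulationResult],
    config: SimConfig,
    archetypes: Optional[Iterable[str]] = None,
    keep_runs: bool = False,
) -> MonteCarloSummary:
    """Aggregate per-run results into mean/SD launch and spend tables."""
    if not results:
        raise ValueError("no simulation results to summarize")
    arch_list = sorted(set(archetypes or []) | {lr.archetype for r in results for lr in r.launches})
    if not arch_list:
        arch_list = list(ARCHETYPES)
    years = list(range(config.start_year, config.end_year + 1))
    counts = np.zeros((len(results), len(arch_list), len(years)))
    arch_index = {a: j for j, a in enumerate(arch_list)}
    year_index = {y: k for k, y in enumerate(years)}
    spend_years: set = set()
    for r in results:
        spend_years.update(r.phase3_spend_by_year)
    spend_years_sorted = sorted(spend_years) or years
    spend = np.zeros((len(results), len(spend_years_sorted)))
    for i, r in enumerate(results):
        for lr in r.launches:
            counts[i, arch_index[lr.archetype], year_index[lr.launch_year]] += 1
        for k, y in enumerate(spend_years_sorted):
            spend[i, k] = r.phase3_spend_by_year.get(y, 0.0)
    totals = counts.sum(axis=(1, 2))
    return MonteCarloSummary(
        launches_mean=pd.DataFrame(counts.mean(axis=0), index=arch_list, columns=years),
        launches_sd=pd.DataFrame(counts.std(axis=0, ddof=0), index=arch_list, columns=years),
        spend_mean=pd.Series(
            spend.mean(axis=0), index=pd.Index(spend_years_sorted, name="year")
        ),
        total_launches_mean=float(totals.mean()),
        total_launches_sd=float(totals.std(ddof=0)),
        phase3_entrants_mean=float(np.mean([r.phase3_entrants for r in results])),
        n_runs=len(results),
        runs=list(results) if keep_runs else None,
    )


def run_monte_carlo(
    candidates: Sequence[Candidate],
    phase_params: Mapping[Tuple[str, str], PhaseCell],
    config: SimConfig,
    n_runs: int,
    base_seed: int,
    keep_runs: bool = False,
) -> MonteCarloSummary:
    """Repeat :func:`simulate_once` ``n_runs`` times and aggregate.

    Per-run seeds derive from ``base_seed`` via :func:`run_seed`.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    results = [
        simulate_once(candidates, phase_params, config, run_seed(base_seed, r))
        for r in range(n_runs)
    ]
    archetypes = set(config.archetypes) | {c.archetype for c in candidates}
    return summarize_runs(results, config, archetypes, keep_runs=keep_runs)
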