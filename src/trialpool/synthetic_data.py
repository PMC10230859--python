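"""Synthetic portfolios and disease parameter tables.

The published analysis rests on two inputs that live in a supplementary
appendix rather than the main text: the 2019 candidate portfolio for each
funding design option, and per-disease epidemiological/economic
parameters.  This module generates stand-ins with the documented
structure -- the printed marginal counts are honoured exactly, and the
unprinted cells are filled by seeded multinomial draws -- so that every
downstream stage is testable end to end.

Design options:

1. vaccines only, four diseases, 116 candidates split 23/63/30 across
   preclinical / phase I / phase II;
2. all product classes, nine diseases, 327 candidates with disease
   counts 272 (HIV+TB+malaria) / 16 / 14 / 9 / 9 / 5 / 2;
3. all product classes, the full disease list, 506 candidates with
   pinned shares for malaria/TB/HIV/Ebola and an 11.5% joint share for
   the non-Chagas, non-HIV neglected tropical diseases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .benefits_model import DiseaseEpiParams
from .pipeline_des import ARCHETYPES, PRODUCT_CLASS, active_phases, base_phase_params

__all__ = [
    "OPTION_DISEASES",
    "OPTION_TOTALS",
    "DEFAULT_AGE_GROUPS",
    "DEFAULT_ARCHETYPE_SPLIT",
    "DEFAULT_RANGES",
    "PortfolioEntry",
    "PortfolioSpec",
    "EpiParamDraw",
    "generate_portfolio",
    "generate_disease_params",
    "worked_fixture",
]

_OPTION1 = ("HIV", "TB", "malaria", "pneumonia")
_OPTION2 = _OPTION1 + ("Chagas", "schistosomiasis", "leishmaniasis", "dengue", "leprosy")
_OPTION3 = _OPTION2 + (
    "shigellosis",
    "Ebola",
    "hepatitis C",
    "enterotoxigenic E. coli",
    "non-typhoidal salmonella",
    "human African trypanosomiasis",
    "onchocerciasis",
    "cholera",
    "hookworm",
    "meningitis",
    "rheumatic fever",
    "diarrhoeal diseases",
    "Buruli ulcer",
    "trachoma",
    "typhoid",
    "paratyphoid",
    "cryptosporidiosis",
    "multiple salmonella infections",
    "hepatitis B",
    "herpes simplex-2",
    "gonorrhoea",
    "chlamydia",
)

OPTION_DISEASES: Dict[int, Tuple[str, ...]] = {1: _OPTION1, 2: _OPTION2, 3: _OPTION3}
OPTION_TOTALS: Dict[int, int] = {1: 116, 2: 327, 3: 506}

#: Product classes a design option funds.
OPTION_CLASSES: Dict[int, Tuple[str, ...]] = {
    1: ("vaccine",),
    2: ("vaccine", "therapeutic", "diagnostic"),
    3: ("vaccine", "therapeutic", "diagnostic"),
}

CLASS_ARCHETYPES: Dict[str, Tuple[str, ...]] = {
    "vaccine": ("vaccine-simple", "vaccine-complex"),
    "therapeutic": (
        "nce-simple",
        "nce-complex",
        "repurposed-simple",
        "repurposed-complex",
        "biologic-simple",
        "biologic-complex",
    ),
    "diagnostic": ("dx-assay", "dx-platform"),
}

# Option 1 start-phase marginals; other options reuse the proportions.
OPTION1_PHASE_COUNTS: Dict[str, int] = {"preclinical": 23, "phase1": 63, "phase2": 30}
_PHASE_PROPORTIONS: Dict[str, float] = {
    ph: n / 116.0 for ph, n in OPTION1_PHASE_COUNTS.items()
}

# Option 2 printed disease counts; HIV/TB/malaria share the 272 jointly.
OPTION2_BIG3_TOTAL = 272
OPTION2_FIXED_COUNTS: Dict[str, int] = {
    "leishmaniasis": 16,
    "Chagas": 14,
    "pneumonia": 9,
    "schistosomiasis": 9,
    "dengue": 5,
    "leprosy": 2,
}

# Option 3 printed shares, plus the joint share of the neglected tropical
# diseases other than Chagas.
OPTION3_PINNED_SHARES: Dict[str, float] = {
    "malaria": 0.19,
    "TB": 0.17,
    "HIV": 0.17,
    "Ebola": 0.14,
}
OPTION3_NTD_JOINT_SHARE = 0.115
_NTDS = frozenset(
    {
        "Chagas",
        "schistosomiasis",
        "leishmaniasis",
        "dengue",
        "leprosy",
        "human African trypanosomiasis",
        "onchocerciasis",
        "hookworm",
        "Buruli ulcer",
        "trachoma",
    }
)

DEFAULT_AGE_GROUPS: Tuple[str, ...] = ("0-4", "5-14", "15-49", "50-69", "70+")

#: Within-class archetype weights (each class sums to 1); classes in an
#: option share the option's candidates equally.
DEFAULT_ARCHETYPE_SPLIT: Dict[str, Dict[str, float]] = {
    "vaccine": {"vaccine-simple": 0.5, "vaccine-complex": 0.5},
    "therapeutic": {a: 1.0 / 6.0 for a in CLASS_ARCHETYPES["therapeutic"]},
    "diagnostic": {"dx-assay": 0.5, "dx-platform": 0.5},
}

#: Plausible (min, max) ranges for the synthetic epidemiological draw.
#: Per-age-group fields are drawn per age group; the rest once per disease.
DEFAULT_RANGES: Dict[str, Tuple[float, float]] = {
    "incidence": (1e4, 5e6),
    "deaths": (1e2, 5e4),
    "life_expectancy": (5.0, 70.0),
    "dw_untreated": (0.05, 0.5),
    "dw_treated": (0.01, 0.3),
    "dur_untreated": (0.2, 3.0),
    "dur_treated": (0.1, 1.5),
    "cfr_untreated": (0.01, 0.3),
    "cfr_treated": (0.005, 0.15),
    "coverage_baseline": (0.1, 0.7),
    "cost_per_case": (5.0, 500.0),
}

_PER_AGE_FIELDS = (
    "incidence",
    "deaths",
    "life_expectancy",
    "dw_untreated",
    "dw_treated",
    "dur_untreated",
    "dur_treated",
)
_PROBABILITY_FIELDS = (
    "dw_untreated",
    "dw_treated",
    "cfr_untreated",
    "cfr_treated",
    "coverage_baseline",
)


@dataclass(frozen=True)
class PortfolioEntry:
    disease: str
    archetype: str
    phase_at_start: str
    count: int


@dataclass(frozen=True)
class PortfolioSpec:
    """A candidate portfolio for one design option."""

    option_id: int
    entries: Tuple[PortfolioEntry, ...]

    def total(self) -> int:
        return sum(e.count for e in self.entries)

    def phase_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for e in self.entries:
            out[e.phase_at_start] = out.get(e.phase_at_start, 0) + e.count
        return out

    def disease_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for e in self.entries:
            out[e.disease] = out.get(e.disease, 0) + e.count
        return out

    def archetypes(self) -> Tuple[str, ...]:
        return tuple(sorted({e.archetype for e in self.entries}))

    def diseases(self) -> Tuple[str, ...]:
        return tuple(sorted({e.disease for e in self.entries}))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.disease, e.archetype, e.phase_at_start, e.count) for e in self.entries],
            columns=["disease", "archetype", "phase_at_start", "count"],
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, option_id: int) -> "PortfolioSpec":
        required = {"disease", "archetype", "phase_at_start", "count"}
        if not required.issubset(df.columns):
            raise ValueError(f"portfolio table missing columns: {required - set(df.columns)}")
        entries = tuple(
            PortfolioEntry(r.disease, r.archetype, r.phase_at_start, int(r.count))
            for r in df.itertuples()
        )
        return cls(option_id=option_id, entries=entries)

    @classmethod
    def from_csv(cls, path, option_id: int) -> "PortfolioSpec":
        return cls.from_dataframe(pd.read_csv(path), option_id)


class EpiParamDraw:
    """A set of per-disease epidemiological parameter records."""

    def __init__(self, params: Mapping[str, DiseaseEpiParams]):
        self._params: Dict[str, DiseaseEpiParams] = dict(params)

    def __len__(self) -> int:
        return len(self._params)

    def __iter__(self):
        return iter(self._params)

    def __contains__(self, disease: str) -> bool:
        return disease in self._params

    def __getitem__(self, disease: str) -> DiseaseEpiParams:
        return self._params[disease]

    def diseases(self) -> Tuple[str, ...]:
        return tuple(self._params)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for disease, p in self._params.items():
            for i, age in enumerate(p.age_groups):
                rows.append(
                    {
                        "disease": disease,
                        "age_group": age,
                        "incidence": p.incidence[i],
                        "deaths": p.deaths[i],
                        "life_expectancy": p.life_expectancy[i],
                        "dw_untreated": p.dw_untreated[i],
                        "dw_treated": p.dw_treated[i],
                        "dur_untreated": p.dur_untreated[i],
                        "dur_treated": p.dur_treated[i],
                        "cfr_untreated": p.cfr_untreated,
                        "cfr_treated": p.cfr_treated,
                        "coverage_baseline": p.coverage_baseline,
                        "cost_per_case": p.cost_per_case,
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        # %.17g keeps the text round-trip bit-exact
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "EpiParamDraw":
        params: Dict[str, DiseaseEpiParams] = {}
        for disease, grp in df.groupby("disease", sort=False):
            params[disease] = DiseaseEpiParams(
                disease=disease,
                age_groups=tuple(grp["age_group"].astype(str)),
                incidence=grp["incidence"].to_numpy(float),
                deaths=grp["deaths"].to_numpy(float),
                life_expectancy=grp["life_expectancy"].to_numpy(float),
                dw_untreated=grp["dw_untreated"].to_numpy(float),
                dw_treated=grp["dw_treated"].to_numpy(float),
                dur_untreated=grp["dur_untreated"].to_numpy(float),
                dur_treated=grp["dur_treated"].to_numpy(float),
                cfr_untreated=float(grp["cfr_untreated"].iloc[0]),
                cfr_treated=float(grp["cfr_treated"].iloc[0]),
                coverage_baseline=float(grp["coverage_baseline"].iloc[0]),
                cost_per_case=float(grp["cost_per_case"].iloc[0]),
            )
        return cls(params)

    @classmethod
    def from_csv(cls, path) -> "EpiParamDraw":
        return cls.from_dataframe(pd.read_csv(path, float_precision="round_trip"))


def _validate_split(split: Mapping[str, Mapping[str, float]], classes: Sequence[str]) -> None:
    for cls_name in classes:
        if cls_name not in split:
            raise ValueError(f"archetype split missing product class {cls_name!r}")
        weights = split[cls_name]
        for arch, w in weights.items():
            if arch not in CLASS_ARCHETYPES[cls_name]:
                raise ValueError(f"{arch!r} is not a {cls_name} archetype")
            if w < 0:
                raise ValueError("archetype weights must be >= 0")
        total = sum(weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype split for {cls_name!r} sums to {total}, not 1")


def _start_phase_probs(archetype: str) -> Tuple[Tuple[str, ...], np.ndarray]:
    """Valid early start phases of an archetype with renormalized weights.

    Phase III starters are excluded by construction: their late-stage
    trials are assumed already funded.
    """
    params = base_phase_params()
    valid = [
        ph for ph in ("preclinical", "phase1", "phase2")
        if ph in active_phases(archetype, params)
    ]
    probs = np.array([_PHASE_PROPORTIONS[ph] for ph in valid])
    return tuple(valid), probs / probs.sum()


def _option3_disease_counts() -> Dict[str, int]:
    """Integer disease counts for option 3 (largest-remainder rounding).

    Pinned shares for malaria/TB/HIV/Ebola, a joint uniform 11.5% for the
    non-Chagas NTDs, and the remainder spread uniformly over the other
    diseases.  Deterministic: no sampling is involved.
    """
    diseases = OPTION_DISEASES[3]
    ntds = [d for d in diseases if d in _NTDS and d != "Chagas"]
    others = [d for d in diseases if d not in OPTION3_PINNED_SHARES and d not in ntds]
    remainder = 1.0 - sum(OPTION3_PINNED_SHARES.values()) - OPTION3_NTD_JOINT_SHARE
    shares = dict(OPTION3_PINNED_SHARES)
    shares.update({d: OPTION3_NTD_JOINT_SHARE / len(ntds) for d in ntds})
    shares.update({d: remainder / len(others) for d in others})
    total = OPTION_TOTALS[3]
    raw = {d: total * s for d, s in shares.items()}
    counts = {d: int(np.floor(v)) for d, v in raw.items()}
    shortfall = total - sum(counts.values())
    by_frac = sorted(raw, key=lambda d: (-(raw[d] - counts[d]), d))
    for d in by_frac[:shortfall]:
        counts[d] += 1
    return counts


def generate_portfolio(
    option_id: int,
    archetype_split: Optional[Mapping[str, Mapping[str, float]]] = None,
    seed: int = 0,
) -> PortfolioSpec:
    """Generate a candidate portfolio for a design option.

    The printed marginals (totals, option 1 phase counts, option 2/3
    disease counts) are reproduced exactly; allocation within
    unconstrained cells is multinomial under ``archetype_split`` and is
    deterministic given ``seed``.
    """
    if option_id not in OPTION_TOTALS:
        raise ValueError(f"unknown design option: {option_id!r}")
    classes = OPTION_CLASSES[option_id]
    split = archetype_split or DEFAULT_ARCHETYPE_SPLIT
    _validate_split(split, classes)
    rng = np.random.default_rng(seed)
    diseases = OPTION_DISEASES[option_id]

    # flat archetype weights: equal class shares x within-class split
    arch_names: List[str] = []
    arch_weights: List[float] = []
    for cls_name in classes:
        for arch in CLASS_ARCHETYPES[cls_name]:
            w = split[cls_name].get(arch, 0.0)
            if w > 0:
                arch_names.append(arch)
                arch_weights.append(w / len(classes))
    weights = np.array(arch_weights)
    weights = weights / weights.sum()

    counts: Dict[Tuple[str, str, str], int] = {}

    def _add(disease: str, arch: str, phase: str, n: int) -> None:
        if n > 0:
            key = (disease, arch, phase)
            counts[key] = counts.get(key, 0) + n

    if option_id == 1:
        # exact phase marginals; disease x archetype multinomial per phase
        cells = [(d, a) for d in diseases for a in arch_names]
        probs = np.array([weights[arch_names.index(a)] / len(diseases) for d, a in cells])
        probs = probs / probs.sum()
        for phase, n_phase in OPTION1_PHASE_COUNTS.items():
            alloc = rng.multinomial(n_phase, probs)
            for (d, a), n in zip(cells, alloc):
                _add(d, a, phase, int(n))
    else:
        if option_id == 2:
            disease_counts = dict(OPTION2_FIXED_COUNTS)
            big3 = ("HIV", "TB", "malaria")
            alloc = rng.multinomial(OPTION2_BIG3_TOTAL, np.full(3, 1.0 / 3.0))
            disease_counts.update(dict(zip(big3, (int(x) for x in alloc))))
        else:
            disease_counts = _option3_disease_counts()
        for disease in diseases:
            n_d = disease_counts.get(disease, 0)
            if n_d == 0:
                continue
            arch_alloc = rng.multinomial(n_d, weights)
            for arch, n_a in zip(arch_names, arch_alloc):
                if n_a == 0:
                    continue
                phases, probs = _start_phase_probs(arch)
                phase_alloc = rng.multinomial(int(n_a), probs)
                for phase, n_p in zip(phases, phase_alloc):
                    _add(disease, arch, phase, int(n_p))

    entries = tuple(
        PortfolioEntry(d, a, ph, n)
        for (d, a, ph), n in sorted(counts.items())
    )
    return PortfolioSpec(option_id=option_id, entries=entries)


def _check_ranges(ranges: Mapping[str, Tuple[float, float]]) -> None:
    for field_name, (lo, hi) in ranges.items():
        if field_name not in DEFAULT_RANGES:
            raise ValueError(f"unknown parameter field: {field_name!r}")
        if lo > hi:
            raise ValueError(f"{field_name}: min {lo} exceeds max {hi}")
        if lo < 0:
            raise ValueError(f"{field_name}: negative bound for a non-negative field")
        if field_name in _PROBABILITY_FIELDS and hi > 1.0:
            raise ValueError(f"{field_name}: bound above 1 for a proportion field")


def generate_disease_params(
    diseases: Sequence[str],
    ranges: Optional[Mapping[str, Tuple[float, float]]] = None,
    seed: int = 0,
    age_groups: Sequence[str] = DEFAULT_AGE_GROUPS,
) -> EpiParamDraw:
    """Draw one epidemiological record per disease from uniform ranges.

    Ordered pairs are drawn conditionally so the structural invariants
    hold by construction: the treated case-fatality rate never exceeds
    the untreated one, and treated disability weights / illness durations
    never exceed their untreated counterparts.  Deterministic given
    ``seed``; degenerate point ranges reproduce their constants exactly.
    """
    full_ranges = dict(DEFAULT_RANGES)
    full_ranges.update(ranges or {})
    _check_ranges(full_ranges)
    rng = np.random.default_rng(seed)
    n_ages = len(age_groups)

    def _draw(field_name: str, size=None, upper: Optional[float] = None):
        lo, hi = full_ranges[field_name]
        if upper is not None:
            hi = min(hi, upper) if np.isscalar(upper) else np.minimum(hi, upper)
            if np.any(np.asarray(lo) > np.asarray(hi)):
                raise ValueError(
                    f"{field_name}: lower bound exceeds the untreated draw; "
                    "ranges are mutually inconsistent"
                )
        return rng.uniform(lo, hi, size=size)

    params: Dict[str, DiseaseEpiParams] = {}
    for disease in diseases:
        dw_u = _draw("dw_untreated", size=n_ages)
        dur_u = _draw("dur_untreated", size=n_ages)
        cfr_u = float(_draw("cfr_untreated"))
        params[disease] = DiseaseEpiParams(
            disease=disease,
            age_groups=tuple(age_groups),
            incidence=_draw("incidence", size=n_ages),
            deaths=_draw("deaths", size=n_ages),
            life_expectancy=_draw("life_expectancy", size=n_ages),
            dw_untreated=dw_u,
            dw_treated=_draw("dw_treated", size=n_ages, upper=dw_u),
            dur_untreated=dur_u,
            dur_treated=_draw("dur_treated", size=n_ages, upper=dur_u),
            cfr_untreated=cfr_u,
            cfr_treated=float(_draw("cfr_treated", upper=cfr_u)),
            coverage_baseline=float(_draw("coverage_baseline")),
            cost_per_case=float(_draw("cost_per_case")),
        )
    return EpiParamDraw(params)


def worked_fixture() -> Tuple[PortfolioSpec, EpiParamDraw]:
    """A hand-checkable one-candidate, one-disease, one-age-group fixture.

    One simple vaccine candidate in phase II for malaria; round-number
    epidemiology (1000 cases/yr, 100 deaths/yr, 30 years residual life
    expectancy, untreated disability weight 0.2 for 1 year, treated 0.1
    for half a year, case fatality 10% untreated / 5% treated, 20%
    baseline coverage, US$50 treatment cost per case).  The analytic
    launch probability of the candidate is 0.459 x 0.708 = 0.324972.
    """
    portfolio = PortfolioSpec(
        option_id=1,
        entries=(PortfolioEntry("malaria", "vaccine-simple", "phase2", 1),),
    )
    epi = EpiParamDraw(
        {
            "malaria": DiseaseEpiParams(
                disease="malaria",
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
        }
    )
    return portfolio, epi
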