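"""Synthetic, internally consistent parameter bundles and toy fixtures.

Real analyses load a parameter file assembled from published cohort studies,
price lists and utility catalogues.  This module generates bundles with the
same structure and realistic magnitudes so every pipeline stage can run and
be tested without any external data:

* age-banded transition probabilities with mortality rising over the 18–80
  horizon and complication onset/progression rates in the
  0.5–5% per year range typical of type 2 diabetes cohorts;
* a utility ladder strictly ordered NON_DM > DM_NO_COMP > single
  complications ≥ multi-complication > DEATH = 0;
* lognormal-jittered positive annual state costs, dominated by end-stage
  renal disease, and per-test screening cost components in which the venous
  laboratory test carries the largest travel/time burden (amplified in the
  rural setting);
* screening accuracies drawn so that both HbA1c tests are more sensitive
  than fasting capillary glucose, whose sensitivity is centred on the 65.1%
  reported for Chinese screening populations.

Urban and rural bundles generated from the same seed share base transitions,
utilities and state costs; they differ in prevalence, in the rural hazard
ratios (CVD ×1.15, stroke ×1.25, blindness ×2.09, foot ulcer ×1.42, ESRD
×1.15) and in the non-medical screening cost components.  No generated value
is a published supplementary-table value; exact reproduction of a published
analysis requires loading its real parameters through the same schema.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .params import (
    DEFAULT_RURAL_HR,
    CostSet,
    DiscountSpec,
    MissedDiagnosisHR,
    ModelParameters,
    ScreeningStrategy,
    Setting,
    TransitionTable,
    UtilitySet,
    WTPSpec,
)
from .states import PROGRESSION, HealthState

# 5-year age bands over [18, 80) (first band is 18-25)
AGE_BAND_EDGES = (18, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80)

#: Annual background (non-diabetic) death probability per age band.
BACKGROUND_MORTALITY = (
    0.0005, 0.0006, 0.0008, 0.0011, 0.0016, 0.0025,
    0.0040, 0.0065, 0.0105, 0.0170, 0.0280, 0.0460,
)

#: Excess-mortality multiplier on background mortality, by diabetic state.
MORTALITY_MULTIPLIER = {
    HealthState.DM_NO_COMP: 1.5,
    HealthState.DM_CVD: 2.5,
    HealthState.DM_STROKE: 3.0,
    HealthState.DM_DKD: 2.0,
    HealthState.DM_ESRD: 6.0,
    HealthState.DM_DFU: 2.2,
    HealthState.DM_AMPUTATION: 3.0,
    HealthState.DM_DR: 1.6,
    HealthState.DM_BLINDNESS: 1.8,
    HealthState.DM_DPN: 1.7,
    HealthState.DM_MULTI_COMP: 4.0,
}

#: Annual onset probability from complication-free diabetes, by complication.
ONSET_BASE = {
    HealthState.DM_CVD: 0.012,
    HealthState.DM_STROKE: 0.008,
    HealthState.DM_DKD: 0.015,
    HealthState.DM_DFU: 0.005,
    HealthState.DM_DR: 0.020,
    HealthState.DM_DPN: 0.018,
}

#: Annual progression probability to the severe sequela.
PROGRESSION_BASE = {
    HealthState.DM_DKD: 0.030,
    HealthState.DM_DFU: 0.050,
    HealthState.DM_DR: 0.020,
}

MULTI_BASE_NO_COMP = 0.006  # no-complication -> multi-complication
MULTI_BASE_COMP = 0.030     # any single complication -> multi-complication

COST_BASE = {
    HealthState.DM_NO_COMP: 320.0,
    HealthState.DM_CVD: 1900.0,
    HealthState.DM_STROKE: 2300.0,
    HealthState.DM_DKD: 1400.0,
    HealthState.DM_ESRD: 9500.0,
    HealthState.DM_DFU: 1800.0,
    HealthState.DM_AMPUTATION: 2600.0,
    HealthState.DM_DR: 750.0,
    HealthState.DM_BLINDNESS: 1300.0,
    HealthState.DM_DPN: 700.0,
    HealthState.DM_MULTI_COMP: 3800.0,
}

UTILITY_BASE = {
    HealthState.NON_DM: 1.00,
    HealthState.DM_NO_COMP: 0.84,
    HealthState.DM_CVD: 0.70,
    HealthState.DM_STROKE: 0.62,
    HealthState.DM_DKD: 0.68,
    HealthState.DM_ESRD: 0.46,
    HealthState.DM_DFU: 0.64,
    HealthState.DM_AMPUTATION: 0.52,
    HealthState.DM_DR: 0.69,
    HealthState.DM_BLINDNESS: 0.50,
    HealthState.DM_DPN: 0.66,
    HealthState.DM_MULTI_COMP: 0.44,
    HealthState.DEATH: 0.0,
}

#: (Se range, Sp range) per strategy; both HbA1c tests beat FCG on Se.
SE_SP_RANGES = {
    "POCT_HBA1C": ((0.88, 0.93), (0.83, 0.89)),
    "VENOUS_HBA1C": ((0.85, 0.91), (0.88, 0.93)),
    "FCG": ((0.62, 0.68), (0.82, 0.88)),
}

#: Urban per-test cost components (direct medical, direct non-medical,
#: indirect), USD; the rural setting scales the last two.
SCREEN_COST_URBAN = {
    "POCT_HBA1C": (2.8, 0.5, 0.6),
    "VENOUS_HBA1C": (7.5, 2.0, 2.4),
    "FCG": (0.9, 0.5, 0.6),
}
RURAL_NONMED_FACTOR = 2.5
RURAL_INDIRECT_FACTOR = 1.8

#: Default adult age-density table (band low age, band high age, weight).
DEFAULT_AGE_PYRAMID = (
    (18, 30, 0.20),
    (30, 40, 0.19),
    (40, 50, 0.20),
    (50, 60, 0.19),
    (60, 70, 0.13),
    (70, 80, 0.09),
)


class SyntheticSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    setting: Literal["urban", "rural"] = "urban"
    prevalence_range_urban: tuple[float, float] = (0.10, 0.14)
    prevalence_range_rural: tuple[float, float] = (0.09, 0.13)
    jitter: float = Field(default=0.10, ge=0.0, lt=0.5)
    ogtt_cost: float = 8.0
    sex_ratio_male: float = Field(default=0.51, ge=0.0, le=1.0)
    age_range: tuple[int, int] = (18, 80)
    n_population_bands: int = Field(default=6, ge=1)


def _jittered(rng: np.random.Generator, base: float, jitter: float) -> float:
    return float(base * rng.uniform(1.0 - jitter, 1.0 + jitter))


def _build_transitions(rng: np.random.Generator, jitter: float) -> TransitionTable:
    bands = [(AGE_BAND_EDGES[i], AGE_BAND_EDGES[i + 1]) for i in range(len(AGE_BAND_EDGES) - 1)]
    nb = len(bands)
    mort = np.array(BACKGROUND_MORTALITY)
    entries: dict[str, tuple[float, ...]] = {}

    def add_row(frm: HealthState, outflows: dict[HealthState, np.ndarray]) -> None:
        stay = np.ones(nb)
        for to, p in outflows.items():
            entries[f"{frm.value}->{to.value}"] = tuple(p)
            stay = stay - p
        if (stay < 0).any():
            raise ValueError(f"synthetic outflows from {frm.value} exceed 1")
        entries[f"{frm.value}->{frm.value}"] = tuple(stay)

    add_row(HealthState.NON_DM, {HealthState.DEATH: mort})

    death = mort * MORTALITY_MULTIPLIER[HealthState.DM_NO_COMP]
    outflows = {HealthState.DEATH: death}
    for comp, base in ONSET_BASE.items():
        outflows[comp] = np.full(nb, _jittered(rng, base, jitter))
    outflows[HealthState.DM_MULTI_COMP] = np.full(
        nb, _jittered(rng, MULTI_BASE_NO_COMP, jitter)
    )
    add_row(HealthState.DM_NO_COMP, outflows)

    for comp in ONSET_BASE:
        outflows = {
            HealthState.DEATH: mort * MORTALITY_MULTIPLIER[comp],
            HealthState.DM_MULTI_COMP: np.full(nb, _jittered(rng, MULTI_BASE_COMP, jitter)),
        }
        if comp in PROGRESSION:
            outflows[PROGRESSION[comp]] = np.full(
                nb, _jittered(rng, PROGRESSION_BASE[comp], jitter)
            )
        add_row(comp, outflows)

    for sequela in PROGRESSION.values():
        add_row(
            sequela,
            {
                HealthState.DEATH: mort * MORTALITY_MULTIPLIER[sequela],
                HealthState.DM_MULTI_COMP: np.full(
                    nb, _jittered(rng, MULTI_BASE_COMP, jitter)
                ),
            },
        )

    add_row(
        HealthState.DM_MULTI_COMP,
        {HealthState.DEATH: mort * MORTALITY_MULTIPLIER[HealthState.DM_MULTI_COMP]},
    )
    entries["DEATH->DEATH"] = tuple(np.ones(nb))
    return TransitionTable(age_bands=bands, entries=entries)


def generate_baseline_population(
    n_bands: int, spec: SyntheticSpec | None = None
) -> list[tuple[int, str, float]]:
    """Baseline cohort: (age, sex, weight) triples with weights summing to 1.

    The age density follows a plausible adult pyramid (younger bands heavier)
    over ``spec.age_range``, partitioned into ``n_bands`` equal-width bands
    and spread uniformly over the single-year ages within each band; each age
    is split between sexes at the configured ratio.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    spec = spec or SyntheticSpec()
    lo, hi = spec.age_range

    def density(age: int) -> float:
        for b_lo, b_hi, w in DEFAULT_AGE_PYRAMID:
            if b_lo <= age < b_hi:
                return w / (b_hi - b_lo)
        return DEFAULT_AGE_PYRAMID[-1][2] / 10.0

    edges = np.linspace(lo, hi, n_bands + 1)
    pop: list[tuple[int, str, float]] = []
    for i in range(n_bands):
        ages = [a for a in range(int(np.floor(edges[i])), int(np.ceil(edges[i + 1])))
                if lo <= a < hi] or [int(edges[i])]
        band_w = sum(density(a) for a in ages)
        for a in ages:  # band mass spread uniformly over its single-year ages
            w = band_w / len(ages)
            pop.append((a, "M", w * spec.sex_ratio_male))
            if spec.sex_ratio_male < 1.0:
                pop.append((a, "F", w * (1.0 - spec.sex_ratio_male)))
    total = sum(w for _, _, w in pop)
    return [(a, s, w / total) for a, s, w in pop]


def generate_parameter_set(spec: SyntheticSpec) -> ModelParameters:
    """Deterministic (per seed) full parameter bundle for one setting.

    Bundles for ``urban`` and ``rural`` generated from the same seed share
    base transitions, utilities, state costs and test accuracies; the rural
    bundle embeds the default rural hazard ratios and carries higher
    non-medical and indirect screening cost components.
    """
    seed = spec.seed
    rural = spec.setting == "rural"
    rng_t = np.random.default_rng((seed, 1))
    rng_c = np.random.default_rng((seed, 2))
    rng_u = np.random.default_rng((seed, 3))
    rng_s = np.random.default_rng((seed, 4))
    rng_p = np.random.default_rng((seed, 5, 1 if rural else 0))

    transitions = _build_transitions(rng_t, spec.jitter)

    state_costs = {
        state: _jittered(rng_c, base, spec.jitter) for state, base in COST_BASE.items()
    }
    state_costs[HealthState.NON_DM] = 0.0
    state_costs[HealthState.DEATH] = 0.0
    costs = CostSet(state_annual_cost=state_costs, ogtt_cost=spec.ogtt_cost)

    # small shared downward jitter keeps the ladder ordering intact
    utilities = {
        state: (base if base in (0.0, 1.0) else round(base * rng_u.uniform(0.97, 1.0), 4))
        for state, base in UTILITY_BASE.items()
    }
    utility_set = UtilitySet(state_utility=utilities)

    strategies = []
    for name, ((se_lo, se_hi), (sp_lo, sp_hi)) in SE_SP_RANGES.items():
        dm, dnm, ind = SCREEN_COST_URBAN[name]
        if rural:
            dnm *= RURAL_NONMED_FACTOR
            ind *= RURAL_INDIRECT_FACTOR
        strategies.append(
            ScreeningStrategy(
                name=name,
                sensitivity=round(float(rng_s.uniform(se_lo, se_hi)), 4),
                specificity=round(float(rng_s.uniform(sp_lo, sp_hi)), 4),
                cost_direct_medical=dm,
                cost_direct_nonmedical=dnm,
                cost_indirect=ind,
            )
        )

    prev_range = spec.prevalence_range_rural if rural else spec.prevalence_range_urban
    prevalence = round(float(rng_p.uniform(*prev_range)), 4)
    setting = Setting(
        label=spec.setting,
        prevalence=prevalence,
        rural_hr=dict(DEFAULT_RURAL_HR) if rural else {},
    )

    return ModelParameters(
        setting=setting,
        strategies=strategies,
        transitions=transitions,
        costs=costs,
        utilities=utility_set,
        missed_hr=MissedDiagnosisHR(),
        discount=DiscountSpec(),
        wtp=WTPSpec(),
        baseline_population=generate_baseline_population(spec.n_population_bands, spec),
    )


def toy_fixture(name: Literal["two_state", "four_state_chain"]) -> ModelParameters:
    """Minimal bundles with closed-form discounted totals, for validation.

    ``two_state``: alive (NON_DM, utility 1, cost 0) with annual death
    probability q = 0.1; from a single start age a with T = 80 − a cycles,
    the undiscounted no-half-cycle QALY total is the geometric series
    Σ_{t=0}^{T-1} (1 − q)^t, and with discount rate r the ratio becomes
    (1 − q)/(1 + r).

    ``four_state_chain``: DM_NO_COMP → DM_CVD → DM_MULTI_COMP → DEATH with
    age-constant exit probabilities 0.2 / 0.25 / 0.3, utilities
    1 / 0.7 / 0.5 / 0 and annual costs 100 / 1000 / 2000 / 0; totals equal
    the matrix-geometric sum Σ_t d^t · v P^t · u.
    """
    bands = [(18, 80)]
    if name == "two_state":
        entries = {
            "NON_DM->NON_DM": (0.9,),
            "NON_DM->DEATH": (0.1,),
            "DEATH->DEATH": (1.0,),
        }
        utilities = {s: 0.0 for s in HealthState}
        utilities[HealthState.NON_DM] = 1.0
        costs = {s: 0.0 for s in HealthState}
        start_state_pop = [(18, "F", 1.0)]
    elif name == "four_state_chain":
        entries = {
            "DM_NO_COMP->DM_NO_COMP": (0.8,),
            "DM_NO_COMP->DM_CVD": (0.2,),
            "DM_CVD->DM_CVD": (0.75,),
            "DM_CVD->DM_MULTI_COMP": (0.25,),
            "DM_MULTI_COMP->DM_MULTI_COMP": (0.7,),
            "DM_MULTI_COMP->DEATH": (0.3,),
            "DEATH->DEATH": (1.0,),
        }
        utilities = {s: 0.0 for s in HealthState}
        utilities[HealthState.NON_DM] = 1.0  # unused; keeps the utility ladder ordered
        utilities[HealthState.DM_NO_COMP] = 1.0
        utilities[HealthState.DM_CVD] = 0.7
        utilities[HealthState.DM_MULTI_COMP] = 0.5
        costs = {s: 0.0 for s in HealthState}
        costs[HealthState.DM_NO_COMP] = 100.0
        costs[HealthState.DM_CVD] = 1000.0
        costs[HealthState.DM_MULTI_COMP] = 2000.0
        start_state_pop = [(18, "F", 1.0)]
    else:
        raise ValueError(f"unknown toy fixture {name!r}")

    strategy = ScreeningStrategy(
        name="FCG",
        sensitivity=1.0,
        specificity=1.0,
        cost_direct_medical=0.0,
        cost_direct_nonmedical=0.0,
        cost_indirect=0.0,
    )
    return ModelParameters(
        setting=Setting(label="urban", prevalence=0.5),
        strategies=[strategy],
        transitions=TransitionTable(age_bands=bands, entries=entries),
        costs=CostSet(state_annual_cost=costs, ogtt_cost=0.0),
        utilities=UtilitySet(state_utility=utilities),
        discount=DiscountSpec(rate=0.0),
        baseline_population=start_state_pop,
    )
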