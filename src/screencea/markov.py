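"""Disease-progression engine: cohort recursion and microsimulation.

Both the treated/untreated diabetes model (Markov "+") and the non-diabetic
model (Markov "-") run on the same 13-state space with a 1-year cycle; the
negative model simply starts in NON_DM, which can only stay or die.  A cohort
run iterates ``occupancy_{t+1} = occupancy_t · P(age_t)`` until the cohort
reaches the horizon age (80 by default), accruing per-cycle costs and QALYs
with half-cycle correction (trapezoid rule over the trace) and discounting at
integer cycle boundaries, cycle 0 undiscounted.

Three equivalent evaluation routes are provided:

* :func:`run_cohort` — forward recursion, returns the full occupancy trace;
* :func:`expected_values_by_age` — backward value iteration giving expected
  discounted totals for every (state, start age) in one sweep; used by the
  sensitivity analyses, where thousands of model evaluations are needed;
* :func:`run_microsimulation` — seeded individual-level Monte Carlo with the
  half-cycle convention that transitions happen mid-cycle (half weight in the
  origin and destination state for the transition cycle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from .params import (
    AGE_MIN,
    ModelParameters,
    ScreeningStrategy,
    TransitionTable,
    apply_missed_diagnosis_hr,
    apply_rural_hr,
)
from .screening import classify
from .states import N_STATES, STATE_INDEX, STATE_ORDER, HealthState

Arm = Literal["diagnosed", "missed", "negative"]

ARM_START_STATE: dict[str, HealthState] = {
    "diagnosed": HealthState.DM_NO_COMP,
    "missed": HealthState.DM_NO_COMP,
    "negative": HealthState.NON_DM,
}


@dataclass
class CohortTrace:
    """Cycle-by-state occupancy plus discounted per-cycle accruals.

    ``occupancy`` has ``cycles + 1`` rows (cycle starts plus the final end
    point); ``per_cycle_cost`` / ``per_cycle_qaly`` have ``cycles`` entries,
    already discounted and half-cycle corrected where requested.
    """

    occupancy: np.ndarray
    cycles: int
    start_age: int
    per_cycle_cost: np.ndarray
    per_cycle_qaly: np.ndarray

    def to_frame(self):
        """Trace as a DataFrame: cycle, age, one column per state, cost, qaly."""
        import pandas as pd

        rows = self.occupancy[: self.cycles + 1]
        df = pd.DataFrame(rows, columns=[s.value for s in STATE_ORDER])
        df.insert(0, "cycle", np.arange(self.cycles + 1))
        df.insert(1, "age", self.start_age + np.arange(self.cycles + 1))
        df["cost"] = np.concatenate([self.per_cycle_cost, [np.nan]])
        df["qaly"] = np.concatenate([self.per_cycle_qaly, [np.nan]])
        return df


@dataclass
class ArmOutcome:
    total_cost: float
    total_qaly: float
    trace: CohortTrace | None = None
    mc_standard_error: dict[str, float] | None = None


def discount_factor(rate: float, t: int) -> float:
    """Present-value multiplier ``1 / (1 + rate)^t`` for cycle index ``t``."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    if t < 0:
        raise ValueError("cycle index must be >= 0")
    return 1.0 / (1.0 + rate) ** t


def half_cycle_correct(occupancy: np.ndarray) -> np.ndarray:
    """Effective per-cycle occupancy: the mean of each cycle's start and end
    rows (trapezoid rule).  A single-row trace is returned unchanged."""
    occupancy = np.asarray(occupancy, dtype=float)
    if occupancy.ndim == 1:
        occupancy = occupancy[None, :]
    if occupancy.shape[0] < 2:
        warnings.warn("half-cycle correction needs at least two rows; returning input")
        return occupancy
    return 0.5 * (occupancy[:-1] + occupancy[1:])


def arm_transition_table(params: ModelParameters, arm: Arm) -> TransitionTable:
    """Transition table for one decision-tree arm: rural hazard ratios apply
    to everyone in a rural setting; the missed arm additionally carries the
    missed-diagnosis hazard ratios."""
    base = apply_rural_hr(params.transitions, params.setting)
    if arm == "missed":
        return apply_missed_diagnosis_hr(base, params.missed_hr)
    return base


def _check_stochastic(mats: np.ndarray) -> None:
    sums = mats.sum(axis=2)
    if not np.allclose(sums, 1.0, atol=1e-9) or (mats < -1e-12).any():
        raise ValueError("transition matrices are not row-stochastic")


def _stratum_forward(
    mats: np.ndarray,
    table: TransitionTable,
    start_state: HealthState,
    start_age: int,
    horizon_age: int,
    cost_vec: np.ndarray,
    util_vec: np.ndarray,
    rate: float,
    half_cycle: bool,
) -> CohortTrace:
    cycles = max(0, horizon_age - start_age)
    occ = np.zeros((cycles + 1, N_STATES))
    occ[0, STATE_INDEX[start_state]] = 1.0
    for t in range(cycles):
        occ[t + 1] = occ[t] @ mats[table.band_for_age(start_age + t)]
    if half_cycle and cycles >= 1:
        eff = half_cycle_correct(occ)
    else:
        eff = occ[:cycles]
    disc = (1.0 + rate) ** -np.arange(cycles)
    per_cost = (eff @ cost_vec) * disc if cycles else np.zeros(0)
    per_qaly = (eff @ util_vec) * disc if cycles else np.zeros(0)
    return CohortTrace(
        occupancy=occ,
        cycles=cycles,
        start_age=start_age,
        per_cycle_cost=per_cost,
        per_cycle_qaly=per_qaly,
    )


def run_cohort(
    params: ModelParameters,
    arm: Arm,
    start_age_distribution: Mapping[int, float] | None = None,
    *,
    half_cycle: bool = True,
) -> ArmOutcome:
    """Deterministic cohort run for one arm.

    The baseline age distribution is split into single-year strata, each run
    to the horizon age and averaged by population weight.  The returned trace
    is the weighted occupancy aligned on cycle index; strata that reach the
    horizon early are frozen at their final occupancy (so rows keep summing
    to 1) and accrue nothing further.
    """
    if start_age_distribution is None:
        start_age_distribution = params.age_weights()
    table = arm_transition_table(params, arm)
    mats = table.matrices()
    _check_stochastic(mats)
    cost_vec = params.costs.cost_vector()
    util_vec = params.utilities.utility_vector()
    rate = params.discount.rate
    start_state = ARM_START_STATE[arm]

    traces = []
    weights = []
    for age, w in sorted(start_age_distribution.items()):
        if w == 0.0:
            continue
        traces.append(
            _stratum_forward(
                mats, table, start_state, age, params.horizon_age,
                cost_vec, util_vec, rate, half_cycle,
            )
        )
        weights.append(w)
    wsum = sum(weights)
    weights = [w / wsum for w in weights]

    max_cycles = max(tr.cycles for tr in traces)
    occ = np.zeros((max_cycles + 1, N_STATES))
    per_cost = np.zeros(max_cycles)
    per_qaly = np.zeros(max_cycles)
    for tr, w in zip(traces, weights):
        occ[: tr.cycles + 1] += w * tr.occupancy
        if tr.cycles < max_cycles:  # freeze finished strata at their endpoint
            occ[tr.cycles + 1 :] += w * tr.occupancy[-1]
        per_cost[: tr.cycles] += w * tr.per_cycle_cost
        per_qaly[: tr.cycles] += w * tr.per_cycle_qaly
    trace = CohortTrace(
        occupancy=occ,
        cycles=max_cycles,
        start_age=min(tr.start_age for tr in traces),
        per_cycle_cost=per_cost,
        per_cycle_qaly=per_qaly,
    )
    return ArmOutcome(
        total_cost=float(per_cost.sum()),
        total_qaly=float(per_qaly.sum()),
        trace=trace,
    )


def expected_values_by_age(
    table: TransitionTable,
    values: np.ndarray,
    rate: float,
    horizon_age: int = 80,
    *,
    half_cycle: bool = True,
) -> np.ndarray:
    """Expected discounted lifetime accrual ``V[age - 18, state]`` of a
    per-year state value vector, for every start age 18..horizon.

    Backward recursion: ``V(·, horizon) = 0`` and, for age ``a < horizon``,
    ``V(·, a) = accrual_a + P_a V(·, a+1) / (1 + rate)`` with
    ``accrual_a = (values + P_a values) / 2`` under half-cycle correction
    (``values`` otherwise).  Agrees with :func:`run_cohort` to rounding.
    """
    mats = table.matrices()
    _check_stochastic(mats)
    values = np.asarray(values, dtype=float)
    n_ages = horizon_age - AGE_MIN + 1
    V = np.zeros((n_ages, N_STATES))
    d = 1.0 / (1.0 + rate)
    for a in range(horizon_age - 1, AGE_MIN - 1, -1):
        P = mats[table.band_for_age(a)]
        Pv = P @ values
        accrual = 0.5 * (values + Pv) if half_cycle else values
        V[a - AGE_MIN] = accrual + d * (P @ V[a - AGE_MIN + 1])
    return V


def arm_expected_outcome(
    params: ModelParameters,
    arm: Arm,
    *,
    half_cycle: bool = True,
    table: TransitionTable | None = None,
) -> ArmOutcome:
    """Arm totals via the backward sweep (no trace); exact cohort expectation."""
    if table is None:
        table = arm_transition_table(params, arm)
    rate = params.discount.rate
    Vc = expected_values_by_age(
        table, params.costs.cost_vector(), rate, params.horizon_age, half_cycle=half_cycle
    )
    Vq = expected_values_by_age(
        table, params.utilities.utility_vector(), rate, params.horizon_age,
        half_cycle=half_cycle,
    )
    s = STATE_INDEX[ARM_START_STATE[arm]]
    cost = qaly = 0.0
    for age, w in params.age_weights().items():
        cost += w * Vc[age - AGE_MIN, s]
        qaly += w * Vq[age - AGE_MIN, s]
    return ArmOutcome(total_cost=float(cost), total_qaly=float(qaly))


def run_microsimulation(
    params: ModelParameters,
    arm: Arm,
    n_individuals: int,
    seed: int,
    *,
    half_cycle: bool = True,
) -> ArmOutcome:
    """Individual-level Monte Carlo for one arm; bit-reproducible per seed.

    Each individual samples a start age from the baseline population, walks
    the chain with per-cycle categorical draws and accrues discounted values
    with transitions weighted half in the origin and half in the destination
    state (the individual-level analogue of half-cycle correction).
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    table = arm_transition_table(params, arm)
    mats = table.matrices()
    _check_stochastic(mats)
    cum = np.cumsum(mats, axis=2)
    cum[:, :, -1] = 1.0  # guard against rounding in the last column
    cost_vec = params.costs.cost_vector()
    util_vec = params.utilities.utility_vector()
    rate = params.discount.rate
    start_idx = STATE_INDEX[ARM_START_STATE[arm]]

    age_w = params.age_weights()
    ages = np.array(list(age_w), dtype=int)
    probs = np.array(list(age_w.values()))
    sampled_ages = rng.choice(ages, size=n_individuals, p=probs / probs.sum())

    cost_tot = np.zeros(n_individuals)
    qaly_tot = np.zeros(n_individuals)
    for age in np.unique(sampled_ages):
        idx = np.flatnonzero(sampled_ages == age)
        m = idx.size
        states = np.full(m, start_idx, dtype=np.intp)
        cycles = max(0, params.horizon_age - int(age))
        for t in range(cycles):
            band = table.band_for_age(int(age) + t)
            r = rng.random(m)
            nxt = (cum[band][states] < r[:, None]).sum(axis=1)
            d = discount_factor(rate, t)
            if half_cycle:
                cost_tot[idx] += d * 0.5 * (cost_vec[states] + cost_vec[nxt])
                qaly_tot[idx] += d * 0.5 * (util_vec[states] + util_vec[nxt])
            else:
                cost_tot[idx] += d * cost_vec[states]
                qaly_tot[idx] += d * util_vec[states]
            states = nxt

    se = {
        "cost": float(cost_tot.std(ddof=1) / np.sqrt(n_individuals)) if n_individuals > 1 else 0.0,
        "qaly": float(qaly_tot.std(ddof=1) / np.sqrt(n_individuals)) if n_individuals > 1 else 0.0,
    }
    return ArmOutcome(
        total_cost=float(cost_tot.mean()),
        total_qaly=float(qaly_tot.mean()),
        mc_standard_error=se,
    )


def run_strategy(
    params: ModelParameters,
    strategy: ScreeningStrategy,
    mode: Literal["cohort", "microsim"] = "cohort",
    *,
    n_individuals: int = 100_000,
    seed: int = 0,
    half_cycle: bool = True,
    arm_outcomes: Mapping[str, ArmOutcome] | None = None,
) -> ArmOutcome:
    """Strategy-level totals: decision-tree mixture of the three arm runs plus
    the screening-stage cost (incurred at time zero, undiscounted).

    ``arm_outcomes`` lets a caller share the (strategy-independent) arm runs
    across strategies; otherwise they are computed here in the chosen mode.
    """
    cls = classify(params.setting.prevalence, strategy, params.costs)
    if arm_outcomes is None:
        arm_outcomes = compute_arm_outcomes(
            params, mode=mode, n_individuals=n_individuals, seed=seed, half_cycle=half_cycle
        )
    w = {
        "diagnosed": cls.p_diagnosed,
        "missed": cls.p_missed,
        "negative": cls.p_misdiagnosed + cls.p_true_negative,
    }
    cost = cls.screening_cost_per_capita + sum(
        w[a] * arm_outcomes[a].total_cost for a in w
    )
    qaly = sum(w[a] * arm_outcomes[a].total_qaly for a in w)
    se = None
    if all(arm_outcomes[a].mc_standard_error for a in w):
        se = {
            k: float(
                np.sqrt(sum((w[a] * arm_outcomes[a].mc_standard_error[k]) ** 2 for a in w))
            )
            for k in ("cost", "qaly")
        }
    return ArmOutcome(total_cost=float(cost), total_qaly=float(qaly), mc_standard_error=se)


def compute_arm_outcomes(
    params: ModelParameters,
    mode: Literal["cohort", "microsim"] = "cohort",
    *,
    n_individuals: int = 100_000,
    seed: int = 0,
    half_cycle: bool = True,
) -> dict[str, ArmOutcome]:
    """The three strategy-independent arm outcomes for one setting."""
    out: dict[str, ArmOutcome] = {}
    for i, arm in enumerate(("diagnosed", "missed", "negative")):
        if mode == "cohort":
            out[arm] = arm_expected_outcome(params, arm, half_cycle=half_cycle)
        else:
            out[arm] = run_microsimulation(
                params, arm, n_individuals, seed + i, half_cycle=half_cycle
            )
    return out


def evaluate_setting(
    params: ModelParameters,
    mode: Literal["cohort", "microsim"] = "cohort",
    *,
    n_individuals: int = 100_000,
    seed: int = 0,
    half_cycle: bool = True,
) -> dict[str, ArmOutcome]:
    """Strategy-level outcomes for every strategy in the bundle, sharing the
    three arm runs."""
    arms = compute_arm_outcomes(
        params, mode=mode, n_individuals=n_individuals, seed=seed, half_cycle=half_cycle
    )
    return {
        s.name: run_strategy(params, s, mode, arm_outcomes=arms, half_cycle=half_cycle)
        for s in params.strategies
    }
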