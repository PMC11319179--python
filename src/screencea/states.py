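"""Health states of the disease-progression models.

The positive-screen model (Markov "+") tracks a diagnosed or missed type 2
diabetes patient through complication states; the negative model (Markov "-")
is the two-state sub-chain {NON_DM, DEATH} of the same state space.

Macrovascular complications: cardiovascular disease (CVD) and stroke.
Microvascular complications: diabetic kidney disease (DKD), diabetic foot
ulcer (DFU), diabetic retinopathy (DR) and diabetic peripheral neuropathy
(DPN).  DKD, DFU and DR can each progress to a severe sequela (end-stage
renal disease, amputation, blindness).  Any diabetic state other than the
sequela-free ones can accumulate into a single lumped multi-complication
state.  DEATH is absorbing.
"""

from __future__ import annotations

from enum import Enum


class StateClass(str, Enum):
    NONE = "none"
    MACROVASCULAR = "macrovascular"
    MICROVASCULAR = "microvascular"
    TERMINAL = "terminal"


class HealthState(str, Enum):
    NON_DM = "NON_DM"
    DM_NO_COMP = "DM_NO_COMP"
    DM_CVD = "DM_CVD"
    DM_STROKE = "DM_STROKE"
    DM_DKD = "DM_DKD"
    DM_ESRD = "DM_ESRD"
    DM_DFU = "DM_DFU"
    DM_AMPUTATION = "DM_AMPUTATION"
    DM_DR = "DM_DR"
    DM_BLINDNESS = "DM_BLINDNESS"
    DM_DPN = "DM_DPN"
    DM_MULTI_COMP = "DM_MULTI_COMP"
    DEATH = "DEATH"


#: Canonical state order used for occupancy vectors and transition matrices.
STATE_ORDER: tuple[HealthState, ...] = tuple(HealthState)

STATE_INDEX: dict[HealthState, int] = {s: i for i, s in enumerate(STATE_ORDER)}

N_STATES = len(STATE_ORDER)

CLASS_TAG: dict[HealthState, StateClass] = {
    HealthState.NON_DM: StateClass.NONE,
    HealthState.DM_NO_COMP: StateClass.NONE,
    HealthState.DM_CVD: StateClass.MACROVASCULAR,
    HealthState.DM_STROKE: StateClass.MACROVASCULAR,
    HealthState.DM_DKD: StateClass.MICROVASCULAR,
    HealthState.DM_ESRD: StateClass.MICROVASCULAR,
    HealthState.DM_DFU: StateClass.MICROVASCULAR,
    HealthState.DM_AMPUTATION: StateClass.MICROVASCULAR,
    HealthState.DM_DR: StateClass.MICROVASCULAR,
    HealthState.DM_BLINDNESS: StateClass.MICROVASCULAR,
    HealthState.DM_DPN: StateClass.MICROVASCULAR,
    # Lumped multi-complication: not separately classified clinically; tagged
    # microvascular so hazard-ratio adjustment applies the larger multiplier.
    HealthState.DM_MULTI_COMP: StateClass.MICROVASCULAR,
    HealthState.DEATH: StateClass.TERMINAL,
}

#: Severe-sequela progressions: only these parents can reach the child state.
PROGRESSION: dict[HealthState, HealthState] = {
    HealthState.DM_DKD: HealthState.DM_ESRD,
    HealthState.DM_DFU: HealthState.DM_AMPUTATION,
    HealthState.DM_DR: HealthState.DM_BLINDNESS,
}

_PRIMARY_COMPLICATIONS = (
    HealthState.DM_CVD,
    HealthState.DM_STROKE,
    HealthState.DM_DKD,
    HealthState.DM_DFU,
    HealthState.DM_DR,
    HealthState.DM_DPN,
)

DIABETIC_STATES: frozenset[HealthState] = frozenset(
    s for s in HealthState if s not in (HealthState.NON_DM, HealthState.DEATH)
)


def _build_allowed() -> dict[HealthState, frozenset[HealthState]]:
    allowed: dict[HealthState, set[HealthState]] = {}
    D, M = HealthState.DEATH, HealthState.DM_MULTI_COMP
    allowed[HealthState.NON_DM] = {HealthState.NON_DM, D}
    allowed[D] = {D}
    allowed[HealthState.DM_NO_COMP] = {HealthState.DM_NO_COMP, *_PRIMARY_COMPLICATIONS, M, D}
    for s in _PRIMARY_COMPLICATIONS:
        allowed[s] = {s, M, D}
        if s in PROGRESSION:
            allowed[s].add(PROGRESSION[s])
    for s in PROGRESSION.values():
        allowed[s] = {s, M, D}
    allowed[M] = {M, D}
    return {s: frozenset(t) for s, t in allowed.items()}


ALLOWED_TRANSITIONS: dict[HealthState, frozenset[HealthState]] = _build_allowed()


def allowed_transitions(state: HealthState) -> frozenset[HealthState]:
    """Set of states reachable from ``state`` in one cycle (incl. self)."""
    return ALLOWED_TRANSITIONS[HealthState(state)]


def is_allowed(frm: HealthState, to: HealthState) -> bool:
    return HealthState(to) in ALLOWED_TRANSITIONS[HealthState(frm)]
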