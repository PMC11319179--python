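"""Parameter bundle for one screening setting, with validation and I/O.

A :class:`ModelParameters` object holds everything one analysis setting
(urban or rural) needs: undiagnosed-diabetes prevalence, the three screening
strategies' test characteristics and per-test cost components, age-banded
annual transition probabilities, annual state costs, state utility weights,
hazard-ratio multipliers for missed diagnosis and rural residence, the
discount rate, the willingness-to-pay threshold and the baseline population.

Files are JSON or YAML (chosen by suffix); a JSON Schema for the format is
shipped in ``schema/parameters.schema.json`` and regenerable with
:func:`export_schema`.

Hazard-ratio adjustment multiplies annual transition probabilities directly
(the convention of the source estimates), caps each product at 1, and
re-closes every row through the stay probability; if the adjusted outflows
of a row exceed 1 they are rescaled proportionally and a warning is logged.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .states import (
    CLASS_TAG,
    DIABETIC_STATES,
    N_STATES,
    STATE_INDEX,
    STATE_ORDER,
    HealthState,
    StateClass,
    is_allowed,
)

logger = logging.getLogger(__name__)

AGE_MIN = 18

#: Rural-versus-urban hazard ratios for complication incidence.
DEFAULT_RURAL_HR: dict[str, float] = {
    "DM_CVD": 1.15,
    "DM_STROKE": 1.25,
    "DM_BLINDNESS": 2.09,
    "DM_DFU": 1.42,
    "DM_ESRD": 1.15,
}


class StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=False)


class ScreeningStrategy(StrictModel):
    """One screening test: diagnostic accuracy and per-test cost components.

    Costs are USD per screened person, split the way a societal-perspective
    costing splits them: direct medical (registration, reagents, staff time),
    direct non-medical (travel, lodging) and indirect (participant time).
    """

    name: Literal["POCT_HBA1C", "VENOUS_HBA1C", "FCG"]
    sensitivity: float = Field(ge=0.0, le=1.0)
    specificity: float = Field(ge=0.0, le=1.0)
    cut_point_text: str = ""
    cost_direct_medical: float = Field(ge=0.0)
    cost_direct_nonmedical: float = Field(ge=0.0)
    cost_indirect: float = Field(ge=0.0)

    @property
    def cost_per_test(self) -> float:
        return self.cost_direct_medical + self.cost_direct_nonmedical + self.cost_indirect


class Setting(StrictModel):
    label: Literal["urban", "rural"]
    prevalence: float
    rural_hr: dict[str, float] = Field(default_factory=dict)

    @field_validator("prevalence")
    @classmethod
    def _prev_open_unit(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError("prevalence must lie strictly inside (0, 1)")
        return v

    @model_validator(mode="after")
    def _check_hr(self) -> "Setting":
        for key, hr in self.rural_hr.items():
            _parse_hr_key(key)
            if hr <= 0:
                raise ValueError(f"rural_hr[{key!r}] must be > 0")
        if self.label == "urban" and any(v != 1.0 for v in self.rural_hr.values()):
            raise ValueError("urban setting must have all rural_hr equal to 1.0")
        return self


class MissedDiagnosisHR(StrictModel):
    """Hazard ratios penalising untreated (missed) diabetes.

    Defaults follow cohort estimates for poorly controlled glycaemia:
    microvascular 1.391, macrovascular 1.287, death 1.290.
    """

    hr_micro: float = Field(default=1.391, gt=0.0)
    hr_macro: float = Field(default=1.287, gt=0.0)
    hr_death: float = Field(default=1.290, gt=0.0)


def _parse_hr_key(key: str) -> tuple[HealthState | None, HealthState]:
    """Parse a transition identifier: either ``"TO_STATE"`` (all transitions
    into that state) or ``"FROM->TO"`` (one specific transition)."""
    if "->" in key:
        frm_s, to_s = key.split("->", 1)
        try:
            frm, to = HealthState(frm_s), HealthState(to_s)
        except ValueError as exc:
            raise ValueError(f"unknown transition identifier {key!r}") from exc
        if not is_allowed(frm, to):
            raise ValueError(f"transition {key!r} is structurally impossible")
        return frm, to
    try:
        return None, HealthState(key)
    except ValueError as exc:
        raise ValueError(f"unknown transition identifier {key!r}") from exc


class TransitionTable(StrictModel):
    """Age-banded annual transition probabilities.

    ``age_bands`` is an ordered partition of [18, 80) into ``[low, high)``
    intervals (a single band makes the table age-constant).  ``entries`` maps
    ``"FROM->TO"`` to one probability per band.  Rows must sum to 1 within
    1e-6 before normalisation; they are stored exactly re-closed.  Pairs not
    permitted by the progression structure are rejected.
    """

    age_bands: list[tuple[int, int]]
    entries: dict[str, tuple[float, ...]]

    @model_validator(mode="after")
    def _validate(self) -> "TransitionTable":
        bands = self.age_bands
        if not bands:
            raise ValueError("age_bands must be non-empty")
        if bands[0][0] != AGE_MIN or bands[-1][1] != 80:
            raise ValueError("age_bands must span [18, 80)")
        for (lo, hi), (lo2, _hi2) in zip(bands, bands[1:]):
            if hi != lo2 or lo >= hi:
                raise ValueError("age_bands must be an ordered contiguous partition")
        if bands[-1][0] >= bands[-1][1]:
            raise ValueError("age_bands must be an ordered contiguous partition")

        nb = len(bands)
        parsed: dict[tuple[HealthState, HealthState], tuple[float, ...]] = {}
        for key, probs in self.entries.items():
            frm, to = _parse_entry_key(key)
            if len(probs) != nb:
                raise ValueError(f"entry {key!r} must give one probability per age band")
            for p in probs:
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"entry {key!r} has probability outside [0, 1]")
            parsed[(frm, to)] = tuple(probs)

        # Re-close each (from_state, band) row exactly; reject rows that are
        # off by more than 1e-6 before normalisation.
        froms = {frm for frm, _ in parsed}
        new_entries: dict[str, tuple[float, ...]] = {}
        for frm in froms:
            tos = [to for f, to in parsed if f == frm]
            cols = {to: list(parsed[(frm, to)]) for to in tos}
            for b in range(nb):
                total = sum(cols[to][b] for to in tos)
                if abs(total - 1.0) > 1e-6:
                    raise ValueError(
                        f"transition row from {frm.value}, age band {bands[b]} "
                        f"sums to {total:.8f}, not 1"
                    )
                # normalize, but leave rows already exact to ~1 ulp untouched
                # so that validation is a fixed point and files round-trip
                if abs(total - 1.0) > 1e-12:
                    for to in tos:
                        cols[to][b] /= total
            for to in tos:
                new_entries[f"{frm.value}->{to.value}"] = tuple(cols[to][b] for b in range(nb))
        object.__setattr__(self, "entries", new_entries)
        return self

    # -- accessors ---------------------------------------------------------

    @property
    def n_bands(self) -> int:
        return len(self.age_bands)

    def band_for_age(self, age: float) -> int:
        for i, (lo, hi) in enumerate(self.age_bands):
            if lo <= age < hi:
                return i
        if age >= self.age_bands[-1][1]:
            return len(self.age_bands) - 1
        raise ValueError(f"age {age} below the first age band")

    def prob(self, frm: HealthState, to: HealthState, band: int = 0) -> float:
        key = f"{HealthState(frm).value}->{HealthState(to).value}"
        entry = self.entries.get(key)
        return entry[band] if entry is not None else 0.0

    def matrices(self) -> np.ndarray:
        """Stack of row-stochastic matrices, shape ``(n_bands, 13, 13)``.

        States with no explicit row get a self-loop of 1.
        """
        mats = np.zeros((self.n_bands, N_STATES, N_STATES))
        has_row = np.zeros(N_STATES, dtype=bool)
        for key, probs in self.entries.items():
            frm, to = _parse_entry_key(key)
            i, j = STATE_INDEX[frm], STATE_INDEX[to]
            has_row[i] = True
            mats[:, i, j] = probs
        for i in range(N_STATES):
            if not has_row[i]:
                mats[:, i, i] = 1.0
        return mats


def _parse_entry_key(key: str) -> tuple[HealthState, HealthState]:
    if "->" not in key:
        raise ValueError(f"transition entry key {key!r} must be 'FROM->TO'")
    frm_s, to_s = key.split("->", 1)
    try:
        frm, to = HealthState(frm_s), HealthState(to_s)
    except ValueError as exc:
        raise ValueError(f"transition entry {key!r} names an unknown state") from exc
    if not is_allowed(frm, to):
        raise ValueError(f"transition entry {key!r} violates the progression structure")
    return frm, to


class CostSet(StrictModel):
    """Annual state costs (USD/year, direct medical for complication states),
    the confirmatory OGTT cost and the CNY/USD conversion rate used when
    ingesting CNY-denominated inputs."""

    state_annual_cost: dict[HealthState, float]
    ogtt_cost: float = Field(ge=0.0)
    currency_rate: float = Field(default=6.4, gt=0.0)

    @model_validator(mode="after")
    def _check(self) -> "CostSet":
        for state, c in self.state_annual_cost.items():
            if c < 0:
                raise ValueError(f"state_annual_cost[{state.value}] must be >= 0")
        if self.state_annual_cost.get(HealthState.DEATH, 0.0) != 0.0:
            raise ValueError("DEATH annual cost must be 0")
        return self

    def cost_vector(self) -> np.ndarray:
        return np.array([self.state_annual_cost.get(s, 0.0) for s in STATE_ORDER])


class UtilitySet(StrictModel):
    """QALY weight per year in each state; DEATH is 0, NON_DM the ceiling."""

    state_utility: dict[HealthState, float]

    @model_validator(mode="after")
    def _check(self) -> "UtilitySet":
        for state, u in self.state_utility.items():
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"state_utility[{state.value}] must lie in [0, 1]")
        if self.state_utility.get(HealthState.DEATH, 0.0) != 0.0:
            raise ValueError("DEATH utility must be 0")
        non_dm = self.state_utility.get(HealthState.NON_DM, 1.0)
        no_comp = self.state_utility.get(HealthState.DM_NO_COMP, non_dm)
        if no_comp > non_dm:
            warnings.warn("utility ordering violated: DM_NO_COMP > NON_DM", stacklevel=2)
        for state, u in self.state_utility.items():
            if state in DIABETIC_STATES and state != HealthState.DM_NO_COMP and u > no_comp:
                warnings.warn(
                    f"utility ordering violated: {state.value} > DM_NO_COMP", stacklevel=2
                )
        return self

    def utility_vector(self) -> np.ndarray:
        return np.array([self.state_utility.get(s, 0.0) for s in STATE_ORDER])


class DiscountSpec(StrictModel):
    rate: float = 0.05
    sensitivity_range: tuple[float, float] = (0.0, 0.08)

    @model_validator(mode="after")
    def _check(self) -> "DiscountSpec":
        lo, hi = self.sensitivity_range
        if not 0.0 <= lo <= self.rate <= hi <= 1.0:
            raise ValueError("require 0 <= low <= rate <= high <= 1 for the discount rate")
        return self


class WTPSpec(StrictModel):
    """Willingness-to-pay threshold, by default derived as a GDP multiple."""

    gdp_per_capita: float = Field(default=12_551.0, gt=0.0)
    multiplier: int = Field(default=3, ge=1)
    lambda_wtp: float | None = Field(default=None, gt=0.0)

    @property
    def value(self) -> float:
        """λ in USD/QALY: explicit if given, else multiplier × GDP per capita."""
        if self.lambda_wtp is not None:
            return self.lambda_wtp
        return self.multiplier * self.gdp_per_capita


class ModelParameters(StrictModel):
    """Complete parameter bundle for one setting."""

    setting: Setting
    strategies: list[ScreeningStrategy]
    transitions: TransitionTable
    costs: CostSet
    utilities: UtilitySet
    missed_hr: MissedDiagnosisHR = Field(default_factory=MissedDiagnosisHR)
    discount: DiscountSpec = Field(default_factory=DiscountSpec)
    wtp: WTPSpec = Field(default_factory=WTPSpec)
    baseline_population: list[tuple[int, Literal["M", "F"], float]]
    horizon_age: int = 80
    cycle_length: int = 1

    @model_validator(mode="after")
    def _check(self) -> "ModelParameters":
        if self.cycle_length != 1:
            raise ValueError("cycle_length is fixed at 1 year")
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            raise ValueError("duplicate strategy names")
        if not self.baseline_population:
            raise ValueError("baseline_population must be non-empty")
        total = sum(w for _, _, w in self.baseline_population)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"baseline_population weights sum to {total}, not 1")
        if abs(total - 1.0) > 1e-12:  # renormalise only when meaningfully off
            object.__setattr__(
                self,
                "baseline_population",
                [(a, s, w / total) for a, s, w in self.baseline_population],
            )
        for age, _sex, _w in self.baseline_population:
            if not AGE_MIN <= age <= self.horizon_age:
                raise ValueError(f"baseline age {age} outside [18, {self.horizon_age}]")
        return self

    def strategy(self, name: str) -> ScreeningStrategy:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"no strategy named {name!r}")

    def age_weights(self) -> dict[int, float]:
        """Baseline population collapsed over sex to weight per start age."""
        out: dict[int, float] = {}
        for age, _sex, w in self.baseline_population:
            out[age] = out.get(age, 0.0) + w
        return dict(sorted(out.items()))


# ---------------------------------------------------------------------------
# Hazard-ratio application
# ---------------------------------------------------------------------------


def _apply_multipliers(
    table: TransitionTable,
    multiplier: "callable[[HealthState, HealthState], float]",
) -> TransitionTable:
    """Multiply off-diagonal transition probabilities, cap at 1 and re-close
    each row via the stay probability; proportionally rescale outflows (with a
    logged warning) in the degenerate case where they exceed 1."""
    nb = table.n_bands
    parsed = {
        _parse_entry_key(k): list(v) for k, v in table.entries.items()
    }
    froms = {frm for frm, _ in parsed}
    changed = False
    for frm in froms:
        tos = [to for f, to in parsed if f == frm]
        for b in range(nb):
            out: dict[HealthState, float] = {}
            for to in tos:
                if to == frm:
                    continue
                m = multiplier(frm, to)
                p = parsed[(frm, to)][b]
                out[to] = min(1.0, p * m)
                if m != 1.0 and p > 0.0:
                    changed = True
            total_out = sum(out.values())
            if total_out > 1.0:
                logger.warning(
                    "adjusted outflows from %s (band %s) sum to %.6f > 1; "
                    "rescaling proportionally and zeroing the stay probability",
                    frm.value,
                    table.age_bands[b],
                    total_out,
                )
                for to in out:
                    out[to] /= total_out
                total_out = 1.0
            for to, p in out.items():
                parsed[(frm, to)][b] = p
            if (frm, frm) in parsed:
                parsed[(frm, frm)][b] = 1.0 - total_out
            elif total_out > 0.0:
                raise ValueError(
                    f"row from {frm.value} has outflows but no stay entry to re-close"
                )
    if not changed:
        return table
    entries = {f"{f.value}->{t.value}": tuple(v) for (f, t), v in parsed.items()}
    return TransitionTable(age_bands=list(table.age_bands), entries=entries)


def apply_missed_diagnosis_hr(table: TransitionTable, hr: MissedDiagnosisHR) -> TransitionTable:
    """Penalise untreated diabetes: transitions from diabetic states into
    microvascular-class states ×hr_micro, macrovascular ×hr_macro and DEATH
    ×hr_death.  Background (NON_DM) mortality is left untouched."""

    def mult(frm: HealthState, to: HealthState) -> float:
        if frm not in DIABETIC_STATES:
            return 1.0
        tag = CLASS_TAG[to]
        if tag is StateClass.MICROVASCULAR:
            return hr.hr_micro
        if tag is StateClass.MACROVASCULAR:
            return hr.hr_macro
        if to is HealthState.DEATH:
            return hr.hr_death
        return 1.0

    return _apply_multipliers(table, mult)


def apply_rural_hr(table: TransitionTable, setting: Setting) -> TransitionTable:
    """Apply the setting's rural hazard ratios; urban settings return the
    table unchanged.  Map keys are either a destination state (all transitions
    into it) or a specific ``"FROM->TO"`` pair; the specific key wins."""
    if setting.label == "urban":
        return table
    by_to: dict[HealthState, float] = {}
    by_pair: dict[tuple[HealthState, HealthState], float] = {}
    for key, hr in setting.rural_hr.items():
        frm, to = _parse_hr_key(key)
        if frm is None:
            by_to[to] = hr
        else:
            by_pair[(frm, to)] = hr

    def mult(frm: HealthState, to: HealthState) -> float:
        if (frm, to) in by_pair:
            return by_pair[(frm, to)]
        return by_to.get(to, 1.0)

    return _apply_multipliers(table, mult)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_parameters(path: str | Path) -> ModelParameters:
    """Read and validate a parameter file (JSON or YAML by suffix)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return ModelParameters.model_validate(data)


def write_parameters(params: ModelParameters, path: str | Path) -> None:
    """Serialise a parameter bundle; round-trips exactly through
    :func:`load_parameters`."""
    path = Path(path)
    data = params.model_dump(mode="json")
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def import_transitions_csv(path: str | Path) -> TransitionTable:
    """Build a transition table from a CSV with columns
    ``from_state,to_state,age_low,age_high,probability``."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"from_state", "to_state", "age_low", "age_high", "probability"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"transition CSV missing columns: {sorted(missing)}")
    bands = sorted(
        {(int(lo), int(hi)) for lo, hi in zip(df["age_low"], df["age_high"])}
    )
    band_index = {b: i for i, b in enumerate(bands)}
    entries: dict[str, list[float]] = {}
    for _, row in df.iterrows():
        key = f"{row['from_state']}->{row['to_state']}"
        entries.setdefault(key, [0.0] * len(bands))
        entries[key][band_index[(int(row["age_low"]), int(row["age_high"]))]] = float(
            row["probability"]
        )
    return TransitionTable(
        age_bands=bands, entries={k: tuple(v) for k, v in entries.items()}
    )


def export_schema(path: str | Path) -> None:
    """Write the JSON Schema of the parameter file format."""
    Path(path).write_text(json.dumps(ModelParameters.model_json_schema(), indent=2))
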