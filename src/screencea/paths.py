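"""Dotted-path access into a :class:`~screencea.params.ModelParameters`.

Sensitivity analyses need to perturb single parameters generically.  A
parameter id is a dotted path such as::

    setting.prevalence
    discount.rate
    costs.ogtt_cost
    costs.state_annual_cost.DM_CVD
    utilities.state_utility.DM_NO_COMP
    missed_hr.hr_micro
    strategies.POCT_HBA1C.sensitivity
    transitions.DM_NO_COMP->DM_STROKE

A transition path addresses one (from, to) pair across all age bands:
reading returns the first band's value; writing rescales every band by the
same factor (or sets all bands when the first band is zero), caps at 1 and
re-closes the row through the stay probability (proportional rescaling of
outflows if they exceed 1, matching the hazard-ratio contract).
"""

from __future__ import annotations

from typing import Any, Mapping

from .params import ModelParameters

_PROBABILITY_PREFIXES = ("transitions.",)
_PROBABILITY_EXACT_SUFFIXES = (".sensitivity", ".specificity")


def is_probability_path(path: str) -> bool:
    """Whether the addressed quantity must live in [0, 1]."""
    if path == "setting.prevalence" or path.startswith("utilities."):
        return True
    if path.startswith(_PROBABILITY_PREFIXES):
        return True
    return path.endswith(_PROBABILITY_EXACT_SUFFIXES)


def _strategy_dict(data: dict, name: str) -> dict:
    for s in data["strategies"]:
        if s["name"] == name:
            return s
    raise KeyError(f"no strategy named {name!r}")


def _resolve(data: dict, path: str) -> tuple[Any, str]:
    """Container and final key for a non-transition path."""
    parts = path.split(".")
    if parts[0] == "strategies":
        if len(parts) != 3:
            raise KeyError(f"bad strategy path {path!r}")
        return _strategy_dict(data, parts[1]), parts[2]
    node: Any = data
    for p in parts[:-1]:
        node = node[p]
    if parts[-1] not in node:
        raise KeyError(f"unknown parameter path {path!r}")
    return node, parts[-1]


def get_param(params: ModelParameters, path: str) -> float:
    data = params.model_dump(mode="json")
    if path.startswith("transitions."):
        key = path[len("transitions."):]
        entries = data["transitions"]["entries"]
        if key not in entries:
            raise KeyError(f"unknown transition {key!r}")
        return float(entries[key][0])
    node, key = _resolve(data, path)
    return float(node[key])


def _set_transition(entries: dict[str, list[float]], key: str, value: float) -> None:
    if key not in entries:
        raise KeyError(f"unknown transition {key!r}")
    frm = key.split("->", 1)[0]
    old = entries[key]
    base = old[0]
    if base > 0:
        scale = value / base
        new = [min(1.0, p * scale) for p in old]
    else:
        new = [min(1.0, value)] * len(old)
    entries[key] = new
    # re-close the row band by band via the stay probability
    self_key = f"{frm}->{frm}"
    row_keys = [k for k in entries if k.startswith(frm + "->") and k != self_key]
    n_bands = len(old)
    for b in range(n_bands):
        out = sum(entries[k][b] for k in row_keys)
        if out > 1.0:
            for k in row_keys:
                entries[k][b] /= out
            out = 1.0
        if self_key in entries:
            entries[self_key][b] = 1.0 - out
        elif out > 0:
            raise ValueError(f"row from {frm} has no stay entry to re-close")


def set_params(params: ModelParameters, updates: Mapping[str, float]) -> ModelParameters:
    """Return a new, re-validated bundle with the given parameters replaced."""
    data = params.model_dump(mode="json")  # fresh nested containers
    for path, value in updates.items():
        if path.startswith("transitions."):
            _set_transition(
                data["transitions"]["entries"], path[len("transitions."):], float(value)
            )
        else:
            node, key = _resolve(data, path)
            node[key] = float(value)
    return ModelParameters.model_validate(data)


def set_param(params: ModelParameters, path: str, value: float) -> ModelParameters:
    return set_params(params, {path: value})
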