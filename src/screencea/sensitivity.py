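"""One-way and probabilistic sensitivity analysis.

One-way (OWSA): each parameter is pushed to the low and high end of its range
(reported 95% CI where available, otherwise ±20% of the base value) with all
others held at base, the full pipeline is re-run, and the resulting ICUR pair
forms one tornado-diagram bar.

Probabilistic (PSA): every parameter gets a distribution — Beta(α, β) with α
the event count and β the non-event count for probabilities backed by counts,
lognormal for costs (the point estimate is the median and the draw's standard
deviation is 10% of its mean, i.e. σ = sqrt(ln(1 + 0.1²))), uniform for
everything else — and the joint model is re-evaluated per draw, the paper's
convention being 1,000 iterations.  Each draw is seeded from
``(seed, draw_index)`` so individual draws are reproducible in isolation.
The cost-effectiveness acceptability curve (CEAC) reports, for each
willingness-to-pay λ, the fraction of draws with positive net monetary
benefit λ·ΔE − ΔC (ties count as not cost-effective).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import DEFAULT_COMPARISONS, compute_icur
from .markov import evaluate_setting
from .params import ModelParameters
from .paths import get_param, is_probability_path, set_params
from .states import HealthState

logger = logging.getLogger(__name__)

#: σ giving a lognormal coefficient of variation of exactly 10%.
LOGNORMAL_SIGMA_10PCT = math.sqrt(math.log(1.0 + 0.1**2))


@dataclass(frozen=True)
class ParamRange:
    parameter_id: str
    low: float
    high: float
    source: Literal["reported_95CI", "pm20pct"] = "pm20pct"


@dataclass(frozen=True)
class PSADistribution:
    kind: Literal["beta", "lognormal", "uniform"]
    alpha: float | None = None
    beta_count: float | None = None
    mu: float | None = None
    sigma: float | None = None
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "beta":
            if not (self.alpha and self.alpha > 0 and self.beta_count and self.beta_count > 0):
                raise ValueError("beta distribution needs alpha > 0 and beta_count > 0")
        elif self.kind == "lognormal":
            if self.sigma is None or self.sigma <= 0 or self.mu is None:
                raise ValueError("lognormal distribution needs mu and sigma > 0")
        elif self.kind == "uniform":
            if self.low is None or self.high is None or not self.low < self.high:
                raise ValueError("uniform distribution needs low < high")
        else:
            raise ValueError(f"unknown distribution kind {self.kind!r}")

    @property
    def mean(self) -> float:
        if self.kind == "beta":
            return self.alpha / (self.alpha + self.beta_count)
        if self.kind == "lognormal":
            return math.exp(self.mu + self.sigma**2 / 2.0)
        return 0.5 * (self.low + self.high)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.kind == "beta":
            return rng.beta(self.alpha, self.beta_count, size=size)
        if self.kind == "lognormal":
            return rng.lognormal(self.mu, self.sigma, size=size)
        return rng.uniform(self.low, self.high, size=size)


@dataclass(frozen=True)
class TornadoEntry:
    parameter_id: str
    icur_at_low: float
    icur_at_high: float
    bar_width: float


@dataclass
class PSASample:
    draw_index: int
    parameters: dict[str, float]
    strategy_outcomes: dict[str, tuple[float, float]]  # name -> (cost, utility)
    deltas: dict[tuple[str, str], tuple[float, float]]  # (ref, comp) -> (dC, dE)


# ---------------------------------------------------------------------------
# Distribution fitting
# ---------------------------------------------------------------------------


def fit_beta(events: float, non_events: float) -> PSADistribution:
    """Beta distribution from counts: α = events, β = non-events.

    A zero count gets a +0.5 continuity correction; both zero is an error.
    """
    if events < 0 or non_events < 0:
        raise ValueError("counts must be non-negative")
    if events == 0 and non_events == 0:
        raise ValueError("at least one count must be positive")
    a = events if events > 0 else 0.5
    b = non_events if non_events > 0 else 0.5
    return PSADistribution(kind="beta", alpha=a, beta_count=b)


def fit_lognormal(point_estimate: float, cv: float = 0.10) -> PSADistribution:
    """Lognormal with the point estimate as the median (μ = ln(point)) and a
    coefficient of variation of ``cv`` (σ = sqrt(ln(1 + cv²)), so the draw's
    standard deviation is ``cv`` times its mean)."""
    if point_estimate <= 0:
        raise ValueError("point estimate must be > 0")
    return PSADistribution(
        kind="lognormal",
        mu=math.log(point_estimate),
        sigma=math.sqrt(math.log(1.0 + cv**2)),
    )


def fit_uniform_pm(base: float, fraction: float = 0.20, clip_unit: bool = False) -> PSADistribution:
    lo, hi = base * (1 - fraction), base * (1 + fraction)
    if clip_unit:
        lo, hi = max(0.0, lo), min(1.0, hi)
    return PSADistribution(kind="uniform", low=lo, high=hi)


# ---------------------------------------------------------------------------
# Parameter enumeration and defaults
# ---------------------------------------------------------------------------


def enumerate_parameter_paths(params: ModelParameters) -> list[str]:
    """All scalar parameter ids the sensitivity analyses vary by default."""
    paths: list[str] = ["setting.prevalence", "discount.rate", "costs.ogtt_cost"]
    for s in params.strategies:
        paths.append(f"strategies.{s.name}.sensitivity")
        paths.append(f"strategies.{s.name}.specificity")
        for f in ("cost_direct_medical", "cost_direct_nonmedical", "cost_indirect"):
            if getattr(s, f) > 0:
                paths.append(f"strategies.{s.name}.{f}")
    for state, c in params.costs.state_annual_cost.items():
        if c > 0:
            paths.append(f"costs.state_annual_cost.{state.value}")
    for state, u in params.utilities.state_utility.items():
        if 0 < u <= 1 and state != HealthState.DEATH:
            paths.append(f"utilities.state_utility.{state.value}")
    for f in ("hr_micro", "hr_macro", "hr_death"):
        paths.append(f"missed_hr.{f}")
    for key, probs in params.transitions.entries.items():
        frm, to = key.split("->", 1)
        if frm != to and probs[0] > 0:
            paths.append(f"transitions.{key}")
    return sorted(set(paths))


def pm20_range(params: ModelParameters, path: str, fraction: float = 0.20) -> ParamRange:
    base = get_param(params, path)
    lo, hi = base * (1 - fraction), base * (1 + fraction)
    if is_probability_path(path):
        lo, hi = max(0.0, lo), min(1.0, hi)
    return ParamRange(parameter_id=path, low=lo, high=hi, source="pm20pct")


def default_owsa_ranges(params: ModelParameters) -> list[ParamRange]:
    """±20% on every varied parameter, except the discount rate, which uses
    its declared sensitivity range (0–8% by default)."""
    ranges = []
    for path in enumerate_parameter_paths(params):
        if path == "discount.rate":
            lo, hi = params.discount.sensitivity_range
            ranges.append(ParamRange(parameter_id=path, low=lo, high=hi, source="reported_95CI"))
        else:
            ranges.append(pm20_range(params, path))
    return ranges


def default_psa_distributions(
    params: ModelParameters, effective_sample_size: float = 1000.0
) -> dict[str, PSADistribution]:
    """Synthetic PSA mapping: beta (via pseudo-counts at the given effective
    sample size) for prevalence, Se/Sp and transition probabilities;
    lognormal for costs; uniform ±20% for utilities and hazard ratios.
    The discount rate is held fixed in the PSA."""
    dists: dict[str, PSADistribution] = {}
    for path in enumerate_parameter_paths(params):
        if path == "discount.rate":
            continue
        base = get_param(params, path)
        if path.startswith(("costs.",)) or path.endswith(
            ("cost_direct_medical", "cost_direct_nonmedical", "cost_indirect")
        ):
            if base > 0:
                dists[path] = fit_lognormal(base)
        elif path.startswith("utilities.") or path.startswith("missed_hr."):
            if base > 0:
                dists[path] = fit_uniform_pm(
                    base, clip_unit=path.startswith("utilities.")
                )
        elif is_probability_path(path) or path == "setting.prevalence":
            if 0 < base < 1:
                dists[path] = fit_beta(
                    base * effective_sample_size, (1 - base) * effective_sample_size
                )
    return dists


# ---------------------------------------------------------------------------
# One-way sensitivity analysis
# ---------------------------------------------------------------------------


def _evaluate_icur(
    params: ModelParameters, comparison: tuple[str, str]
) -> float:
    ref, comp = comparison
    outcomes = evaluate_setting(params)
    res = compute_icur(outcomes[ref], outcomes[comp], params.wtp, ref, comp)
    return res.icur if res.icur is not None else float("nan")


def owsa(
    params: ModelParameters,
    ranges: Sequence[ParamRange],
    comparison: tuple[str, str],
) -> list[TornadoEntry]:
    """Tornado data: ICUR at each range endpoint, sorted by descending bar
    width (ties broken by parameter id).

    An endpoint whose perturbed bundle fails validation is skipped with a
    logged warning and recorded as NaN; the bar width then falls back to the
    distance between the valid endpoint and the base-case ICUR.
    """
    base_icur = _evaluate_icur(params, comparison)
    entries: list[TornadoEntry] = []
    for rng_spec in ranges:
        endpoint_icurs: list[float] = []
        for value in (rng_spec.low, rng_spec.high):
            try:
                # a +-20% push on one utility may transiently break the
                # utility ladder; expected here, so soft warnings are muted
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    perturbed = set_params(params, {rng_spec.parameter_id: value})
                endpoint_icurs.append(_evaluate_icur(perturbed, comparison))
            except (ValueError, KeyError) as exc:
                logger.warning(
                    "OWSA endpoint %s=%s skipped: %s", rng_spec.parameter_id, value, exc
                )
                endpoint_icurs.append(float("nan"))
        lo_icur, hi_icur = endpoint_icurs
        if math.isnan(lo_icur) and math.isnan(hi_icur):
            width = 0.0
        elif math.isnan(lo_icur):
            width = abs(hi_icur - base_icur)
        elif math.isnan(hi_icur):
            width = abs(lo_icur - base_icur)
        else:
            width = abs(hi_icur - lo_icur)
        entries.append(
            TornadoEntry(
                parameter_id=rng_spec.parameter_id,
                icur_at_low=lo_icur,
                icur_at_high=hi_icur,
                bar_width=width,
            )
        )
    return sorted(entries, key=lambda e: (-e.bar_width, e.parameter_id))


def tornado_frame(entries: Sequence[TornadoEntry], ranges: Sequence[ParamRange]) -> pd.DataFrame:
    by_id = {r.parameter_id: r for r in ranges}
    return pd.DataFrame(
        {
            "parameter_id": [e.parameter_id for e in entries],
            "low": [by_id[e.parameter_id].low for e in entries],
            "high": [by_id[e.parameter_id].high for e in entries],
            "icur_low": [e.icur_at_low for e in entries],
            "icur_high": [e.icur_at_high for e in entries],
            "width": [e.bar_width for e in entries],
        }
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


def psa(
    params: ModelParameters,
    dists: Mapping[str, PSADistribution],
    n_iter: int = 1000,
    seed: int = 0,
    comparisons: Sequence[tuple[str, str]] | None = None,
    max_redraws: int = 100,
) -> list[PSASample]:
    """Joint parameter draws propagated through the full pipeline.

    Probability-valued draws are clipped to [0, 1] (clip count logged); a
    draw whose bundle still fails validation is rejected and redrawn.  Draw
    ``i`` is generated from ``default_rng((seed, i, attempt))`` so every
    sample is reproducible independently of the rest of the run.
    """
    if comparisons is None:
        comparisons = [
            (r, c)
            for (r, c) in DEFAULT_COMPARISONS
            if any(s.name == r for s in params.strategies)
            and any(s.name == c for s in params.strategies)
        ]
    paths = sorted(dists)
    samples: list[PSASample] = []
    n_clipped = 0
    n_rejected = 0
    for i in range(n_iter):
        for attempt in range(max_redraws):
            rng = np.random.default_rng((seed, i, attempt))
            values: dict[str, float] = {}
            for path in paths:
                v = float(dists[path].sample(rng))
                if is_probability_path(path) and not 0.0 <= v <= 1.0:
                    v = min(1.0, max(0.0, v))
                    n_clipped += 1
                values[path] = v
            try:
                # independent utility draws may transiently break the utility
                # ladder; that is expected under the uniform PSA spec, so the
                # soft ordering warnings are silenced here
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    drawn = set_params(params, values)
            except (ValueError, KeyError):
                n_rejected += 1
                continue
            break
        else:
            raise RuntimeError(f"draw {i} rejected {max_redraws} times")
        outcomes = evaluate_setting(drawn)
        strat = {
            name: (out.total_cost, out.total_qaly) for name, out in outcomes.items()
        }
        deltas = {
            (r, c): (strat[c][0] - strat[r][0], strat[c][1] - strat[r][1])
            for r, c in comparisons
        }
        samples.append(
            PSASample(
                draw_index=i, parameters=values, strategy_outcomes=strat, deltas=deltas
            )
        )
    if n_clipped:
        logger.info("PSA clipped %d probability draws to [0, 1]", n_clipped)
    if n_rejected:
        logger.info("PSA rejected and redrew %d invalid draws", n_rejected)
    return samples


def psa_frame(samples: Sequence[PSASample]) -> pd.DataFrame:
    """Long-form scatter table: draw, reference, comparator, ΔC, ΔE."""
    rows = []
    for s in samples:
        for (r, c), (dc, de) in s.deltas.items():
            rows.append(
                {
                    "draw": s.draw_index,
                    "reference": r,
                    "comparator": c,
                    "delta_cost": dc,
                    "delta_utility": de,
                }
            )
    return pd.DataFrame(rows)


def ceac(
    samples: Sequence[PSASample],
    lambda_grid: Sequence[float],
    comparison: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Probability the comparator is cost-effective at each λ.

    One column per comparison: the fraction of draws with net monetary
    benefit λ·ΔE − ΔC strictly positive.
    """
    if not samples:
        raise ValueError("need at least one PSA sample")
    lambdas = np.asarray(list(lambda_grid), dtype=float)
    if lambdas.size == 0:
        raise ValueError("lambda grid must be non-empty")
    comparisons = [comparison] if comparison else list(samples[0].deltas)
    out = {"lambda": lambdas}
    for comp in comparisons:
        dc = np.array([s.deltas[comp][0] for s in samples])
        de = np.array([s.deltas[comp][1] for s in samples])
        nmb = lambdas[:, None] * de[None, :] - dc[None, :]
        out[f"p_ce_{comp[1]}_vs_{comp[0]}"] = (nmb > 0).mean(axis=1)
    return pd.DataFrame(out)


def default_lambda_grid(wtp_value: float, n_points: int = 101) -> np.ndarray:
    """0 to 3×WTP, inclusive."""
    return np.linspace(0.0, 3.0 * wtp_value, n_points)
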