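"""One-shot screening decision tree.

A screened cohort splits on true disease status (undiagnosed type 2 diabetes
prevalence ``p``) and the test result.  Screen-positives get a confirmatory
OGTT, treated as a perfect gold standard, so the four terminal arms are:

* diagnosed       p · Se            (screen+, OGTT+)  → treated Markov(+)
* missed          p · (1 − Se)      (screen−)         → untreated Markov(+)
* misdiagnosed    (1 − p)(1 − Sp)   (screen+, OGTT−)  → Markov(−)
* true negative   (1 − p) · Sp      (screen−)         → Markov(−)

The screening-stage cost per screened person is the per-test cost plus the
OGTT cost weighted by the screen-positive probability.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .params import CostSet, ScreeningStrategy


@dataclass(frozen=True)
class ClassificationResult:
    p_diagnosed: float
    p_missed: float
    p_misdiagnosed: float
    p_true_negative: float
    screening_cost_per_capita: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def classify(
    prevalence: float, strategy: ScreeningStrategy, costs: CostSet | None = None
) -> ClassificationResult:
    """Split a screened cohort into the four decision-tree arms.

    The four fractions partition 1; diagnosed + missed equals the prevalence.
    ``screening_cost_per_capita`` is 0 unless a :class:`CostSet` supplies the
    OGTT cost.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must lie in (0, 1), got {prevalence}")
    se, sp = strategy.sensitivity, strategy.specificity
    result = ClassificationResult(
        p_diagnosed=prevalence * se,
        p_missed=prevalence * (1.0 - se),
        p_misdiagnosed=(1.0 - prevalence) * (1.0 - sp),
        p_true_negative=(1.0 - prevalence) * sp,
        screening_cost_per_capita=(
            screening_stage_cost(prevalence, strategy, costs) if costs is not None else 0.0
        ),
    )
    return result


def screen_positive_rate(prevalence: float, strategy: ScreeningStrategy) -> float:
    return prevalence * strategy.sensitivity + (1.0 - prevalence) * (
        1.0 - strategy.specificity
    )


def screening_stage_cost(
    prevalence: float, strategy: ScreeningStrategy, costs: CostSet
) -> float:
    """Expected screening-stage cost per screened person (USD): all three
    per-test cost components plus the OGTT cost for screen-positives."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must lie in (0, 1), got {prevalence}")
    return strategy.cost_per_test + screen_positive_rate(prevalence, strategy) * costs.ogtt_cost
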