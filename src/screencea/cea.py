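"""Cost-utility analysis: C/U ratios, pairwise ICURs, dominance and WTP verdicts.

The incremental cost-utility ratio between a comparator and a reference is
ICUR = ΔC / ΔE with ΔC = C_comp − C_ref and ΔE = E_comp − E_ref.  A
comparator *dominates* when it is cheaper and more effective (ΔC < 0,
ΔE > 0) and is *dominated* when dearer and less effective (ΔC > 0, ΔE < 0);
in the latter case the signed negative ICUR is still reported, matching the
reporting convention of published cost-utility tables.  A comparator is
cost-effective at willingness-to-pay λ iff it dominates or ΔE > 0 and
ICUR ≤ λ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .markov import ArmOutcome
from .params import WTPSpec

#: Pairwise comparisons reported by default: each HbA1c strategy against the
#: usual-care comparator (FCG), plus venous against POCT.
DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("FCG", "POCT_HBA1C"),
    ("FCG", "VENOUS_HBA1C"),
    ("POCT_HBA1C", "VENOUS_HBA1C"),
)


@dataclass(frozen=True)
class CEAResult:
    reference: str
    comparator: str
    delta_cost: float
    delta_utility: float
    icur: float | None
    cu_ratio_reference: float
    verdict: str  # cost_effective | not_cost_effective | dominant | dominated


def cost_utility_ratio(cost: float, utility: float) -> float:
    """Average cost per QALY of a single strategy."""
    if utility <= 0:
        raise ValueError("utility must be > 0 for a C/U ratio")
    return cost / utility


def compute_icur(
    ref_outcome: ArmOutcome,
    comp_outcome: ArmOutcome,
    wtp: WTPSpec | float,
    reference: str = "reference",
    comparator: str = "comparator",
) -> CEAResult:
    """Incremental comparison of a comparator strategy against a reference."""
    lam = wtp.value if isinstance(wtp, WTPSpec) else float(wtp)
    d_cost = comp_outcome.total_cost - ref_outcome.total_cost
    d_util = comp_outcome.total_qaly - ref_outcome.total_qaly
    icur = d_cost / d_util if d_util != 0.0 else None

    if d_util > 0 and d_cost < 0:
        verdict = "dominant"
    elif d_util < 0 and d_cost > 0:
        verdict = "dominated"
    elif d_util == 0.0:
        verdict = "cost_effective" if d_cost <= 0 else "not_cost_effective"
    elif d_util > 0:
        verdict = "cost_effective" if icur <= lam else "not_cost_effective"
    else:  # less effective and cheaper: not acceptable under a pure QALY-gain rule
        verdict = "not_cost_effective"
    return CEAResult(
        reference=reference,
        comparator=comparator,
        delta_cost=d_cost,
        delta_utility=d_util,
        icur=icur,
        cu_ratio_reference=(
            cost_utility_ratio(ref_outcome.total_cost, ref_outcome.total_qaly)
            if ref_outcome.total_qaly > 0
            else float("nan")
        ),
        verdict=verdict,
    )


def is_cost_effective(result: CEAResult, lam: float) -> bool:
    """Re-evaluate a comparison's verdict at another willingness-to-pay."""
    if result.verdict == "dominant":
        return True
    if result.delta_utility > 0:
        return result.icur <= lam
    if result.delta_utility == 0:
        return result.delta_cost <= 0
    return False


def full_comparison(
    outcomes: Mapping[str, ArmOutcome],
    wtp: WTPSpec | float,
    comparisons: Sequence[tuple[str, str]] | None = None,
    setting_label: str = "",
) -> tuple[list[CEAResult], pd.DataFrame]:
    """Per-strategy summary plus pairwise incremental results.

    Returns the list of :class:`CEAResult` and a table with one row per
    strategy (cost, utility, C/U) and, for each comparison in which the
    strategy is the comparator, its incremental cost/utility and ICUR —
    the familiar published cost-utility table layout.
    """
    if len(outcomes) < 2:
        raise ValueError("need at least two strategies to compare")
    if comparisons is None:
        comparisons = [
            (r, c) for (r, c) in DEFAULT_COMPARISONS if r in outcomes and c in outcomes
        ]
    results = [
        compute_icur(outcomes[r], outcomes[c], wtp, reference=r, comparator=c)
        for r, c in comparisons
    ]

    rows = []
    for name, out in outcomes.items():
        rows.append(
            {
                "setting": setting_label,
                "strategy": name,
                "reference": "",
                "cost": out.total_cost,
                "incr_cost": float("nan"),
                "utility": out.total_qaly,
                "incr_utility": float("nan"),
                "cu_ratio": cost_utility_ratio(out.total_cost, out.total_qaly),
                "icur": float("nan"),
                "verdict": "",
            }
        )
    for res in results:
        rows.append(
            {
                "setting": setting_label,
                "strategy": res.comparator,
                "reference": res.reference,
                "cost": outcomes[res.comparator].total_cost,
                "incr_cost": res.delta_cost,
                "utility": outcomes[res.comparator].total_qaly,
                "incr_utility": res.delta_utility,
                "cu_ratio": cost_utility_ratio(
                    outcomes[res.comparator].total_cost,
                    outcomes[res.comparator].total_qaly,
                ),
                "icur": res.icur if res.icur is not None else float("nan"),
                "verdict": res.verdict,
            }
        )
    return results, pd.DataFrame(rows)
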