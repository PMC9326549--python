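"""Per-infant decision tree for universal newborn screening vs no screening.

The tree combines the screening test characteristics (false-negative and
false-positive rates), SCID birth incidence, diagnostic costs and the two
treatment cohorts into expected cost and QALYs per infant screened.

Healthy (non-SCID) infants accrue identical QALYs under both strategies,
so their quality-adjusted survival cancels from every increment and is
omitted from the totals: per-infant QALYs are SCID-attributable QALYs
only. Their only cost contribution is the false-positive work-up in the
screening arm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

from .parameters import ParameterSet

if TYPE_CHECKING:  # pragma: no cover
    from .cohorts import CohortResult

__all__ = [
    "StrategyOutcome",
    "CEAResult",
    "expected_outcome_screen",
    "expected_outcome_no_screen",
    "icer",
    "evaluate_screening",
]


@dataclass
class StrategyOutcome:
    """Expected cost and (SCID-attributable) QALYs per infant."""

    label: str
    cost: float
    qaly: float

    def __post_init__(self) -> None:
        if self.cost < 0 or self.qaly < 0:
            raise ValueError("strategy outcome cost/QALY must be non-negative")


@dataclass
class CEAResult:
    """Incremental comparison of two strategies.

    ``icer`` is defined only when the quadrant admits a meaningful ratio:
    a strategy that is cheaper and more effective is ``dominant`` (no ratio
    reported), one that is costlier and less effective is ``dominated``.
    ``note`` flags the degenerate no-QALY-difference case.
    """

    intervention: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: Optional[float] = None
    dominance: Optional[str] = None
    note: Optional[str] = None

    def per_100k(self) -> dict:
        """Increments scaled to a birth cohort of 100,000 infants."""
        return {
            "delta_cost_per_100k": self.delta_cost * 1e5,
            "delta_qaly_per_100k": self.delta_qaly * 1e5,
        }


def expected_outcome_screen(
    params: ParameterSet,
    early: "CohortResult",
    late: "CohortResult",
) -> StrategyOutcome:
    """Universal screening arm.

    True positives (sensitivity ``1 − FN``) are confirmed and treated
    early; false negatives present clinically and follow the late pathway
    with the clinical diagnostic work-up; false positives among healthy
    infants incur the confirmatory diagnostic cost.
    """
    _check_rates(params)
    inc = params.incidence
    fn = params.false_negative_rate
    fp = params.false_positive_rate
    cost = (
        params.screen_cost
        + inc * (
            (1 - fn) * (params.confirm_dx_cost + early.total_cost)
            + fn * (params.dx_cost_no_nbs + late.total_cost)
        )
        + (1 - inc) * fp * params.confirm_dx_cost
    )
    qaly = inc * ((1 - fn) * early.total_qaly + fn * late.total_qaly)
    return StrategyOutcome("screen", cost, qaly)


def expected_outcome_no_screen(
    params: ParameterSet,
    early: "CohortResult",
    late: "CohortResult",
) -> StrategyOutcome:
    """No-screening arm: only the family-history fraction is detected early."""
    _check_rates(params)
    inc = params.incidence
    w = params.pct_early_dx_no_nbs
    cost = inc * (
        w * (params.dx_cost_no_nbs + early.total_cost)
        + (1 - w) * (params.dx_cost_no_nbs + late.total_cost)
    )
    qaly = inc * (w * early.total_qaly + (1 - w) * late.total_qaly)
    return StrategyOutcome("no_screen", cost, qaly)


def _check_rates(params: ParameterSet) -> None:
    for name in ("false_negative_rate", "false_positive_rate"):
        v = getattr(params, name)
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} outside [0, 1]: {v}")


def icer(a: StrategyOutcome, b: StrategyOutcome) -> CEAResult:
    """Incremental cost-effectiveness of strategy ``a`` over ``b``."""
    dc = a.cost - b.cost
    dq = a.qaly - b.qaly
    res = CEAResult(
        intervention=a.label, comparator=b.label, delta_cost=dc, delta_qaly=dq
    )
    if dq == 0.0:
        res.note = "no QALY difference" if dc != 0.0 else "identical strategies"
    elif dc < 0 and dq > 0:
        res.dominance = "dominant"
    elif dc > 0 and dq < 0:
        res.dominance = "dominated"
    else:
        res.icer = dc / dq
    return res


def evaluate_screening(
    params: ParameterSet,
    life_table,
    horizon_years: float,
    discount_rate: Optional[float] = None,
    **model_kwargs,
):
    """Run the full screening comparison at one horizon.

    Returns ``(screen, no_screen, cea)`` with per-infant
    :class:`StrategyOutcome` values and the incremental result of
    screening over no screening.
    """
    from .cohorts import run_strategy

    early = run_strategy(params, life_table, "early", horizon_years,
                         discount_rate, **model_kwargs)
    late = run_strategy(params, life_table, "late", horizon_years,
                        discount_rate, **model_kwargs)
    screen = expected_outcome_screen(params, early, late)
    no_screen = expected_outcome_no_screen(params, early, late)
    return screen, no_screen, icer(screen, no_screen)
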