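"""Discrete-time Markov cohort engine.

A :class:`MarkovModel` couples a state space with (possibly time-varying)
transition matrices and reward rules; :func:`run_cohort` propagates the
cohort occupancy and accumulates discounted costs and QALYs.

Conventions
-----------
* **Half-cycle correction**: state-residence rewards (per-cycle costs and
  utilities) are accrued on the trapezoidal average of start- and
  end-of-cycle occupancy, the standard continuity correction treating
  transitions as occurring mid-cycle on average.
* **One-off transition costs** are charged on the probability flow through
  the transition and discounted to the cycle at which the transition
  completes; they are not half-cycle corrected.
* **Discounting** uses the cycle-start convention, ``(1 + r)^(-t)`` with
  ``t = cycle_index × cycle_length`` years. The alternative mid-cycle
  convention differs by under 0.4% at a 3% annual rate.

The engine is fully deterministic; the stochastic counterpart used as a
correctness oracle lives in :mod:`scidcea.synthetic`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .states import HealthState

__all__ = [
    "MarkovModel",
    "MarkovTrace",
    "per_cycle_probability",
    "discount_factor",
    "run_cohort",
]

_ROW_TOL = 1e-10


def per_cycle_probability(p_period: float, n_cycles: int) -> float:
    """Spread a period probability over ``n_cycles`` at constant hazard.

    Returns ``1 - (1 - p_period)**(1/n_cycles)``; compounding the result
    ``n_cycles`` times recovers ``p_period`` exactly.
    """
    if not 0.0 <= p_period <= 1.0:
        raise ValueError(f"p_period must lie in [0, 1], got {p_period}")
    if n_cycles < 1:
        raise ValueError("n_cycles must be a positive integer")
    return 1.0 - (1.0 - p_period) ** (1.0 / n_cycles)


def discount_factor(cycle_index: int, annual_rate: float, cycle_length: float) -> float:
    """Cycle-start discount factor ``(1 + r)^(-cycle_index × cycle_length)``."""
    if annual_rate < 0:
        raise ValueError("discount rate must be non-negative")
    return float((1.0 + annual_rate) ** (-(cycle_index * cycle_length)))


@dataclass
class MarkovModel:
    """A cohort model: states, initial occupancy, transitions and rewards.

    ``transition(t)`` must return a row-stochastic matrix for cycle ``t``;
    ``state_cost(t)`` the per-cycle residence cost vector (already pro-rated
    to the cycle length); ``transition_cost(t)`` an optional matrix of
    one-off costs charged per unit of flow from state i to state j during
    cycle ``t``.
    """

    states: Sequence[HealthState]
    initial_occupancy: np.ndarray
    transition: Callable[[int], np.ndarray]
    utilities: np.ndarray
    cycle_length: float = 0.25
    state_cost: Optional[Callable[[int], np.ndarray]] = None
    transition_cost: Optional[Callable[[int], np.ndarray]] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.initial_occupancy = np.asarray(self.initial_occupancy, dtype=float)
        self.utilities = np.asarray(self.utilities, dtype=float)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def dead_index(self) -> Optional[int]:
        try:
            return list(self.states).index(HealthState.DEAD)
        except ValueError:
            return None

    def validate(self, horizon_cycles: int = 1) -> None:
        """Check stochasticity, absorbing death and initial occupancy."""
        if abs(self.initial_occupancy.sum() - 1.0) > _ROW_TOL:
            raise ValueError("initial occupancy must sum to 1")
        if np.any(self.initial_occupancy < 0):
            raise ValueError("initial occupancy must be non-negative")
        dead = self.dead_index
        for t in range(horizon_cycles):
            P = self.transition(t)
            if P.shape != (self.n_states, self.n_states):
                raise ValueError(f"transition matrix at cycle {t} has shape {P.shape}")
            if np.any(P < -_ROW_TOL):
                raise ValueError(f"negative transition probability at cycle {t}")
            rows = P.sum(axis=1)
            if np.any(np.abs(rows - 1.0) > _ROW_TOL):
                raise ValueError(
                    f"non-stochastic transition matrix at cycle {t}: row sums {rows}"
                )
            if dead is not None and abs(P[dead, dead] - 1.0) > _ROW_TOL:
                raise ValueError(f"Dead is not absorbing at cycle {t}")


@dataclass
class MarkovTrace:
    """Per-cycle occupancy with discounted cost and QALY streams."""

    states: Sequence[HealthState]
    cycle_length: float
    occupancy: np.ndarray  # (horizon+1, n_states)
    discounted_cost: np.ndarray  # (horizon,)
    discounted_qaly: np.ndarray  # (horizon,)
    label: str = ""

    @property
    def total_cost(self) -> float:
        return float(self.discounted_cost.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.discounted_qaly.sum())

    @property
    def horizon_cycles(self) -> int:
        return self.discounted_cost.shape[0]

    def to_frame(self) -> pd.DataFrame:
        n = self.occupancy.shape[0]
        df = pd.DataFrame(
            self.occupancy,
            columns=[getattr(s, "name", str(s)) for s in self.states],
        )
        df.insert(0, "cycle", np.arange(n))
        df.insert(1, "age_years", np.arange(n) * self.cycle_length)
        df["disc_cost"] = np.append(self.discounted_cost, np.nan)
        df["disc_qaly"] = np.append(self.discounted_qaly, np.nan)
        return df

    def to_csv(self, path: str | Path, header_comments: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, index=False)


def run_cohort(
    model: MarkovModel,
    horizon_cycles: int,
    annual_discount_rate: float = 0.03,
) -> MarkovTrace:
    """Propagate the cohort and accumulate discounted rewards.

    Per cycle ``t`` (ages ``t·Δ`` to ``(t+1)·Δ`` years):

    * QALY accrual  ``½(occ_t + occ_{t+1}) · u × Δ × d(t)``
    * residence cost ``½(occ_t + occ_{t+1}) · c(t) × d(t)``
    * one-off costs  ``Σ_{i,j} occ_t[i] P_t[i,j] K_t[i,j] × d(t+1)``

    where ``d`` is the cycle-start discount factor.
    """
    if horizon_cycles < 1:
        raise ValueError("horizon_cycles must be >= 1")
    model.validate(horizon_cycles)

    n = model.n_states
    occ = np.zeros((horizon_cycles + 1, n))
    occ[0] = model.initial_occupancy
    disc_cost = np.zeros(horizon_cycles)
    disc_qaly = np.zeros(horizon_cycles)
    cl = model.cycle_length

    for t in range(horizon_cycles):
        P = model.transition(t)
        occ[t + 1] = occ[t] @ P
        mid = 0.5 * (occ[t] + occ[t + 1])
        d_t = discount_factor(t, annual_discount_rate, cl)
        disc_qaly[t] = float(mid @ model.utilities) * cl * d_t
        cost = 0.0
        if model.state_cost is not None:
            cost += float(mid @ model.state_cost(t)) * d_t
        if model.transition_cost is not None:
            K = model.transition_cost(t)
            if K is not None:
                flow = occ[t][:, None] * P
                cost += float((flow * K).sum()) * discount_factor(
                    t + 1, annual_discount_rate, cl
                )
        disc_cost[t] = cost

    return MarkovTrace(
        states=model.states,
        cycle_length=cl,
        occupancy=occ,
        discounted_cost=disc_cost,
        discounted_qaly=disc_qaly,
        label=model.label,
    )
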