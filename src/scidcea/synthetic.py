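"""Synthetic inputs and the individual-level microsimulation oracle.

Two generators live here:

* :func:`make_life_table` builds a parametric Gompertz–Makeham life table,
  the package's stand-in for a national mortality schedule (the bundled
  default fixture under ``scidcea/data`` is produced by it and labelled
  synthetic).
* :func:`microsimulate` draws individual patient trajectories from the
  *exact* transition matrices and reward rules of a cohort model. Its
  empirical occupancy and mean discounted cost/QALY converge on the
  deterministic cohort results, which makes it the package's brute-force
  correctness oracle for the Markov engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .lifetable import LifeTable
from .markov import MarkovModel, discount_factor

__all__ = ["SyntheticLifeTableSpec", "make_life_table", "MicrosimRun", "microsimulate"]


@dataclass(frozen=True)
class SyntheticLifeTableSpec:
    """Gompertz–Makeham hazard ``h(a) = makeham + gompertz_a·exp(gompertz_b·a)``
    with an overriding first-year (infant) death probability."""

    makeham: float = 2e-4
    gompertz_a: float = 2e-5
    gompertz_b: float = 0.095
    infant_q0: float = 0.0033
    max_age: int = 100

    def __post_init__(self) -> None:
        if min(self.makeham, self.gompertz_a, self.gompertz_b) < 0:
            raise ValueError("all hazard parameters must be non-negative")
        if not 0.0 <= self.infant_q0 <= 1.0:
            raise ValueError("infant_q0 must lie in [0, 1]")


def make_life_table(spec: SyntheticLifeTableSpec = SyntheticLifeTableSpec()) -> LifeTable:
    """Annual ``q(age) = 1 − exp(−(makeham + gompertz_a·e^{gompertz_b·age}))``."""
    ages = np.arange(spec.max_age + 1)
    hazard = spec.makeham + spec.gompertz_a * np.exp(spec.gompertz_b * ages)
    q = 1.0 - np.exp(-hazard)
    q[0] = spec.infant_q0
    if np.any(q > 1.0):  # unreachable for finite hazards; guards bad inputs
        raise ValueError("specification produces q > 1 before max_age")
    return LifeTable(q=q, label="synthetic-gompertz-makeham")


@dataclass
class MicrosimRun:
    """Result of an individual-level simulation of a cohort model."""

    n_individuals: int
    seed: int
    occupancy: np.ndarray       # empirical (horizon+1, n_states)
    cost: np.ndarray            # per-individual discounted cost, (n,)
    qaly: np.ndarray            # per-individual discounted QALY, (n,)
    paths: Optional[np.ndarray] = None  # (n, horizon+1) state indices

    @property
    def mean_cost(self) -> float:
        return float(self.cost.mean())

    @property
    def mean_qaly(self) -> float:
        return float(self.qaly.mean())

    def occupancy_se(self) -> np.ndarray:
        """Binomial Monte-Carlo standard error of each occupancy entry."""
        p = self.occupancy
        return np.sqrt(p * (1.0 - p) / self.n_individuals)


def microsimulate(
    model: MarkovModel,
    n: int,
    seed: int,
    horizon_cycles: int,
    annual_discount_rate: float = 0.03,
    store_paths: bool = False,
) -> MicrosimRun:
    """Simulate ``n`` independent trajectories of ``model``.

    Rewards mirror :func:`scidcea.markov.run_cohort` exactly: residence
    rewards use the trapezoidal average of the start- and end-of-cycle
    state indicator, one-off transition costs are charged on the realized
    transition at the completing cycle's discount factor. Deterministic
    for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    model.validate(horizon_cycles)
    rng = np.random.default_rng(seed)
    S = model.n_states
    cl = model.cycle_length

    states = rng.choice(S, size=n, p=model.initial_occupancy)
    occupancy = np.zeros((horizon_cycles + 1, S))
    occupancy[0] = np.bincount(states, minlength=S) / n
    cost = np.zeros(n)
    qaly = np.zeros(n)
    paths = np.empty((n, horizon_cycles + 1), dtype=np.int8) if store_paths else None
    if paths is not None:
        paths[:, 0] = states

    for t in range(horizon_cycles):
        P = model.transition(t)
        cum = np.cumsum(P, axis=1)
        cum[:, -1] = 1.0  # guard against rounding in the last column
        u = rng.random(n)
        nxt = (u[:, None] > cum[states]).sum(axis=1)

        d_t = discount_factor(t, annual_discount_rate, cl)
        d_t1 = discount_factor(t + 1, annual_discount_rate, cl)
        u_mid = 0.5 * (model.utilities[states] + model.utilities[nxt])
        qaly += u_mid * cl * d_t
        if model.state_cost is not None:
            c = model.state_cost(t)
            cost += 0.5 * (c[states] + c[nxt]) * d_t
        if model.transition_cost is not None:
            K = model.transition_cost(t)
            if K is not None:
                cost += K[states, nxt] * d_t1

        states = nxt
        occupancy[t + 1] = np.bincount(states, minlength=S) / n
        if paths is not None:
            paths[:, t + 1] = states

    return MicrosimRun(
        n_individuals=n, seed=seed, occupancy=occupancy,
        cost=cost, qaly=qaly, paths=paths,
    )
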