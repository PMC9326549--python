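"""Model parameter registry: costs, probabilities, utilities and their
uncertainty distributions.

Every input of the cost-effectiveness analysis lives in :class:`ParameterSet`.
Default values are the published expected values of the Australian SCID
newborn-screening evaluation (2018 US$, converted from A$ by purchasing
power parity). Monetary defaults are the *printed* US$ figures rather than
re-derived PPP conversions, which occasionally disagree with naive division
by a few hundredths of a percent; :func:`convert_currency` is provided as a
documented utility, not as the source of truth.

Parameters that carry published uncertainty ranges are exposed through
:meth:`ParameterSet.distributions` as :class:`ParameterDistribution` records
(gamma for costs, beta for probabilities/proportions, ``fixed`` otherwise)
for use in one-way and probabilistic sensitivity analysis.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .states import HealthState

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterSet",
    "ParameterDistribution",
    "load_parameters",
    "convert_currency",
]


class ParameterDistribution(BaseModel):
    """Uncertainty specification for one parameter.

    ``low``/``high`` are interpreted as a central 95% interval around the
    expected value when fitting a sampling distribution (see
    :func:`scidcea.sensitivity.fit_distribution`).
    """

    name: str
    family: Literal["gamma", "beta", "fixed"]
    expected: float
    low: Optional[float] = None
    high: Optional[float] = None

    @model_validator(mode="after")
    def _ordered(self) -> "ParameterDistribution":
        if self.low is not None and self.high is not None:
            if not (self.low <= self.expected <= self.high):
                raise ValueError(
                    f"{self.name}: require low <= expected <= high, got "
                    f"({self.low}, {self.expected}, {self.high})"
                )
        return self


def _prob(default: float) -> float:
    return Field(default=default, ge=0.0, le=1.0)


def _money(default: float) -> float:
    return Field(default=default, ge=0.0)


class ParameterSet(BaseModel):
    """Complete, validated input registry for the SCID screening evaluation.

    All monetary amounts are 2018 US$. Annual state costs are pro-rated to
    the cycle length by the cohort builders; one-off costs are charged on
    the transition that triggers them.
    """

    model_config = {"validate_assignment": True}

    # --- screening & diagnostic costs (per infant / per case) ---
    screen_cost: float = _money(4.82)
    repeat_screen_cost: float = _money(6.89)
    confirm_dx_cost: float = _money(2119.0)
    dx_cost_no_nbs: float = _money(3446.0)

    # --- treatment & care costs (per SCID patient) ---
    hsct_cost_early: float = _money(119_282.0)
    hsct_cost_late: float = _money(271_697.0)
    death_pre_hsct_cost: float = _money(178_923.0)
    annual_cost_well: float = _money(34.0)
    annual_cost_moderate: float = _money(24_052.0)
    annual_cost_poor: float = _money(12_873.0)
    end_of_life_cost: float = _money(41_841.0)

    # --- societal productivity costs: carried but excluded from the default
    # (government-payer) perspective ---
    productivity_cost_well: float = _money(0.0)
    productivity_cost_moderate: float = _money(1394.0)
    productivity_cost_poor: float = _money(0.0)
    include_productivity_costs: bool = False

    # --- epidemiology & test characteristics ---
    incidence: float = Field(default=2e-5, ge=0.0, le=1e-3)
    false_negative_rate: float = _prob(0.005)
    false_positive_rate: float = _prob(0.0003)
    pct_early_dx_no_nbs: float = _prob(0.2)

    # --- survival ---
    p_survive_to_tx_early: float = _prob(0.9423)
    p_survive_to_tx_late: float = _prob(0.78)
    surv5_early: float = _prob(0.94)
    surv5_late: float = _prob(0.82)

    # --- post-HSCT outcome splits over (Well, Moderate, Poor) ---
    post_hsct_split_early: Tuple[float, float, float] = (0.80, 0.15, 0.05)
    post_hsct_split_late: Tuple[float, float, float] = (0.50, 0.30, 0.20)

    # --- utilities ---
    utility_pre_symptomatic: float = _prob(0.95)
    utility_hsct: float = _prob(0.50)
    utility_well: float = _prob(0.95)
    utility_moderate: float = _prob(0.75)
    utility_poor: float = _prob(0.50)
    utility_dead: float = _prob(0.0)

    # --- time & discounting ---
    discount_rate: float = Field(default=0.03, ge=0.0)
    cycle_length: float = Field(default=0.25, gt=0.0)
    horizons: Tuple[int, ...] = (5, 60)

    # --- currency conversion factors ---
    ppp_eur_usd: float = Field(default=0.796, gt=0.0)
    ppp_aud_usd: float = Field(default=1.45, gt=0.0)
    cpi_2016_2019: float = Field(default=0.0557, ge=0.0)

    @field_validator("post_hsct_split_early", "post_hsct_split_late")
    @classmethod
    def _simplex(cls, v: Tuple[float, float, float]) -> Tuple[float, float, float]:
        if any(x < 0 for x in v):
            raise ValueError("post-HSCT split shares must be non-negative")
        if abs(sum(v) - 1.0) > 1e-12:
            raise ValueError(f"post-HSCT split must sum to 1, got {sum(v)!r}")
        return v

    @model_validator(mode="after")
    def _horizon_cycles(self) -> "ParameterSet":
        for h in self.horizons:
            n = h / self.cycle_length
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"horizon {h} y is not an integer number of "
                    f"{self.cycle_length} y cycles"
                )
        return self

    # ------------------------------------------------------------------
    def utility(self, state: HealthState) -> float:
        """Health-state utility weight in [0, 1]."""
        return {
            HealthState.PRE_SYMPTOMATIC: self.utility_pre_symptomatic,
            HealthState.HSCT: self.utility_hsct,
            HealthState.WELL: self.utility_well,
            HealthState.MODERATE: self.utility_moderate,
            HealthState.POOR: self.utility_poor,
            HealthState.DEAD: self.utility_dead,
        }[state]

    def utilities(self) -> np.ndarray:
        """Utility vector in canonical state order."""
        return np.array([self.utility(s) for s in HealthState])

    def annual_state_costs(self) -> np.ndarray:
        """Annual care cost per state, in canonical order.

        Pre-symptomatic and HSCT residence carry no recurring cost (the
        transplant itself is a one-off transition cost). Productivity costs
        are added only under the societal perspective flag.
        """
        c = np.zeros(len(HealthState))
        c[HealthState.WELL] = self.annual_cost_well
        c[HealthState.MODERATE] = self.annual_cost_moderate
        c[HealthState.POOR] = self.annual_cost_poor
        if self.include_productivity_costs:
            c[HealthState.WELL] += self.productivity_cost_well
            c[HealthState.MODERATE] += self.productivity_cost_moderate
            c[HealthState.POOR] += self.productivity_cost_poor
        return c

    # ------------------------------------------------------------------
    def distributions(self) -> dict[str, ParameterDistribution]:
        """Uncertainty registry: every parameter with published bounds.

        Parameters without bounds are reported with ``family="fixed"``. The
        repeat-screen-cost row's published bounds are denominated in A$ and
        are converted here (its tree impact is below one US cent per
        infant); this interpretation is logged because the source row is
        ambiguous.
        """
        logger.debug(
            "repeat_screen_cost bounds interpreted as A$ and converted to US$"
        )
        aud = self.ppp_aud_usd
        rows = [
            ("screen_cost", "gamma", self.screen_cost * 0.9, self.screen_cost * 1.1),
            ("repeat_screen_cost", "gamma", 7.0 / aud, 25.0 / aud),
            ("hsct_cost_early", "gamma", self.hsct_cost_early * 0.9, self.hsct_cost_early * 1.1),
            ("hsct_cost_late", "gamma", self.hsct_cost_late * 0.9, self.hsct_cost_late * 1.1),
            ("incidence", "beta", 1.2e-5, 2.5e-5),
            ("false_negative_rate", "beta", 0.0, 0.01),
            ("false_positive_rate", "beta", 2e-4, 8e-4),
            ("pct_early_dx_no_nbs", "beta", 0.1, 0.3),
            ("surv5_early", "beta", 0.91, 0.98),
            ("surv5_late", "beta", 0.70, 0.90),
            # the discount rate has a published one-way range but no
            # sampling distribution
            ("discount_rate", "fixed", 0.0, 0.05),
        ]
        out: dict[str, ParameterDistribution] = {}
        for name, family, low, high in rows:
            out[name] = ParameterDistribution(
                name=name, family=family,
                expected=getattr(self, name), low=low, high=high,
            )
        for name in type(self).model_fields:
            if name in out:
                continue
            value = getattr(self, name)
            if isinstance(value, (int, float)) and not isinstance(value, bool):
                out[name] = ParameterDistribution(
                    name=name, family="fixed", expected=float(value)
                )
        return out

    # ------------------------------------------------------------------
    # serialization
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    def to_csv(self, path: str | Path) -> None:
        """Write one row per scalar parameter (name, expected, family, low,
        high, units, source)."""
        dists = self.distributions()
        rows = []
        for name, d in dists.items():
            rows.append(
                dict(
                    name=name,
                    expected=d.expected,
                    family=d.family,
                    low="" if d.low is None else d.low,
                    high="" if d.high is None else d.high,
                    units=_UNITS.get(name, ""),
                    source="published expected value",
                )
            )
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_mapping(cls, data: Mapping[str, object]) -> "ParameterSet":
        unknown = set(data) - set(cls.model_fields)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**data)


_UNITS = {
    "screen_cost": "US$/infant",
    "repeat_screen_cost": "US$",
    "confirm_dx_cost": "US$",
    "dx_cost_no_nbs": "US$",
    "hsct_cost_early": "US$",
    "hsct_cost_late": "US$",
    "death_pre_hsct_cost": "US$",
    "annual_cost_well": "US$/year",
    "annual_cost_moderate": "US$/year",
    "annual_cost_poor": "US$/year",
    "end_of_life_cost": "US$",
    "incidence": "probability/birth",
    "discount_rate": "fraction/year",
    "cycle_length": "years",
}


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    """Load a parameter file (JSON mapping or registry CSV).

    Omitted keys take their published expected values. ``None`` returns the
    full default set.
    """
    if path is None:
        return ParameterSet()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, comment="#")
        if not {"name", "expected"} <= set(df.columns):
            raise ValueError("parameter CSV needs 'name' and 'expected' columns")
        data = {}
        valid = set(ParameterSet.model_fields)
        for _, row in df.iterrows():
            if row["name"] in valid:
                data[row["name"]] = row["expected"]
            else:
                raise KeyError(f"unknown parameter: {row['name']!r}")
        return ParameterSet.from_mapping(data)
    return ParameterSet.from_mapping(json.loads(path.read_text()))


def convert_currency(
    amount: float,
    source: str,
    apply_cpi: bool = False,
    params: ParameterSet | None = None,
) -> float:
    """Convert A$2016 or €2016 to 2018 US$ by OECD purchasing power parity.

    ``source`` is ``"AUD2016"`` (divide by 1.45) or ``"EUR2016"`` (divide by
    0.796); ``apply_cpi`` additionally uplifts by the 2016→2019 Australian
    CPI factor. Published converted values occasionally differ from this
    arithmetic by rounding; the registry defaults therefore store the
    published US$ figures directly.
    """
    p = params or ParameterSet()
    factors = {"AUD2016": p.ppp_aud_usd, "EUR2016": p.ppp_eur_usd}
    try:
        ppp = factors[source]
    except KeyError:
        raise ValueError(f"unknown currency tag {source!r}; expected one of {sorted(factors)}")
    out = amount / ppp
    if apply_cpi:
        out *= 1.0 + p.cpi_2016_2019
    return out
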