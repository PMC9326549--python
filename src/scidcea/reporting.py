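"""Run configuration, provenance and report assembly.

The main product is :func:`report_table3`, which assembles both panels of
the headline cost-effectiveness table — the per-patient treatment
comparison (early vs late HSCT) and the per-infant screening comparison
(universal NBS vs none) — at each requested horizon, optionally with PSA
percentile confidence intervals. All outputs are CSV with ``#`` header
comments carrying provenance (parameter hash, life-table label, seed,
software version), and re-parse through :func:`pandas.read_csv` with
``comment='#'``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .cohorts import run_strategy
from .lifetable import LifeTable, default_life_table, load_life_table
from .parameters import ParameterSet, load_parameters
from .screening import expected_outcome_no_screen, expected_outcome_screen, icer
from .sensitivity import run_psa

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "log_provenance", "report_table3", "write_csv_with_header"]


class RunConfig(BaseModel):
    """Configuration of one reporting run (JSON-serialisable)."""

    params_path: Optional[str] = None
    life_table_path: Optional[str] = None
    horizons: Tuple[int, ...] = (5, 60)
    discount_rate: Optional[float] = None
    seed: int = 0
    n_iter: int = 0
    out_dir: str = "."
    perspective: str = Field(default="government", pattern="^(government|societal)$")

    def load(self) -> tuple[ParameterSet, LifeTable]:
        try:
            params = load_parameters(self.params_path)
        except FileNotFoundError as exc:
            raise FileNotFoundError(f"parameter file not found: {exc}") from exc
        if self.perspective == "societal":
            params = ParameterSet(**{**params.model_dump(),
                                     "include_productivity_costs": True})
        if self.life_table_path is None:
            lt = default_life_table()
        else:
            lt = load_life_table(self.life_table_path)
        return params, lt


def log_provenance(config: RunConfig, params: ParameterSet, lt: LifeTable) -> dict:
    """Provenance record embedded in every output header."""
    if lt.label == "unlabelled":
        logger.warning("life table has no label; provenance will be incomplete")
    digest = hashlib.sha256(
        (params.model_dump_json()
         + json.dumps(lt.q.tolist())
         + str(config.seed)).encode()
    ).hexdigest()[:16]
    return {
        "provenance_hash": digest,
        "life_table": lt.label,
        "seed": config.seed,
        "software": f"scidcea {__version__}",
        "perspective": config.perspective,
    }


def write_csv_with_header(df: pd.DataFrame, path: str | Path,
                          provenance: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in provenance.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def _ci(series: pd.Series) -> tuple[float, float]:
    return (float(np.percentile(series, 2.5)), float(np.percentile(series, 97.5)))


def report_table3(
    config: RunConfig,
    out_path: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Assemble the headline table: treatment and screening panels.

    With ``n_iter > 0`` a PSA at each horizon provides 95% percentile
    confidence intervals for every cell; with ``n_iter = 0`` only point
    estimates are reported.
    """
    params, lt = config.load()
    prov = log_provenance(config, params, lt)
    rows = []
    for horizon in config.horizons:
        early = run_strategy(params, lt, "early", horizon, config.discount_rate)
        late = run_strategy(params, lt, "late", horizon, config.discount_rate)
        screen = expected_outcome_screen(params, early, late)
        no_screen = expected_outcome_no_screen(params, early, late)
        psa = None
        if config.n_iter > 0:
            psa = run_psa(params, lt, n_iter=config.n_iter, seed=config.seed,
                          horizon_years=horizon)

        def row(panel, strategy, cost, qaly,
                dc=np.nan, dq=np.nan, ratio="", keys=None):
            r = dict(horizon_years=horizon, panel=panel, strategy=strategy,
                     cost=cost, incr_cost=dc, qaly=qaly, incr_qaly=dq,
                     icer=ratio)
            if psa is not None and keys:
                it = psa.iterations
                r["cost_ci_low"], r["cost_ci_high"] = _ci(it[keys[0]])
                r["qaly_ci_low"], r["qaly_ci_high"] = _ci(it[keys[1]])
            return r

        t_cea = icer(
            type(screen)("early_hsct", early.total_cost, early.total_qaly),
            type(screen)("late_hsct", late.total_cost, late.total_qaly),
        )
        rows.append(row("treatment", "late_hsct", late.total_cost,
                        late.total_qaly, keys=("late_cost", "late_qaly")))
        rows.append(row("treatment", "early_hsct", early.total_cost,
                        early.total_qaly, dc=t_cea.delta_cost,
                        dq=t_cea.delta_qaly,
                        ratio=t_cea.dominance or f"{t_cea.icer:.0f}",
                        keys=("early_cost", "early_qaly")))
        s_cea = icer(screen, no_screen)
        rows.append(row("screening", "no_screen", no_screen.cost,
                        no_screen.qaly, keys=("no_screen_cost", "no_screen_qaly")))
        srow = row("screening", "screen", screen.cost, screen.qaly,
                   dc=s_cea.delta_cost, dq=s_cea.delta_qaly,
                   ratio=s_cea.dominance or f"{s_cea.icer:.0f}",
                   keys=("screen_cost", "screen_qaly"))
        if psa is not None:
            srow["icer_ci_low"], srow["icer_ci_high"] = psa.icer_ci
        rows.append(srow)

    df = pd.DataFrame(rows)
    if out_path is not None:
        write_csv_with_header(df, out_path, prov)
    return df
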