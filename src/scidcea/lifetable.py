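"""General-population mortality (life table) support.

The cohort models apply disease-specific excess mortality with the general
population's age-specific death probability as a floor. A life table is a
vector of annual death probabilities ``q(age)`` for single-year ages 0-100.

The bundled default table is *synthetic*: the source vintage of the
mortality schedule used in the original analysis is not stated, so the
package ships a Gompertz–Makeham schedule (see
:func:`scidcea.synthetic.make_life_table`) with parameters typical of a
contemporary high-income country. Any table can be substituted from CSV.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LifeTable", "load_life_table", "default_life_table"]


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities by single-year age.

    ``q[a]`` is the probability of dying between exact ages ``a`` and
    ``a + 1``; ages beyond the table reuse the last entry.
    """

    q: np.ndarray
    label: str = "unlabelled"

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 1 or q.size < 2:
            raise ValueError("life table needs a 1-D vector of at least 2 ages")
        if np.any((q < 0) | (q > 1)):
            raise ValueError("life-table q values must lie in [0, 1]")
        object.__setattr__(self, "q", q)

    @property
    def max_age(self) -> int:
        return self.q.size - 1

    def annual_q(self, age_years: float) -> float:
        """Annual death probability at (floored) ``age_years``."""
        if age_years < 0:
            raise ValueError("age must be non-negative")
        return float(self.q[min(int(age_years), self.max_age)])

    def survival_curve(self) -> np.ndarray:
        """Probability of surviving from birth to each exact age."""
        return np.concatenate([[1.0], np.cumprod(1.0 - self.q)])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": np.arange(self.q.size), "qx": self.q}).to_csv(
            path, index=False
        )


def load_life_table(path: str | Path, label: str | None = None) -> LifeTable:
    """Read a CSV with columns ``age`` and ``qx`` (single-year ages)."""
    df = pd.read_csv(path, comment="#")
    if not {"age", "qx"} <= set(df.columns):
        raise ValueError(f"{path}: life table CSV needs 'age' and 'qx' columns")
    df = df.sort_values("age")
    ages = df["age"].to_numpy()
    if not np.array_equal(ages, np.arange(ages.min(), ages.max() + 1)) or ages.min() != 0:
        raise ValueError(f"{path}: ages must be consecutive single years starting at 0")
    return LifeTable(q=df["qx"].to_numpy(float), label=label or Path(path).stem)


def default_life_table() -> LifeTable:
    """The bundled synthetic Gompertz–Makeham life table (ages 0-100)."""
    ref = importlib.resources.files("scidcea.data") / "life_table_synthetic.csv"
    with importlib.resources.as_file(ref) as path:
        return load_life_table(path, label="synthetic-gompertz-makeham")
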