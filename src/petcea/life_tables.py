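"""Background mortality: life-table I/O, a synthetic Gompertz generator,
and the annual-to-cycle probability conversion.

The model needs single-year age-specific death probabilities qx covering
the whole horizon.  National life tables are read from a two-column CSV
(``age,qx``); for self-contained runs and tests a Gompertz curve of
adult-human magnitude stands in, labelled synthetic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "LifeTableError",
    "read_life_table",
    "write_life_table",
    "synthetic_life_table",
    "annual_to_cycle_probability",
]


class LifeTableError(ValueError):
    """The life table violates its format or domain constraints."""


@dataclass(frozen=True)
class LifeTable:
    """Annual death probability qx per single year of age.

    Ages are contiguous integers; the last age has qx = 1, closing the
    table so every cohort is eventually extinguished.
    """

    ages: np.ndarray
    qx: np.ndarray
    source: str = "unspecified"

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.ndim != 1 or ages.size == 0 or ages.shape != qx.shape:
            raise LifeTableError("ages and qx must be equal-length 1-D arrays")
        if not np.all(np.diff(ages) == 1):
            raise LifeTableError("ages must be contiguous and strictly increasing by 1")
        if np.any(qx < 0.0) or np.any(qx > 1.0) or np.any(~np.isfinite(qx)):
            raise LifeTableError("every qx must lie in [0, 1]")
        if qx[-1] != 1.0:
            raise LifeTableError(
                f"qx at the final age {ages[-1]} must be 1 to close the table"
            )

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def annual_qx(self, age: float) -> float:
        """qx at floor(age); ages past the end of the table are lethal (qx = 1)."""
        a = int(np.floor(age))
        if a < self.min_age:
            raise LifeTableError(f"age {age} below life table start {self.min_age}")
        if a > self.max_age:
            return 1.0
        return float(self.qx[a - self.min_age])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})


def read_life_table(source: str | Path | io.TextIOBase) -> LifeTable:
    """Read a life table from CSV with header ``age,qx``."""
    try:
        df = pd.read_csv(source)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise LifeTableError(f"unreadable life-table CSV: {exc}") from exc
    missing = {"age", "qx"} - set(df.columns)
    if missing:
        raise LifeTableError(f"life-table CSV missing column(s): {sorted(missing)}")
    name = str(source) if isinstance(source, (str, Path)) else "stream"
    return LifeTable(df["age"].to_numpy(), df["qx"].to_numpy(), source=name)


def write_life_table(lt: LifeTable, dest: str | Path | io.TextIOBase) -> None:
    lt.to_frame().to_csv(dest, index=False)


def synthetic_life_table(
    gompertz_a: float = 0.0045,
    gompertz_b: float = 0.095,
    age_lo: int = 60,
    age_hi: int = 120,
) -> LifeTable:
    """Deterministic synthetic life table from a Gompertz hazard.

    qx(age) = 1 - exp(-a * exp(b * (age - age_lo))), clamped to [0, 1],
    with qx forced to 1 at ``age_hi``.  The defaults (a = 0.0045/year,
    b = 0.095/year at age 60) give qx(60) = 0.0045 and a mortality rate
    doubling roughly every 7.3 years — the magnitude and slope of an
    adult human mortality curve, comparable to 2010s East-Asian national
    life tables.  This is a synthetic stand-in, not any published table.
    """
    if gompertz_a <= 0 or gompertz_b < 0:
        raise LifeTableError("Gompertz parameters must be positive (b may be 0)")
    ages = np.arange(age_lo, age_hi + 1)
    hazard = gompertz_a * np.exp(gompertz_b * (ages - age_lo))
    qx = np.clip(1.0 - np.exp(-hazard), 0.0, 1.0)
    qx[-1] = 1.0
    return LifeTable(
        ages, qx, source=f"synthetic-gompertz(a={gompertz_a}, b={gompertz_b})"
    )


def annual_to_cycle_probability(p_annual: float, cycles_per_year: int) -> float:
    """Convert an annual probability to a per-cycle probability.

    Assumes a constant hazard within the year, so the complement is split
    as a power: 1 - (1 - p)^(1/n).  Exactly recovers p when the n cycle
    complements are multiplied back together.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"p_annual must lie in [0, 1], got {p_annual}")
    if cycles_per_year < 1:
        raise ValueError("cycles_per_year must be >= 1")
    if p_annual == 1.0:
        return 1.0
    return float(1.0 - (1.0 - p_annual) ** (1.0 / cycles_per_year))
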