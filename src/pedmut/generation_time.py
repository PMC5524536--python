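"""Generation time of an age-structured, overlapping-generations population.

For iteroparous fish stocks the generation length equals the mean age of
parents, approximated here as the mean age of spawners — age-specific
abundance times the age-specific mature proportion — weighted by the
age-specific mean body weight, which serves as a fecundity proxy (weight
and fecundity are nearly proportional in clupeids).
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Union

import pandas as pd

__all__ = ["AgeClassRecord", "mean_generation_time", "read_age_table", "generation_time_series"]


@dataclass(frozen=True)
class AgeClassRecord:
    """One age class of a stock table.

    age: years (a plus-group such as "9+" is entered at its nominal age);
    abundance: number of fish or any relative index;
    maturity: proportion reproductive, in [0, 1];
    mean_weight: mean individual mass, any consistent unit (fecundity proxy).
    """

    age: float
    abundance: float
    maturity: float
    mean_weight: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.maturity <= 1.0:
            raise ValueError(f"maturity {self.maturity} outside [0, 1]")
        if self.abundance < 0 or self.mean_weight < 0:
            raise ValueError("abundance and mean_weight must be non-negative")


TableLike = Union[Iterable[AgeClassRecord], pd.DataFrame]


def _as_frame(table: TableLike) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.DataFrame([vars(r) for r in table])
    if df.empty:
        raise ValueError("age table is empty")
    missing = {"age", "abundance", "maturity", "mean_weight"} - set(df.columns)
    if missing:
        raise ValueError(f"age table lacks columns: {sorted(missing)}")
    return df


def mean_generation_time(table: TableLike) -> float:
    """Fecundity-weighted mean age of spawners, in years.

    G = sum_a age_a * N_a * m_a * w_a / sum_a N_a * m_a * w_a, where N is
    abundance, m the mature proportion and w the mean weight.  Invariant to
    rescaling of the abundance or weight columns; bounded by the youngest
    and oldest age present.
    """
    df = _as_frame(table)
    spawn_mass = df["abundance"] * df["maturity"] * df["mean_weight"]
    denom = float(spawn_mass.sum())
    if denom <= 0.0:
        raise ValueError("zero spawning biomass: no mature fish in table")
    return float((df["age"] * spawn_mass).sum() / denom)


def read_age_table(path: Union[str, PathLike]) -> pd.DataFrame:
    """Read a TSV with columns age, abundance, maturity, mean_weight and an
    optional year column for time series."""
    df = pd.read_csv(path, sep="\t")
    _as_frame(df)
    return df


def generation_time_series(df: pd.DataFrame) -> pd.Series:
    """Per-year generation time for a table with a ``year`` column."""
    if "year" not in df.columns:
        raise ValueError("time series requires a 'year' column")
    return df.groupby("year").apply(mean_generation_time, include_groups=False)
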