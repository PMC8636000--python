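"""Individual-level plant records: domain types, tabular I/O, validation.

The unit of observation is one marked plant in a paired herbivore-exclusion
experiment. Each plant belongs to a population, to a pair within that
population, and to one of two treatments: HP (herbivores present) or HE
(herbivores manually excluded). Three floral traits are recorded
(flowering start as day-of-year, flower number, corolla size in mm)
together with female-fitness components (fruits, seeds per fruit, total
seeds) and the count of herbivore-damaged flowers.

Herbivory intensity of a plant is the proportion of its flowers showing
herbivore damage; population intensity is the mean of per-plant intensities
over a population x treatment slice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREATMENTS = ("HP", "HE")

#: Required columns of the plant table, in canonical order.
PLANT_COLUMNS = [
    "population_id",
    "pair_id",
    "treatment",
    "flowering_start",
    "n_flowers",
    "corolla_size",
    "n_fruits",
    "seeds_per_fruit",
    "seeds_total",
    "n_damaged_flowers",
]

#: The three floral traits entering selection analyses, in canonical order.
TRAIT_COLUMNS = ["flowering_start", "n_flowers", "corolla_size"]

_INT_COLUMNS = ["flowering_start", "n_flowers", "n_fruits", "n_damaged_flowers"]
_FLOAT_COLUMNS = ["corolla_size", "seeds_per_fruit", "seeds_total"]


class SchemaError(ValueError):
    """The table is missing a required column or has an unusable dtype."""


class RowValidationError(ValueError):
    """A row violates a record-level invariant; carries the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


class EmptyGroupError(ValueError):
    """A population x treatment slice is empty or too small."""


class UndefinedIntensityError(ValueError):
    """Herbivory intensity is undefined for a plant without flowers."""


@dataclass(frozen=True)
class PlantRecord:
    """One plant's traits, fitness components and herbivore damage.

    Attributes
    ----------
    population_id, pair_id
        Categorical labels; pairs are nested within populations.
    treatment
        ``"HP"`` (herbivores present) or ``"HE"`` (herbivores excluded).
    flowering_start
        Day of year (Julian day) on which the first flower opened.
    n_flowers
        Total flowers produced over the season.
    corolla_size
        Mean maximum corolla diameter of the first three flowers, mm.
    n_fruits, seeds_per_fruit, seeds_total
        Female fitness components; ``seeds_total`` is the fitness measure
        used in selection analyses.
    n_damaged_flowers
        Flowers showing herbivore damage; at most ``n_flowers``.
    """

    population_id: str
    pair_id: str
    treatment: str
    flowering_start: int
    n_flowers: int
    corolla_size: float
    n_fruits: int
    seeds_per_fruit: float
    seeds_total: float
    n_damaged_flowers: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise RowValidationError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        if self.n_flowers < 0 or self.n_fruits < 0 or self.n_damaged_flowers < 0:
            raise RowValidationError("counts must be nonnegative")
        if self.n_damaged_flowers > self.n_flowers:
            raise RowValidationError(
                f"n_damaged_flowers ({self.n_damaged_flowers}) exceeds "
                f"n_flowers ({self.n_flowers})"
            )
        if self.n_fruits > self.n_flowers:
            raise RowValidationError(
                f"n_fruits ({self.n_fruits}) exceeds n_flowers ({self.n_flowers})"
            )
        if self.corolla_size <= 0:
            raise RowValidationError("corolla_size must be positive (mm)")
        if self.seeds_per_fruit < 0 or self.seeds_total < 0:
            raise RowValidationError("seed counts must be nonnegative")


@dataclass
class Dataset:
    """A validated collection of plant records plus free-form metadata.

    Internally a :class:`pandas.DataFrame` with the columns of
    :data:`PLANT_COLUMNS`; row order is preserved from the source.
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = _coerce_frame(self.df)
        _validate_rows(self.df)
        _validate_structure(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterator[PlantRecord]:
        for row in self.df.itertuples(index=False):
            yield PlantRecord(*row)

    @classmethod
    def from_records(
        cls, records: Iterable[PlantRecord], metadata: dict | None = None
    ) -> "Dataset":
        df = pd.DataFrame([r.__dict__ for r in records], columns=PLANT_COLUMNS)
        return cls(df, metadata or {})

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.df["population_id"]))

    def slice(self, population: str, treatment: str | None = None) -> pd.DataFrame:
        """Rows of one population, optionally restricted to one treatment."""
        mask = self.df["population_id"] == population
        if treatment is not None:
            if treatment not in TREATMENTS:
                raise ValueError(f"unknown treatment {treatment!r}")
            mask &= self.df["treatment"] == treatment
        out = self.df[mask]
        if out.empty:
            raise EmptyGroupError(
                f"no records for population {population!r}"
                + ("" if treatment is None else f", treatment {treatment!r}")
            )
        return out

    def flowering(self) -> "Dataset":
        """Subset to plants with at least one flower (intensity defined).

        Plants that produced no flowers cannot enter intensity or selection
        analyses; they are dropped with a logged warning.
        """
        mask = self.df["n_flowers"] > 0
        n_dropped = int((~mask).sum())
        if n_dropped:
            logger.warning("dropping %d plant(s) with n_flowers = 0", n_dropped)
            out = Dataset.__new__(Dataset)
            out.df = self.df[mask].reset_index(drop=True)
            out.metadata = dict(self.metadata)
            return out
        return self


def _coerce_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df[PLANT_COLUMNS].copy()
    for col in _INT_COLUMNS:
        try:
            df[col] = df[col].astype("int64")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"column {col!r} is not integer-valued: {exc}") from exc
    for col in _FLOAT_COLUMNS:
        try:
            df[col] = df[col].astype("float64")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"column {col!r} is not numeric: {exc}") from exc
    df["population_id"] = df["population_id"].astype(str)
    df["pair_id"] = df["pair_id"].astype(str)
    df["treatment"] = df["treatment"].astype(str)
    return df


def _validate_rows(df: pd.DataFrame) -> None:
    # Header is line 1, so data row i (0-based) sits on file line i + 2.
    bad = ~df["treatment"].isin(TREATMENTS)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise RowValidationError(
            f"treatment must be HP or HE, got {df['treatment'].iloc[i]!r}", line=i + 2
        )
    for cond, msg in [
        (df["n_damaged_flowers"] > df["n_flowers"], "n_damaged_flowers > n_flowers"),
        (df["n_fruits"] > df["n_flowers"], "n_fruits > n_flowers"),
        (df["n_flowers"] < 0, "negative n_flowers"),
        (df["n_damaged_flowers"] < 0, "negative n_damaged_flowers"),
        (df["corolla_size"] <= 0, "corolla_size must be positive"),
        (df["seeds_total"] < 0, "negative seeds_total"),
    ]:
        if cond.any():
            i = int(np.flatnonzero(cond.to_numpy())[0])
            raise RowValidationError(msg, line=i + 2)


def _validate_structure(df: pd.DataFrame) -> None:
    by_pop = df.groupby("population_id")["treatment"].agg(set)
    incomplete = [p for p, s in by_pop.items() if not set(TREATMENTS) <= s]
    if incomplete:
        raise RowValidationError(
            f"population(s) missing a treatment arm: {', '.join(map(str, incomplete))}"
        )
    dup = df.duplicated(["population_id", "pair_id", "treatment"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise RowValidationError(
            "duplicate (population, pair, treatment) combination", line=i + 2
        )


def read_plant_table(path, dialect: str = "csv") -> Dataset:
    """Read a delimited plant table into a validated :class:`Dataset`.

    Parameters
    ----------
    path
        CSV (default) or TSV file with a header row naming all columns in
        :data:`PLANT_COLUMNS` (any order; extra columns are ignored).
    dialect
        ``"csv"`` or ``"tsv"``.

    Raises
    ------
    SchemaError
        If a required column is absent or non-numeric.
    RowValidationError
        If a row violates a record invariant; the message cites the
        1-based file line (header = line 1).
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    df = pd.read_csv(path, sep=sep)
    return Dataset(df)


def write_plant_table(data: Dataset, path, dialect: str = "csv") -> None:
    """Write a :class:`Dataset` back to delimited text (UTF-8, header)."""
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    data.df.to_csv(path, sep=sep, index=False)


def herbivory_intensity(plant: PlantRecord) -> float:
    """Proportion of a plant's flowers damaged by herbivores, in [0, 1]."""
    if plant.n_flowers == 0:
        raise UndefinedIntensityError(
            "herbivory intensity undefined for a plant with no flowers"
        )
    return plant.n_damaged_flowers / plant.n_flowers


def intensity_column(df: pd.DataFrame) -> pd.Series:
    """Vectorized per-plant herbivory intensity for a plant-table frame.

    Rows with ``n_flowers == 0`` must be removed first
    (see :meth:`Dataset.flowering`).
    """
    if (df["n_flowers"] == 0).any():
        raise UndefinedIntensityError(
            "frame contains plants with n_flowers = 0; drop them first"
        )
    return df["n_damaged_flowers"] / df["n_flowers"]


def population_intensity(
    data: Dataset, population: str, treatment: str
) -> tuple[float, float, int]:
    """Mean, sample SD (n-1) and n of per-plant herbivory intensity.

    Computed over the flowering plants of one population x treatment slice.
    """
    sliced = data.flowering().slice(population, treatment)
    if len(sliced) < 2:
        raise EmptyGroupError(
            f"need >= 2 flowering plants in ({population}, {treatment}), "
            f"got {len(sliced)}"
        )
    vals = intensity_column(sliced)
    return float(vals.mean()), float(vals.std(ddof=1)), int(len(vals))
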