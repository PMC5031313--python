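"""Demographic strata used throughout the model.

Every prevalence and population quantity in the pipeline is indexed by one of
30 demographic cells: five age bands (0-18, 19-45, 46-55, 56-64, 65+ years,
band edges inclusive) crossed with sex (male, female) and race (white, black,
other).  Cell assignment is a pure function of age in whole years, sex and
race; race labels outside the white/black dichotomy collapse to "other" via a
configurable mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

AGE_BANDS: tuple[str, ...] = ("0-18", "19-45", "46-55", "56-64", "65+")
SEXES: tuple[str, ...] = ("male", "female")
RACES: tuple[str, ...] = ("white", "black", "other")

# upper (inclusive) edge of each age band; None = unbounded
_AGE_UPPER: tuple[int | None, ...] = (18, 45, 55, 64, None)

#: race labels that keep their own level; everything else maps to "other"
DEFAULT_RACE_MAP: Mapping[str, str] = {"white": "white", "black": "black"}

N_CELLS = len(AGE_BANDS) * len(SEXES) * len(RACES)


@dataclass(frozen=True, order=True)
class DemographicCell:
    """One of the 30 age x sex x race strata (index j of the cost model)."""

    age_band: str
    sex: str
    race: str

    def __post_init__(self) -> None:
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}; expected one of {AGE_BANDS}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        if self.race not in RACES:
            raise ValueError(f"unknown race {self.race!r}; expected one of {RACES}")

    @property
    def index(self) -> int:
        """Canonical cell index in [0, 30): age-major, then sex, then race."""
        a = AGE_BANDS.index(self.age_band)
        s = SEXES.index(self.sex)
        r = RACES.index(self.race)
        return (a * len(SEXES) + s) * len(RACES) + r

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.age_band}/{self.sex}/{self.race}"


#: all 30 cells in canonical order
ALL_CELLS: tuple[DemographicCell, ...] = tuple(
    DemographicCell(a, s, r) for a in AGE_BANDS for s in SEXES for r in RACES
)
CELL_INDEX: Mapping[DemographicCell, int] = {c: i for i, c in enumerate(ALL_CELLS)}

#: per-cell age band index (length 30), used to select 65+ cells etc.
CELL_AGE_IDX: np.ndarray = np.array([AGE_BANDS.index(c.age_band) for c in ALL_CELLS])
CELL_SEX_IDX: np.ndarray = np.array([SEXES.index(c.sex) for c in ALL_CELLS])
CELL_RACE_IDX: np.ndarray = np.array([RACES.index(c.race) for c in ALL_CELLS])

#: boolean mask over the canonical cell order selecting the 65+ cells
MASK_65PLUS: np.ndarray = CELL_AGE_IDX == len(AGE_BANDS) - 1
#: boolean mask selecting the child (0-18) cells
MASK_CHILD: np.ndarray = CELL_AGE_IDX == 0


def age_to_band(age_years: float) -> str:
    """Map an age in whole years to its band label (edges inclusive)."""
    if age_years < 0:
        raise ValueError(f"age must be nonnegative, got {age_years}")
    for band, upper in zip(AGE_BANDS, _AGE_UPPER):
        if upper is None or age_years <= upper:
            return band
    raise AssertionError("unreachable")  # pragma: no cover


def age_to_band_index(age_years: np.ndarray) -> np.ndarray:
    """Vectorized band index for an array of ages."""
    age = np.asarray(age_years)
    if np.any(age < 0):
        raise ValueError("ages must be nonnegative")
    edges = np.array([u for u in _AGE_UPPER if u is not None])
    return np.searchsorted(edges, age, side="left").astype(int)


def normalize_race(label: str, race_map: Mapping[str, str] | None = None) -> str:
    """Collapse an input race label to the model's three levels."""
    mapping = DEFAULT_RACE_MAP if race_map is None else race_map
    return mapping.get(str(label).strip().lower(), "other")


def assign_cell(
    age_years: float, sex: str, race: str, race_map: Mapping[str, str] | None = None
) -> DemographicCell:
    """Assign a person to their unique demographic cell.

    Pure function of (age, sex, race); ``race`` may be any label and is
    collapsed through ``race_map`` (default: white/black kept, rest "other").
    """
    return DemographicCell(age_to_band(age_years), sex, normalize_race(race, race_map))


def cell_index_from_columns(
    age: np.ndarray, sex: Iterable[str], race: Iterable[str],
    race_map: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Vectorized canonical cell index for parallel age/sex/race columns."""
    a = age_to_band_index(np.asarray(age))
    sex_arr = np.asarray([SEXES.index(s) for s in sex])
    race_arr = np.asarray([RACES.index(normalize_race(r, race_map)) for r in race])
    return (a * len(SEXES) + sex_arr) * len(RACES) + race_arr
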