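"""Per-meal healthiness and nutrition scores.

Healthiness is a proxy score ``l`` in {0,1,2,3}: one point for each of
fried food, a sweetened sugar beverage, and a high-salt sauce or pickle
present in the meal. ``l = 0`` defines a healthy meal.

Nutrition is the dietary diversity score (DDS): the number of distinct
food groups, out of a 12-group registry, present in the meal. Because a
larger DDS means a *better* meal while the impact indicators point in the
unhealthy direction, the indicators use the reciprocal of DDS, normalized
over the analysis set.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError

NORMALIZATION_SCHEMES = ("max", "minmax")


def load_food_groups() -> pd.DataFrame:
    """Load the bundled 12-group food-group registry (code, name)."""
    ref = resources.files("opfe.data").joinpath("food_groups.csv")
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, dtype=str)
    if len(df) != 12 or df["code"].duplicated().any():
        raise ConfigurationError("food-group registry must hold 12 unique groups")
    return df


FOOD_GROUP_CODES: frozenset[str] = frozenset(load_food_groups()["code"])


@dataclass
class MealRecord:
    """One single-meal product: the atomic unit of the food environment."""

    outlet_id: str
    meal_id: str
    composition: tuple[str, ...]
    food_groups: frozenset[str]
    fried: bool
    sugar_beverage: bool
    high_salt: bool
    monthly_sales: int
    exclusion_flags: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.monthly_sales < 0:
            raise InvalidInputError("monthly_sales must be non-negative")
        unknown = set(self.food_groups) - FOOD_GROUP_CODES
        if unknown:
            raise InvalidInputError(f"unknown food groups: {sorted(unknown)}")


def _require_bool(value, name: str) -> bool:
    # missing labels are an error, never imputed: silent zeros would bias l
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    raise InvalidInputError(f"unhealthy-food label {name!r} must be a boolean, got {value!r}")


def healthy_score(meal: MealRecord) -> int:
    """Healthy score l: count of unhealthy proxy foods in the meal.

    l = 1[fried] + 1[sugar beverage] + 1[high-salt sauce/pickle], so
    0 <= l <= 3 and l = 0 marks a healthy meal.
    """
    return (
        _require_bool(meal.fried, "fried")
        + _require_bool(meal.sugar_beverage, "sugar_beverage")
        + _require_bool(meal.high_salt, "high_salt")
    )


def dds(meal: MealRecord) -> int:
    """Dietary diversity score: number of distinct food groups in the meal."""
    groups = set(meal.food_groups)
    if not groups:
        raise InvalidInputError("meal has no food groups; DDS is undefined")
    return len(groups)


def _check_dds_values(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("empty DDS sequence")
    if np.any(arr < 1):
        raise InvalidInputError("every DDS value must be >= 1")
    return arr


def normalize_reciprocal_dds(
    dds_values: Sequence[float] | np.ndarray, scheme: str = "max"
) -> np.ndarray:
    """Normalize the reciprocal 1/DDS over the analysis meal set.

    The default ``"max"`` scheme divides each 1/DDS by the largest
    reciprocal present, mapping the least diverse meal to 1 and keeping
    every weight strictly positive. The ``"minmax"`` alternative rescales
    to [0, 1]; it sends the most diverse meal's weight to exactly 0, which
    removes that meal's sales from the unhealthy impact sums — offered only
    for sensitivity analysis.
    """
    arr = _check_dds_values(np.asarray(dds_values))
    recip = 1.0 / arr
    return _normalize(recip, scheme)


def normalize_dds(
    dds_values: Sequence[float] | np.ndarray, scheme: str = "max"
) -> np.ndarray:
    """Normalize DDS itself (used by the healthy-outlet indicator HII)."""
    arr = _check_dds_values(np.asarray(dds_values))
    return _normalize(arr, scheme)


def _normalize(values: np.ndarray, scheme: str) -> np.ndarray:
    if scheme not in NORMALIZATION_SCHEMES:
        raise InvalidInputError(
            f"unknown normalization scheme {scheme!r}; choose from {NORMALIZATION_SCHEMES}"
        )
    if scheme == "max":
        return values / values.max()
    lo, hi = values.min(), values.max()
    if hi == lo:  # constant input: every meal carries full weight
        return np.ones_like(values)
    return (values - lo) / (hi - lo)


def score_meals(meals: pd.DataFrame, scheme: str = "max") -> pd.DataFrame:
    """Vectorized scoring of a meal table.

    Expects columns ``fried``, ``sugar_beverage``, ``high_salt`` (booleans)
    and ``food_groups`` (frozensets or semicolon-joined strings). Returns a
    copy with ``l``, ``dds``, ``dds_norm`` and ``recip_dds_norm`` columns;
    the two normalizations are computed over the whole table so that
    outlets remain comparable.
    """
    df = meals.copy()
    for col in ("fried", "sugar_beverage", "high_salt"):
        if df[col].isna().any():
            raise InvalidInputError(f"missing values in label column {col!r}")
        if not (df[col].isin([True, False]).all()):
            raise InvalidInputError(f"label column {col!r} must be boolean")
    df["l"] = (
        df["fried"].astype(int)
        + df["sugar_beverage"].astype(int)
        + df["high_salt"].astype(int)
    )

    def _groups(v) -> int:
        if isinstance(v, str):
            v = {g for g in v.split(";") if g}
        n = len(set(v))
        if n == 0:
            raise InvalidInputError("meal has no food groups; DDS is undefined")
        return n

    df["dds"] = df["food_groups"].map(_groups)
    df["dds_norm"] = normalize_dds(df["dds"].to_numpy(), scheme)
    df["recip_dds_norm"] = normalize_reciprocal_dds(df["dds"].to_numpy(), scheme)
    return df


def meal_records_to_frame(records: Iterable[MealRecord]) -> pd.DataFrame:
    """Flatten MealRecord objects into the tabular schema used downstream."""
    rows = [
        {
            "outlet_id": r.outlet_id,
            "meal_id": r.meal_id,
            "composition": ";".join(r.composition),
            "food_groups": ";".join(sorted(r.food_groups)),
            "fried": r.fried,
            "sugar_beverage": r.sugar_beverage,
            "high_salt": r.high_salt,
            "monthly_sales": r.monthly_sales,
            "exclusion_flags": ";".join(sorted(r.exclusion_flags)),
        }
        for r in records
    ]
    return pd.DataFrame(rows)
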