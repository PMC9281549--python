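"""Two-level classification system for takeaway meals and food outlets.

The registry holds 3 Level I categories (1 = Meal, 2 = Snacks and Beverage,
3 = Other) and 14 Level II categories, each with a string code whose prefix
is its Level I code (e.g. ``"1-7"`` for western fast-food) and a unique
short name (ST, ND, SET, ...).

Classification is rule-based and deterministic:

* a meal composed of items from a single Level II category takes that
  category;
* when the Level I groups tie in item count, Level I code 1 (Meal) has
  priority and the modal Level II code within the winning Level I decides;
* otherwise the modal Level II code across all items decides;
* an outlet takes the category of the meals it sells most, subject to a
  dominance check (the max/min count ratio, MMR), and falls back to
  Unknown ``"3-1"`` on a tie or when dominance fails.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, InvalidInputError

UNKNOWN_CODE = "3-1"

#: Level II codes retained in the analysis set (single-meal products only).
MEAL_ANALYSIS_CODES = frozenset({"1-1", "1-2", "1-3", "1-7", "1-8"})


@dataclass(frozen=True)
class TaxonomyCategory:
    level1_code: int
    level1_name: str
    level2_code: str
    level2_name: str
    short_name: str
    description: str


class Taxonomy:
    """Registry of the bundled category system with code/short-name lookup."""

    def __init__(self, categories: Sequence[TaxonomyCategory]):
        self.categories = tuple(categories)
        self._by_code: Mapping[str, TaxonomyCategory] = {
            c.level2_code: c for c in self.categories
        }
        self._by_short: Mapping[str, TaxonomyCategory] = {
            c.short_name: c for c in self.categories
        }
        self._validate()

    def _validate(self) -> None:
        level1 = {c.level1_code for c in self.categories}
        if len(level1) != 3:
            raise ConfigurationError(
                f"expected 3 Level I categories, found {len(level1)}"
            )
        if len(self.categories) != 14:
            raise ConfigurationError(
                f"expected 14 Level II categories, found {len(self.categories)}"
            )
        if len(self._by_code) != len(self.categories):
            raise ConfigurationError("duplicate Level II codes in registry")
        if len(self._by_short) != len(self.categories):
            raise ConfigurationError("duplicate short names in registry")
        for c in self.categories:
            prefix = c.level2_code.split("-", 1)[0]
            if prefix != str(c.level1_code):
                raise ConfigurationError(
                    f"Level II code {c.level2_code} does not carry "
                    f"Level I prefix {c.level1_code}"
                )

    def __len__(self) -> int:
        return len(self.categories)

    @property
    def level1_codes(self) -> set[int]:
        return {c.level1_code for c in self.categories}

    @property
    def level2_codes(self) -> set[str]:
        return set(self._by_code)

    def by_code(self, level2_code: str) -> TaxonomyCategory:
        try:
            return self._by_code[level2_code]
        except KeyError:
            raise InvalidInputError(f"unknown Level II code: {level2_code!r}") from None

    def by_short_name(self, short_name: str) -> TaxonomyCategory:
        try:
            return self._by_short[short_name]
        except KeyError:
            raise InvalidInputError(f"unknown short name: {short_name!r}") from None

    def level1_of(self, level2_code: str) -> int:
        return self.by_code(level2_code).level1_code


def load_taxonomy() -> Taxonomy:
    """Load the bundled category registry.

    Returns
    -------
    Taxonomy
        Registry with 3 Level I and 14 Level II categories.
    """
    ref = resources.files("opfe.data").joinpath("taxonomy.csv")
    try:
        with ref.open("r", encoding="utf-8") as fh:
            df = pd.read_csv(fh, dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise ConfigurationError(f"cannot read bundled taxonomy: {exc}") from exc
    required = {"level1", "code1", "level2", "code2", "short_name", "description"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"bundled taxonomy missing columns: {sorted(required - set(df.columns))}"
        )
    cats = [
        TaxonomyCategory(
            level1_code=int(row.code1),
            level1_name=row.level1,
            level2_code=row.code2,
            level2_name=row.level2,
            short_name=row.short_name,
            description=row.description,
        )
        for row in df.itertuples(index=False)
    ]
    return Taxonomy(cats)


def _modal_code(codes: Iterable[str]) -> str:
    """Most frequent code; ties break to the smallest code string."""
    counts = Counter(codes)
    best = max(counts.values())
    return min(c for c, n in counts.items() if n == best)


def classify_meal(
    composition: Sequence[str],
    taxonomy: Taxonomy | None = None,
    *,
    level1_tolerance: float = 0.0,
) -> str:
    """Assign a Level II category to a meal from its item categories.

    Parameters
    ----------
    composition
        Multiset (any sequence) of Level II codes, one per item in the meal.
    taxonomy
        Registry used for code validation; the bundled one by default.
    level1_tolerance
        Relative tolerance under which Level I item counts are considered
        "the same or similar" (0 means exactly equal).

    Returns
    -------
    str
        The meal's Level II code.
    """
    if taxonomy is None:
        taxonomy = load_taxonomy()
    items = list(composition)
    if not items:
        raise InvalidInputError("meal composition is empty")
    for code in items:
        taxonomy.by_code(code)  # raises on unknown code

    distinct = set(items)
    if len(distinct) == 1:  # single Level II category
        return items[0]

    level1_counts = Counter(taxonomy.level1_of(c) for c in items)
    if len(level1_counts) > 1:
        lo, hi = min(level1_counts.values()), max(level1_counts.values())
        if hi - lo <= level1_tolerance * hi:
            # Level I groups tie: priority to the smallest Level I code,
            # then the modal Level II code within it.
            winner = min(level1_counts)
            within = [c for c in items if taxonomy.level1_of(c) == winner]
            return _modal_code(within)
    return _modal_code(items)


def max_min_ratio(counts: Mapping[str, int]) -> float:
    """Ratio of the largest to the smallest category count (MMR)."""
    values = list(counts.values())
    return max(values) / min(values)


def classify_outlet(
    meal_categories: Sequence[str],
    taxonomy: Taxonomy | None = None,
    *,
    mmr_cutoff: float = 1.5,
) -> str:
    """Assign a Level II category to an outlet from its meals' categories.

    An outlet selling a single meal type takes that type. Otherwise the
    modal type wins provided it is unique and the max/min count ratio (MMR)
    across the types sold reaches ``mmr_cutoff``; a modal tie or a failed
    dominance check yields Unknown ``"3-1"``.
    """
    if taxonomy is None:
        taxonomy = load_taxonomy()
    cats = list(meal_categories)
    if not cats:
        raise InvalidInputError("outlet has no classified meals")
    for code in cats:
        taxonomy.by_code(code)

    counts = Counter(cats)
    if len(counts) == 1:
        return cats[0]
    best = max(counts.values())
    modal = [c for c, n in counts.items() if n == best]
    if len(modal) > 1:  # same or similar number of meal types
        return UNKNOWN_CODE
    if max_min_ratio(counts) < mmr_cutoff:
        return UNKNOWN_CODE
    return modal[0]
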