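"""Table readers/writers, GeoJSON polygon I/O and record-exclusion filtering.

The meal CSV schema (strict; booleans are 0/1, sets are semicolon-joined):

=================  =========================================================
column             contents
=================  =========================================================
outlet_id          outlet identifier (string)
meal_id            meal identifier, unique within the table
composition        Level II codes of the meal's items, ``;``-separated
food_groups        food-group codes from the 12-group registry, ``;``-sep.
fried              0/1 — meal contains fried food
sugar_beverage     0/1 — meal contains a sweetened sugar beverage
high_salt          0/1 — meal contains a high-salt sauce or pickle
monthly_sales      non-negative integer, units sold in the recorded month
exclusion_flags    ``;``-separated rule codes i..x, may be empty
=================  =========================================================

Exclusion filtering is flag-driven: recognizing, say, a multi-person group
meal from its name is manual interpretation performed upstream, and this
module only consumes its output. A record is dropped if it carries an
active flag (attributed to the first matching rule in i..x order) or if its
meal category falls outside the five single-meal types retained for
analysis (ST, ND, SET, WFF, HLR).
"""

from __future__ import annotations

import json
from typing import Sequence

import pandas as pd
from shapely.geometry import mapping, shape

from .errors import ConfigurationError, SchemaError
from .scoring import FOOD_GROUP_CODES
from .taxonomy import MEAL_ANALYSIS_CODES

#: Record-exclusion rule codes, in the order used for attribution.
EXCLUSION_RULES = ("i", "ii", "iii", "iv", "v", "vi", "vii", "viii", "ix", "x")

MEAL_COLUMNS = (
    "outlet_id",
    "meal_id",
    "composition",
    "food_groups",
    "fried",
    "sugar_beverage",
    "high_salt",
    "monthly_sales",
    "exclusion_flags",
)
BOOL_COLUMNS = ("fried", "sugar_beverage", "high_salt")

#: Human-readable register of the record-exclusion rules.
EXCLUSION_RULE_DESCRIPTIONS = {
    "i": "sauce ingredients",
    "ii": "separate beverages or other drinks",
    "iii": "concomitant or packaged food not deliverable alone",
    "iv": "pot, fried-and-BBQ, or seafood category food",
    "v": "multi-person set meals or group meals",
    "vi": "separate stir-fried/cold dishes or separate staple foods",
    "vii": "items sold separately by delicatessen",
    "viii": "single soups",
    "ix": "non-meal items such as cakes, candies, dried fruits, snacks",
    "x": "other foods not recognizable as a meal",
}


def _parse_bool(value, column: str, line: int) -> bool:
    s = str(value).strip()
    if s == "0":
        return False
    if s == "1":
        return True
    raise SchemaError(f"line {line}: column {column!r} must be 0/1, got {value!r}")


def read_meal_table(path) -> tuple[pd.DataFrame, list[str]]:
    """Read and validate a meal CSV.

    Returns the validated frame (booleans decoded, food-group membership
    checked) and a list of row-level error messages; rows with errors are
    dropped rather than silently kept. A missing column raises
    :class:`SchemaError` immediately.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(MEAL_COLUMNS) - set(raw.columns)
    if missing:
        raise SchemaError(f"meal table missing required columns: {sorted(missing)}")

    errors: list[str] = []
    keep = []
    for idx, row in enumerate(raw.itertuples(index=False), start=2):  # 1-based + header
        try:
            rec = {
                "outlet_id": row.outlet_id,
                "meal_id": row.meal_id,
                "composition": row.composition,
                "food_groups": row.food_groups,
                "fried": _parse_bool(row.fried, "fried", idx),
                "sugar_beverage": _parse_bool(row.sugar_beverage, "sugar_beverage", idx),
                "high_salt": _parse_bool(row.high_salt, "high_salt", idx),
                "monthly_sales": int(row.monthly_sales),
                "exclusion_flags": row.exclusion_flags,
            }
            if rec["monthly_sales"] < 0:
                raise SchemaError(f"line {idx}: negative monthly_sales")
            groups = {g for g in rec["food_groups"].split(";") if g}
            if not groups:
                raise SchemaError(f"line {idx}: empty food_groups")
            unknown = groups - FOOD_GROUP_CODES
            if unknown:
                raise SchemaError(f"line {idx}: unknown food groups {sorted(unknown)}")
            for flag in rec["exclusion_flags"].split(";"):
                if flag and flag not in EXCLUSION_RULES:
                    raise SchemaError(f"line {idx}: unknown exclusion flag {flag!r}")
            keep.append(rec)
        except (SchemaError, ValueError) as exc:
            errors.append(str(exc))
    return pd.DataFrame(keep, columns=MEAL_COLUMNS), errors


def write_meal_table(df: pd.DataFrame, path) -> None:
    """Write a meal table in the documented schema (booleans as 0/1)."""
    out = df.copy()
    for col in BOOL_COLUMNS:
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False, columns=list(MEAL_COLUMNS))


def read_outlet_table(path) -> pd.DataFrame:
    """Read an outlet CSV with outlet_id and either x/y (metres) or lon/lat."""
    df = pd.read_csv(path)
    if "outlet_id" not in df.columns:
        raise SchemaError("outlet table missing column 'outlet_id'")
    if not ({"x", "y"} <= set(df.columns) or {"lon", "lat"} <= set(df.columns)):
        raise SchemaError("outlet table needs x/y or lon/lat columns")
    return df


def read_polygons(path) -> list[tuple[str, object]]:
    """Read (id, geometry) pairs from a GeoJSON FeatureCollection.

    The feature id comes from the ``id`` member or an ``id``/``name``
    property; file order is preserved (it decides boundary ties downstream).
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise SchemaError("polygon file must be a GeoJSON FeatureCollection")
    polygons = []
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        pid = feat.get("id") or props.get("id") or props.get("name") or f"feature-{i}"
        geom = shape(feat["geometry"])
        polygons.append((str(pid), geom))
    return polygons


def write_polygons(polygons: Sequence[tuple[str, object]], path) -> None:
    features = [
        {
            "type": "Feature",
            "id": pid,
            "properties": {"id": pid},
            "geometry": mapping(geom),
        }
        for pid, geom in polygons
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def apply_exclusions(
    meals: pd.DataFrame,
    active_rules: Sequence[str] = EXCLUSION_RULES,
    *,
    meal_categories: pd.Series | None = None,
    allowed_categories: frozenset[str] = MEAL_ANALYSIS_CODES,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop flagged records and meals outside the retained categories.

    Each dropped record is attributed to exactly one reason: the first
    active flag it carries in i..x order, or ``"category"`` when only its
    classified meal type (``meal_categories``, aligned with ``meals``)
    falls outside ``allowed_categories``. Returns the retained frame and a
    per-rule count report.
    """
    for rule in active_rules:
        if rule not in EXCLUSION_RULES:
            raise ConfigurationError(f"unknown exclusion rule {rule!r}")
    active = [r for r in EXCLUSION_RULES if r in set(active_rules)]

    report = {r: 0 for r in active}
    report["category"] = 0
    drop = []
    for idx, row in meals.iterrows():
        flags = {f for f in str(row["exclusion_flags"]).split(";") if f}
        hit = next((r for r in active if r in flags), None)
        if hit is not None:
            report[hit] += 1
            drop.append(idx)
            continue
        if meal_categories is not None and meal_categories.loc[idx] not in allowed_categories:
            report["category"] += 1
            drop.append(idx)
    kept = meals.drop(index=drop)
    return kept, report
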