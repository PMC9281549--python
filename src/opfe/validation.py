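"""Replicate-based checks that the indicator pipeline recovers planted structure.

Two seeded studies:

* :func:`paperlike_ordering_replicates` — does the end-to-end pipeline
  recover the expected qualitative per-type orderings (mean healthy score:
  HLR lowest / WFF highest; mean DDS: HLR highest / ST lowest) and a
  positive mean standardized TUHII for western fast-food outlets?
* :func:`planted_cluster_detection` — when one polygon is planted with a
  cluster of high-sales, unhealthy-leaning outlets, does the maximum of the
  UHII kernel-density surface fall inside that polygon?
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Point

from .indicators import compute_outlet_indicators
from .scoring import score_meals
from .spatial import kernel_density
from .synthetic import GeneratorConfig, default_paperlike_config, generate
from .taxonomy import classify_meal, load_taxonomy

CODE = {"ST": "1-1", "ND": "1-2", "SET": "1-3", "WFF": "1-7", "HLR": "1-8"}


def _scored_tables(config: GeneratorConfig):
    taxonomy = load_taxonomy()
    data = generate(config)
    meals = data["meals"].copy()
    for col in ("fried", "sugar_beverage", "high_salt"):
        meals[col] = meals[col].astype(bool)
    meals["category"] = [
        classify_meal([c for c in comp.split(";") if c], taxonomy)
        for comp in meals["composition"]
    ]
    scored = score_meals(meals)
    return scored, data, taxonomy


def paperlike_ordering_replicates(
    n_replicates: int = 20, n_outlets: int = 800, seed: int = 0
) -> dict:
    """Count replicates reproducing the qualitative per-type orderings.

    Returns per-check success counts over ``n_replicates`` seeded runs:
    ``l_order`` (mean l: HLR < ND < overall < ST < WFF), ``dds_order``
    (mean DDS: ST < ND < overall < WFF < HLR) and ``wff_ztuhii_positive``
    (mean z-TUHII of WFF outlets > 0).
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    counts = {"l_order": 0, "dds_order": 0, "wff_ztuhii_positive": 0}
    for s in seeds:
        scored, _, taxonomy = _scored_tables(
            default_paperlike_config(seed=int(s), n_outlets=n_outlets)
        )
        by_type = scored.groupby("category").agg(l=("l", "mean"), dds=("dds", "mean"))
        l = by_type["l"]
        d = by_type["dds"]
        l_tot = scored["l"].mean()
        d_tot = scored["dds"].mean()
        if l[CODE["HLR"]] < l[CODE["ND"]] < l_tot < l[CODE["ST"]] < l[CODE["WFF"]]:
            counts["l_order"] += 1
        if d[CODE["ST"]] < d[CODE["ND"]] < d_tot < d[CODE["WFF"]] < d[CODE["HLR"]]:
            counts["dds_order"] += 1
        outlet_table = compute_outlet_indicators(scored, taxonomy)
        wff = outlet_table.loc[outlet_table["category"] == CODE["WFF"], "z_TUHII"]
        if len(wff) > 0 and wff.mean() > 0:
            counts["wff_ztuhii_positive"] += 1
    counts["n_replicates"] = n_replicates
    return counts


def planted_cluster_config(seed: int, n_outlets: int = 300) -> GeneratorConfig:
    """Paper-like config with one polygon planted full of heavy-sales WFF/ST outlets."""
    config = default_paperlike_config(seed=seed, n_outlets=n_outlets)
    config.grid_dims = (3, 3)
    config.polygon_size = 1000.0
    config.planted_cluster = {
        "polygon_id": "P11",  # centre cell of the 3x3 grid
        "type_mixture": {"WFF": 0.85, "ST": 0.15},
    }
    return config


def planted_cluster_detection(
    n_replicates: int = 50,
    n_outlets: int = 300,
    seed: int = 0,
    *,
    cell_size: float = 30.0,
    bandwidth: float = 300.0,
) -> dict:
    """Share of replicates whose maximum UHII density cell lies in the cluster."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    hits = 0
    for s in seeds:
        config = planted_cluster_config(seed=int(s), n_outlets=n_outlets)
        scored, data, taxonomy = _scored_tables(config)
        outlet_table = compute_outlet_indicators(scored, taxonomy)
        outlet_table = outlet_table.merge(
            data["outlets"][["outlet_id", "x", "y"]], on="outlet_id"
        )
        unhealthy = outlet_table.dropna(subset=["UHII"])
        surface = kernel_density(
            unhealthy[["x", "y"]].to_numpy(),
            unhealthy["UHII"].to_numpy(),
            cell_size=cell_size,
            bandwidth=bandwidth,
        )
        x, y = surface.argmax_xy()
        cluster_geom = dict(data["polygons"])[config.planted_cluster["polygon_id"]]
        if cluster_geom.covers(Point(x, y)):
            hits += 1
    return {"hits": hits, "n_replicates": n_replicates, "rate": hits / n_replicates}
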