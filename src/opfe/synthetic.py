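"""Seeded synthetic takeaway-food-environment datasets.

The generator emulates the statistical structure the indicator system
assumes in real platform data: outlets of several types scattered over a
grid of administrative polygons, each selling tens of single-meal products
whose unhealthy-label probabilities, food-group richness and monthly sales
depend on the outlet type. It exists so that every pipeline stage is
testable without the proprietary platform crawl; it makes no claim to
reproduce that crawl's actual distributions.

The default configuration orders the per-type expectations the way a
Chinese takeaway market plausibly does: light-recipe outlets (HLR) sell
the healthiest (lowest expected healthy score l) and most diverse
(highest expected DDS) meals, western fast-food (WFF) the unhealthiest,
and staple-rice outlets (ST) the least diverse; WFF outlets also move the
largest monthly volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import ConfigurationError
from .scoring import load_food_groups

from .io import EXCLUSION_RULES

MEAL_TYPES = ("ST", "ND", "SET", "WFF", "HLR")
OUTLET_TYPES = MEAL_TYPES + ("UN",)
SHORT_TO_CODE = {"ST": "1-1", "ND": "1-2", "SET": "1-3", "WFF": "1-7", "HLR": "1-8"}


@dataclass
class TypeParams:
    """Per-outlet-type generative parameters.

    ``p_fried``/``p_sugar``/``p_salt`` are the per-meal probabilities of
    the three unhealthy labels (their sum is the expected healthy score l);
    ``dds_mean`` is the expected number of distinct food groups (support
    1-12); ``sales_mu``/``sales_sigma`` parameterize log-normal monthly
    sales; ``group_bias`` optionally up-weights particular food groups.
    """

    p_fried: float
    p_sugar: float
    p_salt: float
    dds_mean: float
    sales_mu: float
    sales_sigma: float
    group_bias: dict[str, float] = field(default_factory=dict)
    #: share of outlets of this type that sell only healthy meals (W = 1);
    #: real platforms show a sizeable fully-healthy outlet group.
    p_all_healthy: float = 0.0

    @property
    def expected_l(self) -> float:
        return self.p_fried + self.p_sugar + self.p_salt

    def validate(self) -> None:
        for name, p in (
            ("p_fried", self.p_fried),
            ("p_sugar", self.p_sugar),
            ("p_salt", self.p_salt),
            ("p_all_healthy", self.p_all_healthy),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if not 1.0 <= self.dds_mean <= 12.0:
            raise ConfigurationError(f"dds_mean must be in [1, 12], got {self.dds_mean}")
        if self.sales_sigma < 0:
            raise ConfigurationError("sales_sigma must be non-negative")


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_outlets: int = 800
    grid_dims: tuple[int, int] = (3, 3)  # polygon grid (rows, cols)
    polygon_size: float = 2000.0  # metres per grid cell
    type_mixture: dict[str, float] = field(default_factory=dict)
    type_params: dict[str, TypeParams] = field(default_factory=dict)
    meals_per_outlet: tuple[int, int] = (8, 40)
    meal_type_purity: float = 0.9  # share of a typed outlet's meals in its own type
    un_all_healthy_rate: float = 0.12  # W = 1 rate for mixed-menu (UN) outlets
    exclusion_rate: float = 0.0  # fraction of meals carrying a random exclusion flag
    planted_cluster: dict | None = None  # {"polygon_id": ..., "type_mixture": {...}}

    def validate(self) -> None:
        if self.n_outlets < 1:
            raise ConfigurationError("n_outlets must be positive")
        if set(self.type_mixture) - set(OUTLET_TYPES):
            raise ConfigurationError(f"unknown outlet types in mixture: {self.type_mixture}")
        total = sum(self.type_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"type mixture must sum to 1, got {total}")
        if any(w < 0 for w in self.type_mixture.values()):
            raise ConfigurationError("mixture weights must be non-negative")
        for t, params in self.type_params.items():
            if t not in MEAL_TYPES:
                raise ConfigurationError(f"unknown meal type {t!r}")
            params.validate()
        lo, hi = self.meals_per_outlet
        if not (1 <= lo <= hi):
            raise ConfigurationError("invalid meals_per_outlet range")
        if not 0.0 <= self.exclusion_rate <= 1.0:
            raise ConfigurationError("exclusion_rate must be in [0, 1]")


def default_paperlike_config(seed: int = 0, n_outlets: int = 800) -> GeneratorConfig:
    """Configuration whose per-type expectations follow the field's ordering.

    Expected healthy score: HLR < ND < overall < ST < WFF.
    Expected DDS: ST < ND < overall < WFF < HLR.
    Noodle/dumpling (ND) and set-meal (SET) outlets dominate the mixture,
    and WFF outlets have the heaviest sales, so their unhealthy impact per
    outlet is high despite their small count.
    """
    params = {
        "HLR": TypeParams(0.06, 0.04, 0.04, dds_mean=6.3, sales_mu=3.0, sales_sigma=0.8,
                          group_bias={"vegetables": 3.0, "fruits": 3.0, "mushrooms_algae": 2.0},
                          p_all_healthy=0.45),
        "ND": TypeParams(0.10, 0.06, 0.14, dds_mean=4.7, sales_mu=3.2, sales_sigma=0.8,
                         group_bias={"cereals": 3.0, "meat_poultry_offal": 2.0},
                         p_all_healthy=0.18),
        "SET": TypeParams(0.18, 0.10, 0.17, dds_mean=4.9, sales_mu=3.2, sales_sigma=0.8,
                          group_bias={"cereals": 3.0, "vegetables": 2.0},
                          p_all_healthy=0.12),
        "ST": TypeParams(0.30, 0.12, 0.22, dds_mean=4.5, sales_mu=3.1, sales_sigma=0.8,
                         group_bias={"cereals": 4.0, "eggs": 2.0},
                         p_all_healthy=0.08),
        "WFF": TypeParams(0.45, 0.24, 0.10, dds_mean=5.3, sales_mu=4.2, sales_sigma=0.8,
                          group_bias={"cereals": 2.0, "meat_poultry_offal": 3.0, "dairy": 2.0},
                          p_all_healthy=0.05),
    }
    mixture = {"ST": 0.12, "ND": 0.33, "SET": 0.32, "WFF": 0.08, "HLR": 0.07, "UN": 0.08}
    return GeneratorConfig(
        seed=seed, n_outlets=n_outlets, type_mixture=mixture, type_params=params
    )


def _grid_polygons(dims: tuple[int, int], size: float) -> list[tuple[str, Polygon]]:
    rows, cols = dims
    polys = []
    for r in range(rows):
        for c in range(cols):
            x0, y0 = c * size, r * size
            polys.append(
                (
                    f"P{r}{c}",
                    Polygon(
                        [(x0, y0), (x0 + size, y0), (x0 + size, y0 + size), (x0, y0 + size)]
                    ),
                )
            )
    return polys


def _sample_food_groups(rng, params: TypeParams, codes: list[str]) -> list[str]:
    # group count ~ 1 + Binomial(11, (mean-1)/11), keeping the expectation at dds_mean
    p = (params.dds_mean - 1.0) / 11.0
    k = 1 + rng.binomial(11, p)
    w = np.array([params.group_bias.get(c, 1.0) for c in codes], dtype=float)
    w /= w.sum()
    chosen = rng.choice(len(codes), size=k, replace=False, p=w)
    return [codes[j] for j in chosen]


def generate(config: GeneratorConfig) -> dict:
    """Generate outlet and meal tables plus the polygon set.

    Fully reproducible given ``config.seed``. Returns a dict with keys
    ``outlets`` (outlet_id, x, y, true_type), ``meals`` (the documented
    meal CSV schema) and ``polygons`` (list of (id, shapely Polygon)).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    polygons = _grid_polygons(config.grid_dims, config.polygon_size)
    group_codes = load_food_groups()["code"].tolist()

    types = list(config.type_mixture)
    weights = np.array([config.type_mixture[t] for t in types])
    cluster = config.planted_cluster or {}
    cluster_pid = cluster.get("polygon_id")
    cluster_mix = cluster.get("type_mixture")
    if cluster_mix is not None:
        c_types = list(cluster_mix)
        c_weights = np.array([cluster_mix[t] for t in c_types])
        if abs(c_weights.sum() - 1.0) > 1e-9:
            raise ConfigurationError("planted-cluster mixture must sum to 1")

    poly_ids = [pid for pid, _ in polygons]
    if cluster_pid is not None and cluster_pid not in poly_ids:
        raise ConfigurationError(f"planted cluster polygon {cluster_pid!r} not in grid")

    outlet_rows, meal_rows = [], []
    for k in range(config.n_outlets):
        pid = poly_ids[rng.integers(len(poly_ids))]
        geom = dict(polygons)[pid]
        minx, miny, maxx, maxy = geom.bounds
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if pid == cluster_pid and cluster_mix is not None:
            otype = c_types[rng.choice(len(c_types), p=c_weights)]
        else:
            otype = types[rng.choice(len(types), p=weights)]
        oid = f"O{k:05d}"
        if otype == "UN":
            healthy_rate = config.un_all_healthy_rate
        else:
            healthy_rate = config.type_params[otype].p_all_healthy
        all_healthy = rng.random() < healthy_rate
        outlet_rows.append(
            {"outlet_id": oid, "x": x, "y": y, "true_type": otype, "all_healthy": all_healthy}
        )

        n_meals = int(rng.integers(config.meals_per_outlet[0], config.meals_per_outlet[1] + 1))
        for m in range(n_meals):
            if otype == "UN":
                mtype = MEAL_TYPES[rng.integers(len(MEAL_TYPES))]
            elif rng.random() < config.meal_type_purity:
                mtype = otype
            else:
                mtype = MEAL_TYPES[rng.integers(len(MEAL_TYPES))]
            params = config.type_params[mtype]
            groups = _sample_food_groups(rng, params, group_codes)
            sales = int(np.round(rng.lognormal(params.sales_mu, params.sales_sigma)))
            flags = ""
            if config.exclusion_rate > 0 and rng.random() < config.exclusion_rate:
                flags = EXCLUSION_RULES[rng.integers(len(EXCLUSION_RULES))]
            meal_rows.append(
                {
                    "outlet_id": oid,
                    "meal_id": f"{oid}-M{m:03d}",
                    "composition": SHORT_TO_CODE[mtype],
                    "food_groups": ";".join(sorted(groups)),
                    "fried": int(not all_healthy and rng.random() < params.p_fried),
                    "sugar_beverage": int(not all_healthy and rng.random() < params.p_sugar),
                    "high_salt": int(not all_healthy and rng.random() < params.p_salt),
                    "monthly_sales": sales,
                    "exclusion_flags": flags,
                }
            )

    return {
        "outlets": pd.DataFrame(outlet_rows),
        "meals": pd.DataFrame(meal_rows),
        "polygons": polygons,
    }
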