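"""Outlet-level impact indicators.

An outlet's health weight W is the fraction of its meals that are healthy
(healthy score l = 0). Outlets partition into healthy (W = 1) and unhealthy
(W < 1), and three sales-weighted impact indicators are defined per outlet:

* TUHII = sum_i l_i * r_i * S_i over all meals (total unhealthy impact),
* HII   = sum_i d_i * S_i for healthy outlets only,
* UHII  = sum_i r_i * S_i for unhealthy outlets only,

where S_i is monthly sales, d_i the normalized DDS and r_i the normalized
reciprocal DDS of meal i. Note that UHII deliberately carries no l factor:
it sums over ALL of an unhealthy outlet's meals, healthy ones included.

Indicators are Z-standardized (TUHII across all outlets; HII within the
healthy subset; UHII within the unhealthy subset) and quartile-labelled,
and between-category differences are tested with Levene's test followed by
classic or Welch's one-way ANOVA.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InvalidInputError, StateError
from .taxonomy import Taxonomy, classify_outlet

W_LABELS = ("uH", "ruH", "rH", "H")
Q_LABELS = ("Q1", "Q2", "Q3", "Q4")


def health_weight(l_values: Sequence[int] | np.ndarray) -> float:
    """Health weight W = N_h / N_t: share of an outlet's meals with l = 0."""
    arr = np.asarray(l_values)
    if arr.size == 0:
        raise InvalidInputError("outlet has no meals; health weight undefined")
    return float(np.mean(arr == 0))


def _check_meal_arrays(*arrays) -> tuple[np.ndarray, ...]:
    out = []
    n = None
    for a in arrays:
        arr = np.asarray(a, dtype=float)
        if np.isnan(arr).any():
            raise StateError(
                "missing normalized scores: run the DDS normalization over "
                "the analysis set before computing indicators"
            )
        if n is not None and arr.size != n:
            raise InvalidInputError("meal arrays have mismatched lengths")
        n = arr.size
        out.append(arr)
    return tuple(out)


def tuhii(
    l: Sequence[int] | np.ndarray,
    recip_dds_norm: Sequence[float] | np.ndarray,
    sales: Sequence[float] | np.ndarray,
) -> float:
    """Total unhealthy impact: sum of l_i * r_i * S_i over the outlet's meals."""
    l_arr, r_arr, s_arr = _check_meal_arrays(l, recip_dds_norm, sales)
    return float(np.sum(l_arr * r_arr * s_arr))


def hii(
    dds_norm: Sequence[float] | np.ndarray,
    sales: Sequence[float] | np.ndarray,
    *,
    w: float = 1.0,
) -> float:
    """Healthy-outlet impact: sum of d_i * S_i. Defined only when W = 1."""
    if w != 1.0:
        raise InvalidInputError(f"HII is defined only for healthy outlets (W = 1), got W = {w}")
    d_arr, s_arr = _check_meal_arrays(dds_norm, sales)
    return float(np.sum(d_arr * s_arr))


def uhii(
    recip_dds_norm: Sequence[float] | np.ndarray,
    sales: Sequence[float] | np.ndarray,
    *,
    w: float = 0.0,
) -> float:
    """Unhealthy-outlet impact: sum of r_i * S_i over ALL the outlet's meals.

    Defined only when W < 1. There is no l factor, so an unhealthy outlet's
    healthy meals still contribute their sales-weighted terms.
    """
    if w >= 1.0:
        raise InvalidInputError(f"UHII is defined only for unhealthy outlets (W < 1), got W = {w}")
    r_arr, s_arr = _check_meal_arrays(recip_dds_norm, sales)
    return float(np.sum(r_arr * s_arr))


def z_standardize(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Z-score with the sample (n-1) standard deviation."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DegenerateInputError("Z-standardization needs at least 2 values")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("cannot Z-standardize a constant sequence")
    return (arr - arr.mean()) / sd


def quartile_labels(
    values: Sequence[float] | np.ndarray, scheme: str = "indicator"
) -> np.ndarray:
    """Quartile-group labels for health weight or a standardized indicator.

    ``scheme="W"`` yields H (>= 75% quantile), rH (median <= x < 75%),
    ruH (25% <= x < median), uH (< 25%); ``scheme="indicator"`` yields
    Q4/Q3/Q2/Q1 with the same boundary rule. Quantiles use the linear
    interpolation definition.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise DegenerateInputError("quartile labelling needs at least 4 values")
    if scheme == "W":
        labels = W_LABELS
    elif scheme == "indicator":
        labels = Q_LABELS
    else:
        raise InvalidInputError(f"unknown quartile scheme {scheme!r}")
    q25, q50, q75 = np.quantile(arr, [0.25, 0.50, 0.75])
    if q25 == q75:
        warnings.warn("degenerate quartiles: all values collapse to the top group")
    out = np.where(
        arr >= q75, labels[3],
        np.where(arr >= q50, labels[2], np.where(arr >= q25, labels[1], labels[0])),
    )
    return out.astype(object)


def group_difference_test(
    values: Sequence[float] | np.ndarray,
    group_labels: Sequence,
) -> dict:
    """Levene's test, then classic or Welch's one-way ANOVA.

    Levene's test (centered at the mean) decides homoscedasticity at the
    0.05 level; the classic F-test is used when variances are homogeneous,
    Welch's ANOVA otherwise. Groups with fewer than 2 observations are
    dropped with a warning.
    """
    arr = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if arr.size != labels.size:
        raise InvalidInputError("values and group labels have different lengths")
    groups = {}
    for g in pd.unique(labels):
        sample = arr[labels == g]
        if sample.size < 2:
            warnings.warn(f"group {g!r} has fewer than 2 observations; excluded")
            continue
        groups[g] = sample
    if len(groups) < 2:
        raise DegenerateInputError("need at least 2 groups with >= 2 observations")

    samples = list(groups.values())
    levene_f, levene_p = stats.levene(*samples, center="mean")
    if levene_p >= 0.05:
        kind = "anova"
        f, p = stats.f_oneway(*samples)
    else:
        kind = "welch"
        import pingouin as pg

        long = pd.DataFrame(
            {
                "value": np.concatenate(samples),
                "group": np.repeat(
                    [str(g) for g in groups], [s.size for s in samples]
                ),
            }
        )
        res = pg.welch_anova(data=long, dv="value", between="group")
        pcol = "p_unc" if "p_unc" in res.columns else "p-unc"
        f, p = float(res["F"].iloc[0]), float(res[pcol].iloc[0])
    return {
        "levene_F": float(levene_f),
        "levene_p": float(levene_p),
        "anova_kind": kind,
        "F": float(f),
        "p": float(p),
        "n_groups": len(groups),
    }


def compute_outlet_indicators(
    scored_meals: pd.DataFrame,
    taxonomy: Taxonomy | None = None,
    *,
    mmr_cutoff: float = 1.5,
) -> pd.DataFrame:
    """Aggregate a scored meal table into one indicator row per outlet.

    Requires the columns produced by :func:`opfe.scoring.score_meals` plus
    ``outlet_id``, ``category`` (the meal's Level II code) and
    ``monthly_sales``. Returns a frame with outlet category, n_meals, W,
    TUHII, HII/UHII (each NaN where undefined), Z-standardized indicators
    (TUHII over all outlets, HII within W = 1, UHII within W < 1) and the
    quartile labels.
    """
    required = {"outlet_id", "category", "l", "dds_norm", "recip_dds_norm", "monthly_sales"}
    missing = required - set(scored_meals.columns)
    if missing:
        raise InvalidInputError(f"scored meal table missing columns: {sorted(missing)}")

    rows = []
    for outlet_id, grp in scored_meals.groupby("outlet_id", sort=True):
        w = health_weight(grp["l"].to_numpy())
        t = tuhii(grp["l"], grp["recip_dds_norm"], grp["monthly_sales"])
        row = {
            "outlet_id": outlet_id,
            "category": classify_outlet(
                grp["category"].tolist(), taxonomy, mmr_cutoff=mmr_cutoff
            ),
            "n_meals": len(grp),
            "W": w,
            "TUHII": t,
            "HII": hii(grp["dds_norm"], grp["monthly_sales"], w=1.0) if w == 1.0 else np.nan,
            "UHII": uhii(grp["recip_dds_norm"], grp["monthly_sales"], w=w) if w < 1.0 else np.nan,
        }
        rows.append(row)
    out = pd.DataFrame(rows)

    if len(out) >= 2 and out["TUHII"].nunique() > 1:
        out["z_TUHII"] = z_standardize(out["TUHII"].to_numpy())
    else:
        warnings.warn("too few or constant TUHII values; z_TUHII undefined")
        out["z_TUHII"] = np.nan
    healthy = out["W"] == 1.0
    out["z_HII"] = np.nan
    out["z_UHII"] = np.nan
    if healthy.sum() >= 2 and out.loc[healthy, "HII"].nunique() > 1:
        out.loc[healthy, "z_HII"] = z_standardize(out.loc[healthy, "HII"].to_numpy())
    if (~healthy).sum() >= 2 and out.loc[~healthy, "UHII"].nunique() > 1:
        out.loc[~healthy, "z_UHII"] = z_standardize(out.loc[~healthy, "UHII"].to_numpy())

    out["w_label"] = (
        quartile_labels(out["W"].to_numpy(), scheme="W") if len(out) >= 4 else None
    )
    out["q_TUHII"] = (
        quartile_labels(out["z_TUHII"].to_numpy(), scheme="indicator")
        if len(out) >= 4 and out["z_TUHII"].notna().all()
        else None
    )
    out["q_HII"] = None
    out["q_UHII"] = None
    if healthy.sum() >= 4 and out.loc[healthy, "z_HII"].notna().all():
        out.loc[healthy, "q_HII"] = quartile_labels(
            out.loc[healthy, "z_HII"].to_numpy(), scheme="indicator"
        )
    if (~healthy).sum() >= 4 and out.loc[~healthy, "z_UHII"].notna().all():
        out.loc[~healthy, "q_UHII"] = quartile_labels(
            out.loc[~healthy, "z_UHII"].to_numpy(), scheme="indicator"
        )
    return out
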