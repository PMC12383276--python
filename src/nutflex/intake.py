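"""Fruit-availability and daily macronutrient-intake accounting.

The habitat-level predictor is the fruit availability index (FAI): the
percentage of monitored phenology trees bearing fruit in a calendar month.
Months are split into low- and high-fruit periods at the median FAI over a
reference span.  Daily intakes are carried in kcal for four macronutrient
classes — available protein, total nonstructural carbohydrates (TNC),
lipid, and neutral detergent fiber (NDF) — and non-protein energy (NPe) is
the sum of TNC, NDF and lipid.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MACRONUTRIENTS",
    "KCAL_FACTORS",
    "compute_fai",
    "classify_fruit_periods",
    "compute_daily_intake",
    "compute_npe",
    "add_derived_intakes",
    "compute_ratio",
]

MACRONUTRIENTS = ("protein", "tnc", "lipid", "ndf")

#: kcal per gram dry matter.  NDF uses a fermentable-fiber convention.
#: These are configuration, not constants of nature: pass ``factors`` to
#: :func:`compute_daily_intake` to override.
KCAL_FACTORS: dict[str, float] = {"protein": 4.0, "tnc": 4.0, "lipid": 9.0, "ndf": 1.6}


def _kcal_cols(df: pd.DataFrame) -> list[str]:
    return [f"kcal_{m}" for m in MACRONUTRIENTS]


def compute_fai(phenology: pd.DataFrame) -> pd.DataFrame:
    """Monthly percentage of observed trees bearing fruit.

    Parameters
    ----------
    phenology : DataFrame with columns ``tree_id``, ``month`` (YYYY-MM) and
        boolean ``fruiting``; one row per tree per month.

    Returns
    -------
    DataFrame with columns ``month`` and ``fai`` (percent, 0-100), sorted
    by month.  Invariant to row order and tree relabeling.
    """
    required = {"tree_id", "month", "fruiting"}
    missing = required - set(phenology.columns)
    if missing:
        raise ValueError(f"phenology table lacks columns: {sorted(missing)}")
    if phenology.duplicated(["tree_id", "month"]).any():
        raise ValueError("duplicate (tree_id, month) rows in phenology table")
    grp = phenology.groupby("month", sort=True)["fruiting"]
    counts = grp.size()
    empty = counts[counts == 0]
    if len(empty):
        raise ValueError(f"months with zero observed trees: {list(empty.index)}")
    fai = 100.0 * grp.sum() / counts
    return pd.DataFrame({"month": fai.index, "fai": fai.to_numpy(float)}).reset_index(drop=True)


def classify_fruit_periods(
    fai: pd.DataFrame, reference_span: Iterable[str] | None = None
) -> pd.DataFrame:
    """Label each month low/high relative to the median FAI.

    The cutoff is the median FAI over ``reference_span`` (a collection of
    YYYY-MM keys; default: every month present).  Months with FAI strictly
    above the median are ``high``; ties go to ``low`` (conservative,
    deterministic assignment of scarcity).
    """
    if "fai" not in fai.columns:
        raise ValueError("expected a 'fai' column")
    if reference_span is None:
        ref = fai["fai"]
    else:
        span = set(reference_span)
        if not span:
            raise ValueError("reference_span is empty")
        ref = fai.loc[fai["month"].isin(span), "fai"]
        if ref.empty:
            raise ValueError("reference_span matches no months in the series")
    cutoff = float(ref.median())
    out = fai.copy()
    out["period_label"] = np.where(out["fai"] > cutoff, "high", "low")
    out.attrs["fai_median"] = cutoff
    return out


def compute_daily_intake(
    records: pd.DataFrame,
    compositions: pd.DataFrame,
    *,
    factors: Mapping[str, float] | None = None,
    registered_days: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate feeding records into one row of kcal per individual-day.

    kcal of macronutrient m for one item = dry grams x fraction_m x
    kcal-factor_m, summed over items.  ``records`` needs ``individual_id``,
    ``date``, ``food_item_id``, ``units_g`` (grams dry matter);
    ``compositions`` needs ``food_item_id`` plus ``frac_<m>`` columns.
    ``registered_days`` (optional ``individual_id``/``date`` frame) forces
    all-zero rows for observed days with no feeding records.
    """
    f = dict(KCAL_FACTORS)
    if factors:
        f.update(factors)
    comp = compositions.set_index("food_item_id")
    unknown = set(records["food_item_id"]) - set(comp.index)
    if unknown:
        raise ValueError(f"feeding records reference unknown food items: {sorted(unknown)}")
    if (records["units_g"] < 0).any():
        bad = records.loc[records["units_g"] < 0]
        raise ValueError(f"negative ingested units for items: {sorted(set(bad['food_item_id']))}")
    merged = records.merge(comp, left_on="food_item_id", right_index=True, how="left")
    for m in MACRONUTRIENTS:
        frac = merged[f"frac_{m}"]
        if ((frac < 0) | (frac > 1)).any():
            raise ValueError(f"composition fractions for {m} outside [0, 1]")
        merged[f"kcal_{m}"] = merged["units_g"] * frac * f[m]
    day = (
        merged.groupby(["individual_id", "date"], sort=True)[_kcal_cols(merged)]
        .sum()
        .reset_index()
    )
    if registered_days is not None:
        reg = registered_days[["individual_id", "date"]].drop_duplicates()
        day = reg.merge(day, on=["individual_id", "date"], how="left").fillna(
            {c: 0.0 for c in _kcal_cols(day)}
        )
    return add_derived_intakes(day)


def compute_npe(day: pd.DataFrame | pd.Series | Mapping[str, float]) -> pd.Series | float:
    """Non-protein energy: kcal from TNC + NDF + lipid."""
    if isinstance(day, pd.DataFrame):
        return day["kcal_tnc"] + day["kcal_ndf"] + day["kcal_lipid"]
    return float(day["kcal_tnc"]) + float(day["kcal_ndf"]) + float(day["kcal_lipid"])


def add_derived_intakes(follows: pd.DataFrame) -> pd.DataFrame:
    """Attach kcal_npe, kcal_total and percent protein energy columns."""
    out = follows.copy()
    out["kcal_npe"] = compute_npe(out)
    out["kcal_total"] = out["kcal_npe"] + out["kcal_protein"]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * out["kcal_protein"] / out["kcal_total"]
    out["pct_protein_energy"] = pct.where(out["kcal_total"] > 0)
    return out


_RATIO_ALIASES = {"npe": ("tnc", "ndf", "lipid"), "total": MACRONUTRIENTS}


def _resolve_set(spec: str | Sequence[str]) -> tuple[str, ...]:
    if isinstance(spec, str):
        spec = _RATIO_ALIASES.get(spec, (spec,))
    out = tuple(spec)
    unknown = set(out) - set(MACRONUTRIENTS)
    if unknown:
        raise ValueError(f"unknown macronutrients: {sorted(unknown)}")
    return out


def compute_ratio(
    follows: pd.DataFrame,
    numerator: str | Sequence[str],
    denominator: str | Sequence[str],
) -> pd.Series:
    """Daily ratio of summed kcal between two macronutrient sets.

    ``numerator``/``denominator`` are macronutrient names, sequences of
    them, or the aliases ``"npe"`` and ``"total"``.  Days with a zero
    denominator yield NaN (flagged missing, never infinity) and a logged
    warning with the count.
    """
    num = sum(follows[f"kcal_{m}"] for m in _resolve_set(numerator))
    den = sum(follows[f"kcal_{m}"] for m in _resolve_set(denominator))
    zero = den <= 0
    if np.asarray(zero).any():
        logger.warning(
            "compute_ratio: %d day(s) with zero denominator set to missing", int(zero.sum())
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    return pd.Series(np.where(zero, np.nan, ratio), index=follows.index, name="ratio")
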