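"""Cleaning, normalising and matching of urinary biomarker samples.

Urinary analyte concentrations scale with hydration, so they are corrected
to a reference specific gravity (SG); overly dilute samples (SG < 1.002)
are excluded outright because the correction blows up as SG approaches
1.000.  Duplicate-assay coefficients of variation above 15% void the
analyte value.  Samples are then matched to the full-day feeding follow of
the *previous* day (a first-morning urine void reflects the prior day's
intake after the overnight fast).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SG_REFERENCE",
    "ExclusionLog",
    "sg_correct",
    "exclude_dilute",
    "filter_cv",
    "ketone_presence",
    "match_urine_to_intake",
]

#: Population mean specific gravity used as the correction reference.
SG_REFERENCE = 1.023

#: Minimum SG retained; more dilute samples yield unstable corrections.
SG_MIN = 1.002

#: Duplicate-assay CV (in percent) above which an analyte value is voided.
CV_MAX = 15.0

KETONE_LEVELS = ("negative", "trace", "+", "++", "+++", "missing")

ANALYTES = ("cpeptide_pg_ml", "urea_mg_ml", "d15n_permil")


@dataclass
class ExclusionLog:
    """Counts of rows/values removed, keyed by rule name."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, rule: str, n: int) -> None:
        self.counts[rule] = self.counts.get(rule, 0) + int(n)

    def total(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict[str, int]:
        return dict(self.counts)


def sg_correct(value, sg, sg_ref: float = SG_REFERENCE):
    """Correct a concentration for urine dilution via specific gravity.

    corrected = value * (sg_ref - 1) / (sg - 1)

    Exactly inverts a dilution of the form observed = true * (sg - 1) /
    (sg_ref - 1).  Undefined at SG <= 1.000 (raises).
    """
    value = np.asarray(value, float)
    sg = np.asarray(sg, float)
    if np.any(sg <= 1.0):
        raise ValueError("specific-gravity correction undefined for SG <= 1.000")
    out = value * (sg_ref - 1.0) / (sg - 1.0)
    return float(out) if out.ndim == 0 else out


def exclude_dilute(
    samples: pd.DataFrame, threshold: float = SG_MIN, log: ExclusionLog | None = None
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop samples with SG strictly below ``threshold`` (boundary kept)."""
    log = log or ExclusionLog()
    mask = samples["sg"] < threshold
    log.add("sg_below_1.002", int(mask.sum()))
    return samples.loc[~mask].copy(), log


def filter_cv(
    samples: pd.DataFrame,
    analyte: str,
    threshold: float = CV_MAX,
    log: ExclusionLog | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Void ``analyte`` values whose assay CV exceeds ``threshold`` (strict >).

    Only the named analyte's value is set missing; the row and every other
    column are untouched.  Idempotent.
    """
    log = log or ExclusionLog()
    cv_col = f"cv_{analyte.split('_')[0]}"
    if cv_col not in samples.columns:
        raise ValueError(f"no CV column {cv_col!r} for analyte {analyte!r}")
    out = samples.copy()
    mask = (out[cv_col] > threshold) & out[analyte].notna()
    log.add(f"cv_gt_{threshold:g}_{analyte}", int(mask.sum()))
    out.loc[mask, analyte] = np.nan
    return out, log


def ketone_presence(category, trace_positive: bool = True):
    """Collapse the colorimetric ketone category to presence/absence.

    Any colour change (trace, +, ++, +++) counts as positive by default —
    dipsticks only detect acetoacetate and miss mild ketosis, so this
    maximises sensitivity; set ``trace_positive=False`` to demand at least
    '+'.  ``missing`` maps to NA.  Unknown categories raise.
    """
    def _one(cat):
        if pd.isna(cat):
            return pd.NA
        cat = str(cat)
        if cat not in KETONE_LEVELS:
            raise ValueError(f"unknown ketone category {cat!r}; expected one of {KETONE_LEVELS}")
        if cat == "missing":
            return pd.NA
        if cat == "negative":
            return False
        if cat == "trace":
            return bool(trace_positive)
        return True

    if isinstance(category, (pd.Series, np.ndarray, list, tuple)):
        return pd.Series([_one(c) for c in category], dtype="boolean",
                         index=getattr(category, "index", None))
    return _one(category)


def prepare_samples(
    samples: pd.DataFrame,
    *,
    sg_ref: float = SG_REFERENCE,
    trace_positive: bool = True,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Full cleaning pass: dilute exclusion, SG correction, CV filters, ketone coding."""
    out, log = exclude_dilute(samples)
    # isotope ratios are not concentrations, so delta-15N is never SG-corrected
    for col in ("cpeptide_pg_ml", "urea_mg_ml"):
        if col in out.columns:
            out[col] = sg_correct(out[col].to_numpy(float), out["sg"].to_numpy(float), sg_ref)
            out, log = filter_cv(out, col, log=log)
    if "ketone_category" in out.columns:
        out["ketone_positive"] = ketone_presence(out["ketone_category"], trace_positive)
    return out, log


def match_urine_to_intake(
    samples: pd.DataFrame,
    follows: pd.DataFrame,
    fai: pd.DataFrame | None = None,
    log: ExclusionLog | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Join each urine sample to the full-day follow of the previous day.

    A sample collected on date d matches the same individual's follow on
    d - 1 day; samples whose prior day was not followed, or was not a
    full nest-to-nest day, are dropped and counted.  The month's FAI and
    low/high period label are attached when ``fai`` (with ``period_label``)
    is given.  Duplicate (individual, date) follow rows raise.
    """
    log = log or ExclusionLog()
    if follows.duplicated(["individual_id", "date"]).any():
        dups = follows.loc[follows.duplicated(["individual_id", "date"]), ["individual_id", "date"]]
        raise ValueError(f"duplicate follow rows for: {dups.to_records(index=False).tolist()[:5]}")
    f = follows.copy()
    f["date"] = pd.to_datetime(f["date"])
    s = samples.copy()
    s["collection_date"] = pd.to_datetime(s["collection_date"])
    s["prior_date"] = s["collection_date"] - pd.Timedelta(days=1)
    merged = s.merge(
        f,
        left_on=["individual_id", "prior_date"],
        right_on=["individual_id", "date"],
        how="left",
        suffixes=("", "_follow"),
    )
    no_follow = merged["date"].isna()
    partial = (~no_follow) & (~merged["full_day"].astype("boolean").fillna(False))
    log.add("no_prior_day_follow", int(no_follow.sum()))
    log.add("prior_day_not_full", int(partial.sum()))
    matched = merged.loc[~(no_follow | partial)].drop(columns=["prior_date"]).copy()
    if fai is not None:
        cols = ["month", "fai"] + (["period_label"] if "period_label" in fai.columns else [])
        # follows may already carry FAI columns; the authoritative series wins
        matched = matched.drop(columns=[c for c in cols if c in matched.columns])
        key = matched["date"].dt.strftime("%Y-%m")
        matched = matched.merge(fai[cols], left_on=key.rename("month"), right_on="month", how="left")
    return matched.reset_index(drop=True), log
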