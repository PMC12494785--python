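"""On-treatment burden-change (delta-ctDNA) classification and dynamics.

A delta-ctDNA event is the change in mGE/ml between the two plasma samples
bracketing a clinical workup.  Classification depends on the patient's
baseline stratum:

* high group — what matters is only whether the burden lands below the
  prognostic cutoff: ``decrease_below_cutoff`` vs ``stays_above_cutoff``
  (regardless of the magnitude of the change);
* low group — the change is scored against a stability band of 25 absolute
  mGE/ml units: a drop of at least the band is a ``decrease``, a change
  within the open band is ``stable``, and a rise of at least the band is an
  ``increase_below_cutoff`` or ``increase_above_cutoff`` depending on where
  it lands relative to the cutoff.

The six categories partition all inputs; a change of exactly one band width
counts as movement, not stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError

DAYS_PER_MONTH = 30.4375

HIGH, LOW = "ctDNA_high", "ctDNA_low"
CATEGORIES = (
    "decrease_below_cutoff", "stays_above_cutoff",  # high group
    "decrease", "stable", "increase_below_cutoff", "increase_above_cutoff",  # low group
)
REGRESSION_OR_STABLE = "regression_or_stable"
PROGRESSION_OR_DEATH = "progression_or_death_within_3m"

EVENT_COLUMNS = ["patient_id", "group", "workup_id", "workup_day", "prev_sample_id",
                 "next_sample_id", "prev_mge", "next_mge", "delta_mge", "category",
                 "disease_status", "percent_decrease"]


def classify_delta_event(prev_mge: float, next_mge: float, group: str,
                         cutoff: float = 350.0, band: float = 25.0) -> str:
    """Classify one burden change; see the module docstring for semantics."""
    if group not in (HIGH, LOW):
        raise DomainError(f"group must be {HIGH!r} or {LOW!r}, got {group!r}")
    if prev_mge < 0 or next_mge < 0:
        raise DomainError("mGE values must be non-negative")
    if group == HIGH:
        return "decrease_below_cutoff" if next_mge < cutoff else "stays_above_cutoff"
    delta = next_mge - prev_mge
    if delta <= -band:
        return "decrease"
    if delta < band:
        return "stable"
    return "increase_above_cutoff" if next_mge > cutoff else "increase_below_cutoff"


def percent_decrease(prev_mge: float, next_mge: float) -> float:
    """Relative drop in percent, 100*(prev-next)/prev; negative for a rise."""
    if prev_mge <= 0:
        raise DomainError("percent decrease undefined for a zero/negative previous burden")
    return 100.0 * (prev_mge - next_mge) / prev_mge


def _status_label(workup_status: str, death_day: Optional[float],
                  next_sample_day: float, window_months: float) -> str:
    if workup_status == "progression":
        return PROGRESSION_OR_DEATH
    if death_day is not None and death_day <= next_sample_day + window_months * DAYS_PER_MONTH:
        return PROGRESSION_OR_DEATH
    return REGRESSION_OR_STABLE


def compute_delta_events(samples: pd.DataFrame, workups: pd.DataFrame,
                         patients: pd.DataFrame, cutoff: float = 350.0,
                         band: float = 25.0, min_positive: int = 1,
                         death_window_months: float = 3.0) -> pd.DataFrame:
    """Build one classified event per consecutive sample pair around a workup.

    Eligible patients have at least two assessable quantified plasma samples
    of which at least ``min_positive`` is ctDNA positive, and an assigned
    group.  For each dated workup, the nearest assessable sample strictly
    before it and the first at/after it form the bracket; several workups
    falling inside one bracket collapse to a single event (the earliest).
    Disease status is ``progression_or_death_within_3m`` when the workup
    read progression or the patient died within the window measured from
    the next sample's date.
    """
    if len(workups) and workups["days_from_baseline"].isna().any():
        bad = workups.loc[workups["days_from_baseline"].isna(), "workup_id"].tolist()
        raise DomainError(f"undated workup(s): {bad}")
    pat = patients.set_index("patient_id")
    rows = []
    for pid, s in samples.groupby("patient_id"):
        s = s[s["ctdna_status"].isin(["positive", "negative"])]
        s = s.sort_values("days_from_baseline")
        if len(s) < 2 or (s["ctdna_status"] == "positive").sum() < min_positive:
            continue
        if pid not in pat.index:
            continue
        prec = pat.loc[pid]
        group = prec.get("group", "unassigned")
        if group not in (HIGH, LOW):
            continue
        death_day = None
        if bool(prec.get("death_event", False)):
            death_day = float(prec["os_months"]) * DAYS_PER_MONTH
        w = workups[workups["patient_id"] == pid].sort_values("days_from_baseline")
        days = s["days_from_baseline"].to_numpy(dtype=float)
        seen_pairs = set()
        for _, wrow in w.iterrows():
            wday = float(wrow["days_from_baseline"])
            before = np.flatnonzero(days < wday)
            at_or_after = np.flatnonzero(days >= wday)
            if len(before) == 0 or len(at_or_after) == 0:
                continue
            i_prev, i_next = before[-1], at_or_after[0]
            prev, nxt = s.iloc[i_prev], s.iloc[i_next]
            pair = (prev["sample_id"], nxt["sample_id"])
            if pair in seen_pairs:
                continue
            seen_pairs.add(pair)
            prev_mge, next_mge = float(prev["mge_per_ml"]), float(nxt["mge_per_ml"])
            category = classify_delta_event(prev_mge, next_mge, group, cutoff, band)
            status = _status_label(str(wrow["disease_status"]), death_day,
                                   float(nxt["days_from_baseline"]), death_window_months)
            pct = percent_decrease(prev_mge, next_mge) if prev_mge > 0 else np.nan
            rows.append([pid, group, wrow["workup_id"], wday, prev["sample_id"],
                         nxt["sample_id"], prev_mge, next_mge, next_mge - prev_mge,
                         category, status, pct])
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def concordance_table(events: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate event category against disease status per group.

    Returns tidy counts with the proportion of each status within its
    (group, category) cell family, reproducing summaries of the form
    "24/33 decreased-or-stable events linked to regression or stable
    disease".
    """
    cols = ["group", "category", "disease_status", "count", "category_total", "proportion"]
    if len(events) == 0:
        return pd.DataFrame(columns=cols)
    counts = (events.groupby(["group", "category", "disease_status"])
              .size().rename("count").reset_index())
    totals = (counts.groupby(["group", "category"])["count"]
              .transform("sum"))
    counts["category_total"] = totals
    counts["proportion"] = counts["count"] / totals
    return counts[cols]


def _first_two_slope(df: pd.DataFrame, time_col: str, value_col: str) -> Optional[float]:
    d = df.dropna(subset=[value_col]).sort_values(time_col)
    if len(d) < 2:
        return None
    t = d[time_col].to_numpy(dtype=float)[:2]
    v = d[value_col].to_numpy(dtype=float)[:2]
    if t[1] == t[0]:
        return None
    return float((v[1] - v[0]) / (t[1] - t[0]))


def slope_correlation(ctdna_series: pd.DataFrame, ca199_series: pd.DataFrame,
                      time_col: str = "days_from_baseline",
                      value_cols: tuple[str, str] = ("mge_per_ml", "ca19_9")) -> float:
    """Spearman correlation of early ctDNA and CA19-9 slopes across patients.

    For each patient, the slope between the first two measurements of each
    analyte is computed; the rank correlation is taken over patients with
    both slopes available (at least three required).
    """
    slopes = {}
    for pid, d in ctdna_series.groupby("patient_id"):
        sl = _first_two_slope(d, time_col, value_cols[0])
        if sl is not None:
            slopes[pid] = [sl, None]
    for pid, d in ca199_series.groupby("patient_id"):
        sl = _first_two_slope(d, time_col, value_cols[1])
        if sl is not None and pid in slopes:
            slopes[pid][1] = sl
    paired = [(a, b) for a, b in slopes.values() if b is not None]
    if len(paired) < 3:
        raise DomainError(
            f"need >= 3 patients with both slopes, got {len(paired)}"
        )
    a, b = zip(*paired)
    return float(stats.spearmanr(a, b).statistic)
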