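"""Prognostic cutpoint discovery and survival summaries.

The dichotomizing burden threshold is found by maximally selected rank
statistics: every admissible split of the cohort by baseline burden is
scored with the standardized log-rank statistic, and the candidate with the
largest absolute statistic wins.  Candidates are midpoints between
consecutive distinct burden values; a split is admissible when both groups
retain at least ``ceil(minprop * n)`` patients (``minprop`` defaults to
0.1).  Ties break toward the smaller cutpoint so the search is
deterministic.

Kaplan-Meier medians and Cox proportional-hazards fits delegate to
lifelines; the contract is the returned quantities, not the optimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError

from .exceptions import ConvergenceError, DomainError


def logrank_z(times: Sequence[float], events: Sequence[bool],
              group_mask: Sequence[bool]) -> float:
    """Standardized log-rank statistic (O - E) / sqrt(V) for the masked group.

    Positive values mean the masked group experienced more events than
    expected under the null of identical hazards; squaring the result gives
    the familiar one-degree-of-freedom chi-square statistic.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(group_mask, dtype=bool)
    if g.all() or (~g).all():
        raise DomainError("log-rank requires two non-empty groups")
    if not e.any():
        raise DomainError("log-rank requires at least one event")
    order = np.argsort(t, kind="mergesort")
    t, e, g = t[order], e[order], g[order]
    n = len(t)
    uniq_first = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    d = np.add.reduceat(e.astype(np.int64), uniq_first)
    d1 = np.add.reduceat((e & g).astype(np.int64), uniq_first)
    n_at = n - uniq_first
    # subjects of the masked group still at risk just before each distinct time
    g_from_right = np.cumsum(g[::-1])[::-1]
    n1_at = g_from_right[uniq_first]
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = n1_at / n_at
        expected = d * p1
        var = d * p1 * (1.0 - p1) * (n_at - d) / np.maximum(n_at - 1, 1)
        var[n_at <= 1] = 0.0
    total_var = var.sum()
    if total_var <= 0:
        raise DomainError("log-rank variance is zero; groups are degenerate")
    return float((d1 - expected).sum() / math.sqrt(total_var))


@dataclass
class CutpointResult:
    """Outcome of the maximally-selected-rank-statistic search."""

    cutpoint: float
    statistic: float  # standardized log-rank z at the chosen split
    minprop: float
    candidate_grid: np.ndarray = field(repr=False)
    per_candidate_stats: pd.DataFrame = field(repr=False)


def candidate_cutpoints(values: Sequence[float], minprop: float = 0.1) -> np.ndarray:
    """Admissible candidate cutpoints: midpoints between consecutive distinct
    sorted values whose induced split leaves at least ceil(minprop*n)
    subjects on each side."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    min_group = math.ceil(minprop * n)
    distinct = np.unique(v)
    if len(distinct) < 2:
        raise DomainError("all burden values identical; no admissible split exists")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n_low = np.searchsorted(np.sort(v), mids, side="right")
    ok = (n_low >= min_group) & ((n - n_low) >= min_group)
    grid = mids[ok]
    if len(grid) == 0:
        raise DomainError(
            f"no candidate split satisfies minprop={minprop} with n={n}"
        )
    return grid


def find_optimal_cutpoint(values: Sequence[float], times: Sequence[float],
                          events: Sequence[bool], minprop: float = 0.1) -> CutpointResult:
    """Maximally selected rank statistics over baseline burden values.

    Scans every admissible candidate split and returns the one maximizing
    the absolute standardized log-rank statistic.  ``per_candidate_stats``
    exposes the whole profile so users can add permutation calibration if a
    corrected p-value is needed.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if not (len(v) == len(t) == len(e)):
        raise DomainError("values, times and events must have equal length")
    grid = candidate_cutpoints(v, minprop)
    rows = []
    best_cut, best_abs, best_z = None, -np.inf, 0.0
    for cut in grid:
        mask = v > cut
        z = logrank_z(t, e, mask)
        rows.append((cut, int((~mask).sum()), int(mask.sum()), z, abs(z)))
        if abs(z) > best_abs:  # strict: ties stay with the smaller cutpoint
            best_cut, best_abs, best_z = float(cut), abs(z), z
    stats = pd.DataFrame(rows, columns=["cutpoint", "n_low", "n_high", "z", "abs_z"])
    return CutpointResult(cutpoint=best_cut, statistic=best_z, minprop=minprop,
                          candidate_grid=grid, per_candidate_stats=stats)


def assign_groups(patients: pd.DataFrame, cutpoint: float,
                  mge_col: str = "baseline_mge") -> pd.DataFrame:
    """Dichotomize patients at the burden cutpoint.

    High iff baseline burden strictly exceeds the cutpoint (a value exactly
    on the boundary goes to the low group); negative baselines (0 mGE/ml)
    are low; a missing baseline leaves the patient unassigned.
    """
    out = patients.copy()
    mge = out[mge_col]
    out["group"] = np.where(mge > cutpoint, "ctDNA_high", "ctDNA_low")
    out.loc[mge.isna(), "group"] = "unassigned"
    return out


def km_median(times: Sequence[float], events: Sequence[bool]) -> Optional[float]:
    """Kaplan-Meier median survival: first time the estimate drops to <= 0.5.

    Returns ``None`` when the curve never crosses 0.5 (heavy censoring).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=bool))
    med = kmf.median_survival_time_
    return None if np.isinf(med) else float(med)


@dataclass
class CoxResult:
    """Hazard ratio for one exposure with a Wald 95% CI, plus the full summary."""

    exposure: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    summary: pd.DataFrame = field(repr=False)


def cox_fit(df: pd.DataFrame, duration_col: str, event_col: str,
            covariates: Sequence[str], exposure: Optional[str] = None) -> CoxResult:
    """Cox proportional-hazards fit via partial likelihood (lifelines).

    ``covariates`` are the model columns; ``exposure`` names the one whose
    hazard ratio is reported (defaults to the first covariate).  Wald-type
    95% confidence intervals on the log hazard ratio.
    """
    exposure = exposure or covariates[0]
    cols = [duration_col, event_col] + list(covariates)
    data = df[cols].dropna()
    for c in covariates:
        if data[c].nunique() < 2:
            raise DomainError(f"covariate {c!r} is constant; Cox fit is unidentifiable")
    n_events = int(data[event_col].sum())
    if n_events < len(covariates):
        raise DomainError(
            f"{n_events} events for {len(covariates)} parameters; fit underdetermined"
        )
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=duration_col, event_col=event_col)
    except (_LLConvergenceError, np.linalg.LinAlgError) as err:
        raise ConvergenceError(f"Cox fit failed to converge: {err}") from err
    s = cph.summary
    row = s.loc[exposure]
    return CoxResult(
        exposure=exposure,
        hr=float(row["exp(coef)"]),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        p=float(row["p"]),
        summary=s.reset_index(),
    )
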