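"""Quit outcomes and QALYs.

Quit status follows the Russell-standard convention for smoking trials:
participants with missing outcome data are counted as smokers. A quit
requires biochemical verification, except in the covid-era pathway where a
self-report backed by a returned saliva sample qualifies; a purely
self-reported definition is available for sensitivity analysis.

QALYs use the standard area-under-the-curve approach: utilities at baseline,
late pregnancy and six months post-partum, interpolated linearly over elapsed
time in years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

VALUE_SET_RANGE = (-0.594, 1.0)


@dataclass(frozen=True)
class QuitOutcome:
    status: str  # "quit" | "smoker"
    basis: str   # "verified" | "self_report" | "imputed_smoker"


def russell_quit(
    reported,
    verified_flag,
    covid_era: bool = False,
    *,
    covid_selfreport_allowed: bool = True,
    self_report_definition: bool = False,
) -> QuitOutcome:
    """Classify one participant's quit outcome.

    ``reported`` is the tri-state self-report ("quit"/"smoker"/"missing" or
    NaN); ``verified_flag`` is True when biochemical verification confirmed
    the quit, False when verification failed or was absent. Missing reports
    are imputed as smokers (Russell standard). With
    ``self_report_definition=True`` the self-report alone decides (sensitivity
    definition), still with missing imputed as smoker.
    """
    missing = reported is None or reported == "missing" or (
        isinstance(reported, float) and np.isnan(reported)
    )
    if missing:
        return QuitOutcome("smoker", "imputed_smoker")
    if reported != "quit":
        return QuitOutcome("smoker", "self_report")
    if self_report_definition:
        return QuitOutcome("quit", "self_report")
    if verified_flag:
        return QuitOutcome("quit", "verified")
    if covid_era and covid_selfreport_allowed:
        return QuitOutcome("quit", "self_report")
    return QuitOutcome("smoker", "self_report")


def quit_indicator(
    table: pd.DataFrame,
    timepoint: str = "late_pregnancy",
    *,
    self_report_definition: bool = False,
) -> pd.Series:
    """Russell-standard 0/1 quit indicator for every participant.

    For the late-pregnancy timepoint the verified column is ``quit_late``
    (already verification-resolved by the generator) and the self-report
    column is ``quit_late_selfreport``; post-partum has a single resolved
    column. Missing always counts as smoker, so the Russell rate can never
    exceed the complete-case rate.
    """
    if timepoint == "late_pregnancy":
        col = "quit_late_selfreport" if self_report_definition else "quit_late"
    elif timepoint == "postpartum_6mo":
        col = "quit_postpartum"
    else:
        raise ValueError(f"unknown timepoint: {timepoint!r}")
    vals = table[col] if col in table.columns else pd.Series("missing", index=table.index)
    return (vals == "quit").astype(float)


def eq5d_to_utility(responses, valueset) -> float:
    """Map a five-dimension five-level profile to a utility.

    ``responses`` is a 5-character string ("11111") or a length-5 sequence of
    levels in 1..5. ``valueset`` is either a dict mapping profile strings to
    utilities, or a dict of per-dimension level decrements
    ``{dimension_index: {level: decrement}}`` applied additively from the
    full-health anchor of 1. Level 1 in any dimension contributes no
    decrement.
    """
    if isinstance(responses, str):
        levels = [int(c) for c in responses]
    else:
        levels = [int(x) for x in responses]
    if len(levels) != 5 or any(not 1 <= lv <= 5 for lv in levels):
        raise ValueError(f"malformed EQ-5D-5L profile: {responses!r}")
    profile = "".join(str(lv) for lv in levels)

    if profile in valueset:
        return float(valueset[profile])
    if all(isinstance(k, str) for k in valueset):
        raise KeyError(f"profile {profile} not in lookup value set")
    u = 1.0
    for dim, lv in enumerate(levels):
        decs = valueset.get(dim, {})
        if lv > 1:
            if lv not in decs:
                raise KeyError(f"value set has no decrement for dimension {dim} level {lv}")
            u -= float(decs[lv])
    return u


def identity_valueset() -> dict:
    """Test value set with all decrements zero: every profile maps to 1."""
    return {dim: {lv: 0.0 for lv in range(2, 6)} for dim in range(5)}


def load_valueset(path) -> dict:
    """Read a value set from CSV.

    Accepts either columns (profile, utility) for a full lookup table, or
    (dimension, level, decrement) for an additive decrement set (dimension
    indices 0-4, levels 2-5). The shipped tables are editable data; no
    published national tariff is reproduced here.
    """
    df = pd.read_csv(path, comment="#")
    cols = set(df.columns)
    if {"profile", "utility"} <= cols:
        return {str(p).strip(): float(u) for p, u in zip(df["profile"], df["utility"])}
    if {"dimension", "level", "decrement"} <= cols:
        vs = identity_valueset()
        for _, row in df.iterrows():
            vs[int(row["dimension"])][int(row["level"])] = float(row["decrement"])
        return vs
    raise ValueError(
        "value set CSV needs (profile, utility) or (dimension, level, decrement) columns"
    )


def qaly_auc(times_years, utilities) -> float:
    """Trapezoid QALY integral over the non-missing utility points.

    Times are years from baseline and must be strictly increasing. At least
    two non-missing points are required; otherwise the QALY is undefined
    (returned as NaN so it flows to imputation rather than silently zero).
    Missing interior points are bridged linearly between their neighbours.
    """
    t = np.asarray(times_years, dtype=float)
    u = np.asarray(utilities, dtype=float)
    if len(t) != len(u):
        raise ValueError("times and utilities must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    keep = ~np.isnan(u)
    if keep.sum() < 2:
        return np.nan
    return float(np.trapezoid(u[keep], t[keep]))


def qaly_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant QALYs over the late-pregnancy and post-partum windows.

    ``qaly_late`` integrates baseline -> late pregnancy; ``qaly_postpartum``
    integrates baseline -> six months post-partum. Follow-up durations come
    from the per-participant ``t_late_years`` / ``t_postpartum_years``
    columns.
    """
    out = table.copy()
    t0 = np.zeros(len(out))
    t1 = out["t_late_years"].to_numpy(dtype=float)
    t2 = t1 + out["t_postpartum_years"].to_numpy(dtype=float)
    u0 = out["utility_baseline"].to_numpy(dtype=float)
    u1 = out["utility_late"].to_numpy(dtype=float)
    u2 = out["utility_postpartum"].to_numpy(dtype=float)

    qaly_late = np.where(
        np.isnan(u0) | np.isnan(u1), np.nan, (u0 + u1) / 2.0 * (t1 - t0)
    )
    out["qaly_late"] = qaly_late
    qpp = np.full(len(out), np.nan)
    for i in range(len(out)):
        qpp[i] = qaly_auc([t0[i], t1[i], t2[i]], [u0[i], u1[i], u2[i]])
    out["qaly_postpartum"] = qpp
    return out
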