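"""Contingent voucher awards and unit costing of trial resource use.

Cost components: shopping vouchers awarded at four milestones (engagement/quit
date £50, 4-week verified quit £50, 12-week verified quit £100, late-pregnancy
verified quit £200 — the last independent of earlier milestones), voucher
postage, stop-smoking-service adviser time, NRT, and neonatal stay costs
proxied by gestational age at birth through WHO preterm classes. Prices are
2020 GBP; currency arithmetic is carried in full float precision and rounded
to pennies (half-even) only at reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MILESTONES = ("engagement", "quit_4wk", "quit_12wk", "quit_late")


@dataclass
class VoucherSchedule:
    engagement_amount: float = 50.0
    quit4_amount: float = 50.0
    quit12_amount: float = 100.0
    late_amount: float = 200.0
    quit4_requires_previous: bool = True
    quit12_requires_previous: bool = True
    late_requires_previous: bool = False
    covid_selfreport_allowed: bool = True
    postage_per_voucher: float = 2.92
    resend_postage: float = 2.05

    def __post_init__(self):
        for f_ in (
            "engagement_amount", "quit4_amount", "quit12_amount",
            "late_amount", "postage_per_voucher", "resend_postage",
        ):
            if getattr(self, f_) < 0:
                raise ValueError(f"{f_} must be >= 0")

    @property
    def maximum_total(self) -> float:
        return (
            self.engagement_amount + self.quit4_amount
            + self.quit12_amount + self.late_amount
        )

    def with_(self, **kw) -> "VoucherSchedule":
        return replace(self, **kw)


@dataclass
class UnitCostTable:
    """Unit costs, price year 2020, GBP.

    ``nrt_cost_per_week`` is a configurable weekly NRT price (sourced from a
    national formulary in practice; the shipped default is a documented
    configuration value, not a published figure).
    """

    adviser_rate_per_hour: dict = field(default_factory=lambda: {5: 39.0, 6: 49.0})
    nrt_cost_per_week: float = 12.0
    neonatal_per_day: dict = field(
        default_factory=lambda: {
            "moderate_late": 536.45, "very": 709.16, "extremely": 1707.50,
        }
    )
    neonatal_los_days: dict = field(
        default_factory=lambda: {"moderate_late": 13, "very": 44, "extremely": 93}
    )
    #: sites using a typical-use profile instead of individual records:
    #: site -> (sss_contact_minutes, nrt_weeks) applied when individual data
    #: are absent
    typical_use_profiles: dict = field(default_factory=dict)
    price_year: int = 2020
    currency: str = "GBP"

    def __post_init__(self):
        if any(v < 0 for v in self.adviser_rate_per_hour.values()):
            raise ValueError("adviser rates must be >= 0")
        if self.nrt_cost_per_week < 0:
            raise ValueError("nrt_cost_per_week must be >= 0")
        for cls in ("moderate_late", "very", "extremely"):
            if cls not in self.neonatal_per_day or cls not in self.neonatal_los_days:
                raise ValueError(f"preterm class {cls!r} needs per-day cost and LOS")

    def with_(self, **kw) -> "UnitCostTable":
        return replace(self, **kw)


def round_money(x: float) -> float:
    """Round to pennies, half-even (banker's rounding)."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return np.nan
    return float(np.round(np.float64(x) + 0.0, 2))


def _met(value) -> bool:
    # missing milestone data counts as not achieved for award purposes
    return value == "quit"


def voucher_awards(record, schedule: VoucherSchedule, excluded: tuple = ()):
    """Vouchers awarded to one participant.

    Returns ``(awards, total)`` where awards is a list of (milestone, amount)
    pairs. The 4- and 12-week vouchers require the previous milestone's
    criteria to have been met (criteria-met chaining, not voucher-awarded
    chaining); the late-pregnancy voucher depends only on late-pregnancy quit
    — biochemically verified, or self-reported with a returned saliva sample
    in the covid era when the schedule allows it. ``excluded`` lists milestones
    whose issued voucher is excluded from analysis (e.g. stolen/never
    received): the criteria still count toward chaining but the amount does
    not accrue.
    """
    engaged = bool(record.get("engaged", False))
    q4 = _met(record.get("quit_4wk"))
    q12 = _met(record.get("quit_12wk"))
    q_late = _met(record.get("quit_late"))
    covid = bool(record.get("covid_era", False))
    sr = _met(record.get("quit_late_selfreport"))
    saliva = bool(record.get("saliva_returned", False))

    eligible = {}
    eligible["engagement"] = engaged
    eligible["quit_4wk"] = q4 and (engaged or not schedule.quit4_requires_previous)
    eligible["quit_12wk"] = q12 and (
        eligible["quit_4wk"] or not schedule.quit12_requires_previous
    )
    late_ok = q_late or (
        schedule.covid_selfreport_allowed and covid and sr and saliva
    )
    if schedule.late_requires_previous:
        late_ok = late_ok and eligible["quit_12wk"]
    eligible["quit_late"] = late_ok

    amounts = {
        "engagement": schedule.engagement_amount,
        "quit_4wk": schedule.quit4_amount,
        "quit_12wk": schedule.quit12_amount,
        "quit_late": schedule.late_amount,
    }
    awards = [
        (m, amounts[m]) for m in MILESTONES if eligible[m] and m not in excluded
    ]
    return awards, float(sum(a for _, a in awards))


def postage_cost(n_sent: int, n_resent_charged: int, schedule: VoucherSchedule) -> float:
    if n_sent < 0 or n_resent_charged < 0:
        raise ValueError("voucher counts must be >= 0")
    return n_sent * schedule.postage_per_voucher + n_resent_charged * schedule.resend_postage


def neonatal_cost(gestational_age_birth_weeks, unit_costs: UnitCostTable):
    """Neonatal stay cost from the gestational-age proxy.

    Term births (>= 37 weeks) cost nothing; preterm classes map to a length
    of stay times a per-day cost. Missing gestational age propagates as
    missing (handled downstream by imputation, never silently zeroed).
    """
    ga = gestational_age_birth_weeks
    if ga is None or (isinstance(ga, float) and np.isnan(ga)):
        return np.nan
    if not 20.0 < ga < 45.0:
        raise ValueError(f"gestational age {ga} weeks outside (20, 45)")
    if ga >= 37.0:
        return 0.0
    if ga >= 32.0:
        cls = "moderate_late"
    elif ga >= 28.0:
        cls = "very"
    else:
        cls = "extremely"
    return unit_costs.neonatal_los_days[cls] * unit_costs.neonatal_per_day[cls]


def support_costs(record, unit_costs: UnitCostTable):
    """(SSS cost, NRT cost) for one participant.

    Adviser time is costed at the site's grade rate per hour; NRT at the
    configured weekly price. Sites with a typical-use profile substitute the
    profile when the individual value is absent.
    """
    grade = record.get("adviser_grade")
    if grade not in unit_costs.adviser_rate_per_hour:
        raise KeyError(f"unknown adviser grade: {grade!r}")
    site = record.get("site")
    profile = unit_costs.typical_use_profiles.get(site)

    minutes = record.get("sss_contact_minutes")
    weeks = record.get("nrt_weeks")
    if profile is not None:
        if minutes is None or (isinstance(minutes, float) and np.isnan(minutes)):
            minutes = profile[0]
        if weeks is None or (isinstance(weeks, float) and np.isnan(weeks)):
            weeks = profile[1]

    def _cost(value, per_unit, divisor=1.0):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return np.nan
        return value / divisor * per_unit

    sss = _cost(minutes, unit_costs.adviser_rate_per_hour[grade], 60.0)
    nrt = _cost(weeks, unit_costs.nrt_cost_per_week)
    return sss, nrt


def cost_participants(
    table: pd.DataFrame,
    schedule: VoucherSchedule,
    unit_costs: UnitCostTable,
) -> pd.DataFrame:
    """Attach per-participant cost columns to a trial table.

    Control-arm participants receive no vouchers or postage. Missing resource
    data yields missing component costs; ``cost_total`` is missing whenever
    any component is.
    """
    out = table.copy()
    n = len(out)
    vouchers = np.zeros(n)
    postage = np.zeros(n)
    sss = np.full(n, np.nan)
    nrt = np.full(n, np.nan)
    neonatal = np.full(n, np.nan)

    issuance_cols = ("voucher_engagement", "voucher_4wk", "voucher_12wk", "voucher_late")
    has_issuance = all(c in out.columns for c in issuance_cols)
    amounts = (
        schedule.engagement_amount, schedule.quit4_amount,
        schedule.quit12_amount, schedule.late_amount,
    )

    records = out.to_dict("records")
    for i, rec in enumerate(records):
        if rec["arm"] == "incentives":
            if has_issuance:
                # recorded issuance data takes precedence over re-deriving
                # awards from (possibly masked) milestone flags
                flags = [bool(rec[c]) for c in issuance_cols]
                vouchers[i] = sum(a for a, f in zip(amounts, flags) if f)
                n_sent = sum(flags)
            else:
                awards, total = voucher_awards(rec, schedule)
                vouchers[i] = total
                n_sent = len(awards)
            postage[i] = postage_cost(
                n_sent, int(rec.get("n_resent_charged", 0) or 0), schedule
            )
        s, r = support_costs(rec, unit_costs)
        sss[i], nrt[i] = s, r
        ga = rec.get("gestational_age_birth_weeks")
        if rec.get("miscarriage", False):
            neonatal[i] = 0.0  # no neonatal stay to cost
        else:
            neonatal[i] = neonatal_cost(ga, unit_costs)

    out["cost_vouchers"] = vouchers
    out["cost_postage"] = postage
    out["cost_sss"] = sss
    out["cost_nrt"] = nrt
    out["cost_intervention"] = vouchers + postage + sss + nrt
    out["cost_neonatal"] = neonatal
    out["cost_total"] = out["cost_intervention"] + neonatal
    return out


COMPONENTS = (
    "cost_vouchers", "cost_postage", "cost_sss", "cost_nrt",
    "cost_intervention", "cost_neonatal", "cost_total",
)


def arm_cost_summary(costed: pd.DataFrame) -> pd.DataFrame:
    """Per-arm component means and standard errors over non-missing values.

    SE = sample SD / sqrt(n non-missing).
    """
    rows = []
    for arm, g in costed.groupby("arm"):
        if len(g) == 0:
            raise ValueError(f"empty arm: {arm}")
        for comp in COMPONENTS:
            x = g[comp].dropna()
            if len(x) == 0:
                raise ValueError(f"no non-missing values for {comp} in arm {arm}")
            mean = float(x.mean())
            se = float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan
            rows.append(
                {"arm": arm, "component": comp, "mean": mean, "se": se,
                 "n": int(len(x))}
            )
    return pd.DataFrame(rows)
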