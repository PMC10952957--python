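"""Synthetic trial-cohort generator.

Emulates the statistical structure of a two-arm randomized trial of financial
incentives for smoking cessation in pregnancy: 471/470 participants across
seven sites, milestone quit pathways nested as engagement ⊇ 4-week ⊇ 12-week
quit, a biochemically verified late-pregnancy quit rate of ~0.268 vs ~0.123,
post-partum sustained quit as a subset of late-pregnancy quitters, EQ-5D-style
utilities on the crosswalk value-set range [-0.594, 1], resource use (stop
smoking service contact, NRT weeks), gestational age at birth as a neonatal
proxy, and missing-at-random missingness driven by miscarriage and site.

No real participant data is recreated; every default documented here is a
synthetic stand-in calibrated to published marginal summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from ._rng import substream

ARMS = ("incentives", "control")
UTILITY_RANGE = (-0.594, 1.0)
PRETERM_CLASSES = ("extremely", "very", "moderate_late", "term")

#: Columns that inject_missingness may mask, with their kind.
MASKABLE = {
    "sss_contact_minutes": "numeric",
    "nrt_weeks": "numeric",
    "quit_late": "tristate",
    "quit_postpartum": "tristate",
    "utility_baseline": "numeric",
    "utility_late": "numeric",
    "utility_postpartum": "numeric",
    "gestational_age_birth_weeks": "numeric",
}


def _per_arm(incentives, control):
    return {"incentives": incentives, "control": control}


@dataclass
class CohortSpec:
    """Parameters of the synthetic trial cohort.

    Milestone probabilities are marginal per-arm probabilities; the generator
    derives the conditional continuation probabilities so the nesting
    engagement ⊇ 4-week quit ⊇ 12-week quit holds exactly while the marginals
    match. Control-arm milestone marginals below the late-pregnancy quit rate
    are unpublished and are synthetic defaults.
    """

    n_incentives: int = 471
    n_control: int = 470
    n_sites: int = 7
    site_weights: tuple | None = None  # None -> uniform

    engage_prob: dict = field(default_factory=lambda: _per_arm(0.714, 0.55))
    quit_prob_4wk: dict = field(default_factory=lambda: _per_arm(0.362, 0.16))
    quit_prob_12wk: dict = field(default_factory=lambda: _per_arm(0.292, 0.10))
    quit_prob_late: dict = field(default_factory=lambda: _per_arm(0.268, 0.123))
    selfreport_prob_late: dict = field(default_factory=lambda: _per_arm(0.359, 0.185))
    quit_prob_postpartum: dict = field(default_factory=lambda: _per_arm(0.079, 0.051))
    #: P(still quit at late pregnancy | quit at 12 weeks)
    persistence_12wk_to_late: float = 0.75

    utility_mean: dict = field(
        default_factory=lambda: {
            "baseline": _per_arm(0.670, 0.670),
            "late": _per_arm(0.686, 0.666),
            "postpartum": _per_arm(0.695, 0.690),
        }
    )
    utility_sd: float = 0.11

    #: quit-status-dependent distribution over preterm classes
    #: (extremely, very, moderate_late, term); synthetic, chosen so arm mean
    #: neonatal costs land in the observed few-hundred-to-two-thousand range.
    preterm_probs: dict = field(
        default_factory=lambda: {
            "quit": (0.003, 0.007, 0.040, 0.950),
            "smoker": (0.006, 0.012, 0.060, 0.922),
        }
    )
    miscarriage_prob: float = 0.019
    covid_era_frac: float = 0.55
    saliva_return_prob: float = 1.0

    #: mean SSS contact minutes and NRT weeks per arm (synthetic resource use)
    sss_minutes_mean: dict = field(default_factory=lambda: _per_arm(72.0, 57.0))
    nrt_weeks_mean: dict = field(default_factory=lambda: _per_arm(5.33, 4.17))

    #: per-voucher resend probability and P(charged | resent): 87 resends of
    #: ~793 vouchers, 59 of them charged.
    resend_prob: float = 0.11
    resend_charged_prob: float = 0.678

    #: follow-up durations in years: recruitment -> late pregnancy -> 6 months
    #: post-partum.
    t_late_years: float = 0.5
    t_postpartum_years: float = 0.65

    missing_rates: dict = field(
        default_factory=lambda: {
            "sss_contact_minutes": 0.10,
            "nrt_weeks": 0.12,
            "quit_late": 0.10,
            "quit_postpartum": 0.20,
            "utility_baseline": 0.002,
            "utility_late": 0.23,
            "utility_postpartum": 0.28,
            "gestational_age_birth_weeks": 0.12,
        }
    )

    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        probs = {
            "engage_prob": self.engage_prob,
            "quit_prob_4wk": self.quit_prob_4wk,
            "quit_prob_12wk": self.quit_prob_12wk,
            "quit_prob_late": self.quit_prob_late,
            "selfreport_prob_late": self.selfreport_prob_late,
            "quit_prob_postpartum": self.quit_prob_postpartum,
        }
        for name, d in probs.items():
            for arm in ARMS:
                p = d[arm]
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{arm}]={p} outside [0, 1]")
        for name, p in [
            ("miscarriage_prob", self.miscarriage_prob),
            ("covid_era_frac", self.covid_era_frac),
            ("saliva_return_prob", self.saliva_return_prob),
            ("resend_prob", self.resend_prob),
            ("resend_charged_prob", self.resend_charged_prob),
            ("persistence_12wk_to_late", self.persistence_12wk_to_late),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for col, r in self.missing_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missing_rates[{col}]={r} outside [0, 1]")
        for arm in ARMS:
            if not (
                self.quit_prob_12wk[arm]
                <= self.quit_prob_4wk[arm]
                <= self.engage_prob[arm]
            ):
                raise ValueError(
                    f"milestone nesting violated in arm {arm}: need "
                    "quit_prob_12wk <= quit_prob_4wk <= engage_prob"
                )
            if self.quit_prob_postpartum[arm] > self.quit_prob_late[arm] + 1e-12:
                raise ValueError(
                    f"quit_prob_postpartum > quit_prob_late in arm {arm}"
                )
            if self.selfreport_prob_late[arm] < self.quit_prob_late[arm]:
                raise ValueError(
                    f"selfreport_prob_late < quit_prob_late in arm {arm}: "
                    "verified quitters are a subset of self-reported quitters"
                )
        if self.site_weights is not None:
            w = np.asarray(self.site_weights, dtype=float)
            if len(w) != self.n_sites:
                raise ValueError("site_weights length != n_sites")
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("site_weights must be non-negative and sum to 1")
        for status, pv in self.preterm_probs.items():
            pv = np.asarray(pv, dtype=float)
            if (pv < 0).any() or abs(pv.sum() - 1.0) > 1e-9:
                raise ValueError(f"preterm_probs[{status}] must sum to 1")

    def with_(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.random(size)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _gestational_age(rng, preterm_class):
    """Uniform gestational age within the WHO class bounds (weeks)."""
    bounds = {
        "extremely": (24.0, 28.0),
        "very": (28.0, 32.0),
        "moderate_late": (32.0, 37.0),
        "term": (37.0, 42.0),
    }
    lo, hi = np.empty(len(preterm_class)), np.empty(len(preterm_class))
    for cls, (a, b) in bounds.items():
        m = preterm_class == cls
        lo[m], hi[m] = a, b
    return lo + rng.random(len(preterm_class)) * (hi - lo)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a full-information participant table.

    Milestones use a single latent persistence uniform per participant:
    ``u < p`` defines membership in each nested milestone, which guarantees
    engagement ⊇ 4-week quit ⊇ 12-week quit with the exact marginals of the
    spec. Late-pregnancy quit is correlated with the 12-week state through
    ``persistence_12wk_to_late``; post-partum quitters are a subset of
    late-pregnancy quitters. All randomness flows through named substreams of
    ``spec.seed``.
    """
    spec.validate()
    n = spec.n_incentives + spec.n_control
    arm = np.array(
        ["incentives"] * spec.n_incentives + ["control"] * spec.n_control
    )

    def per_arm(d):
        return np.where(arm == "incentives", d["incentives"], d["control"])

    site_rng = substream(spec.seed, "site")
    w = (
        np.full(spec.n_sites, 1.0 / spec.n_sites)
        if spec.site_weights is None
        else np.asarray(spec.site_weights, dtype=float)
    )
    site = site_rng.choice(np.arange(1, spec.n_sites + 1), size=n, p=w)
    # grades 5 and 6 split across sites (per-site adviser banding)
    adviser_grade = np.where(site <= (spec.n_sites + 1) // 2, 5, 6)

    cov_rng = substream(spec.seed, "covariates")
    age = np.round(_truncnorm(cov_rng, 28.0, 5.5, 16.0, 45.0, n), 1)
    years_smoking = np.round(
        np.minimum(cov_rng.gamma(4.0, 2.5, n), np.maximum(age - 12.0, 0.5)), 1
    )
    gest_booking = np.round(_truncnorm(cov_rng, 14.0, 4.0, 4.0, 23.9, n), 1)
    covid_era = substream(spec.seed, "covid").random(n) < spec.covid_era_frac

    # nested milestones from one persistence uniform
    u = substream(spec.seed, "milestones").random(n)
    engaged = u < per_arm(spec.engage_prob)
    q4 = u < per_arm(spec.quit_prob_4wk)
    q12 = u < per_arm(spec.quit_prob_12wk)

    # late-pregnancy verified quit: sticky from 12 weeks, new quits make up
    # the remainder of the marginal
    late_rng = substream(spec.seed, "late_quit")
    p12, plate = per_arm(spec.quit_prob_12wk), per_arm(spec.quit_prob_late)
    stay = spec.persistence_12wk_to_late
    new = np.clip((plate - p12 * stay) / np.maximum(1.0 - p12, 1e-12), 0.0, 1.0)
    v = late_rng.random(n)
    quit_late = np.where(q12, v < stay, v < new)

    # self-reported quit at late pregnancy: superset of verified quit
    sr_rng = substream(spec.seed, "selfreport")
    psr = per_arm(spec.selfreport_prob_late)
    extra = np.clip((psr - plate) / np.maximum(1.0 - plate, 1e-12), 0.0, 1.0)
    selfreport_late = quit_late | (~quit_late & (sr_rng.random(n) < extra))
    saliva = substream(spec.seed, "saliva").random(n) < spec.saliva_return_prob

    verification = np.where(
        quit_late & ~covid_era,
        "CO",
        np.where(quit_late & covid_era, "saliva", "self_report"),
    )

    pp_rng = substream(spec.seed, "postpartum")
    ppp = per_arm(spec.quit_prob_postpartum)
    cond = np.where(plate > 0, ppp / np.maximum(plate, 1e-12), 0.0)
    quit_pp = quit_late & (pp_rng.random(n) < cond)

    # utilities: truncated normal on the crosswalk value-set range
    lo, hi = UTILITY_RANGE
    util = {}
    for tp in ("baseline", "late", "postpartum"):
        rng_u = substream(spec.seed, f"utility_{tp}")
        mean = per_arm(spec.utility_mean[tp])
        util[tp] = np.round(
            _truncnorm(rng_u, mean, spec.utility_sd, lo, hi, n), 4
        )

    # resource use
    res_rng = substream(spec.seed, "resources")
    sss_minutes = np.round(res_rng.gamma(2.0, per_arm(spec.sss_minutes_mean) / 2.0))
    nrt_weeks = res_rng.poisson(per_arm(spec.nrt_weeks_mean)).astype(float)

    # birth outcome: miscarriage, else preterm class depends on verified quit
    birth_rng = substream(spec.seed, "birth")
    miscarriage = birth_rng.random(n) < spec.miscarriage_prob
    classes = np.array(PRETERM_CLASSES)
    pq = np.asarray(spec.preterm_probs["quit"], dtype=float)
    ps = np.asarray(spec.preterm_probs["smoker"], dtype=float)
    cum = np.where(quit_late[:, None], np.cumsum(pq), np.cumsum(ps))
    draw = birth_rng.random(n)
    preterm_class = classes[(draw[:, None] < cum).argmax(axis=1)]
    ga = _gestational_age(birth_rng, preterm_class)
    ga = np.where(miscarriage, np.nan, np.round(ga, 1))

    # voucher issuance is administrative data recorded when vouchers are
    # sent: computed here on the full-information milestones (incentives arm
    # only) and never subject to missingness
    incent = arm == "incentives"
    v_eng = incent & engaged
    v_4wk = incent & q4  # nested in engagement by construction
    v_12wk = incent & q12
    v_late = incent & (quit_late | (covid_era & selfreport_late & saliva))

    post_rng = substream(spec.seed, "postage")
    n_sent = (
        v_eng.astype(int) + v_4wk.astype(int)
        + v_12wk.astype(int) + v_late.astype(int)
    )
    n_resent = post_rng.binomial(n_sent, spec.resend_prob)
    n_resent_charged = post_rng.binomial(n_resent, spec.resend_charged_prob)

    table = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "arm": arm,
            "site": site,
            "adviser_grade": adviser_grade,
            "age_years": age,
            "years_smoking": years_smoking,
            "gestation_at_booking_weeks": gest_booking,
            "covid_era": covid_era,
            "engaged": engaged,
            "quit_4wk": np.where(q4, "quit", "smoker"),
            "quit_12wk": np.where(q12, "quit", "smoker"),
            "quit_late": np.where(quit_late, "quit", "smoker"),
            "quit_late_selfreport": np.where(selfreport_late, "quit", "smoker"),
            "saliva_returned": saliva,
            "quit_postpartum": np.where(quit_pp, "quit", "smoker"),
            "verification": verification,
            "utility_baseline": util["baseline"],
            "utility_late": util["late"],
            "utility_postpartum": util["postpartum"],
            "t_late_years": spec.t_late_years,
            "t_postpartum_years": spec.t_postpartum_years,
            "sss_contact_minutes": sss_minutes,
            "nrt_weeks": nrt_weeks,
            "voucher_engagement": v_eng,
            "voucher_4wk": v_4wk,
            "voucher_12wk": v_12wk,
            "voucher_late": v_late,
            "n_resent": n_resent,
            "n_resent_charged": n_resent_charged,
            "gestational_age_birth_weeks": ga,
            "miscarriage": miscarriage,
            "withdrew": False,
        }
    )
    return table


def inject_missingness(
    table: pd.DataFrame,
    missing_rates: dict,
    drivers: tuple = ("miscarriage", "site"),
    seed: int = 0,
) -> pd.DataFrame:
    """Mask values missing-at-random, driven by observed covariates.

    For each variable, the missingness probability follows a logistic model
    whose linear predictor loads on the driver columns (never on the masked
    value itself); the intercept is solved so the marginal missingness equals
    the target rate. Rates 0 and 1 short-circuit to no masking / full masking.
    """
    for d in drivers:
        if d not in table.columns:
            raise KeyError(f"unknown driver column: {d!r}")
    out = table.copy()
    n = len(out)

    # fixed tilt: miscarriage strongly predicts missing follow-up; a smooth
    # site gradient stands in for between-site data-collection differences
    lp = np.zeros(n)
    if "miscarriage" in drivers:
        lp = lp + 1.5 * out["miscarriage"].to_numpy(dtype=float)
    if "site" in drivers:
        s = out["site"].to_numpy(dtype=float)
        lp = lp + 0.15 * (s - s.mean())
    for d in drivers:
        if d not in ("miscarriage", "site"):
            x = out[d].to_numpy(dtype=float)
            sd = x.std() or 1.0
            lp = lp + 0.3 * (x - x.mean()) / sd

    for col, rate in missing_rates.items():
        if col not in MASKABLE:
            raise KeyError(f"column {col!r} is not maskable")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missing rate for {col!r} outside [0, 1]")
        rng = substream(seed, f"missing_{col}")
        if rate == 0.0:
            continue
        if rate == 1.0:
            mask = np.ones(n, dtype=bool)
        else:
            a = optimize.brentq(
                lambda a: special.expit(a + lp).mean() - rate, -30.0, 30.0
            )
            mask = rng.random(n) < special.expit(a + lp)
        if MASKABLE[col] == "tristate":
            out.loc[mask, col] = "missing"
        else:
            out.loc[mask, col] = np.nan
    return out


def generate_trial_table(spec: CohortSpec, with_missingness: bool = True) -> pd.DataFrame:
    """Convenience: generate the cohort and apply its configured missingness."""
    table = generate_cohort(spec)
    if with_missingness and spec.missing_rates:
        table = inject_missingness(
            table, spec.missing_rates, seed=spec.seed
        )
    return table
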