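"""Lifetime mother-infant cost-utility model.

A decision-tree / Markov cohort structure in three sections: pregnancy (a
decision tree over quit status and birth outcome, where the intervention cost
is charged once), childhood (infant cohort, birth to age 15) and lifetime
(mother to age 100 from age 28; infant adulthood from 15 to 100).
Smoking-related morbidity and mortality apply in every section; costs and
QALYs accumulate per cycle (1 year) with annual discounting at 3.5%.

The trial-facing inputs (per-arm quit rates, intervention costs, relapse)
follow published trial summaries. The remaining parameter set — state lists,
state costs and utilities, mortality and morbidity rates — is a documented
synthetic default chosen to satisfy the qualitative orderings a smoking model
must have (smokers cost more, accrue less utility and die sooner than
quitters; an exposed child is likelier to fall ill and to take up smoking).
It is not the published external parameter set of any existing model, so
absolute outputs are illustrative; structural and directional behaviour is
what this module asserts and tests.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .within_trial import classify_quadrant, icer

ARMS = ("incentives", "control")
MOTHER_STATES = ("quitter", "smoker", "dead")
CHILD_STATES = ("healthy", "morbid", "dead")
ADULT_STATES = ("nonsmoker", "smoker", "dead")
SECTIONS = (
    "maternal_pregnancy", "maternal_lifetime", "infant_pregnancy",
    "infant_childhood", "infant_adulthood", "combined",
)
PREGNANCY_OUTCOMES = ("normal", "adverse_live", "adverse_pregnancy")


def _age_band(age: float) -> int:
    for i, hi in enumerate((45, 65, 85, 101)):
        if age < hi:
            return i
    return 3


@dataclass
class ModelParams:
    """Inputs of the lifetime model. Ages in years, money in 2020 GBP."""

    cohort_size: int = 944
    pregnancy_year: int = 2019
    mother_age: int = 28
    max_age: int = 100
    discount_rate: float = 0.035
    wtp_reference: float = 20_000.0
    half_cycle_correction: bool = False

    quit_rate: dict = field(default_factory=lambda: {"incentives": 0.268, "control": 0.123})
    quit_rate_se: dict = field(default_factory=lambda: {"incentives": 0.020, "control": 0.015})
    intervention_cost: dict = field(default_factory=lambda: {"incentives": 262.0, "control": 91.0})
    intervention_cost_se: dict = field(default_factory=lambda: {"incentives": 11.7, "control": 6.40})

    relapse_1yr: float = 0.47
    relapse_1yr_se: float = 0.046
    annual_relapse: float = 0.02
    background_quit: float = 0.02

    #: P(birth outcome | smoking status at late pregnancy); synthetic
    pregnancy_outcome_probs: dict = field(
        default_factory=lambda: {
            "quit": {"normal": 0.82, "adverse_live": 0.06, "adverse_pregnancy": 0.12},
            "smoker": {"normal": 0.685, "adverse_live": 0.105, "adverse_pregnancy": 0.21},
        }
    )
    pregnancy_outcome_cost_mother: dict = field(
        default_factory=lambda: {"normal": 1500.0, "adverse_live": 4000.0, "adverse_pregnancy": 3000.0}
    )
    pregnancy_outcome_cost_infant: dict = field(
        default_factory=lambda: {"normal": 300.0, "adverse_live": 9000.0, "adverse_pregnancy": 1000.0}
    )
    pregnancy_utility: dict = field(default_factory=lambda: {"quit": 0.72, "smoker": 0.695})
    infant_pregnancy_utility: dict = field(
        default_factory=lambda: {"normal": 0.97, "adverse_live": 0.85, "adverse_pregnancy": 0.0}
    )

    #: annual state costs by age band (<45, 45-64, 65-84, 85+); smokers
    #: always at least as costly as quitters (smoking-attributable cost >= 0)
    state_costs: dict = field(
        default_factory=lambda: {
            "quitter": (220.0, 420.0, 900.0, 1500.0),
            "smoker": (420.0, 900.0, 1700.0, 2400.0),
        }
    )
    state_cost_cv: float = 0.10  # PSA coefficient of variation on state costs
    state_utilities: dict = field(
        default_factory=lambda: {
            "quitter": (0.88, 0.84, 0.77, 0.66),
            "smoker": (0.82, 0.76, 0.68, 0.58),
        }
    )
    state_utility_se: float = 0.02
    #: Gompertz baseline annual mortality and smoking-status relative risks
    mortality_base: float = 4.0e-4
    mortality_slope: float = 0.088
    mortality_rr: dict = field(default_factory=lambda: {"quitter": 1.15, "smoker": 2.1})

    # infant childhood (0-15)
    child_morbidity_base: float = 0.05
    child_morbidity_rr_exposed: float = 1.6
    child_recovery: float = 0.5
    child_mortality: float = 6.0e-4
    child_mortality_rr_morbid: float = 1.5
    child_state_costs: dict = field(default_factory=lambda: {"healthy": 120.0, "morbid": 1300.0})
    child_state_utilities: dict = field(default_factory=lambda: {"healthy": 0.95, "morbid": 0.87})

    # infant adulthood (15-100)
    adult_uptake_base: float = 0.15
    child_uptake_multiplier: float = 1.9  # relative risk with a smoking mother

    def validate(self) -> None:
        for arm in ARMS:
            if not 0 <= self.quit_rate[arm] <= 1:
                raise ValueError(f"quit_rate[{arm}] outside [0, 1]")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        for status, d in self.pregnancy_outcome_probs.items():
            if abs(sum(d.values()) - 1.0) > 1e-9:
                raise ValueError(f"pregnancy outcome probabilities for {status!r} must sum to 1")
        for p in (self.relapse_1yr, self.annual_relapse, self.background_quit,
                  self.child_morbidity_base, self.child_recovery,
                  self.adult_uptake_base):
            if not 0 <= p <= 1:
                raise ValueError("probability parameter outside [0, 1]")
        for state in ("quitter", "smoker"):
            if state not in self.state_costs or state not in self.state_utilities:
                raise ValueError(f"state {state!r} needs both a cost and a utility entry")

    def copy(self) -> "ModelParams":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# primitive operations

def adjust_for_gaming(rate: float, fraction: float) -> float:
    """Deflate a quit rate for gaming by a proportional fraction."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("gaming fraction must lie in [0, 1]")
    return rate * (1.0 - fraction)


def discount_factor(years_from_start: float, rate: float) -> float:
    """(1+rate)^(-years); year 0 is undiscounted."""
    if rate < -1:
        raise ValueError("discount rate below -100%")
    if years_from_start < 0:
        raise ValueError("years_from_start must be >= 0")
    return float((1.0 + rate) ** (-years_from_start))


def extrapolate_relapse(rate_6mo: float, method: str, fixed_value: float | None = None) -> float:
    """Extend a 6-month relapse probability to one year.

    ``constant_hazard`` compounds the 6-month hazard twice: 1-(1-p)^2.
    ``passthrough`` uses the 6-month figure unchanged. ``fixed`` injects a
    supplied externally derived 1-year value.
    """
    if not 0.0 <= rate_6mo <= 1.0:
        raise ValueError("relapse probability outside [0, 1]")
    if method == "constant_hazard":
        return 1.0 - (1.0 - rate_6mo) ** 2
    if method == "passthrough":
        return rate_6mo
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("method 'fixed' requires fixed_value")
        return float(fixed_value)
    raise ValueError(f"unknown extrapolation method: {method!r}")


# ---------------------------------------------------------------------------
# Markov engine

def run_markov(
    transitions: np.ndarray,
    start_occ: np.ndarray,
    cost_rewards: np.ndarray,
    utility_rewards: np.ndarray,
    discount_rate: float,
    year_offset: float = 1.0,
    half_cycle_correction: bool = False,
) -> dict:
    """Run a cohort through cycle-indexed transition tables.

    ``transitions`` has shape (T, S, S) with rows summing to 1;
    ``cost_rewards`` / ``utility_rewards`` have shape (T, S) and accrue per
    person-year in each state during each cycle. Occupancy during cycle t is
    the start-of-cycle vector (or the half-cycle average when requested),
    discounted at ``year_offset + t`` years from model start. Cohort mass is
    conserved every cycle (asserted), and the trace is returned alongside the
    discounted totals.
    """
    T, S, S2 = transitions.shape
    if S != S2:
        raise ValueError("transition tables must be square")
    rows = transitions.sum(axis=2)
    if not np.allclose(rows, 1.0, atol=1e-9):
        bad = np.argwhere(np.abs(rows - 1.0) > 1e-9)[0]
        raise ValueError(f"transition row {tuple(bad)} does not sum to 1")
    if (transitions < -1e-12).any():
        raise ValueError("negative transition probability")

    occ = np.asarray(start_occ, dtype=float)
    mass = occ.sum()
    trace = np.empty((T + 1, S))
    trace[0] = occ
    cost = qaly = 0.0
    for t in range(T):
        nxt = trace[t] @ transitions[t]
        assert abs(nxt.sum() - mass) < 1e-6 * max(mass, 1.0), "cohort mass not conserved"
        trace[t + 1] = nxt
        during = 0.5 * (trace[t] + nxt) if half_cycle_correction else trace[t]
        df = discount_factor(year_offset + t, discount_rate)
        cost += float(during @ cost_rewards[t]) * df
        qaly += float(during @ utility_rewards[t]) * df
    return {"trace": trace, "cost": cost, "qaly": qaly}


def _three_state_transitions(T, p_stop_to_smoke, p_smoke_to_stop, mort_stop, mort_smoke):
    """(T,3,3) tables over (non-smoking, smoking, dead); death absorbing."""
    trans = np.zeros((T, 3, 3))
    for t in range(T):
        mq, ms = min(mort_stop[t], 1.0), min(mort_smoke[t], 1.0)
        rel = p_stop_to_smoke[t] if np.ndim(p_stop_to_smoke) else p_stop_to_smoke
        bq = p_smoke_to_stop[t] if np.ndim(p_smoke_to_stop) else p_smoke_to_stop
        trans[t, 0] = [(1 - mq) * (1 - rel), (1 - mq) * rel, mq]
        trans[t, 1] = [(1 - ms) * bq, (1 - ms) * (1 - bq), ms]
        trans[t, 2] = [0.0, 0.0, 1.0]
    return trans


def build_mother_model(params: ModelParams, arm: str) -> dict:
    """Mother Markov section: ages ``mother_age+1`` .. ``max_age``."""
    T = params.max_age - params.mother_age
    ages = params.mother_age + 1 + np.arange(T)
    base = params.mortality_base * np.exp(params.mortality_slope * (ages - params.mother_age))
    mort_q = np.minimum(base * params.mortality_rr["quitter"], 1.0)
    mort_s = np.minimum(base * params.mortality_rr["smoker"], 1.0)
    relapse = np.full(T, params.annual_relapse)
    relapse[0] = params.relapse_1yr
    trans = _three_state_transitions(T, relapse, params.background_quit, mort_q, mort_s)

    bands = np.array([_age_band(a) for a in ages])
    costs = np.zeros((T, 3))
    utils = np.zeros((T, 3))
    for i, state in enumerate(("quitter", "smoker")):
        costs[:, i] = np.asarray(params.state_costs[state])[bands]
        utils[:, i] = np.asarray(params.state_utilities[state])[bands]

    q = params.quit_rate[arm]
    start = np.array([q, 1.0 - q, 0.0]) * params.cohort_size
    return {
        "states": MOTHER_STATES, "transitions": trans, "cost_rewards": costs,
        "utility_rewards": utils, "start_occ": start,
    }


def run_pregnancy_tree(params: ModelParams, arm: str) -> dict:
    """Pregnancy decision tree (year 0, undiscounted).

    Expected outcomes mix the quit and smoker branches by the arm quit rate;
    the per-arm intervention cost is charged here, once. Returns cohort-level
    expected mother/infant costs and QALYs plus expected counts of adverse
    live births and adverse pregnancy outcomes.
    """
    params.validate()
    q = params.quit_rate[arm]
    N = params.cohort_size
    probs = {
        o: q * params.pregnancy_outcome_probs["quit"][o]
        + (1 - q) * params.pregnancy_outcome_probs["smoker"][o]
        for o in PREGNANCY_OUTCOMES
    }
    mother_cost = N * (
        params.intervention_cost[arm]
        + sum(probs[o] * params.pregnancy_outcome_cost_mother[o] for o in PREGNANCY_OUTCOMES)
    )
    mother_qaly = N * (
        q * params.pregnancy_utility["quit"] + (1 - q) * params.pregnancy_utility["smoker"]
    )
    infant_cost = N * sum(
        probs[o] * params.pregnancy_outcome_cost_infant[o] for o in PREGNANCY_OUTCOMES
    )
    infant_qaly = N * sum(
        probs[o] * params.infant_pregnancy_utility[o] for o in PREGNANCY_OUTCOMES
    )
    return {
        "outcome_probs": probs,
        "mother_cost": mother_cost, "mother_qaly": mother_qaly,
        "infant_cost": infant_cost, "infant_qaly": infant_qaly,
        "adverse_live_births": N * probs["adverse_live"],
        "adverse_pregnancy_outcomes": N * probs["adverse_pregnancy"],
        "live_births": N * (1.0 - probs["adverse_pregnancy"]),
    }


def build_child_model(params: ModelParams, arm: str, live_births: float) -> dict:
    """Infant childhood Markov section: ages 1..15.

    Household smoke exposure is the share of mothers smoking after year-1
    relapse; it scales the morbidity onset probability.
    """
    T = 15
    q1 = params.quit_rate[arm] * (1.0 - params.relapse_1yr)
    exposed = 1.0 - q1
    p_morbid = params.child_morbidity_base * (
        exposed * params.child_morbidity_rr_exposed + (1.0 - exposed)
    )
    mort = params.child_mortality
    trans = np.zeros((T, 3, 3))
    for t in range(T):
        mh, mm = mort, min(mort * params.child_mortality_rr_morbid, 1.0)
        trans[t, 0] = [(1 - mh) * (1 - p_morbid), (1 - mh) * p_morbid, mh]
        trans[t, 1] = [(1 - mm) * params.child_recovery, (1 - mm) * (1 - params.child_recovery), mm]
        trans[t, 2] = [0, 0, 1.0]
    costs = np.tile(
        [params.child_state_costs["healthy"], params.child_state_costs["morbid"], 0.0], (T, 1)
    )
    utils = np.tile(
        [params.child_state_utilities["healthy"], params.child_state_utilities["morbid"], 0.0], (T, 1)
    )
    start = np.array([live_births, 0.0, 0.0])
    return {
        "states": CHILD_STATES, "transitions": trans, "cost_rewards": costs,
        "utility_rewards": utils, "start_occ": start, "exposed_share": exposed,
    }


def build_adult_model(params: ModelParams, arm: str, alive_at_15: np.ndarray,
                      mother_smoking_share: float) -> dict:
    """Infant adulthood section: ages 16..100.

    Smoking uptake at 15 is the base uptake times the uptake relative risk
    for the share of infants whose mother smokes.
    """
    uptake = params.adult_uptake_base * (
        mother_smoking_share * params.child_uptake_multiplier + (1.0 - mother_smoking_share)
    )
    uptake = min(uptake, 1.0)
    T = params.max_age - 15
    ages = 16 + np.arange(T)
    base = params.mortality_base * np.exp(
        params.mortality_slope * np.maximum(ages - params.mother_age, 0.0)
    )
    base = np.maximum(base, params.child_mortality)
    mort_n = np.minimum(base * params.mortality_rr["quitter"], 1.0)
    mort_s = np.minimum(base * params.mortality_rr["smoker"], 1.0)
    trans = _three_state_transitions(
        T, params.annual_relapse, params.background_quit, mort_n, mort_s
    )
    bands = np.array([_age_band(a) for a in ages])
    costs = np.zeros((T, 3))
    utils = np.zeros((T, 3))
    for i, state in enumerate(("quitter", "smoker")):
        costs[:, i] = np.asarray(params.state_costs[state])[bands]
        utils[:, i] = np.asarray(params.state_utilities[state])[bands]
    alive = float(np.sum(alive_at_15[:2]))
    start = np.array([alive * (1 - uptake), alive * uptake, 0.0])
    return {
        "states": ADULT_STATES, "transitions": trans, "cost_rewards": costs,
        "utility_rewards": utils, "start_occ": start, "uptake": uptake,
    }


def run_arm(params: ModelParams, arm: str) -> dict:
    """Discounted per-person costs and QALYs for one arm, by section."""
    N = params.cohort_size
    tree = run_pregnancy_tree(params, arm)

    mother = build_mother_model(params, arm)
    mres = run_markov(
        mother["transitions"], mother["start_occ"], mother["cost_rewards"],
        mother["utility_rewards"], params.discount_rate, year_offset=1.0,
        half_cycle_correction=params.half_cycle_correction,
    )
    child = build_child_model(params, arm, tree["live_births"])
    cres = run_markov(
        child["transitions"], child["start_occ"], child["cost_rewards"],
        child["utility_rewards"], params.discount_rate, year_offset=1.0,
        half_cycle_correction=params.half_cycle_correction,
    )
    adult = build_adult_model(
        params, arm, cres["trace"][-1],
        mother_smoking_share=_smoking_share(mres["trace"], 15),
    )
    ares = run_markov(
        adult["transitions"], adult["start_occ"], adult["cost_rewards"],
        adult["utility_rewards"], params.discount_rate, year_offset=16.0,
        half_cycle_correction=params.half_cycle_correction,
    )

    sections = {
        "maternal_pregnancy": {
            "cost": tree["mother_cost"] / N, "qaly": tree["mother_qaly"] / N,
        },
        "maternal_lifetime": {
            "cost": (tree["mother_cost"] + mres["cost"]) / N,
            "qaly": (tree["mother_qaly"] + mres["qaly"]) / N,
        },
        "infant_pregnancy": {
            "cost": tree["infant_cost"] / N, "qaly": tree["infant_qaly"] / N,
            "adverse_live_births": tree["adverse_live_births"],
            "adverse_pregnancy_outcomes": tree["adverse_pregnancy_outcomes"],
        },
        "infant_childhood": {
            "cost": (tree["infant_cost"] + cres["cost"]) / N,
            "qaly": (tree["infant_qaly"] + cres["qaly"]) / N,
        },
        "infant_adulthood": {
            "cost": (tree["infant_cost"] + cres["cost"] + ares["cost"]) / N,
            "qaly": (tree["infant_qaly"] + cres["qaly"] + ares["qaly"]) / N,
        },
    }
    sections["combined"] = {
        "cost": sections["maternal_lifetime"]["cost"] + sections["infant_adulthood"]["cost"],
        "qaly": sections["maternal_lifetime"]["qaly"] + sections["infant_adulthood"]["qaly"],
    }
    sections["_traces"] = {"mother": mres["trace"], "child": cres["trace"], "adult": ares["trace"]}
    return sections


def _smoking_share(mother_trace: np.ndarray, cycle: int) -> float:
    occ = mother_trace[min(cycle, len(mother_trace) - 1)]
    alive = occ[0] + occ[1]
    return float(occ[1] / alive) if alive > 0 else 0.0


def run_deterministic(params: ModelParams) -> pd.DataFrame:
    """Deterministic per-section incrementals with ICER / dominance labels."""
    params.validate()
    inc = run_arm(params, "incentives")
    con = run_arm(params, "control")
    rows = []
    for sec in SECTIONS:
        a, b = inc[sec], con[sec]
        dc, dq = a["cost"] - b["cost"], a["qaly"] - b["qaly"]
        r = icer(dc, dq)
        row = {
            "section": sec,
            "cost_incentives": a["cost"], "cost_control": b["cost"],
            "qaly_incentives": a["qaly"], "qaly_control": b["qaly"],
            "delta_cost": dc, "delta_qaly": dq,
            "icer": r["icer_raw"], "label": r["label"],
        }
        if sec == "infant_pregnancy":
            row["delta_adverse_live_births"] = (
                a["adverse_live_births"] - b["adverse_live_births"]
            )
            row["delta_adverse_pregnancy_outcomes"] = (
                a["adverse_pregnancy_outcomes"] - b["adverse_pregnancy_outcomes"]
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

def beta_mm(mean: float, se: float):
    """Method-of-moments beta parameters; degenerate when se == 0."""
    if se == 0:
        return None
    if not 0 < mean < 1:
        raise ValueError("beta mean must be in (0, 1)")
    v = se * se
    if v >= mean * (1 - mean):
        raise ValueError("SE incompatible with beta support")
    k = mean * (1 - mean) / v - 1.0
    return mean * k, (1 - mean) * k


def gamma_mm(mean: float, se: float):
    """Method-of-moments gamma (shape, scale); degenerate when se == 0."""
    if se == 0:
        return None
    if mean <= 0:
        raise ValueError("gamma mean must be positive")
    shape = (mean / se) ** 2
    return shape, se * se / mean


def _draw_beta(rng, mean, se):
    p = beta_mm(mean, se)
    return mean if p is None else float(rng.beta(*p))


def _draw_gamma(rng, mean, se):
    p = gamma_mm(mean, se)
    return mean if p is None else float(rng.gamma(p[0], p[1]))


def draw_params(params: ModelParams, rng: np.random.Generator) -> ModelParams:
    """One PSA draw: beta for probabilities/utilities, gamma for costs.

    Varied parameters: per-arm quit rates and intervention costs, the 1-year
    relapse probability, state costs (CV ``state_cost_cv``) and state
    utilities (SE ``state_utility_se``). Setting all SEs to zero makes the
    draw degenerate at the deterministic values.
    """
    p = params.copy()
    for arm in ARMS:
        p.quit_rate[arm] = _draw_beta(rng, params.quit_rate[arm], params.quit_rate_se[arm])
        p.intervention_cost[arm] = _draw_gamma(
            rng, params.intervention_cost[arm], params.intervention_cost_se[arm]
        )
    p.relapse_1yr = _draw_beta(rng, params.relapse_1yr, params.relapse_1yr_se)
    for state in ("quitter", "smoker"):
        p.state_costs[state] = tuple(
            _draw_gamma(rng, c, params.state_cost_cv * c) for c in params.state_costs[state]
        )
        p.state_utilities[state] = tuple(
            _draw_beta(rng, u, params.state_utility_se) for u in params.state_utilities[state]
        )
    return p


def run_psa(params: ModelParams, n_samples: int, seed: int = 0) -> dict:
    """Probabilistic sensitivity analysis.

    Draws ``n_samples`` parameter sets, runs the deterministic model on each,
    and summarizes per-section incrementals: mean, 2.5/97.5-percentile
    intervals, and the probability of positive net monetary benefit at the
    reference willingness-to-pay threshold. Seed-reproducible.
    """
    rng = substream(seed, "psa")
    records = {sec: [] for sec in SECTIONS}
    for _ in range(n_samples):
        drawn = draw_params(params, rng)
        res = run_deterministic(drawn)
        for _, row in res.iterrows():
            records[row["section"]].append((row["delta_cost"], row["delta_qaly"]))

    det = run_deterministic(params).set_index("section")
    summary = []
    samples = {}
    lam = params.wtp_reference
    for sec in SECTIONS:
        arr = np.array(records[sec])
        samples[sec] = pd.DataFrame(arr, columns=["delta_cost", "delta_qaly"])
        dc, dq = arr[:, 0], arr[:, 1]
        nmb = lam * dq - dc
        r = icer(float(det.loc[sec, "delta_cost"]), float(det.loc[sec, "delta_qaly"]))
        summary.append(
            {
                "section": sec,
                "delta_cost": det.loc[sec, "delta_cost"],
                "delta_cost_lo": float(np.percentile(dc, 2.5)),
                "delta_cost_hi": float(np.percentile(dc, 97.5)),
                "delta_qaly": det.loc[sec, "delta_qaly"],
                "delta_qaly_lo": float(np.percentile(dq, 2.5)),
                "delta_qaly_hi": float(np.percentile(dq, 97.5)),
                "icer": r["icer_raw"], "label": r["label"],
                "prob_cost_effective": float((nmb > 0).mean()),
            }
        )
    return {"summary": pd.DataFrame(summary), "samples": samples, "n_samples": n_samples}


# ---------------------------------------------------------------------------
# break-even intervention cost and scenario registry

def break_even_intervention_cost(params: ModelParams, section: str = "combined") -> float:
    """Incentives-arm intervention cost at which the incremental cost is zero.

    The sectional incremental cost is affine in the incentives-arm
    intervention cost (charged once, per person, in the pregnancy tree), so
    two evaluations identify the break-even point exactly. Below this cost
    the strategy is dominant whenever its incremental QALYs are positive.
    """
    def dcost(c):
        p = params.copy()
        p.intervention_cost["incentives"] = c
        res = run_deterministic(p).set_index("section")
        return float(res.loc[section, "delta_cost"])

    d0, d1 = dcost(0.0), dcost(1000.0)
    slope = (d1 - d0) / 1000.0
    if slope == 0:
        raise ValueError("incremental cost does not depend on intervention cost")
    return float(-d0 / slope)


LIFETIME_SCENARIOS = ("base", "S1a", "S1b", "S2", "S3a", "S3b", "S4")


def scenario_params(params: ModelParams, scenario: str) -> ModelParams:
    """Apply a named sensitivity substitution to a copy of the base inputs."""
    p = params.copy()
    if scenario == "base":
        return p
    if scenario == "S1a":
        p.quit_rate["incentives"] = adjust_for_gaming(params.quit_rate["incentives"], 0.11)
        p.quit_rate["control"] = adjust_for_gaming(params.quit_rate["control"], 0.20)
    elif scenario == "S1b":
        p.quit_rate["incentives"] = adjust_for_gaming(params.quit_rate["incentives"], 0.11)
        p.quit_rate["control"] = adjust_for_gaming(params.quit_rate["control"], 0.11)
    elif scenario == "S2":
        p.quit_rate = {"incentives": 0.359, "control": 0.185}
        p.quit_rate_se = {"incentives": 0.022, "control": 0.018}
    elif scenario == "S3a":
        p.intervention_cost["incentives"] = 131.0
        p.intervention_cost_se["incentives"] = 13.265
        p.quit_rate = {"incentives": 0.046, "control": 0.025}
        p.quit_rate_se = {"incentives": 0.005, "control": 0.003}
    elif scenario == "S3b":
        p.intervention_cost["incentives"] = 463.0
        p.intervention_cost_se["incentives"] = 47.4
        p.quit_rate["incentives"] = 0.34
        p.quit_rate_se["incentives"] = 0.035
    elif scenario == "S4":
        p.relapse_1yr = extrapolate_relapse(0.0, "fixed", fixed_value=0.814)
        p.relapse_1yr_se = 0.079
    else:
        raise ValueError(f"unknown lifetime scenario: {scenario!r}")
    return p


def run_all_scenarios(
    params: ModelParams,
    scenarios=LIFETIME_SCENARIOS,
    n_psa: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Deterministic (and optionally probabilistic) results per scenario.

    With ``n_psa > 0`` each scenario's combined-section incrementals carry
    percentile intervals and a probability of cost-effectiveness at the
    reference threshold.
    """
    rows = []
    for sc in scenarios:
        p = scenario_params(params, sc)
        det = run_deterministic(p).set_index("section")
        row = {
            "scenario": sc,
            "delta_cost": float(det.loc["combined", "delta_cost"]),
            "delta_qaly": float(det.loc["combined", "delta_qaly"]),
            "icer": float(det.loc["combined", "icer"]),
            "label": det.loc["combined", "label"],
        }
        if n_psa > 0:
            psa = run_psa(p, n_psa, seed=seed)
            s = psa["summary"].set_index("section").loc["combined"]
            row.update(
                delta_cost_lo=s["delta_cost_lo"], delta_cost_hi=s["delta_cost_hi"],
                delta_qaly_lo=s["delta_qaly_lo"], delta_qaly_hi=s["delta_qaly_hi"],
                prob_cost_effective=s["prob_cost_effective"],
            )
        rows.append(row)
    return pd.DataFrame(rows)
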