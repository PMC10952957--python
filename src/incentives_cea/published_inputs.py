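"""Published summary estimates from the motivating multicentre UK trial.

These are analysis *inputs*: arm-level quit rates with standard errors,
per-arm intervention costs, gaming fractions, voucher issuance tallies and
the reported scenario incrementals. They parameterize the lifetime model,
calibrate the synthetic cohort, and feed the ICER-consistency checker; none
of them is an output of this package.
"""

from __future__ import annotations

# (mean, SE) per arm
QUIT_RATES = {
    "late_pregnancy": {"incentives": (0.268, 0.020), "control": (0.123, 0.015)},
    "late_pregnancy_selfreport": {"incentives": (0.359, 0.022), "control": (0.185, 0.018)},
    "postpartum_6mo": {"incentives": (0.079, 0.010), "control": (0.051, 0.010)},
}

#: observed within-trial gaming: verified quits later contradicted by a
#: residual blood sample (2 of 18 incentives, 2 of 10 control), applied as
#: proportional deflations
GAMING_FRACTIONS = {"incentives": 0.11, "control": 0.20}

#: per-arm intervention cost (vouchers+postage+SSS+NRT), (mean, SE), 2020 GBP
INTERVENTION_COST = {"incentives": (262.0, 11.7), "control": (91.0, 6.40)}

#: voucher administration tallies (incentives arm, n=471)
VOUCHER_TALLY = {
    "engagement": 337,
    "quit_4wk": 171,
    "quit_12wk": 138,
    "quit_late": 150,
    "resent": 87,
    "resent_charged": 59,
    "excluded": 3,  # stolen or never received; excluded from analysis
}

#: reported within-trial scenario incrementals: scenario id ->
#: (delta_cost £, delta_effect, effect unit, reported rounded ICER £ or None)
#: Effects in quitter proportion or QALYs. Used by the consistency checker
#: and as desk-scale ICER-arithmetic inputs.
REPORTED_INCREMENTALS = {
    "base_quitter": (637.0, 0.144, "quitter", 4400.0),
    "base_qaly": (637.0, 0.004, "qaly", 150_000.0),
    "S2_quitter": (637.0, 0.174, "quitter", 3700.0),
    "S3_quitter": (637.0, 0.141, "quitter", 4500.0),
    "S4_quitter": (637.0, 0.130, "quitter", 4900.0),
    "S5_quitter": (637.0, 0.027, "quitter", 24_000.0),
    "S6_qaly": (637.0, 0.006, "qaly", 106_000.0),
    "S8_quitter": (176.0, 0.144, "quitter", 4500.0),
    "S9_quitter": (644.0, 0.144, "quitter", 4500.0),
    "S10_quitter": (631.0, 0.144, "quitter", 4400.0),
}

#: lifetime-model trial inputs (means and SEs)
LIFETIME_TRIAL_INPUTS = {
    "cohort_size": 944,
    "pregnancy_year": 2019,
    "mother_age": 28,
    "discount_rate": 0.035,
    "wtp_reference": 20_000.0,
    "relapse_1yr_model": (0.47, 0.046),
    "relapse_1yr_trial_extrapolated": (0.814, 0.079),
    "scenarios": {
        "S3a": {
            "intervention_cost": (131.0, 13.265),
            "quit_rates": {"incentives": (0.046, 0.005), "control": (0.025, 0.003)},
        },
        "S3b": {
            "intervention_cost": (463.0, 47.4),
            "quit_rates": {"incentives": (0.34, 0.035)},
        },
    },
}
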