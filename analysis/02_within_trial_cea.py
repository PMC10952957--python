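"""Within-trial cost-effectiveness analysis on the simulated cohort.

Reads results/cohort.csv (run 01_simulate_cohort.py first; regenerates it if
absent), costs every participant, imputes missing inputs, and runs the base
case plus all ten sensitivity scenarios. Writes the scenario table, the
bootstrap cost-effectiveness plane and the acceptability curve under
results/within_trial/.
"""

import warnings
from pathlib import Path

from incentives_cea import io, plots, within_trial as wt
from incentives_cea.synthetic_cohort import CohortSpec, generate_trial_table

warnings.filterwarnings("ignore")

SEED = 1
ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "within_trial"


def main() -> None:
    cohort_path = ROOT / "cohort.csv"
    if cohort_path.exists():
        table = io.read_cohort(cohort_path)
    else:
        table = generate_trial_table(CohortSpec(seed=SEED))

    cfg = wt.AnalysisConfig(seed=SEED, n_imputations=10, bootstrap_reps=1000)
    completed = wt.impute_chained(table, cfg)
    scenarios = wt.run_scenarios(table, cfg, wt.SCENARIOS, completed=completed)

    OUT.mkdir(parents=True, exist_ok=True)
    scenarios.to_csv(OUT / "scenario_results.csv", index=False)

    prep = wt._prepare(completed[0], cfg.schedule, cfg.unit_costs)
    samples = wt.bootstrap_cea(prep, cfg)
    curve = wt.ceac(samples, cfg.wtp_grid)
    samples.to_csv(OUT / "bootstrap_samples.csv", index=False)
    curve.to_csv(OUT / "ceac.csv", index=False)
    plots.plot_ce_plane(samples, OUT / "ce_plane.png", cfg.wtp_reference)
    plots.plot_ceac(curve, OUT / "ceac.png")

    base = scenarios.set_index("scenario").loc["base"]
    at20k = curve.set_index("threshold").loc[cfg.wtp_reference, "probability"]
    print("base case (pooled over imputations):")
    print(f"  incremental cost £{base.delta_cost:.0f} "
          f"(95% CI {base.delta_cost_lo:.0f} to {base.delta_cost_hi:.0f})")
    print(f"  incremental quit rate {base.delta_quit:.3f} "
          f"-> £{base.icer_quitter:.0f} per quitter")
    print(f"  incremental QALYs {base.delta_qaly:.4f} "
          f"-> ICER label: {base.icer_qaly_label}, rounded £{base.icer_qaly}")
    print(f"  P(cost-effective) at £20 000/QALY: {at20k:.0%}")
    print("\nscenario table:")
    cols = ["delta_cost", "delta_quit", "delta_qaly", "icer_quitter",
            "icer_quitter_label", "icer_qaly"]
    print(scenarios.set_index("scenario")[cols].round(4).to_string())
    print(f"\nwrote {OUT}")


if __name__ == "__main__":
    main()
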