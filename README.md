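# incentives-cea

Health-economic evaluation of offering financial incentives (shopping
vouchers worth up to £400, contingent on verified smoking-cessation
milestones) to pregnant women, compared with usual stop-smoking support
alone. The package re-implements, as a tested pipeline on synthetic trial
data, the two standard analyses a trial health economist runs:

1. **Within-trial cost-effectiveness / cost-utility analysis** —
   participant-level costing (vouchers, postage, adviser time, NRT, neonatal
   stays proxied by gestational age at birth), Russell-standard quit
   outcomes (missing ⇒ smoker), QALYs by area under the utility curve,
   GLM-adjusted incremental costs and effects, chained-equations multiple
   imputation with Rubin's-rules pooling, a 1000-replicate arm-stratified
   bootstrap with cost-effectiveness plane and acceptability curve, and ten
   sensitivity scenarios.
2. **Lifetime mother–infant model** — a decision tree over pregnancy
   outcomes feeding Markov cohort sections for the mother (to age 100) and
   the infant (childhood to 15, then adulthood), with annual cycles, 3.5%
   discounting, relapse and gaming adjustments, probabilistic sensitivity
   analysis (beta draws for probabilities/utilities, gamma for costs, by
   method of moments), and a break-even search over the intervention cost.

It is written for health economists and methodologists who want a
reproducible, inspectable version of this analysis class: every number is
computed from code plus declared inputs, and no real participant data is
used or required.

## The core quantities

For intervention *i* (incentives) vs comparator *c* (usual care), with
Δ*C* = *C·i* − *C·c* and Δ*E* = *E·i* − *E·c*:

- **ICER** = Δ*C*/Δ*E* (cost per additional quitter, or per QALY), reported
  to two significant figures (nearest £100 below £10 000, nearest £1000
  above), with the raw ratio retained. Δ*C* < 0 < Δ*E* is *dominant*;
  Δ*E* < 0 < Δ*C* is *dominated*.
- **Net monetary benefit** at willingness-to-pay λ: NMB = λ·Δ*E* − Δ*C*; the
  CEAC plots P(NMB > 0) over λ from bootstrap or PSA samples.
- **QALYs** by trapezoid AUC over EQ-5D-5L utilities at baseline, late
  pregnancy and six months post-partum.
- **Gaming adjustment**: quit rate × (1 − f) for deflation fraction f
  (0.268 × 0.89 = 0.239; 0.123 × 0.80 = 0.098).

Arm-level inputs to the lifetime model (quit rates 0.268/0.123, intervention
costs £262/£91, relapse 0.47, gaming fractions) are published trial
summaries shipped in `incentives_cea.published_inputs`. The remaining
lifetime parameters (state costs/utilities, mortality, child morbidity) are
a documented synthetic set — see `docs/methods.md` — so lifetime outputs are
structurally, not numerically, comparable to published results.

## Worked example

```python
from incentives_cea import within_trial as wt, lifetime as lt

wt.icer(637.0, 0.144)
# {'delta_cost': 637.0, 'delta_effect': 0.144,
#  'icer_raw': 4423.6, 'icer_rounded': 4400.0, 'label': 'ratio'}

det = lt.run_deterministic(lt.ModelParams()).set_index("section")
print(det.loc["combined", ["delta_cost", "delta_qaly", "label"]])
# delta_cost   -115.448344
# delta_qaly      0.414674
# label            dominant

lt.break_even_intervention_cost(lt.ModelParams())
# 377.45
```

Read: at the published incremental cost (£637) and quit-rate difference
(0.144), incentives cost £4400 per additional late-pregnancy quitter. Under
the synthetic lifetime parameter set the combined mother–infant strategy is
dominant (saves £115 per person and gains 0.41 discounted QALYs), and would
remain cost-saving up to an intervention cost of about £377 per participant.

The full analysis is driven by the numbered scripts:

```bash
python analysis/01_simulate_cohort.py     # synthetic trial -> results/cohort.csv
python analysis/02_within_trial_cea.py    # base case + S1..S10, bootstrap, CEAC
python analysis/03_lifetime_model.py      # sections, scenarios, PSA, break-even
python analysis/04_consistency_checks.py  # reported-ICER consistency audit
```

or by the equivalent CLI (`incentives-cea simulate|within-trial|lifetime|report`),
which additionally writes a run manifest (seed, config hashes, outputs) next
to each result set.

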