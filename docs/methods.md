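# Methods

This note documents the models, the synthetic data, the numerical choices
and the design decisions behind the package. It states no empirical result
that the tests or `scripts/acceptance.py` do not themselves compute.

## 1. Synthetic trial cohort

No analysable participant-level dataset is publicly available for this
trial, so every analysis runs on a synthetic cohort whose *marginal*
structure matches published summaries: 471/470 participants across seven
sites; milestone marginals in the incentives arm of 71.4% (engagement),
36.2% (4-week quit), 29.2% (12-week quit); verified late-pregnancy quit
rates of 0.268/0.123; self-reported quit rates 0.359/0.185; post-partum
sustained quit 0.079/0.051; utilities near 0.67–0.69 on the crosswalk range
[−0.594, 1]; and per-variable missingness of roughly 10–28%.

Generation choices:

- **Milestones** use a single latent persistence uniform per participant:
  membership in each nested milestone is `u < p`, which guarantees
  engagement ⊇ 4-week ⊇ 12-week quit with exact marginals. Late-pregnancy
  quit is tied to the 12-week state through a persistence probability
  (default 0.75, i.e. three-quarters of 12-week quitters hold to late
  pregnancy), with "new" quits filling the marginal. Post-partum quitters
  are drawn as a subset of late-pregnancy quitters, enforcing the rate
  ordering by construction.
- **Covid-era fraction 0.55**: the late-pregnancy *voucher* issuance
  proportion (31.8%) exceeds the verified quit rate (0.268) because
  covid-era self-reports backed by a saliva sample also qualified. With
  verified ⊆ self-reported quit, issuance = 0.268 + f·(0.359 − 0.268);
  f = 0.55 reproduces 31.8%. This is an analytic calibration to published
  marginals, not a recruitment-curve estimate.
- **Control-arm engagement/4-week/12-week marginals** (0.55/0.16/0.10) are
  unpublished; the defaults were chosen once to give the observed mild
  asymmetry in stop-smoking-service costs (≈£41 vs £52) and are synthetic.
- **Utilities** are truncated normal on the value-set range, SD 0.11
  (chosen so the SE of mean QALYs at the observed n matches the reported
  0.002); arm-specific late-pregnancy means 0.686/0.666 reproduce the
  reported QALY means 0.339/0.334 over the 0.5-year window. Published
  sources report no utility SDs; these are declared synthetic.
- **Preterm distribution** is quit-status-dependent (quitting protective),
  with class probabilities chosen so arm mean neonatal costs land in the
  published few-hundred-to-two-thousand-pound range. The *published* arm
  imbalance (incentives arm costlier) is attributed by its authors to
  chance; a quit-protective generator cannot reproduce it systematically
  and does not try to.
- **Voucher issuance is administrative data**: issuance flags are computed
  at generation from full-information milestones and are never masked, so
  recosting after missingness injection or imputation cannot corrupt
  voucher/postage costs — mirroring a trial data-management system.
- **Follow-up durations** default to 0.5 years (recruitment → late
  pregnancy) and 0.65 years (late pregnancy → 6 months post-partum),
  config-exposed per participant; the within-trial horizon stays under the
  one-year no-discounting boundary for the primary window.
- **Missingness** is missing-at-random by construction: a logistic model on
  miscarriage and site (never on the masked value), intercept solved by
  root-finding so the marginal rate hits the target. One master seed feeds
  named substreams per variable, so adding a variable never perturbs
  existing draws.

What passing tests show — and do not: the pipeline's estimators recover the
generator's truth under MAR missingness and calibrated marginals. Real
trial data differ in ways the generator does not emulate (correlated
utility trajectories, informative site effects, seasonal recruitment,
verification error), so numerical agreement with published *adjusted*
results is not expected and not asserted; the published neonatal imbalance
in particular makes the trial-scale incremental cost estimate noisy by
design.

## 2. Costing

Unit costs are 2020 GBP: vouchers £50/£50/£100/£200 (the last independent
of earlier milestones; the 4- and 12-week vouchers require the *criteria*
of the previous milestone — a strictness switch can demand the previous
voucher itself); postage £2.92 per issued voucher plus £2.05 per charged
resend; adviser time £39/£49 per hour by grade; neonatal stays by WHO
preterm class (13 × £536.45, 44 × £709.16, 93 × £1707.50; term = £0;
missing gestational age propagates to imputation). The weekly NRT price
(£12) is a configuration default, documented rather than sourced from a
printed figure. Sites can carry a typical-use profile substituted when
individual resource data are absent. Stolen/never-received vouchers are
excludable per milestone without breaking award chaining. Currency
arithmetic is full-precision float; reporting rounds to pennies half-even.

## 3. Within-trial analysis

- **Adjusted differences**: GLM with arm plus fixed covariate lists (costs:
  site, age, years smoking, covid era; QALYs: site, age, baseline utility,
  gestation at booking, covid era). Costs default to gamma/log — standard
  for right-skewed cost data — with the between-arm difference computed as
  the average marginal effect by recycled predictions and a delta-method
  SE. Because the synthetic neonatal tail spans zero to six figures, IRLS
  can stall at a local stationary point: the fit tries IRLS, Newton and
  L-BFGS from a log-scale OLS start and keeps the best-likelihood converged
  solution, so near-identical inputs (e.g. a postage-price scenario) map to
  the same optimum. Non-positive outcomes or total non-convergence fall
  back to Gaussian/identity, recorded in the result metadata, never
  silently. QALYs and quit proportions use Gaussian/identity (the latter a
  linear probability model whose unadjusted form equals the difference in
  arm rates).
- **Multiple imputation**: chained equations (predictive mean matching via
  statsmodels' MICE) on *disaggregated* inputs — SSS minutes, NRT weeks,
  gestational age, utilities — with composite costs and QALYs recomputed
  per completed table. Quit outcomes are never imputed: the Russell
  standard counts missing as smoker. m = 20 by default (10 in the analysis
  drivers; m is not stated in the source literature). Rubin's rules pool
  point estimates and variances with Barnard–Rubin degrees of freedom.
  Gestational age after miscarriage is structurally absent and is excluded
  from the imputation model, then restored as missing.
- **Bootstrap**: arm-stratified resampling, each replicate re-running the
  adjusted-difference GLMs; failed replicates are redrawn and counted. The
  default design imputes once and bootstraps the completed data; a config
  switch nests single-imputation inside each replicate instead. The
  bootstrap-mean consistency oracle is asserted for the identity-link
  estimator, for which it is exact; the gamma AME carries genuine
  finite-sample resampling bias under the heavy cost tail and is not used
  as a consistency check, though it remains the default point estimator.
- **ICER reporting**: two significant figures — nearest £100 below £10 000,
  nearest £1000 at or above — inferred from the published pattern
  (£4400, £3700, £24 000, £106 000); raw ratios always retained. Dominance
  labels follow the cost-effectiveness plane quadrants; the label agrees
  with the NMB sign at the reference threshold (£20 000/QALY) by
  construction, and tests assert it.
- **Scenarios** S1–S10: miscarriage covariate; self-reported quit; gaming
  deflation 11%/20% and 11%/11% (applied to the estimated rates, with the
  incremental recomputed); post-partum quit; post-partum QALYs; complete
  case; neonatal means equalized across arms; postage £6; postage £0.
- **Consistency audit**: reported (ΔC, ΔE, ICER) triples are checked by
  recomputing the rounded ratio from the reported inputs. Two published
  rows fail their own arithmetic — the base-case cost-per-QALY (printed
  rounded inputs give ≈£159 000, suggesting an unrounded ΔQALY was used)
  and the neonatal-equalized scenario's cost-per-quitter (its printed ΔC
  implies ≈£1200) — and are flagged, reported as computed, and excluded
  from any assertion of agreement.

## 4. Lifetime model

Structure: a pregnancy decision tree (quit status → {normal birth, adverse
live birth, adverse pregnancy outcome}), then annual-cycle Markov sections —
mother from age 28 to 100 over (quitter, smoker, dead); infant childhood
ages 1–15 over (healthy, morbid, dead) with household-exposure-scaled
morbidity; infant adulthood 16–100 with smoking uptake = base uptake ×1.9
for the share with a smoking mother. The intervention cost is charged once,
in the pregnancy tree; sectional results are reported per person;
`combined = maternal lifetime + infant (childhood + adulthood)`, an
accounting identity asserted in tests. Costs and QALYs discount at 3.5%
per year; year 0 (pregnancy) is undiscounted. Cycle length is one year with
no half-cycle correction by default (a flag enables it). The first
post-partum year applies the 1-year relapse probability (0.47; a
sensitivity substitutes the trial-extrapolated 0.814 via the `fixed`
extrapolation method — the published extrapolation method is unstated, so
constant-hazard and passthrough alternatives are provided but not asserted).

The state lists, state costs/utilities, Gompertz mortality (base 4×10⁻⁴,
slope 0.088, relative risks 1.15/2.1) and child parameters are a
**synthetic default set**, not the published external model's values, which
are not printed in the source material. They satisfy the orderings the
analysis depends on — smokers cost more, accrue less utility, die sooner;
exposure raises child morbidity and uptake — and the package asserts
structural properties (mass conservation, row normalization, discount
closed forms, monotonicity of combined ΔQALY in the quit rate, degenerate
PSA equivalence, dominance labelling, existence of a break-even
intervention cost) rather than absolute magnitudes. Because the sectional
incremental cost is affine in the intervention cost, the break-even point
is found exactly from two evaluations.

PSA draws beta distributions for probabilities and utilities and gamma for
costs, parameterized by method of moments from (mean, SE); SE = 0 yields a
degenerate draw, so an all-zero-SE PSA reproduces the deterministic run
bit-for-bit. Intervals are 2.5/97.5 percentiles; the probability of
cost-effectiveness is the fraction of draws with positive NMB at £20 000.
The analysis drivers use 2000 draws and the CLI defaults to 10 000; the
two agree to Monte-Carlo error and the smaller size keeps driver runtime
near a minute.

## 5. Reproducibility and problem sizes

One integer seed governs everything through named substreams (generator
variables, missingness per column, MICE, bootstrap, PSA). The acceptance
script uses: desk-scale arithmetic (n = 1), a 9410-participant cohort for
costing calibration (tight SEs on arm means), the 941-participant trial
scale for imputation/bootstrap/CEAC (1000 replicates), and 2000 PSA draws —
about a minute of single-CPU time in total.

## 6. Known limitations

- Lifetime magnitudes are illustrative by design (synthetic parameter set);
  only structure, input transformations and directional behaviour transfer.
- The generator draws utilities directly rather than via EQ-5D profiles;
  the profile-to-utility mapping is exercised through its own value-set
  interface with synthetic tables.
- Gamma AME intervals use the delta method, not profile likelihood; with
  the extreme neonatal tail the Gaussian fallback engages on some
  resamples.
- The neonatal proxy attaches singleton births to the mother's record;
  multiple births are out of scope.
- No patient-borne costs, spill-over effects, EVPI/EVSI, or covariate
  selection beyond the fixed lists.
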