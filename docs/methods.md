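# Methods

## The decision problem

`adscreen` models a population screening programme for Alzheimer's disease
(AD) in Chinese adults. A closed cohort (default 100,000 people) enters at
age 60 and is followed in annual cycles until age 80 or death. Two
strategies are compared: a screening arm, in which a two-step cascade
(short cognitive scale, then a diagnostic work-up for scale-positives) is
offered on a configurable schedule and every confirmed case is offered
treatment, and a no-screening arm, in which patients only start treatment
through routine care-seeking. Outcomes are discounted per-capita costs
(societal perspective, USD), QALYs, the ICER, net monetary benefit at a
willingness-to-pay threshold of three times GDP per capita, and counts of
deaths and untreated severe AD cases averted by screening.

## Disease model

Cognitive conditions are NORMAL, MCI, mild AD, moderate AD, severe AD and
DEAD. Progression is stepwise (NORMAL → MCI → mild → moderate → severe);
regression exists from MCI to NORMAL and from moderate to mild AD. Each
disease condition is split by treatment status. Because the drug effect is
time-limited (default 3 years), treated states are tunnel states indexed by
years on treatment: a treated person advances through tunnel years
1..N; years below the cap use the treated transition probabilities, and the
cap year uses the untreated probabilities — the drug effect has lapsed —
while the person keeps accruing treated-state costs (treatment is assumed to
continue to the end of the simulation unless the discontinuation scenario is
active). The moderate→mild regression probability is never drug-modified;
if a configuration supplies a different treated value the builder overrides
it and logs a warning. With N = 3 the chain has 19 states (NORMAL, a
one-year false-positive tunnel, 4 conditions × (1 untreated + 3 treated
years), DEAD); with a lifetime drug effect, 11.

Death competes with progression in every living state. Age-band natural
mortality and a per-condition excess mortality are combined as independent
risks, `1 − (1 − p_nat)(1 − p_excess)`; the combination rule is a model
choice, as the sources state both risks but not how they interact. The
published natural-mortality table stops at the 70–74 band while the horizon
runs to 80, so the 75–79 band is extrapolated log-linearly (least squares on
the log rates of the three published bands) and flagged `assumed`. After
death and the specified exits, the residual "stay" probability closes each
row; a negative residual is a validation error, so every matrix is
row-stochastic by construction (checked to 1e-9).

Care-seeking uptake: in every cycle an untreated patient starts treatment
spontaneously with the annual visit rate of their condition (2.8% for MCI,
21.1% for AD). This applies in **both** arms — people the screening missed
remain eligible for routine care — so the no-screening pathway is a floor,
and setting participation to zero makes the two arms identical
cell-for-cell, a property the tests enforce.

## Screening cascade

A diseased participant is detected and treated with probability
`participation × scale sensitivity × diagnostic sensitivity × treatment
uptake` (defaults 0.80 × 0.81 × 0.90 × uptake); a cognitively normal
participant is falsely labelled positive with probability `participation ×
(1 − 0.805) × (1 − 0.90)`. Screening is applied at the start of a cycle,
before that cycle's transitions (the ordering is a model choice). Detected
untreated patients move into tunnel year 1; false positives move into a
one-year NORMAL tunnel during which they incur one treated year's
false-positive cost and then return to plain NORMAL (they keep NORMAL
transition behaviour during that year — the tunnel affects money, not
biology). Already-treated patients are not re-screened. The
earlier-treatment assumption behind screening (diagnosis roughly two years
before routine presentation) is realised implicitly: screened positives
start treatment at the screening cycle while unscreened patients wait for
visit-rate uptake; `lead_time_years` is carried as a reporting annotation
only. This is the principal structural judgement call in the model.

## Economics

Costs and utilities accrue on start-of-cycle occupancy for the full cycle
(no half-cycle correction; the discount rate, default 0, is configurable so
both choices can be explored). Annual state costs: MCI untreated 8.5,
MCI treated 8,469.9, mild/moderate/severe treated 12,137.4 / 12,810.9 /
22,529.4, any untreated AD stage 13,375.6 (the source prints a single
untreated-AD row), false-positive year 155.5 — all USD. Each screening
round costs a fixed 72,185.2 programme overhead, 8.2 per participant for
the scale, and 152.4 per person referred to the work-up; the referred mass
is `participation × (untreated diseased × scale sensitivity + normals ×
(1 − scale specificity))`, evaluated on the pre-screening distribution.
Because the programme overhead is a fixed per-round amount, per-capita cost
in the screening arm is not invariant to cohort size; state costs and QALYs
are exactly linear in occupancy.

Utilities are 1 for NORMAL (including the false-positive year) and 0 for
DEAD; disease-state utilities come from the configuration. ICERs are
flagged `dominant` / `dominated` / `undefined` when the ratio is not
interpretable; NMB = λ·ΔQALY − ΔCost with λ = 3 × 11,368.69 = 34,106.07
USD/QALY by default. NMB is reported both per capita over the horizon and
per capita-year, as the source is ambiguous between the two renderings.
Averted events are differences in cumulative incident counts (new deaths,
new entries into untreated severe AD), not end-of-horizon prevalence.

## Parameter uncertainty

Each parameter may carry a distribution: beta for probabilities and
utilities, gamma for costs, fitted by the method of moments to match the
mean exactly with `sd = (high − low)/3.92`, i.e. the (low, high) interval is
read as a normal-approximate 95% interval. Whether the published bounds are
95% CIs or min–max ranges is not stated in the sources; the 95% reading is
a documented convention. One published cost row (treated MCI: mean 8,469.9,
bounds 467.8–779.6) is internally inconsistent; it ships as printed with
provenance `printed-inconsistent`, and its gamma spec anchors the mean and
takes the spread from the bounds. The severe-AD comorbidity cost row is
treated the same way.

The one-way (tornado) analysis reruns both arms with each distributed
parameter at its interval ends, ranking by absolute NMB swing (the ICER's
sign flips make an ICER-based swing ill-defined; both outcomes are
reported). The probabilistic analysis redraws all distributed parameters
jointly and independently (no correlation structure is specified by the
sources) for a default 10,000 iterations, reruns both arms per draw, and
reports the CEAC — the NMB-positive fraction on a 0–4×GDP threshold grid
plus exactly 1× and 3× GDP — together with a second, distinct statistic:
the fraction of QALY-gaining draws lying below the 3×GDP ray on the
cost-effectiveness plane. One master seed spawns an independent child
stream per iteration, so any single iteration is reproducible in isolation
and seeded runs are bit-identical.

## Scenarios

`freq5`/`freq10` repeat the cascade every 5/10 years (re-screening targets
the whole surviving untreated population, not only the never-screened);
`lifetime_drug` removes the drug-effect cap; `start65`/`start70` shift the
cohort entry and screening start, rerunning the no-screening comparator at
the shifted age and switching to the published prevalence for those ages
(MCI 70–80: 18.46%; AD 65–69: 0.85%, 70–74: 2.08%); `comorbid` swaps in
comorbidity-adjusted treated-stage costs (15,076.1 / 18,615.4 / 28,829.5)
while leaving health outcomes untouched; `stop_at_severe` redirects every
flow into treated severe AD onto the untreated severe state, stopping both
the drug effect and treated-state costs on progression to severe disease.
Scenario runs deep-copy the base parameters and never mutate them.

## Synthetic parameters and the microsimulation oracle

The sources publish only part of the input vector; stage-transition
probabilities, disease utilities, excess mortalities, entry-age prevalence
and the post-screening treatment uptake live in an unpublished supplement.
The synthetic generator fills those gaps so every stage of the pipeline is
testable: printed values are fixed at their printed numbers, and gaps are
drawn from documented uniform priors respecting the clinical orderings
(utility decreases and excess mortality increases with severity; treatment
multiplies progression by 0.5–0.8 and MCI regression by 1.2–1.5; priors
keep every row's exits + death well below 1 so all draws are feasible).
`paper_anchored` aims at plausible magnitudes, `stress` at extreme but
feasible corners, `minimal` at a tiny round-number set for unit tests.
These priors exist for structural testability, not clinical estimation:
results computed on synthetic sets exercise the machinery and its
invariants, and qualitative orderings (e.g. averted events increase with
screening frequency), but their absolute values do not estimate the
published ones, which depend on the unpublished inputs.

The microsimulation oracle replays the identical transition rows and
cascade person by person with categorical draws and aggregates to a trace.
It is the binding validator of the cohort engine: occupancy must agree
within a 4-binomial-SE band in every cell (for near-empty cells the band's
sides are floored at the exact binomial quantile carrying the same tail
mass, since the normal approximation is too sharp below expected counts of
a few persons).

## Problem sizes and numerical choices

The test suite runs cohorts of 1,000–50,000 and oracle comparisons at
2,000–4,000 individuals across 20 synthetic sets; the conservation and
consistency sweep covers 1,000 random sets at cohort 10,000; the
acceptance script uses the full 100,000 cohort for the deterministic runs
and 10,000 PSA iterations at cohort 20,000 (per-capita outcomes are
scale-free in the cohort size apart from the fixed programme overhead).
Mass conservation is checked to 1e-6 persons absolute, row sums and
screening redistribution to 1e-9, and matrix-product oracle agreement to
1e-8. Ties and degenerate inputs: a zero QALY increment yields an
`undefined` ICER with NMB still reported; a disabled policy yields an
empty screening schedule; `drug_effect_years = 1` gives a single tunnel
year that is already at the cap (a programme whose drug never modifies
transitions but still incurs treated costs).

## Known limitations

- Values standing in for the unpublished supplement are synthetic; absolute
  economic outputs on synthetic sets are not estimates of the published
  results.
- No half-cycle correction; costs and QALYs use start-of-cycle occupancy.
- False positives retain NORMAL transition behaviour during their treated
  year; whether they should face modified risks is unspecified in the
  sources.
- Parameters are drawn independently in the PSA; no correlation structure.
- The false-positive year charges the dedicated false-positive cost and the
  diagnostic work-up is charged to everyone referred to step 2; whether the
  sources intended both charges is an interpretation, documented here.
- No semi-Markov machinery, individual covariates, regional heterogeneity,
  or budget-impact analysis.
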