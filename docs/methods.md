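# Methods

`nbscea` implements a decision-analytic evaluation of adding SMA and SCID to
a newborn bloodspot screening panel: Markov cohort models nested in a
two-strategy decision tree, with probabilistic and one-way sensitivity
analyses and a staggered-cohort budget-impact calculation. This note records
the model, its conventions, the numerical choices, and what the synthetic
fixture does and does not represent.

## Model structure

A `DecisionTree` holds strategies (screen vs don't screen), each splitting a
birth cohort over chance branches. Branch probabilities are disease
incidences times detection splits; a `model: null` branch carries the
unaffected newborns. Affected branches enter time-homogeneous Markov cohort
models: 11 severity-ordered motor-milestone states for SMA on 6-month
cycles, 6 states (pre-symptomatic, transplant recovery, immune
reconstitution, active infection, chronic complications, death) for SCID on
3-month cycles. Constant transition probabilities over the whole horizon are
a deliberate modelling assumption — treatment effects observed over short
trials are extrapolated unchanged — and the schema has no representation for
time-varying matrices.

**Disease-attributable accrual.** Unaffected newborns accrue no cost, QALYs
or life-years; strategy expectations are therefore per-newborn
*disease-attributable* outcomes (magnitudes like 0.001 QALY per newborn
screened), which is the convention under which rare-disease screening
results are usually tabulated. Comparisons are unaffected by this choice:
the unaffected branch is identical across strategies and cancels from every
increment.

## Accrual and discounting conventions

* **Beginning-of-cycle accrual, no half-cycle correction by default.** State
  membership at each cycle start earns that cycle's annual utility and cost
  scaled by the cycle length; the final boundary row accrues nothing. An
  optional half-cycle-correction flag (average of adjacent boundary
  occupancies, discounted at mid-cycle) exists but is off for all shipped
  results.
* **Exact fractional-year discounting.** `(1+r)^(-t)` with real-valued `t`,
  so a 6-month cycle at 3% p.a. discounts by `1.03^-0.5`. This is the least
  surprising convention when 6- and 3-month cycles coexist in one tree.
* **Utilities and costs are specified per year** and scaled by cycle length
  internally, keeping SMA and SCID configurations comparable despite
  different cycle lengths.
* **One-off event costs** (gene therapy at entry, HSCT at transplant time)
  attach to event times in years and are charged to the non-death occupancy
  at the latest cycle boundary not after the event time, discounted at the
  exact event time. The cohort engine treats them as expectations; the
  microsimulation oracle charges them per surviving individual.
* **Calendar-year aggregation** for budget profiles buckets undiscounted
  cycle costs by `floor(cycle start time)`, one-off events by
  `floor(event time)` — matching "Year 1 … Year 5" budget columns.

## Incremental analysis

Pairwise against a named comparator (no efficiency frontier — the evaluation
this package follows reports pairwise ICERs only). Quadrant classification:
cheaper-and-more-effective is *dominant*, costlier-and-less-effective is
*dominated*, otherwise ICER = Δcost/Δeffect. Zero effect with nonzero cost
classifies by cost sign; all-zero increments report a ratio of 0. Scaling to
a cohort is linear in costs and effects and leaves ICERs and labels
unchanged. ICERs are displayed to whole dollars; internal deltas keep full
precision.

## Probabilistic sensitivity analysis

Parameter uncertainty uses the standard health-technology-assessment
families: beta for probabilities and utilities, gamma for costs (lognormal
and uniform also available), parameterized by method of moments from (mean,
SE). Where no standard error is known the default is SE = 20% of the mean —
a package convention, flagged here and in the sampler docstring, not an
empirical estimate. Sampled transition probabilities must target
off-diagonal cells; the diagonal is recomputed as the remainder and draws
with negative remainders are rejected and resampled (counted on the result).
Branch probabilities may be sampled directly; the unaffected residual branch
absorbs the complement. The ICER confidence interval orders iterations by
net monetary benefit at the reporting threshold, because raw ratios are not
monotone across cost-effect quadrants; an interval endpoint lying in the
win-win quadrant prints as "dominant" rather than as a negative ratio, and
the favourable endpoint is reported first. Percentile CIs need at least 40
iterations.

## One-way sensitivity analysis

Each parameter is pinned at a low/high bound (default ±20% of base, clipped
to natural supports: utilities to [−1, 1], probabilities to [0, 1]) with all
else at base case; evaluations run on copies so the base tree provably
survives (its config hash is unchanged). The default tornado output is NMB
at USD 35,000/QALY, which is defined in every quadrant; ICER mode is
available but reports NaN at a bound whose result is dominant/dominated.
Ties in swing order lexicographically by parameter name, for deterministic
output. The published gene-therapy price scenario (USD 2.1M instead of
1.54M) is expressible as a single `one_way` call on the gene-therapy
one-off-cost path, or by editing that value in a spec file; no dedicated
scenario op exists.

## Budget impact

All currency is integer cents. Single-cohort tables hold per-component
undiscounted yearly costs; staggered programme totals assume one new birth
cohort per year, making programme year *y* the cumulative sum of the cohort
vector; the grand total is computed both as Σ cumulative sums and as
Σ (n−k+1)·v[k] and asserted equal to the cent. Grand totals always derive
from yearly totals, never from summing independently rounded component
totals: a published table's component cells carry rounding residue, and
bit-exact reproduction demands one canonical summation order.

The packaged per-100,000 tables transcribe the published future-NBS and
current-NBS panels exactly. Two cells of the source table are internally
inconsistent at the ±1-dollar level (the future panel's year-2 column sums
to 666,228 from components but prints 666,227 in every total row, traceable
to the "Late SCID" year-2 cell; the current panel's "Clinical SCID" total is
similarly 1 below its year sum), and the future panel's printed year-1 total
cell is corrupted in the source. The loader therefore carries the *printed
total row* as the canonical yearly vector — recomputing the corrupted
year-1 cell from components, which the staggered table independently
confirms — tolerates printed-vs-recomputed differences up to $1 as
transcription rounding, and refuses anything larger. Under that convention
every consistent published cell reproduces exactly; the published
programme-level grand total (80,048,061) is itself 2 dollars off any
internally consistent recomputation (80,048,059), and the recomputed value
is the one this package reports.

Budget vectors can also come from the decision tree itself
(`budget_table_from_strategy`, using the engine's undiscounted yearly cost
profiles). The published per-year decay profiles cannot be recovered from
the printed panels alone, so model-driven mode is validated only for
internal consistency, not against the published rows.

## The synthetic fixture

The clinical parameters behind the published evaluation (transition
probabilities, state utilities, state costs) were never published. The
`paperlike_fixture` therefore carries the *structural* constants — 11/6
states, 0.5/0.25-year cycles, 3% discounting, 5- and 60-year horizons, SMA
incidence 1/11,000, SCID incidence 1/65,000 (midpoint of the published
1/50,000–1/100,000 range), screened-vs-clinical splits 8.5:0.6 (SMA) and
2:0.01 (SCID) per 100,000 with 20% of current-practice SCID found early via
family history, gene therapy USD 1.54M as a one-off at entry, screening USD
558,371 per 100,000 — around invented but clinically plausible matrices and
utilities (gene-therapy recipients mostly reach and hold walking milestones;
late-treated patients enter symptomatic states, progress faster and pay
recurring nusinersen costs; early-HSCT infants reconstitute with high
survival, late-HSCT infants face infected time and higher mortality).

One knob is calibrated: the clinical-SMA therapy-cost multiplier is bisected
so the 60-year per-newborn incremental cost lands on the published −86 USD
anchor (the multiplier settles near 0.72, i.e., effective recurring therapy
spend of about USD 180k/year). Everything else is fixed. Consequently the
fixture reproduces the published *sign structure and orders of magnitude* —
60-year dominance with a ~0.0016 QALY and ~0.0014 LY gain per newborn
(published: 0.00095 and 0.00137), a positive 5-year incremental cost of
~43 USD (published: 45.61) — but **not** the published point estimates, and
no test or reported number pretends otherwise. The fixture's PSA puts
~99–100% of iterations below USD 35,000/QALY at 60 years (published: 97%);
that figure depends entirely on distribution choices and is a qualitative
benchmark only. The two-strategy tree also collapses the four-way SMA
treatment menu of the source evaluation to the pair actually compared
(screen + gene therapy vs no-screen + late nusinersen); the schema itself
is general enough to express the full menu.

What passing fixture tests shows: the machinery (engine, tree expectation,
dominance logic, PSA, calibration) behaves correctly on a model with the
right structure and realistic magnitudes. What it does not show: anything
about the true clinical parameters of SMA or SCID, or the exact published
per-newborn values.

## Numerical choices and degenerate inputs

* Row sums, initial distributions and branch probabilities validate to
  1e−9; absorbing states must be identity rows; death states must be
  absorbing with zero utility and cost.
* Horizons must be integer multiples of every member model's cycle length
  (checked to 1e−9); mismatches are rejected at load and at run time.
* Bisection calibration needs a sign change over its bracket, runs at most
  100 iterations, stops on output tolerance or on bracket collapse
  (relative width 1e−13), and reports the achieved value either way.
* The spec schema rejects unknown keys outright — silent typos in
  probability names are the dominant configuration failure mode.
* The schema accepts single-strategy trees (useful for running one arm);
  incremental analysis naturally requires two.
* Problem sizes used in shipped analyses: 1000 PSA iterations (matching the
  published analysis), 100,000 microsimulation paths for the engine
  cross-check, 60-year horizons (120 SMA cycles, 240 SCID cycles).

## Known limitations

Cohort expectations only (no individual-level heterogeneity beyond the
testing oracle); no time-varying transitions or tunnel states; no
correlated parameter sampling; no value-of-information analysis; no
efficiency frontier over more than two strategies; single-currency nominal
accounting (a display-only conversion scalar in the CLI); societal costs
(informal care, productivity) out of scope.
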