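# Methods

## The model

`amdcea` implements a patient-level Markov state-transition model of
ranibizumab treatment for neovascular age-related macular degeneration
(nAMD) in the better-seeing eye. Health states are five visual-acuity
bands — 6/6 to >6/12, 6/12 to 6/24, 6/24 to 6/60, 6/60 to 3/60, <3/60 —
plus absorbing death, reachable from every band. Time runs as one
3-month loading cycle followed by monthly cycles to the horizon
(24 months by default). Costs and benefits are not discounted at any
horizon, reflecting the short time frame the analysis was designed for.

Two strategies are compared for patients presenting with good vision
(better than 6/12):

* **immediate**: start in the best band, receive three loading
  injections over the loading cycle, then pro-re-nata (PRN) injections
  with monthly transitions by the on-treatment matrix;
* **delayed** (usual care): remain untreated in the best band until
  vision drops below 6/12 — the drop time is drawn from a survival
  model — then re-enter in a worse band drawn from the observed
  distribution of bands at treatment start, and follow loading + PRN
  for the remainder of the horizon.

Background mortality is layered on every cycle from a gender-specific
annual life table converted to per-cycle probabilities,
`1 − (1 − q_annual)^(months/12)`.

QALYs accrue as `utility(state at cycle start) × cycle_length / 12`.
Costs accrue per event: every injection costs drug + assessment
(£742.17 + £255.00), every non-injection monthly visit costs monitoring
(£60.00), and untreated delayed-arm months cost nothing. All costs are
GBP at 2012 prices.

## Conventions fixed where the published description is silent

Several mechanical details are unstated in the source material; the
package fixes one convention each, documents it, and covers it with
conservation and oracle tests:

* **Mortality before transition, deaths accrue nothing.** The death
  check happens at cycle start; a patient who dies accrues no utility or
  cost in that cycle. No half-cycle correction is applied.
* **Loading from worse bands.** The published loading-cycle row exists
  only from the best band. Delayed-arm patients re-entering in bands
  2–5 transition by the monthly matrix composed three times (`M³`) over
  a single 3-month cycle, the only self-consistent use of the published
  data. A loading cycle that would overrun the horizon is truncated,
  with injections pro-rated.
* **Draw order.** Per cycle the random draws are: drop (delayed,
  untreated phase only), death, injection, VA transition. Together with
  per-patient substreams derived from `(seed, patient_index)`, this
  gives common random numbers across arms and scenarios: a cost-only
  scenario reproduces base-case trajectories exactly.
* **Row renormalisation.** Printed transition rows carry rounding error
  (sums 0.9999–1.0001) and are rescaled proportionally at load; rows
  already summing to 1 within 1e-12 are left bit-exact.

## Parameters

| parameter | default | units | provenance |
|---|---|---|---|
| loading / monthly transition matrices | printed values, renormalised | prob./cycle | treated-eye visit records |
| state utilities | 0.89, 0.81, 0.57, 0.52, 0.40 (SD 0.16, 0.20, 0.17, 0.24, 0.12) | – | time trade-off elicitation in AMD patients |
| re-entry distribution | 0, .434484, .389154, .145647, .030750 | – | bands at treatment start |
| drug / assessment / monitoring | 742.17 / 255.00 / 60.00 | GBP | 2012 NHS unit costs |
| PRN injection rate | 0.24 | injections/month | calibrated (below) |
| delay to drop below 6/12 | exponential, median 6 | months | stand-in (below) |
| demographics | male 36.6%; age ~ TN(78.8, 7.4²) male, TN(80.1, 7.4²) female, truncated 55–103/108 | years | cohort summary; SD from IQR/1.349 |
| mortality | q(age) pivots, log-linear interp. | prob./year | approximates ONS National Life Tables, England & Wales 2009–2011 |
| Dirichlet `effective_n` | 100 | pseudo-counts/row | configuration (below) |
| cost SD | 10% of mean | – | standard practice for unreported SDs |

Three inputs are not published and are therefore explicit, documented
choices rather than estimates:

* **PRN injection rate (0.24/month).** Chosen so the 2-year
  immediate-arm expected cost reproduces the reported £8469.79 under the
  published unit costs — the only quantitative anchor available. Under
  this rate and the default delay, the immediate arm gives roughly two
  more injections than the delayed arm over two years, somewhat more
  than the reported differential of about one; both cannot be matched
  simultaneously with the published unit costs.
* **Delay survival curve (exponential, median 6 months).** The source
  curve was estimated from fellow-eye imaging data and never printed. A
  one-parameter memoryless stand-in keeps the mechanism while making
  the assumption visible and configurable.
* **Background mortality.** No source is named; the embedded table
  approximates the ONS national life tables contemporaneous with the
  cost year. Two-year results are insensitive to plausible table
  choices; five-year results less so (mortality compounds).

## Probabilistic sensitivity analysis

Utilities are drawn from beta distributions moment-matched to the
published mean/SD (`ν = m(1−m)/s² − 1`, `α = mν`, `β = (1−m)ν`); unit
costs from gamma distributions (`shape = m²/s²`, `scale = s²/m`) with
SD = 10% of the mean; transition rows from Dirichlet distributions with
pseudo-counts `row × effective_n`. The transition counts behind the
published matrices were not printed, so the Dirichlet spread is not
identifiable; `effective_n` (default 100 per row) makes that choice
explicit. Structural zeros are floored at 1e-6 pseudo-counts to keep the
distribution proper. The re-entry distribution is held fixed across
draws. Parameters are sampled independently; parameter streams are
separate from patient streams, so a degenerate PSA (all spreads zero)
reproduces the deterministic base case exactly. By default one patient
path is simulated per parameter draw, the most literal reading of a
"10,000 Monte Carlo simulations" design that conflates patient- and
parameter-level sampling; a nested `n_outer × n_inner` design is a
keyword away. The central ICER is reported as the ratio of mean
increments (mean ΔC / mean ΔE) over draws; the mean of per-draw ratios
is unstable and not offered.

## The deterministic oracle

`cohort_expectation` computes arm means exactly by propagating the
state-occupancy vector through the identical cycle structure, applying
per-cycle survival factors, mixing over the geometric drop-month
distribution (delayed arm), and integrating the truncated-normal age
distributions on a 0.25-year grid. Conservation (occupancy + cumulative
death = 1 every cycle) holds to machine precision, and the Monte Carlo
engine must agree with the oracle within 3 standard errors in both arms
— the main guard against bias bugs in either implementation.

## Synthetic visit records and estimator validation

`synthetic_emr` generates long-format visit tables (patient, eye role,
month, VA band, optional ETDRS letters, injection flag) with the
structure the estimators assume: treated-eye states Markov with a known
matrix, post-loading injections Bernoulli, fellow-eye time to first
visit below 6/12 following a configured distribution (discretised to a
monthly hazard). After the drop, fellow eyes evolve by a natural-history
matrix; its default is a documented transform of the treated matrix
(worsening probabilities doubled, improvements halved) expressing that
untreated eyes deteriorate faster. Because the fellow eye is held in the
best band until the sampled drop, the natural-history first row is
identified only through the survival curve — recovery tests therefore
target the treated matrix, the Kaplan–Meier median and the injection
rate. ETDRS letters are uniform within band cut points (70/55/35/20)
and exercised only in tests; the model operates on bands.

The generator emulates none of the messiness of real records — no
missing visits, no irregular spacing, no two-stop-service baseline
quirks, no bilateral treatment, no between-centre variation. Passing
recovery tests therefore show the estimators are correct for the
assumed structure, not that the structure captures real clinics.

Transition estimation counts transitions over consecutive visit pairs
at the requested spacing and row-normalises; rows with no observations
fall back to the identity row with a warning. The time-to-threshold
estimator is the Kaplan–Meier product-limit fit (via `lifelines`),
cross-checked in tests against a brute-force product over event times.

## Problem sizes

Arm-level results and the acceptance script use 10,000 simulated
patients (Monte Carlo SE ≈ 0.004 QALYs at 2 years); oracle-agreement
tests use 3,000 patients × 5 seeds per arm; recovery studies use 20
cohorts of 5,000 patients; distribution checks use 10⁵ Dirichlet draws
per row. These sizes put sampling error well inside the tolerances
being tested while keeping the full suite in the low minutes.

## Known limitations

* The delayed arm's absolute results are **not** reproducible from
  published inputs: with the published monthly matrix governing
  post-entry recovery and any drop-time distribution, the delayed arm
  cannot fall to the reported 1.35 QALYs (it floors near 1.50). The
  published gap likely encodes features of the unpublished fellow-eye
  curve and post-entry dynamics. Consequently the incremental results
  and ICER printed by this package differ from the published ones;
  immediate-arm absolutes, which rest entirely on printed inputs, are
  the quantities checked against the source.
* One eye per patient; bilateral treatment (16% of the source cohort)
  is out of scope.
* No treatment discontinuation other than death; PRN intensity is
  constant over time and states.
* Mortality does not depend on visual acuity.
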