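# Methods

## Model

The simulator treats a pricing decision system as a deterministic
stock-and-flow model. A model is a roster of named variables:

* **constants** — exogenous dimensionless scores, fixed over the run;
* **auxiliaries** — linear expressions: sums of `coefficient × (literal |
  reference | DELAY1 reference)` terms;
* **stocks** — accumulations `S(t+dt) = S(t) + dt·F(t)` of a named inflow.

`DELAY1(x, T)` is the first-order (exponential) information delay with time
constant `T` years: its output `y` follows `y' = (x − y)/T`, discretized as
`y ← y + (dt/T)(x − y)`. It models scoring criteria that respond to a
certification only after a lag — e.g. a SAKIGAKE designation takes years to
shift a company's rare-disease, small-market and pediatric portfolios.

Integration is explicit forward Euler with a fixed step `dt` (default 1
year over a 50-year horizon). Each step evaluates the auxiliaries in
dependency order from the current delay outputs and stock values, then
relaxes every delay state toward its just-evaluated input, then advances the
stocks with the inflow evaluated at the start of the step; the values
recorded at `t_start` are the initial states before any step. Plain
(undelayed) references among auxiliaries must be acyclic — feedback loops
must pass through a delay or a stock, which carry state between steps — and
evaluation-order ties are broken by declaration order, so runs are
bit-reproducible.

Because all expressions are linear with non-negative coefficients, two exact
properties anchor the test suite:

* **Steady state in closed form.** With constant inputs every delay output
  converges to its input, so replacing each delayed reference by a plain
  reference and solving the (acyclic) algebra once yields the t→∞ value of
  every auxiliary (`asymptotic_values`). Stocks are excluded — they grow
  without bound for any non-zero flow.
* **Superposition.** Scaling all exogenous inputs (constant values, literal
  terms, stock initials, explicit delay initial values) by λ scales every
  trajectory by λ (`scale_model`).

## The Japan pricing model

The bundled model encodes Japan's NHI premium scoring for innovative drugs:
51 variables — 17 constants, 33 auxiliaries, one stock. Each scoring item
(e.g. *evidence from RCT* = 2, *new mechanism* = 2) is a named score
constant read by a pass-through auxiliary row; the three special-designation
rows (rare disease drug, small market size, children's drug) share one base
constant (5) and each add a 5-year delay of the SAKIGAKE premium; the
*validity better than comparator* row adds a 0.5-year delay of the efficacy-
improvement score. Four issue-level auxiliaries aggregate into the value
premium; the five premium subsystems combine into the pricing-decision flow
with weights (1.8, 1.15, 1.05, 1.125, 1.15); a single stock (*new drug
pricing decision evaluation*, initial 0) accumulates the flow. All scores
are dimensionless; time is in years.

Deriving the anchors used by the tests by hand: the value premium sums its
four issues to 30; the SAKIGAKE premium sums its four ×2 criteria to 8; each
special-designation premium settles at 5 + 8 = 13; the flow asymptote is
1.8·30 + 1.15·13 + 1.05·13 + 1.125·13 + 1.15·8 = 106.425, giving a 50-year
equilibrium-initialized stock of 5321.25.

The model ships both as a programmatic builder (`build_japan_model`) and as
a versioned JSON file (`sdpricing/data/japan_model.json`); a test asserts
they are identical.

## Delay initialization

The delay starting state is a genuine modelling choice, and it shapes the
first decade of every run. Three per-delay policies exist — `zero` (the
delayed effect has not begun), `equilibrium` (the system starts settled:
output = the input's closed-form asymptote, self-consistent when delays
chain), `explicit` (a given value) — plus the default `auto`, which resolves
at simulation time to `zero` when `delay_time ≥ dt` and to `equilibrium`
otherwise. The rationale for the dt-dependent branch: a zero-started delay
with `T < dt` has Euler amplification `|1 − dt/T| ≥ 1` and would oscillate
rather than converge, so a delay finer than the step is treated as already
settled. Under the defaults (dt = 1) the 5-year SAKIGAKE delays start at
zero — producing the characteristic transient in which the pediatric premium
starts at 5, below the SAKIGAKE premium's 8, and overtakes it in year 3 —
while the 0.5-year efficacy delay starts in equilibrium. `simulate(...,
delay_init="zero"|"equilibrium")` overrides every delay at once; the CLI
exposes this as `--init-policy`.

## Experiments

**Baseline** (`run_baseline`): the 50-year default run. The flow rises
monotonically to its asymptote (within 5% by year 8, within 0.1% by year
50), so the stock is convex-to-linear.

**Stability test** (`stability_test`): the model is re-run with the Euler
step successively halved (1, 0.5, 0.125 years by default) and the stock
compared at the save points of the coarsest grid, which all runs share; the
coarsest run is the reference. For a constant flow Euler integrates the
stock exactly, so equilibrium-initialized runs agree to the last bit (see
numerical notes); under the default initialization the runs differ only
through the transient, whose time integral is step-independent (for a
zero-started delay the accumulated deficit `Σ (I − y_n)·dt` equals `I·T`
for any `dt < 2T`), leaving a relative deviation at t = 50 of about 0.03%.

**One-at-a-time sensitivity** (`oat_sensitivity`): each listed parameter is
multiplied by a scale (default 1.8, read as a +80% adjustment; the knob also
accepts downward scales), delay states are re-initialized under the
perturbed values, and the model is re-simulated from the start; the
unperturbed baseline is appended for reference. The impact metric is the
offset of the asymptotic flow versus baseline — equivalently the late-
horizon stock slope — with the final stock reported alongside.
`rank_parameters` orders parameters by that delta, descending, exact ties
alphabetical.

A perturbation target may be either a constant (its value is scaled,
affecting every row that reads it) or an auxiliary row (only that row's
exogenous part — its literals and its coefficients on constants — is
scaled). The second form is what makes the three special-designation rows
individually perturbable even though they share one base constant; for the
sixteen pass-through rows both forms coincide.

**Analytic gain** (`analytic_gain`): the derivative of the asymptotic flow
with respect to a unit additive increment at the target, computed by
differencing the closed-form steady state — exact for this linear model and
fully independent of the simulation path. Simulated impacts must equal
`gain × (scale − 1) × base value`; the tests enforce this to 1e-6 at
t = 100 (twenty times the longest delay). Representative gains: NHS
accreditation 7.2 per unit (it enters all four value issues, weighted 1.8);
new mechanism 8.075 (two value paths plus the SAKIGAKE route); japan
premiere and major disease exactly 4.475 each (1.15 directly plus 3.325
through the three delayed special-designation rows) — an exact tie, reported
as such.

## Numerical choices

* Stocks accumulate with Neumaier-compensated summation. This removes the
  step-count-dependent rounding drift of naive accumulation, so runs whose
  flow is constant agree exactly across step sizes (plain summation leaves
  ~1e-11 discrepancies over 400 steps) and the 50-year equilibrium stock
  matches the closed form to ~1e-12.
* Any NaN/∞ intermediate aborts the run with the variable name and time.
* Model JSON is written with sorted keys and shortest-round-trip float
  formatting; trajectory CSV is time-major in declaration order with `repr`
  floats — both byte-identical across re-runs.
* The save grid records every `save_every`-th step and always includes both
  endpoints; requesting an off-grid time raises rather than interpolating.
* `SimConfig` requires the horizon to be an integer number of steps (to
  1e-9 relative), so there is never a partial final step.

## Synthetic fixtures

`generate_fixture_model(seed, ...)` builds random valid linear models for
property tests: scores in [0, 10], plain references restricted to earlier-
declared variables (guaranteeing acyclic algebra and a well-defined steady
state), delay times in [dt, 10·dt], one stock fed by a random auxiliary.
These fixtures exercise the kernel's contracts (round-trip serialization,
superposition, equilibrium stationarity) but are not calibrated to any real
pricing system: passing them demonstrates the simulator's correctness, not
the realism of any particular score assignment.

## Limitations

* Expressions are linear; there are no lookup tables, no saturation, and no
  score interactions beyond additive propagation. Real premium rules cap
  percentages and involve judgement that a linear score sum cannot express.
* Only the first-order delay and the stock integrator are provided — no
  higher-order delays or smoothing functions.
* Premium scores are dimensionless points; the package deliberately does not
  convert them into yen or percentage price mark-ups, and post-launch price
  revisions (market expansion re-pricing, generic entry) are out of scope.
* One-at-a-time perturbation ignores parameter interactions by design; for
  this linear model effects are exactly additive, so variance-based indices
  would add nothing, but the harness would not detect interactions in a
  nonlinear extension.
* Perturbations act from the start of the run with delays re-initialized;
  a step change at a later policy date is not implemented.
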