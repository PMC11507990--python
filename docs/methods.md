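# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `orsched`.

## Problem and assumptions

One surgical specialty plans one week (horizon D = 7 days) at a time under a
block-scheduling policy: a fixed set of OR blocks, each with capacity γ_j
minutes (360 by default, a 6-hour session) on a known day d_j.  The waiting
list is longer than one week of capacity, so the decision is *which* patients
to schedule and *where*, not how to sequence them intra-block (sequencing
enters only through the LPT evaluation rule, below).  New arrivals, surgeon
and bed constraints, no-shows and emergencies are out of scope; canceled
patients are not rescheduled within the simulation.

All durations and capacities are in minutes; waiting times and the horizon in
days.  Days waited until block j, d_j, is stored per block; the generator
assigns blocks to consecutive days starting at day 1.

## Objective and penalty arithmetic

Each urgency class has a maximum waiting time l and urgency coefficient
u = l_max / l (least urgent class: u = 1).  A scheduled patient contributes
`p_ij = [d_j + (w_i + d_j − l_i)⁺] · u_i`: only in-horizon days are charged
(w_i is sunk), plus tardiness at surgery, all at rate u.  An unscheduled
patient contributes `q_i = [(w_i + D + 1) + (w_i + D + 1 − l_i)⁺] · u_i`, a
lower bound on their eventual cost since day D+1 is the earliest they could
still be operated.  Because d_j ≤ D < D + 1, `q_i > p_ij` always: scheduling
a patient never costs more than deferring them, so free capacity is never
wasted at the optimum.

A patient is *tardy* when waiting strictly exceeds l (at w = l the positive
part is zero, so the boundary patient is not yet tardy).  Metrics use
w + d for operated and w + D + 1 for still-waiting patients; NAWD values are
these waiting times times u.  Class-level tardiness averages are over tardy
patients only; overall table rows are count-weighted means of class rows
(tardy-count-weighted for tardiness), and cells with an empty denominator are
reported absent and rendered `-`.

## Robust counterpart

Surgery durations are uncertain.  The robust capacity constraint protects
each block against any subset of at most Γ of its patients requiring their
maximum duration t̄ + t̂ (t̂ = α·σ) while the rest take the mean.  The inner
maximization has the closed form "mean load + sum of the min(Γ, n) largest
t̂", which the package uses for post-solve audits
(`robust_worst_case_load`, `verify_robust_feasibility`); inside the MILP it
is linearized exactly by LP duality with per-block ζ_j and per-pair π_ij
(`duality_gap_check` verifies strong duality of this inner problem
numerically).  One global integer Γ applies to every block.  Γ = 0 or α = 0
reproduces the deterministic model exactly.  Γ is capped in effect at the
number of patients a block can hold: beyond that every scheduled patient is
already at their maximum, which is the saturation budget Γ̄ that
`detect_saturation` extracts from a sweep.

## Solver

Both MILPs are solved with HiGHS through `scipy.optimize.milp` (sparse
constraint matrices; binaries x, continuous ζ, π).  Defaults mirror common
practice for this problem class: 7200 s time limit and 10⁻³ acceptable
relative gap.  Objective coefficients are `p_ij − q_i` plus the constant
Σq_i, so the model stays feasible for any capacity (worst case: everyone
unscheduled).  Reported objectives are recomputed independently from the
penalty formulas (1e-6 relative tolerance, enforced), and robust schedules
are re-audited against the closed-form worst case; a violation raises rather
than returning a silently wrong result.  Multiple optima are accepted —
comparisons should use objectives and aggregate metrics, not patient
identities.  `max_operated_bound` solves the penalty-free unit-objective
variant to bound how many patients could possibly be operated.

## Scenario simulation

Realized durations are lognormal, moment-matched on the natural scale:
s² = ln(1 + σ²/t̄²), μ = ln t̄ − s²/2, so the raw draw r has mean t̄ and SD σ.
This parameterization is stated explicitly because the log-scale alternative
(μ, s set to the mean/SD of log-durations) gives different results.  Draws
are truncated from below: realized = max(r, t̄ − σ, 30) minutes; σ = 0
degenerates to r = t̄ exactly.

Schedules are evaluated with the LPT rule: within each block, cases run in
decreasing order of *mean* duration (ties broken by patient id for
determinism).  Before each case, if the residual time is strictly positive
the patient is operated — their realized time may overrun, recorded as
overtime — otherwise that patient and all remaining ones are canceled, so
the canceled set is always a suffix of the LPT order.  Utilization is
min(used, γ)/γ, capped at 1; the uncapped variant is recoverable from the
recorded used minutes and overtime, since whether published utilization rates
were capped or simply never exceeded 100% is ambiguous.

Scenario k uses seed base_seed + k (one independent stream per scenario), so
evaluating different schedules at the same base seed applies common random
numbers, sharpening cross-(Γ, α) comparisons; the sweep driver relies on
this.  Aggregates report means and standard errors over 100 scenarios by
default.

## Synthetic instances

Real waiting lists are typically published only as per-class aggregates
(count, tardy count, mean waited days).  The generator reproduces exactly
that structure: per class, non-tardy waits are drawn uniformly on [0, l] and
tardy waits uniformly above l, then adjusted by bounded integer shifts until
the class total equals round(count × target mean) — tardy counts match
exactly, class means up to rounding of the total.  Any distribution matching
the aggregates would be admissible; uniform pieces were chosen for
transparency.  Infeasible targets (e.g., a tardy count whose floor already
exceeds the target total) raise an explicit error.

The bundled profiles are a 20-patient list with two blocks and a 40-patient
list with three blocks (counts, tardy counts and mean waits per class as in
the reference tables shipped in `fixtures/`), plus scaled 80/120/140-patient
profiles with 3 or 5 blocks for scalability experiments.  Because the
original per-patient waits and the eight published surgery-time sets are not
available, the generator ships eight synthetic case mixes instead: four
surgery types (base means 50/80/120/180 min at frequencies .30/.35/.25/.10),
scaled by a factor rising from 0.75 to 1.25 across sets while the coefficient
of variation rises from 0.1 to 0.6.  This spans light-load/low-variance to
heavy-load/high-variance regimes and yields 7–12 operable patients per
20-patient instance, in the realistic range for two 6-hour blocks.

What passing tests on these instances shows — and does not.  The suite
verifies the *mechanisms*: exact optimality against brute force on small
instances, the collapse/monotonicity/saturation structure in (Γ, α), and the
qualitative robustness trade-off (cancellations fall, utilization falls, as
the budget grows; at α = 2 cancellations vanish from Γ = 2 on for some case
mixes).  Absolute values of utilization, cancellations or NAWD increases
depend on the case mix and waiting-list composition and should not be read
as predictions for any real department.

## Test and experiment scales

Oracle-equivalence runs use 200 random instances of 4–8 patients and 2
blocks with Γ ≤ 3 (exhaustive enumeration is exact there); monotonicity and
saturation are checked on three 20-patient instances over Γ = 0..5 and
α ∈ {0.5, 1, 2}; scenario-behavior checks run the full eight-instance
20-patient suite at Γ = 0..4, α ∈ {0.5, 1, 2}, 100 scenarios per cell with
common random numbers.  These sizes keep the default test run to a few
minutes while preserving every qualitative claim; the sweep driver itself
accepts arbitrary grids and the large-instance profiles for bigger studies.

## Known limitations

* Single specialty, independent blocks; no overtime variables in the
  optimization (overtime appears only as a simulation statistic).
* The still-waiting penalty is a lower bound, not an unbiased forecast, so
  NAWD of still-waiting patients underestimates their eventual realized cost.
* Saturation detection trusts the solver gap; with a loose gap a
  not-yet-saturated sequence can be declared constant.
* Fractional Γ (partial protection of one extra patient) is not implemented;
  the budget is integer per block.
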