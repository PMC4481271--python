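# Methods

## The model

PSA (prostate-specific antigen, ng/mL) is modeled as the sum of three cancer
cell burdens, each expressed in PSA-equivalent units: androgen-dependent
cells `x1`, reversibly castration-resistant cells `x2` (epigenetic
adaptation, can revert when androgen returns) and irreversibly
castration-resistant cells `x3` (genetic change, never reverts).  Dynamics
are linear daily maps that switch with the treatment flag `m`:

on-treatment (m = 1):

    x1' = d11¹ x1
    x2' = d21¹ x1 + d22¹ x2
    x3' = d31¹ x1 + d32¹ x2 + d33¹ x3

off-treatment (m = 0):

    x1' = d11⁰ x1 + d12⁰ x2
    x2' = d22⁰ x2
    x3' = d33⁰ x3

One step is Δt = 1 day; the discrete coefficients stand in for an underlying
continuous-time rate matrix via d = 1 + wΔt on the diagonal and d = wΔt off
it, and the daily maps themselves are what gets fitted — the continuous
system is never integrated separately.  A patient is the combined parameter
vector `p` of length 13: the initial state (x1(0), x2(0), x3(0)) followed by
the ten coefficients in the fixed order d11¹, d21¹, d22¹, d31¹, d32¹, d33¹,
d11⁰, d12⁰, d22⁰, d33⁰ (the order used by the fitted-parameter file format).

## Constraints and penalty

Biological feasibility is enforced through 38 inequality terms: all
coefficients and initial conditions non-negative; every diagonal coefficient
in [0.8, 1.2] (at most ±20% change of a pool per day); each conversion flux
(d21¹, d31¹, d32¹, d12⁰) at most 0.1; the three constrained column sums
(d11¹+d21¹+d31¹, d22¹+d32¹, d12⁰+d22⁰) in [0.8, 1.2]; d33¹ ≥ 1 (the
irreversible pool cannot shrink under treatment); and two trajectory
conditions under continuous suppression — total PSA ≤ 2 ng/mL at day 360
(therapy works initially) and ≥ 10 ng/mL at day 1800 (castration resistance
eventually emerges).  The last two are evaluated by actually simulating the
all-on course inside the penalty, so the penalty is trajectory-dependent.

Each violated margin e < 0 contributes 10000·(1 − e); a margin e ≥ 0
contributes nothing (the boundary is feasible).  Any single violation
therefore pushes the total cost to at least 10000, so "cost below 10000"
certifies feasibility.  A note on the written constraint list: the prose
form of the column-sum constraint for the off-treatment second column is
ambiguous (it can be read as bounding d22⁰ alone), but the explicit penalty
expression bounds the sum d12⁰ + d22⁰; the explicit expression is
implemented.  The equality-constraint machinery h(D) + h(−D) exists for
completeness but this model has no equality constraints.

## Objective and fitting

With Gaussian observation noise of standard deviation σ, the penalized
negative log posterior of `p` given observations (t_k, o_k) under the
clinically applied on/off schedule is

    J(p) = 1/(2σ²) Σ_k (o_k − ô_k(p))² + ½ (p − p̄)ᵀ Σ⁻¹ (p − p̄) + Q(p)

where ô_k is the model PSA at day t_k.  Dropping the middle term gives the
prior-free fit used to build the cohort in the first place.  σ defaults to
1/√2, which makes the residual weight exactly 1; per-measurement residuals
of cohort fits are typically around 0.64 ± 0.29 ng/mL, so this weight treats
data misfit and prior deviation on comparable scales.  Fitting is done on
raw PSA, not log-PSA.

The minimizer is differential evolution (best/1/bin, population 15×13,
up to 2000 generations, mutation dithered in (0.5, 1.0), crossover 0.9,
convergence tolerance 0 so the budget is always available), followed by an
L-BFGS-B polish, run as 3 independent restarts keeping the best result.
Choices that mattered in development: the relative convergence tolerance had
to be 0 because early populations sit on a penalty plateau where all
energies are large and similar, which triggers a spurious relative-tolerance
stop; crossover 0.9 clearly outperformed 0.7 on this strongly correlated
13-parameter problem; and restarts buy more robustness per CPU-second than
longer single runs, because failures are basin-capture events.  The initial
population is drawn inside the biologically plausible box (diagonals in the
constraint band, d33¹ just above 1, small fluxes, initial burden anchored to
the first observed PSA with random pool splits) rather than uniformly over
the search box, where the penalty dominates every member.  Search bounds are
deliberately wider than the constraint box (diagonals [0.7, 1.3],
off-diagonals [0, 0.15], initial conditions [0, 1.2 × max observed PSA]) so
the penalty, not the box, is what binds.  When a prior is active its mean is
injected into the initial population, so the returned optimum can never be
worse than the prior mean.  All randomness is seeded; identical inputs and
seed give identical results.

Observations on a treatment-switch day belong to the segment starting that
day (half-open convention throughout).

## Cohort prior

The prior is the multivariate Gaussian with the sample mean and covariance
(denominator N−1) of cohort-fitted parameter vectors.  All 13 components are
priored, including the initial conditions: they are patient-specific, but
the cohort spread of presenting burdens is itself informative, and this
matches the fitted-vector definition used throughout.  The covariance gets a
ridge of 1e−8·trace(Σ)/13 on the diagonal by default — 13 parameters
estimated from a few dozen patients can give a numerically singular matrix,
and the inverse must exist for the quadratic form.

Mardia's multivariate skewness and kurtosis test whether cohort fits are
plausibly Gaussian.  The skewness statistic N·b₁ₚ/6 is referred to χ² with
p(p+1)(p+2)/6 degrees of freedom; the kurtosis statistic standardizes b₂ₚ
with Mardia's finite-sample mean p(p+2)(N−1)/(N+1) and variance 8p(p+2)/N
(two-sided normal reference).  The finite-sample kurtosis mean matters: with
the asymptotic mean p(p+2), the two-sided test at N = 200, p = 13 rejects
true Gaussians at roughly 8% instead of 5%.

## Classification

A fitted vector is simulated to a 3600-day horizon under both continuous
suppression and the threshold-switched intermittent protocol (treatment
stops after at least 270 on-days once PSA ≤ 1 ng/mL; resumes at PSA ≥ 10
ng/mL; all thresholds configurable — trial-specific values are conventions
of this package, not published facts).  Relapse is the first day PSA reaches
10 ng/mL and does not decrease over the following 60 days, so a crossing
that resumed therapy promptly reverses does not count.  Type (i): no relapse
under the intermittent schedule within the horizon.  Type (ii): both arms
relapse but the intermittent one strictly later.  Type (iii): otherwise.
The 10 ng/mL threshold matches the feasibility bound that forces relapse
under continuous suppression by day 1800, so every feasible vector has a
continuous-arm relapse day.  This finite-horizon rule is this package's
operationalization of the published three-type scheme (whose original
criteria are stated elsewhere and may be asymptotic rather than
finite-horizon); it is deterministic in (parameters, protocol, threshold,
horizon).

## Synthetic cohorts

The generator emulates intermittent-suppression trial records.  Parameters
are rejection-sampled until the penalty is exactly zero; the proposal draws
conversion rates d21¹, d12⁰ uniformly on [0, 0.1], the fluxes into the
irreversible pool d31¹, d32¹ on [0, 0.01] and d33¹ on [1.0, 1.01] (the
trajectory constraints accept essentially nothing outside these ranges, so
wider proposals only waste rejections), diagonals conditionally uniform so
each constrained column sum lands in [0.8, 1.2], total initial burden
uniform on [5, 30] ng/mL with at most 20% starting reversibly and 2%
irreversibly resistant.  PSA is sampled every 28 days (typical monitoring
cadence) plus at every treatment-switch day, with i.i.d. Gaussian noise of
s.d. 0.64 ng/mL (the typical per-measurement residual scale) clipped at
zero; the clipping bias is negligible at these PSA levels.  Follow-up ends
at the first sampled day whose noiseless PSA reaches 30 ng/mL (3× the
resume threshold): real records stop at established castration resistance
rather than charting years of unchecked growth, and without this cap a
runaway record's squared residuals are dominated by astronomically large
values that no optimizer (and no clinic) would ever see.

What the generator does not emulate: inter-site protocol differences,
non-Gaussian and correlated parameter distributions of real cohorts (real
fitted cohorts decisively fail Mardia normality; the uniform-box sampler
makes no attempt to match that), irregular visit schedules, assay floors,
or drop-out.  Passing recovery tests on these cohorts therefore shows the
estimation machinery works under the model's own assumptions, not that the
model is right for any given patient.

## Standing studies and sizes

The studies in `iasfit.experiments` (run by both the test suite and
`scripts/acceptance.py`) use: 1000 parameter vectors for penalty semantics
(three strata: known-feasible, near-feasible, wide box); 12 patients for
noiseless recovery; a 60-vector prior cohort and 10 test patients for the
shrinkage study at noise 0.64 and one-and-a-half-cycle truncation (patients
whose record relapses before the second on-period cannot be truncated and
are skipped, as in the real studies where only patients with enough cycles
were usable); 200 replicates of 200 draws for Mardia calibration.  These
sizes keep each study to minutes on one core while leaving the comparisons
well away from their decision boundaries.

## Numerical notes

- The hot loops (day stepping, penalty, objective) are numba-compiled;
  `model.step` is the pure-Python reference implementation the kernels are
  tested against.
- Inside the fitting kernels any compartment is capped at 1e30 so that
  runaway candidates (1.2^3600 overflows a double) keep finite, ordered
  energies; no feasible trajectory comes near the cap.
- The exact r×c Fisher test enumerates all tables with the observed margins
  (recursion over rows with margin-implied bounds, log-factorial
  probabilities); the two-sided p-value sums probabilities ≤ the observed
  table's with relative tolerance 1e−7 on the comparison — without the
  tolerance, floating-point ties flip p-values.  A seeded Monte-Carlo
  fallback exists for tables beyond the enumeration budget.
- Degenerate inputs: empty observation series are rejected at model
  construction; schedules must be contiguous from day 0; all-zero rows or
  columns are dropped before the Fisher test and a table degenerate after
  trimming is an error.

## Known limitations

- The differential-evolution budget is tuned for records up to a few
  thousand days; much longer or much noisier records may need more restarts.
- The MAP point estimate carries no posterior uncertainty; the prior term's
  Gaussian form is a first approximation that real cohorts measurably
  violate (see Mardia above).
- The classification rule is a finite-horizon convention; parameter vectors
  whose relapse falls near the horizon can flip label under a different
  horizon.
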