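# Methods

## The model

`hwle` estimates how many years people can expect to spend healthy and
in paid work between two ages (51 and 80 by default) from longitudinal
survey panels of the Health-and-Retirement-Study type: interviews every
two years, staggered entry between ages 51 and 61, exact death dates
from exit interviews, and attrition.

Individuals move among four states,

1. healthy and in work,
2. unhealthy and in work (a health problem limiting paid work, while
   still working),
3. not in work,
4. dead (absorbing),

following a continuous-time Markov process.  All six transitions among
the living states are permitted, plus death from each living state.
Each permitted transition (r, s) has a Gompertz (log-linear in age)
intensity

    q_rs(x, z) = exp( beta_rs + xi_rs (x - x0) + gamma_rs' z ),

with `x0 = 51` a centering age (numerical convenience only; the
estimand is unchanged) and `z` a vector of 0/1 covariates (women vs
men, high vs low education; men and low education are the reference
categories, which fixes the sign convention of the `gamma`
coefficients).

### Likelihood

Living states are interval censored (known only at interview ages)
while death ages are exact.  Writing `P(x1, x2)` for the transition
probability matrix between two ages, each consecutive record pair of a
person contributes

* living r at x1, living s at x2: `log P_rs(x1, x2)`;
* living r at x1, death at xd: `log( sum_j P_rj(x1, xd) q_{j,dead}(xd) )`
  (survival to some living state j just before death, times the death
  intensity at the exact death age);
* right censoring after the last living observation contributes
  nothing.

Because the intensities depend on age, `P` has no closed form; it is
approximated by freezing the intensities on a grid: within each grid
cell the generator is constant (evaluated at the cell's **left**
endpoint) and `P` is an ordered product of matrix exponentials.  The
grid is anchored globally at `x0 + k * grid_step` rather than at each
interval's start, which makes the approximation satisfy
Chapman–Kolmogorov exactly at grid points.  `grid_step` defaults to
0.5 years.  The dead state being absorbing, only the 3x3 living block
is exponentiated (death probabilities are the row-sum deficits).

The test suite checks this computation against an independent
high-accuracy ODE integration of the Kolmogorov forward equations over
the same piecewise-constant intensity function.

### Estimation

Maximum likelihood on the unconstrained working scale (log baseline
intensities; linear age slopes and covariate log-ratios):

* start values: log crude occurrence/exposure rates (observed
  transition counts between consecutive records divided by person-years
  at risk in the origin state), floored at 1e-3 per year; slopes and
  covariate effects start at 0;
* optimizer: L-BFGS-B with central finite-difference gradients (step
  1e-5).  Two numerical aids proved necessary for reliable convergence
  and are internal only: a warm-start pass that optimizes the baselines
  with slopes frozen at zero, and a rescaling of the age-slope
  coordinates (x 0.1) so all coordinates move the log intensity by
  comparable amounts.  Convergence is L-BFGS-B's relative-improvement /
  projected-gradient test; the fit never degrades the start value;
* covariance: inverse of a central finite-difference Hessian of the
  negative log-likelihood at the optimum (step 1e-3, symmetrized).  If
  the Hessian is not positive definite the covariance is flagged
  unusable and confidence intervals are disabled downstream rather than
  reported from a pseudo-inverse.

Linear predictors are clipped at +/-30 before exponentiation so a line
search that wanders into absurd territory gets a finite, recoverable
objective; the clip is far outside any region the data can support.

The likelihood core is a numba-compiled kernel (scaling-and-squaring
Taylor exponential of the 3x3 living block); a pure-numpy path computes
identical numbers and is used when numba is unavailable.  The two are
tested against each other and against the ODE oracle.

### State distribution (prevalence)

Marginal expectancies weight the starting state by the age-specific
distribution over the living states, modelled as a multinomial logit of
the observed living state on centered age and the model's covariates
(reference state: healthy-and-in-work), fitted by statsmodels' MNLogit.
All living person-wave observations enter this fit, not baseline
records only: the estimand is the age-specific distribution and pooling
uses the panel's full information.  When the expectancy window starts
at 51, the weights are the fitted probabilities at exactly 51.
Divergent coefficients (|coef| > 30 or non-finite, e.g. under perfect
separation) raise a diagnostic error instead of returning silently.

### Temporary expectancies

The expected years in living state s between ages a and b is the
integral of the occupancy probability
`p_s(u) = sum_r pi_r(a) P_rs(a, u)` (marginal) or `P_rs(a, u)`
(conditional on a start state).  Working life expectancy is the sum of
the two working states; total (partial) life expectancy the sum over
the three living states.  Three integration rules are available
(default step 0.1 years, decoupled from the likelihood grid):

* **step** (default): the occupancy curve is propagated on the
  integration grid with the same left-endpoint frozen-intensity
  convention as the transition probabilities, and the integral over
  each cell is computed **exactly** under that step-intensity model via
  the augmented-matrix identity
  `exp([[A, I], [0, 0]] h) = [[e^{Ah}, int_0^h e^{At} dt], [0, I]]`.
  This makes the rule exact for genuinely piecewise-constant models
  (e.g. the constant-hazard closed form) rather than first-order
  accurate, while remaining faithful to the forward-stepping
  convention that gives it its name.
* **middle_riemann**: midpoint Riemann sum of the sampled occupancy
  curve.
* **simpson**: composite Simpson's rule; an odd sub-interval count is
  auto-adjusted (logged).

The three rules agree to well under 0.02 years at h = 0.1 on smooth
models; conservation (living + dead years = window width) and
monotonicity under window widening are enforced by tests.

### Confidence intervals

Simulation-based percentile intervals: 500 draws (default) of the
parameter vector from a multivariate normal centered at the estimates
with the fitted covariance; every expectancy is recomputed per draw and
the 2.5th/97.5th percentiles reported.  Point estimates remain the
plug-in values.  Derived sums (working-life, total) are percentiled
from per-draw sums, keeping each draw internally coherent.  In marginal
mode the prevalence parameters are drawn as well, from their own
fitted covariance, independently of the multistate parameters (the
cross-covariance between the two fits is not estimated; both use the
same panel, so the intervals neglect that correlation).  A covariance
that fails positive semi-definiteness is repaired by clipping negative
eigenvalues to zero, with a logged warning.

## The synthetic world

The generator simulates exact continuous-time trajectories by thinning
against a per-band dominating rate.  The total exit intensity is a sum
of exponentials in age, hence convex, so its maximum over a one-year
band is attained at an endpoint; the envelope is 1.1 x the larger
endpoint total, which dominates rigorously even for intensities that
decline with age.  The acceptance ratio is still checked at every
candidate and raises if exceeded.

Default design (the package's stated world; chosen once to mirror the
survey design and the broad features of US cohorts aged 51-80, not
estimated from any dataset):

| quantity | default | note |
| --- | --- | --- |
| wave spacing | 2 years | biennial interviews |
| entry ages | uniform 51-61 | staggered entry |
| cohorts | HRS 1936-41, WB 1942-47, EBB 1948-53 | equal sizes by default |
| initial state distribution | (0.62, 0.08, 0.30) | at entry |
| attrition | 0.03 per wave | non-informative, applies after the second attended wave |
| women / high education | 0.53 / 0.45 | independent draws |
| age cap | 102 | trajectories truncated there |

Baseline intensities per year at age 51 (rows: origin state), with age
slopes in parentheses:

* healthy-working -> unhealthy-working 0.04 (+0.05), -> not-working
  0.06 (+0.055), -> dead 0.002 (+0.09);
* unhealthy-working -> healthy-working 0.35 (-0.02), -> not-working
  0.25 (+0.04), -> dead 0.010 (+0.09);
* not-working -> healthy-working 0.18 (-0.09), -> unhealthy-working
  0.02 (-0.08), -> dead 0.0075 (+0.09).

The mortality slope corresponds to a doubling time of roughly eight
years; work exit accelerates and re-entry fades with age.  These values
were calibrated once against the aggregate expectancies published for
US cohorts of this period and then frozen: the implied marginal
expectancies over ages 51-80 are ~9.3 years healthy-working, ~1.1
unhealthy-working, ~10.4 in work, and ~23.5 alive (of 29 possible).  Optional covariate effects (women,
high education) lower mortality for women, raise education's work
rates, and lower women's re-entry rates, with log intensity ratios of
0.1-0.35 in magnitude.

Survey fields are back-derived from the state at each interview:
working/limitation follow the state definition; weekly hours are drawn
per state (working states ~N(40, 8) and ~N(34, 10) clipped to 15-80,
with 8%/15% part-timers at 3-14 hours); self-rated health is drawn
from state-specific category distributions; the not-working state
reports a work limitation with probability 0.35.  Deaths are recorded
at their exact simulated age while the person is under follow-up;
deaths after attrition or after the last wave are right-censored, as
the likelihood assumes.

What a green test on this world does **not** establish: robustness to
informative attrition, proxy interviews, survey weights, household
clustering, misreported states, or calendar-time effects — none of
which the generator emulates.

## Eligibility and panel construction

Filters follow the survey design: spouse interviews before age 51 are
dropped (rows), persons outside the 1936-1953 birth bands or with no
valid gender/education are dropped, and persons must contribute at
least two usable observations.  An observed exact death counts as the
second usable observation: the likelihood needs one transition
interval, and dropping wave-1 decedents would select the sample on
surviving to the second interview, which demonstrably biases the death
intensities (intercepts down, slopes up) in synthetic recovery studies.
Non-classifiable waves (missing work/health answers) are skipped and
the surrounding interval spans the gap; this treats within-person gaps
as longer intervals, consistent with the Markov assumption.  Persons
re-entering after a skipped wave stay in the sample.

## Design choices where the design was open

* Age slopes are transition-specific by default; `tie_age_slopes`
  shares a single slope across transitions.
* Covariate effects are transition-specific and proportional
  (log-linear) on every permitted intensity.
* Intensities enter the likelihood piecewise-constant at the left grid
  endpoint; the grid step is exposed (`grid_step`), and expectancy
  integration uses its own finer grid (`step_h`).
* The "at least two waves" rule counts exit interviews (see above).
* Sample summaries count living observations as "records" and compute
  person-years as each person's last-minus-first observation age.
* One global seed drives each pipeline stage through derived child
  seeds (`SeedSequence([seed, crc32(stage)])`), so runs are bit
  reproducible and stages are independently perturbable.

## Known limitations

* No misclassification (hidden Markov) layer; observed states are
  taken at face value.
* The five-state refinement splitting not-working by health is out of
  scope (it is known to be fragile to fit in data of this size).
* Wald-type machinery (the MVN draw for CIs) relies on approximate
  normality of the MLE; intensities with very few observable events
  (e.g. rare re-entry into unhealthy work at old ages) have skewed
  likelihoods at realistic sample sizes, and their log-scale intervals
  can undercover.
* The numerical-gradient optimizer resolves parameters to roughly 1e-3
  on the working scale; tighter tolerances would need analytic
  derivatives of the matrix exponentials.
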