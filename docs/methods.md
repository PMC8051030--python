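# Methods

## The decision problem

A 50-year-old patient with end-stage kidney disease can accept a
marginal-quality deceased-donor kidney (KDPI > 74) or remain waitlisted on
dialysis. The package evaluates the choice with two decision-analytic
methods sharing one parameter set, so that differences between the methods
themselves — cycle discretisation, memorylessness — can be isolated from
differences in inputs.

## Event-time model

Every transition is a marginal, covariate-free Weibull time-to-event
distribution on the rate scale, `S(t) = exp(−λ t^γ)`, time in years:

| transition | λ (SE) | γ (SE) |
|---|---|---|
| graft failure after transplant | 0.0698 (0.0072) | 0.3944 (0.0345) |
| death with functioning graft | 0.0502 (0.0059) | 0.9305 (0.0572) |
| death on dialysis after graft failure | 0.0922 (0.0027) | 1.1161 (0.0153) |
| death while waitlisted | 0.0315 (0.0039) | 1.4346 (0.0654) |

γ < 1 (graft failure) gives a falling hazard — most failures are early;
γ > 1 (waitlist mortality) a rising hazard. The exponential is the γ = 1
sub-family, so its maximised likelihood can never exceed the Weibull's on
the same data; `select_best_fit` uses lowest AIC, ties broken by lowest BIC
and then by parsimony (ties never arise with these data shapes, but the rule
must be deterministic).

The fitting stage (`fit_parametric`) supports exponential, Weibull,
log-logistic and log-normal families under right-censoring — censored
records contribute `S(t)`, events `f(t)` — via lifelines, with a
delta-method conversion from the backend's scale parameterization
`S(t) = exp(−(t/s)^γ)` to the rate scale (`λ = s^(−γ)`).

## Markov engine

Per-cycle probabilities come from the survivor-function ratio
`p_k = 1 − S(k·u)/S((k−1)·u)`, which telescopes exactly: the product of
per-cycle survivals over K cycles equals `S(K·u)` to machine precision, so
cumulative incidence is independent of cycle length and all
cycle-length effects in results are accrual-discretisation effects.

Deliberate conventions, each of which materially affects absolute results:

* **Single cohort clock.** All probabilities, including death after graft
  failure, are evaluated at time since model start. Patients entering the
  post-graft-failure state late in the run face that distribution's
  *current* hazard, not a fresh one; with γ = 1.116 (mildly rising hazard)
  this overstates their mortality slightly. Removing the approximation
  requires tunnel states, which are out of scope; the DES engine, which has
  memory, quantifies its effect.
* **Competing exits** from the functioning-graft state (failure, death) are
  applied simultaneously as computed; an exception is raised if they sum
  beyond 1 (never at the default parameters — first-cycle exits total
  ≈ 0.12).
* **Half-cycle correction**, life-table style: each cycle credits the mean
  of its start- and end-of-cycle occupancies — exactly the trapezoid rule
  applied to the occupancy curve, with O(u²) discretisation error. With the
  correction off, end-of-cycle occupancy is credited (O(u) error); the
  refinement tests exercise both.
* **Discounting at the cycle midpoint**, factor `(1.05)^(−t)`, consistent
  with the averaged occupancy. (Start/end conventions shift 5-year totals by
  roughly ±2.5 %; midpoint is the unbiased companion to the trapezoid
  accrual.)
* **First-year transplant cost** accrues at its annual-equivalent rate over
  however many cycles make up year one (57,862.5 per half-year cycle), so
  first-year spending is identical across cycle lengths.

## DES engine

Each patient draws latent times for all potential next events
(inverse-transform from the same Weibull distributions), the earliest wins,
ties (measure zero) resolve as death, and accrual truncates at the horizon.
After graft failure the dialysis-survival clock restarts at the failure
instant. Costs and QALYs integrate continuously over occupancy intervals
with discount `e^(−t·ln 1.05)` — the continuous-time equivalent of the
Markov engine's 5 %/yr — in closed form. The first-year transplant cost
accrues over [0, 1) at its annual rate (a patient dying at month six incurs
half); a lump-sum-at-t=0 alternative is available as a configuration switch.

One seeded generator produces an `(n_patients, k)` uniform matrix per run
(k = 3 latent times for the transplant arm, 1 for the waitlist arm); each
patient owns a row, so results are independent of iteration order and the
vectorised population path is bit-identical to per-patient simulation. The
stabilization analysis re-runs independent populations at increasing sizes
and reports the smallest size from which NMB stays within ±2.5 % of the
largest-size estimate.

## Economics and PSA

`NMB = 28,000 × QALY − cost`, exact by construction. Incremental results
use the cost-saving convention (`Δcost = comparator − intervention`,
`Δeffect = intervention − comparator`), so dominance is both deltas
positive and `ΔNMB = WTP·Δeffect + Δcost` holds as an algebraic identity.
Monetary outputs are rounded to the nearest AUD 1,000 only in the reporting
layer.

The PSA draws all 14 parameters independently per iteration: each λ and γ
normal at (baseline, SE) truncated positive by redrawing; utilities uniform
on their 95 % CIs (transplant 0.74–0.90, dialysis 0.62–0.78), clamped to
[0, 1]; costs uniform over baseline ± 15 %. Only marginal uncertainties are
available, so the likely negative correlation between jointly fitted λ–γ
pairs is ignored — a known fidelity limitation that widens parameter-driven
NMB spread somewhat. Markov PSA default is 5,000 iterations; the DES PSA
defaults to 500 iterations × 1,000 patients, sizes chosen so the
Monte-Carlo standard error of the mean NMB (a few thousand AUD) is an order
of magnitude below the parameter-uncertainty spread being summarised.

## Synthetic registry cohorts

`synthetic.generate_cohort` emulates the registry extraction the fitting
stage assumes: uniform entry over an accrual window, latent Weibull event
time, administrative censoring at study close (default 11 years, matching
an 11-year registry window), optional exponential loss to follow-up
(default off — registry follow-up is essentially complete). The generator
reproduces the *statistical* structure only: no covariates (age, sex, KDPI),
no secular trends, no competing-risk informative censoring. Passing
parameter-recovery tests therefore demonstrates that the fitting machinery
is correct for data of this structure, not that real registry extractions
are free of the confounding those features can introduce.
`generate_competing_cohort` layers two latent processes for end-to-end
competing-risk checks against quadrature of `∫ f_A(t) S_B(t) dt`.

## Problem sizes and numerical choices

Deterministic engines are exact to floating point; tolerances in tests are
10⁻¹² for telescoping/conservation identities. Distributional checks use
n = 10⁵ samples with a Kolmogorov–Smirnov threshold of 0.01; parameter
recovery uses n = 5,000 cohorts and a 3-standard-error band, including under
~40 % administrative censoring. The test suite scales Monte-Carlo work to
run in minutes; the acceptance script uses the full default sizes
(4,000-patient DES, 5,000-iteration Markov PSA) and completes in well under
a minute.

## Relation to published values, and limitations

The comparison this package re-implements was originally run in a
commercial modelling tool whose accrual and discounting conventions are not
fully published. Under the self-consistent conventions above, discounted
QALYs agree closely with the published figures in every configuration (DES
QALYs within ~0.3 %), and every configuration reproduces the published
decision: transplanting the marginal kidney dominates. Absolute discounted
*costs*, however, differ systematically (our transplant-arm totals sit
above the published Markov figure and below the published DES figure), and
no consistent accounting we tested — occupancy credited at cycle start,
midpoint or end; discounting at start, midpoint or end; annual
start-of-period cost payments; lump-sum first-year cost — reproduces all
published cost figures at once, because the published waitlist cost/QALY
ratios imply an effective dialysis cost per utility-weighted year about 4 %
above the printed 81,689/0.70, and the published 6-month-cycle results
differ from the 12-month ones by far more than half-cycle numerics allows.
Cost-level comparisons against the published table should therefore be read
as method-convention differences, not parameter disagreements.

Other limitations, by design: no re-transplantation after graft failure; a
homogeneous cohort (no patient covariates); no donor-organ queue or resource
contention; healthcare-payer perspective only (no patient or societal
costs); and the Markov single-clock approximation discussed above.
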