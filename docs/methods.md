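# Methods

## The measurement problem

In the weapon identification task a racial prime (black/white face) precedes
a target image (gun/tool), and the participant classifies the target under
time pressure. Multinomial processing tree (MPT) models decompose the
response frequencies of the four trees (prime x target) into latent process
probabilities: an automatic bias `A_p` toward responding "gun" and a
controlled process `C_p` that produces the correct response (`p` indexes the
prime, `b`/`w`). Two architectures are of theoretical interest:

* **PCRM** (preemptive conflict resolution): control acts first; with
  probability `1 - C_p` it fails and the automatic process decides.
* **DIM** (default interventionism): the automatic association fires first
  ("gun" with probability `A_p`); control may then intervene (probability
  `C_p`) and force the correct response.

On response frequencies alone the two models are *statistically
equivalent* — for every parameter vector they imply identical category
probabilities (e.g. `P(gun | gun tree) = C + (1-C)A = A + C - AC`), so no
amount of categorical data can separate them. They become distinguishable
once response times (RTs) enter the likelihood, because the architectures
attach latent RT components to *different* branches: in the PCRM the
controlled branches are slow (gun targets, component "slow") or intermediate
(tool targets, "medium") while all automatic branches share one fast
component; in the DIM the uncontrolled default responses are fast, congruent
controlled corrections are medium, and incongruent corrections are slow.

## Parametric extension (branch-mixture likelihood)

Each trial contributes a joint (category, RT) likelihood: the sum, over the
branches that reach the observed category of that tree, of the branch
probability times the density of the branch's RT component,

```
L(trial) = sum_b  p_b(A, C) * f(t; eta_component(b)).
```

Component densities come from one of five families (shifted Wald,
ex-Gaussian, shifted lognormal, normal, shifted gamma), parameterized by a
fast-component base vector plus non-negative additive increments: the medium
component adds `(d1, s1)` and the slow component `(d1+d2, s1+s2)` to the
location-type and shape/SD-type parameter respectively, while the shift
(non-decision time; the Gaussian mean for the ex-Gaussian) is a single
parameter shared by all components. Constraint schemes R1 (all four
increments free), R2 (`s1 = s2 = 0`), R3 (`d1 = d2 = 0`) and EQ (all zero:
one shared RT distribution) control which increments are estimated. All
distribution parameters are box-constrained to [0.001, 1000]; increment
non-negativity is what encodes the ordering fast < medium < slow.

Free-parameter counts: probabilities 4; three-parameter families add 3
(base) + 4/2/2/0 increments under R1/R2/R3/EQ, hence 11/9/9/7 total; the
normal family has no shift, hence 10 (R1) and 6 (EQ).

**Estimation.** Maximum likelihood by L-BFGS-B on a mixed scale: process
probabilities on the logit scale (clipped to ±15), distribution parameters
and increments inside their box, the support-defining shift additionally
capped at `min(observed RT) - 1` ms so every trial keeps positive density.
Gradients are forward finite differences (relative step 1e-5) evaluated in a
single batched likelihood pass — the log-densities are computed for all
perturbed parameter vectors at once — which makes one gradient roughly the
price of two likelihood evaluations. Multistart: one method-of-moments
start (process probabilities from the closed-form inversion of the category
frequencies, base parameters from pooled-RT moments, modest increments) plus
seeded random perturbations; `fit(n_starts=5)` by default, while the study
runner uses 2–3 starts (the moment start is reliable at these sample sizes;
verified against 10–20-start fits on hundreds of replications with
identical optima to ~1e-8). Convergence tolerance is a relative
log-likelihood change of 1e-9. A parameter vector that assigns some trial
zero likelihood scores -inf and is never returned as an optimum. The shift
cap is applied only to families whose support begins at the shift
(Wald/lognormal/gamma); the ex-Gaussian "shift" is a Gaussian mean with full
support, and capping it below the minimum RT would badly distort that
family's fit.

**Goodness of fit.** Because parameters are estimated from raw (ungrouped)
data, a naive Pearson/G2 statistic on binned cells is not chi-square
distributed. We use the Dzhaparidze–Nikulin (DN) statistic: with cells
`(tree, response, RT-bin)`, standardized residuals
`v_j = (n_j - N_t p_j) / sqrt(N_t p_j)` and the `p^{-1/2}`-scaled Jacobian
`B` of cell probabilities in the free parameters (central differences; cell
masses are closed-form CDF differences of the fitted mixture),

```
DN = v' (I - B (B'B)^- B') v  ~  chi2(cells - trees - free parameters).
```

RT bins sit at empirical quantiles within each observed category,
`K = clamp(floor(n_category / 10), 1, 4)`, merged upward until every
expected count is at least 1; every (tree, response) category contributes at
least one cell so the partition is complete. The binning constants and the
df convention were validated by null calibration (the reference
implementation's exact cell construction is not published): at the
zero-effect condition the statistic's mean matches its df (9.2 vs 9.3 over
300 replications), p-values pass a Kolmogorov–Smirnov uniformity check, and
the empirical type-I error at alpha=.05 is about 5–8%.

**Model comparison.** Nested: the likelihood-ratio statistic
`2(logL_full - logL_eq)`, floored at zero, referred to chi-square with df =
difference in free-parameter counts (4 for R1 vs EQ). The EQ restriction
pins the increments at the lower box edge, so the usual
boundary-of-parameter-space caveat applies to the chi-square reference; we
use the standard reference and document the caveat rather than correcting
for it. Non-nested (DIM vs PCRM): Akaike weights
`w_j = exp(-(AIC_j - AIC_min)/2) / sum_i exp(-(AIC_i - AIC_min)/2)`.

## Nonparametric extension (two-bin latency parameters)

RTs are discretized at the per-dataset geometric mean of all RTs (trials
strictly below the boundary are "fast"; ties go to "slow" — with continuous
RTs ties have probability zero, the convention only pins down behavior for
degenerate inputs). Each branch splits into fast/slow sub-branches weighted
by a latency parameter `L` — the probability that a response generated by
that branch's component is fast — giving 16 cells fitted by
product-multinomial ML (logit-scale L-BFGS-B, same multistart scheme).
Goodness of fit is the G2 statistic against the saturated cell frequencies
with df = (16 cells - 4 trees) - 7 free parameters = 5; zero observed
counts contribute nothing and expected probabilities are floored at 1e-12
inside logs.

Three latency modes:

* **free** (default): three unconstrained latency parameters, one per
  component. The theoretical ordering `L_fast > L_medium > L_slow` is a
  prediction to check on the estimates, not an estimation constraint. This
  is the mode the study runner fits, for two reasons. First, the G2 (and
  nested-LRT) chi-square reference is then exact even when the true
  latencies are equal — the zero-effect generating conditions place the
  truth exactly at the order boundary, where a strictly order-constrained
  MLE makes G2 stochastically larger than chi-square(5) (measured: ~15%
  rejection at alpha=.05 instead of ~5%). Second, model discrimination does
  not require the inequality: the two architectures tie latencies across
  *different* branch sets (the PCRM shares one L across all automatic
  branches and splits controlled branches by target; the DIM splits
  controlled corrections by congruency), so their binned likelihoods differ
  whenever the component latencies differ, regardless of constraints.
* **ordered**: the strict ordering imposed via a cascading logistic map
  (`L_fast = expit(a)`, `L_medium = L_fast * expit(b)`,
  `L_slow = L_medium * expit(c)`), useful when the ordering is part of the
  substantive hypothesis and the truth is interior.
* **all_equal**: one shared latency parameter — the nested "no RT
  differences" model (5 free parameters) used as the LRT null.

The per-dataset geometric-mean boundary re-reads the individual-level
binning rule for simulated data that has no individuals; the boundary is
recomputed for every replication and recorded with the counts.

## Synthetic data generator

Datasets emulate a balanced weapon-identification experiment: `n` trials in
each of the four trees (total `N = 4n`), process probabilities
`A_b = .80, A_w = .20, C_b = .70, C_w = .65`, and branch-conditional RTs
from shifted-Wald components with fast-branch base `mu = 100, lambda = 150,
shift = 200` (ms). Two manipulations create inter-component differences
relative to the fastest branch: a location/scale effect (`delta-mu` in
{0, 25, 50, 75}; medium adds `delta-mu`, slow adds `3 delta-mu`) and a shape
effect (`delta-lambda` in {0, 100, 200, 300}; medium adds `delta-lambda`,
slow adds `2 delta-lambda`), at `n` in {100, 300} — a 32-cell grid. The
generator records the generating branch of every trial, accepts any of the
five families for robustness experiments, and derives each replication's
random stream from (root seed, condition index, replication index), so any
single dataset is reproducible in isolation.

What the generator does *not* emulate: participant heterogeneity (one
parameter set per dataset), trial-order or sequence effects, contaminant/
outlier RT processes, and speed–accuracy trade-off beyond what the branch
structure implies. Passing simulations therefore speak to the statistical
machinery under the stated generating process, not to robustness against
those real-data features.

## Monte Carlo studies and problem sizes

Three studies, each aggregating per-replication results over a configurable
condition subset: (1) goodness-of-fit rejection rates (DN for parametric
fits, G2 for the nonparametric model); (2) nested LRT rejection rates (full
vs equal-RT restriction; type-I error at zero effect, power otherwise);
(3) non-nested recovery via the mean Akaike weight in favor of the DIM.
The rejection rate is the relative frequency of p < alpha (alpha = .05 by
default); Monte Carlo standard errors are `sqrt(r(1-r)/M)` for rates and
the sample SE for mean weights. Replications are independent and fully
seeded, so result tables are invariant to evaluation order and exactly
reproducible from a `StudyConfig`. Non-convergent fits are retried once
from fresh starts, then flagged; aggregates exclude flagged replications
and report the exclusion count, and a cell with no converged replication is
reported as missing rather than zero.

Default replication counts in the shipped acceptance runs are 100–200 per
condition (a desk-scale choice; the machinery accepts any M). At these
sizes a calibration estimate at a true rate of 5% carries a Monte Carlo SE
of about 1.5 percentage points.

## Numerical choices

* Likelihood hot paths use hand-vectorized log-densities (the ex-Gaussian
  in the erfcx-stable log form, with an exact `w^2 + log erfc(w)` branch for
  large negative arguments); CDFs and samplers delegate to scipy.stats.
* DN cell masses are exact CDF differences of the fitted mixture, not
  quadrature; density normalization and RT-marginalization checks in the
  test suite use adaptive quadrature at 1e-6 absolute tolerance.
* G2 and multinomial log-likelihoods floor probabilities at 1e-12; the DN
  statistic floors cell masses at 1e-10 and is floored at 0, as is the LRT
  statistic.
* Akaike weights are computed after subtracting the minimum AIC (shift
  invariant, overflow safe).
* The binned log-likelihood omits the multinomial coefficient (constant for
  fixed data), which cancels in G2, LRT and AIC comparisons on the same
  counts.

## Known limitations

* Chi-square references at restriction boundaries (EQ increments pinned at
  the box edge) are used uncorrected, matching standard practice for these
  tests; type-I error of the parametric LRT at the null is mildly
  conservative as a result.
* The DN test's empirical type-I error runs slightly above nominal
  (~6–8% at alpha=.05, n=100/tree) under the validated binning; this is the
  chi-square approximation at moderate cell counts, not an optimizer
  artifact (statistic mean matches df).
* Single-level modeling only: no hierarchical/per-participant structure and
  no Bayesian estimation.
* Two RT bins only in the nonparametric model; subtle shape differences
  that leave the fast-bin mass unchanged are invisible to it by design.
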