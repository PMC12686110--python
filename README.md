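# mptrt — response-time-extended multinomial processing tree models

Multinomial processing tree (MPT) models explain discrete responses as the
outcome of sequences of latent cognitive processes. In the weapon
identification task (a racial prime — black or white face — followed by a
gun or tool target), two process architectures compete: the
**preemptive-conflict-resolution model (PCRM)**, in which a controlled
process acts first and an automatic bias only fires when control fails, and
the **default-interventionist model (DIM)**, in which the automatic bias
fires first and control may subsequently override it. On response
frequencies alone the two are statistically equivalent — for every
parameter vector `(A_b, A_w, C_b, C_w)` they predict identical category
probabilities (`P(gun | gun tree) = C + (1-C)A = A + C - AC`) — so they can
only be separated by bringing response times (RTs) into the likelihood.

`mptrt` implements the two standard ways of doing that, and the Monte Carlo
machinery to study how well they work:

* **Parametric** (`GptModel`): each branch emits an RT from one of three
  latent components (fast/medium/slow) with densities from a chosen family
  (shifted Wald, ex-Gaussian, shifted lognormal, normal, shifted gamma);
  the trial likelihood is the branch mixture
  `sum_b p_b(A, C) f(t; eta_b)`. Components share a base parameter vector
  plus non-negative additive increments under constraint schemes R1
  (location and shape increments free), R2 (location only), R3 (shape
  only), EQ (one shared distribution). Goodness of fit uses the
  Dzhaparidze–Nikulin statistic, which stays chi-square when parameters
  are estimated from raw (ungrouped) data.
* **Nonparametric** (`BinnedMptModel`): RTs are split into fast/slow bins
  at the dataset's geometric mean; each latent component gets a latency
  parameter `L` (its probability of a fast response), and the 16
  `(tree, response, bin)` cells are fitted by product-multinomial ML with a
  standard G² goodness-of-fit test (df = 5).

Both model classes follow the familiar build-then-`fit()` pattern: a model
object is constructed from trial-level data, `fit()` returns a results
object with estimates, log-likelihood, AIC, convergence diagnostics, a
`summary()` table, and the relevant tests (`dn_test()`, `gof()`); nested
comparisons use `lrt(full, restricted)` and non-nested comparisons
`akaike_weights([...])`. A synthetic-data generator reproduces the
simulation design (four product-multinomial trees, shifted-Wald RT
components, location/scale effects `delta-mu` in {0, 25, 50, 75} or shape
effects `delta-lambda` in {0, 100, 200, 300}, 100 or 300 trials per tree),
and `mptrt.study` orchestrates the three study designs: goodness-of-fit
calibration/power, nested LRT power, and DIM-vs-PCRM recovery via mean
Akaike weights.

See `docs/methods.md` for the full model account, estimation details and
limitations.

## Worked example

```python
from mptrt import (BinnedMptModel, Condition, GptModel, akaike_weights,
                   generate_dataset, lrt)

# A DIM-generated dataset with a location/scale effect: component means
# 300/350/450 ms, 300 trials per tree.
ds = generate_dataset(Condition("DIM", "delta_mu", 50, 300), seed=42)

full = GptModel(ds, "DIM", "shifted_wald", "R1").fit(seed=0)
eq = GptModel(ds, "DIM", "shifted_wald", "EQ").fit(seed=0)
print(full.summary())

test = lrt(full, eq)
print(f"LRT: G2({test.df}) = {test.statistic:.2f}, p = {test.pvalue:.3g}")
dn = full.dn_test()
print(f"DN GOF: chi2({dn.df}) = {dn.statistic:.2f}, p = {dn.pvalue:.3f}")
```

prints

```
GPT model (DIM, shifted_wald, R1)
  n trials: 1200   free parameters: 11
  logL -7641.915   AIC 15305.830   converged: True (starts: 5)
  process probabilities:
    A_b      0.8309
    A_w      0.2121
    C_b      0.7379
    C_w      0.6565
  fast-component base parameters:
    mu       106.7918
    lam      130.3635
    shift    201.9991
  increments (R1): d1=38.0490 d2=112.4174 s1=0.0010 s2=0.0010
LRT: G2(4) = 54.70, p = 3.76e-11
DN GOF: chi2(12) = 6.93, p = 0.862
```

The estimates sit near the generating values (`A_b=.80, A_w=.20, C_b=.70,
C_w=.65`; shift 200 ms; location increments 50 and 100): the LRT firmly
rejects the "no RT differences" restriction, while the DN test accepts the
correctly specified model. The nonparametric route on the same data:

```python
dim = BinnedMptModel.from_dataset(ds, "DIM").fit(seed=0)
pcrm = BinnedMptModel(dim.model.counts, "PCRM").fit(seed=0)
print(dim.summary())
print(f"wAIC(DIM): {akaike_weights([dim.aic, pcrm.aic])[0]:.3f}")
```

```
Nonparametric binned MPT (DIM, free)
  boundary (ms): 337.67
  logL -1242.458   AIC 2498.917   G2(5) = 0.677, p = 0.9842
  converged: True (starts: 5)
  estimates:
    A_b        0.8476
    A_w        0.2038
    C_b        0.7391
    C_w        0.6545
    L_fast     0.7739
    L_medium   0.5915
    L_slow     0.5218
wAIC(DIM): 0.632
```

The latency estimates come out in the predicted order (automatic responses
fastest), and the Akaike weight leans toward the generating DIM; with only
two RT bins a single dataset at this effect size carries modest evidence,
which is why model recovery is studied as an average over replications.

A thin CLI wraps the same functionality:

```
mptrt simulate --model DIM --manipulation delta_mu --effect 50 --n 300 --seed 42 --out data.csv
mptrt fit --data data.csv --approach gpt --model DIM --scheme R1 --seed 0
mptrt study --sim 2 --reps 100 --seed 1 --out results/
```

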