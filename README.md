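# occtime

Occupancy-time analysis for stage-structured demographic models with
time-varying transition rates.

Many long-lived organisms move back and forth between reproductive and
non-reproductive life-cycle stages — orchids with dormant years, condors and
sea birds that skip breeding seasons. A question of direct ecological
interest is *how much of its life an individual spends in a given set of
stages*: for the Southern Fulmar, an Antarctic sea bird whose yearly
transition rates depend on sea-ice conditions, the time spent in the
Successful- or Failed-Breeder stages is the number of breeding attempts in
its life. Because environments change — year-to-year fluctuations or
directional climate trends — the transition probabilities change too, and
the model is an **inhomogeneous absorbing Markov chain** rather than the
classical constant-matrix case.

`occtime` computes, exactly up to an explicit truncation tail:

* the distribution and moments of the **lifetime** `N` (time of death),
* the distribution and moments of the **lifetime occupancy time**
  `τ_R = A_R(N)`, the number of steps spent in a target stage set `R`,
* ensemble statistics over **randomly varying environments** (i.i.d. matrix
  selection), with the exact decomposition of variance into demographic and
  environmental components,
* and an individual-trajectory **Monte Carlo simulator** used throughout the
  test suite as an independent stochastic oracle.

## Model

The chain lives on stages `S = {1, …, d}` with a sequence of column
sub-stochastic matrices `B(n)`: entry `B_ij(n)` is the probability of moving
from stage `j` to stage `i` between times `n` and `n+1`, and the column-sum
deficit `b_j(n) = 1 − Σ_i B_ij(n)` is the death probability. Distributions
are column vectors evolving as `x_{n+1} = B(n) x_n`, propagated by the
transition operator `Φ(n, m) = B(n−1)⋯B(m)`.

The lifetime pmf is `P{N = n} = b(n−1)^T Φ(n−1, 0) v`. For a target set `R`
(also written as a 0/1 diagonal matrix), the joint law
`p^R_j(a, n) = P{A_R(n) = a, X_n = j}` obeys a discrete
McKendrick–von-Foerster-type recursion

```
p(a, n+1) = B(n) ( R p(a−1, n) + (I − R) p(a, n) ),    p(0, 0) = v,
```

from which the occupancy pmf follows as
`P{τ_R = a} = Σ_n b(n)^T ( R p(a−1, n) + (I−R) p(a, n) )`. Moments never
need the `(a, n)` table: the vectors `m_k(n) = Σ_a a^k p(a, n)` satisfy

```
m_k(n+1) = B(n) ( m_k(n) + R Σ_{j=1..k} C(k,j) m_{k−j}(n) ),
```

so `E[τ_R^k]` is accumulated in O(K·d) memory per step. For a constant
matrix these reduce to the discrete phase-type distribution
`P{N = n} = b^T B^{n−1} v` and the fundamental-matrix expectation
`E[τ_R] = 1^T R (I − B)^{−1} v`, both available as independent closed-form
cross-checks.

In a random environment, matrices are drawn i.i.d. each year from a labelled
catalog with probabilities (e.g. `P_f + P_o + P_u = 1` for
favorable/ordinary/unfavorable ice years). Per sampled sequence the
demographic mean and variance of `τ_R` are computed analytically; Monte
Carlo enters only at the environmental level, and the law of total variance

```
Var(τ_R) = E_μ[Var_P(τ_R)] + Var_μ[E_P(τ_R)]
```

holds exactly at the estimator level.

## Worked example

```python
import numpy as np
from occtime import occupancy_moments, lifetime_distribution, lifetime_moments
from occtime.datasets import fulmar_model, fulmar_breeding_target

model = fulmar_model("o", start="Pre-breeder")   # constant ordinary ice years
target = fulmar_breeding_target(model)           # R = {Successful, Failed Breeder}

EN = lifetime_moments(lifetime_distribution(model))[1]
res = occupancy_moments(model, target, K=2)
print(f"E[N] = {EN:.2f} years")
print(f"breeding attempts: mean {res.mean:.3f}, variance {res.variance:.2f}, cv {res.cv:.2f}")
```

prints

```
E[N] = 12.54 years
breeding attempts: mean 1.858, variance 31.80, cv 3.03
```

A pre-breeder entering the population in an ordinary-conditions world lives
12.5 years on average but makes fewer than two breeding attempts, with a
coefficient of variation above 3 — most birds die before ever breeding,
while a few breed many times.

The same analysis from the shell:

```sh
occtime fixtures --out-dir fixtures          # writes the fulmar matrices + configs
occtime occupancy-moments --config fixtures/fulmar_ordinary.yaml --k 2
occtime ensemble --config fixtures/fulmar_random.yaml --n-sequences 200 --seed 7
occtime simulate --config fixtures/fulmar_ordinary.yaml --n-reps 100000
```

For a sweep over environment probabilities:

```python
from occtime import simplex_sweep, TargetSet
from occtime.datasets import fulmar_matrices

df = simplex_sweep(fulmar_matrices(), np.array([1.0, 0, 0, 0]),
                   TargetSet(np.array([False, True, True, False])),
                   step=0.25, n_sequences=200)
```

giving one row per `(P_f, P_o, P_u)` grid point with the mean number of
breeding attempts and the demographic/environmental variance split. The mean
rises from 0.23 at the all-unfavorable corner to 6.84 at the all-favorable
corner, and at every interior point the demographic component dwarfs the
environmental one.

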