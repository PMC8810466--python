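# Methods

## Model and assumptions

An individual's life history is a Markov chain on transient stages
`S = {1, …, d}` plus an implicit absorbing death state. Time is discrete
(years, for the bundled sea-bird model). The chain is *inhomogeneous*: the
column sub-stochastic transition matrix `B(n)` may differ at every step.
Reproduction is deliberately excluded — the matrices describe survival and
stage transitions only, so the analysis concerns a single individual's
trajectory, not population growth.

Key conventions:

* **Column-vector orientation.** `B_ij(n)` is the probability `j → i`;
  distributions evolve as `x_{n+1} = B(n) x_n`. Much ecology software is
  row-oriented; transpose on the way in if your matrices are.
* **Empty product.** `Φ(m, m) = Id`, so the cocycle property
  `Φ(n, k) Φ(k, m) = Φ(n, m)` holds for all `m ≤ k ≤ n`.
* **Occupancy counting.** `A_R(n)` counts `X_0, …, X_{n−1}`: the stage
  occupied at time 0 contributes to occupancy one step later, and the stage
  occupied at the step of death *is* counted (death at time `n` from a stage
  in `R` adds that final step). The Monte Carlo simulator counts
  identically, which is what makes deterministic chains match the analytics
  bit-for-bit.
* **Finite schedules.** A finite matrix list is extended to all times either
  by repeating the last matrix (default) or by cycling. This matters because
  every infinite sum is truncated at a finite horizon and the extension rule
  determines the tail behaviour.

## Computational routes

Three independent routes compute overlapping quantities, which is the basis
of the test suite's cross-validation:

1. **Table route** — the joint recursion
   `p(a, n+1) = B(n)(R p(a−1, n) + (I−R) p(a, n))` evolved explicitly,
   giving the full pmf of `τ_R`. Memory is O(n²d/2); a configurable cell
   budget refuses runs that would exhaust memory and points to the moment
   route. The boundary case `a = 0` uses `p(−1, ·) ≡ 0`, so a single
   formula also yields `P{τ_R = 0}` (individuals that die without ever
   entering `R`) and total probability is conserved.
2. **Moment route** — the recursion for `m_k(n) = Σ_a a^k p(a, n)` with
   binomial-coefficient coupling to lower orders, accumulating `E[τ_R^k]`
   step by step in O(K·d) memory. The accumulation starts at `n = 0`, where
   `m_k(0) = 0` for `k ≥ 1` and `m_0(0) = v`; the first term therefore
   contributes `b(0)^T R v` to the mean — exactly the mass that dies at
   time 1 having spent its single step in `R`.
3. **Closed forms** (homogeneous case only) — the phase-type pmf
   `b^T B^{n−1} v` and the fundamental-matrix solve
   `E[τ_R] = 1^T R (I − B)^{−1} v`, computed by direct linear algebra with
   no recursion shared with routes 1–2.

The recursion for `m_0` gives `m_0(n) = Φ(n, 0) v` (the alive distribution
at time `n`); the accompanying statement is self-consistent with the
initial condition `m_0(0) = v` and is what the implementation follows.

## Truncation and tolerances

All series over time are truncated when the surviving mass `1^T Φ(n,0) v`
drops below `eps` (default `1e−12`) or at `n_max` (default `10 000`). The
leftover mass is always reported (`truncation_mass`), never silently
dropped: the pmf then sums to `1 − truncation_mass` and moments are lower
bounds. Chains with a reachable immortal state never meet `eps`; they stop
at `n_max` with the full leftover flagged.

Validation tolerance is `1e−9`: column sums in `(1, 1 + tol]` are accepted
but renormalised to 1 so implied death probabilities are never negative.
A variance more negative than numerical noise raises; within noise it is
clipped to zero. The coefficient of variation of a zero-mean occupancy
(target unreachable) is reported as NaN rather than raising.

Two analytically identical pipelines generally differ in the last bits
because BLAS accumulates in different orders; tests that assert "exact"
identities between routes therefore use absolute tolerances of `1e−12` to
`1e−15`, far below any scientific signal.

## Random environments

The shipped environment model draws one matrix per step i.i.d. from a
labelled catalog with fixed probabilities; the sampler is a narrow surface
behind which autocorrelated or continuous environment models could later
sit. Sequence `r` of an ensemble uses an independent child stream spawned
from the root seed, so results are reproducible and order-independent.

Per sampled sequence the demographic mean and variance of `τ_R` come from
the moment route — no individual-level simulation. The default schedule
length is chosen by survival, not guesswork: long enough that the *most
survivable* matrix in the catalog, held constant, retains less than `eps`
mass. For the fulmar catalog at `eps = 1e−12` this is about 350 years,
making per-sequence truncation negligible for every sampled sequence.

Across sequences, variances use the population (divide-by-n) convention so
the law-of-total-variance identity
`Var = E_μ[Var_P] + Var_μ[E_P]` is exact on the same samples; with the
sample (n−1) convention the identity would only hold asymptotically.

## Monte Carlo simulator

The simulator realises the extended chain with an explicit death state,
using inverse-CDF sampling per column with the fixed stage ordering
`1, …, d, death` (numpy PCG64), so a seed pins the exact trajectories.
Individuals still alive at the horizon cap are counted, reported, and
excluded from moment estimates (their values are censored lower bounds).
The cap defaults to roughly ten times a crude expected-lifetime bound
derived from the best column survival rate.

What the simulator does and does not establish: agreement of analytic
means/variances with simulation at `10^5` replicates within a few standard
errors confirms the recursions and the counting convention under the
modelled assumptions (Markov transitions, i.i.d. individuals, exact
matrices). It says nothing about how well a 4-stage yearly matrix model
describes real birds — stage misclassification, individual heterogeneity
and density dependence are all outside the model.

## Test-scale choices

The exhaustive path-enumeration oracle is exponential in the horizon; tests
run it on chains with `d ≤ 4` and horizons of 6–8 steps, where it is exact
and fast. Randomised model generators cap column sums at 0.95 so death is
always reachable and series converge quickly. The random-environment sweep
in the acceptance tests uses a step-0.25 simplex grid with 200 sequences
per point — coarse relative to a publication-quality sweep (66+ points,
2000 sequences, the library default) but ample to resolve the corner
ordering and the dominance of demographic over environmental variance,
which are large effects.

## Known limitations

* No fecundity: the number of offspring per breeding attempt, and hence any
  population-level projection, is out of scope.
* Only i.i.d. environments ship; Markov-modulated or trending environments
  require a custom schedule callable.
* Exit-conditioned ("backward") occupancy times — how long individuals
  *leaving* at time `n` spent in `R` — are not implemented.
* Moments computed under heavy truncation are lower bounds; the package
  warns but does not extrapolate the tail.
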