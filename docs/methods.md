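# Methods

This note records the mathematical conventions, algorithms and numerical
choices behind `liemarkov`. Everything quantitative stated here was
computed with this package; the test suite (`tests/`) asserts each claim.

## Model family

A Lie Markov DNA model is a linear space of 4×4 rate matrices that is
closed under the matrix commutator, which guarantees multiplicative
closure: the average rate matrix of a two-epoch process under the model,
`Q' = log(exp(Q1) exp(Q2))`, stays in the model's span whenever it is
real. The catalogue contains 37 such spans ("structures"), named
`<dimension>.<ray count><letter>` (e.g. `5.6b` is five-dimensional with
six extreme rays). Each structure respects a purine/pyrimidine-style
pairing of the four bases; applying the pairing permutation for
RY = {A,G|C,T}, WS = {A,T|C,G} or MK = {A,C|G,T} yields up to three
distinct variants per structure. Six structures are fully symmetric
(pairing-independent: 1.1, 3.3a, 4.4a, 6.7a, 9.20b, 12.12) and the other
31 have three pairwise-distinct variants, for 6 + 3·31 = 99 models. A
nine-model reversible panel (HKY, TrN, K81uf, TIMef, TIM, TVMef, TVM,
SYM, GTR) extends the catalogue to 108 for model scans; the remaining
five classical ModelTest names (JC, K80, K81, TrNef, F81) already exist
inside the hierarchy (as 1.1, RY2.2b, 3.3a, RY3.3c, 4.4a).

## Conventions

- Canonical base order is A, G, C, T internally (purines before
  pyrimidines); user-facing text output defaults to alphabetical
  A, C, G, T with `--base-order` overrides (AGCT, TCAG).
- Column convention: `Q[i, j]` is the rate from base `j` to base `i`;
  columns sum to zero and equilibrium frequencies solve `Q π = 0`.
- A trace of −4 corresponds to one expected substitution per site at
  equilibrium for a doubly stochastic matrix; likelihood and simulation
  always normalize `Q` to trace −4 and carry time in branch lengths.

Each model span is generated by a subset of 12 basis matrices
(A, A1, B, C, D, D1, E1, E2, F1, F2, G1, G2). Exactly nine of them are
doubly stochastic; D, E1 and E2 move equilibrium base frequencies. In
parameterization contexts A2 = 3·A1 − A replaces A1 (it is trace-free
and orthogonal to A), except in the degenerate hidden structure 2.2a
(basis {A1, D1}), which contains no transversions and is excluded from
the catalogue.

Equilibrium-base-frequency degrees of freedom follow from the
frequency-moving generators present: 3 when D together with E1/E2 is in
the basis, 1 for D alone, 2 for E1/E2 alone, 0 otherwise. Exactly the
structures 1.1, 2.2b, 3.3a, 3.3c, 3.4, 4.4a and 4.4b (plus hidden 2.2a)
are time reversible.

## Cartesian parameterization

For an n-dimensional model, the stochastic members with fixed trace form
a bounded convex region. The Cartesian map takes `b ∈ [−1, 1]^(n−1)`:

1. `P' = Σ b_i B_i` over the n−1 trace-free generators (A2 in place of
   A1),
2. `P = P' / (−min offdiag P')` — pushes the direction to the
   stochasticity boundary,
3. `Q = A + s·P` with saturation `s = max |b_i|`.

The output always has trace −12 (three substitutions per site) and is
rescaled afterwards as needed. At `s = 1` some off-diagonal rate is
exactly zero (the matrix sits on the boundary). The inverse expresses
`Q − A` in the direction basis by least squares and rescales by
`(−min offdiag(Q − A)) / max_j |c_j|`; round trips reproduce `b` to
better than 1e−10 across 1000 random draws for every model
(acceptance criterion 4).

Extreme rays of each model's stochastic cone are enumerated by choosing
(n−1)-subsets of the 12 off-diagonal nonnegativity constraints, solving
for the null direction, and keeping feasible, deduplicated rays. The ray
count equals the model-name suffix for all 37 structures.

## Embeddability Monte Carlo

Random members at a predetermined trace are drawn by sampling `b`
uniformly on the hypercube, applying the Cartesian map and rescaling the
trace. For a pair (Q1, Q2), `Q' = log(exp(Q1) exp(Q2))` (principal
matrix logarithm; eigendecomposition fast path with a conditioning and
reconstruction guard, `scipy.linalg.logm` fallback). `Q'` is classified
nonembeddable when its imaginary part exceeds 1e−8 or a real
off-diagonal entry is below −1e−9. Real products are additionally
checked against the model span; no escape was ever observed (10^3
pairs per model across all 99 models, acceptance criterion 7), matching
the closure theory.

Measured with this sampler (seeds fixed a priori, n = 2000 per trace
point, geometric bisection):

- Models 2.2b, 3.3a, 3.3b, 3.3c and 4.4a show 0 nonembeddable pairs in
  10^4 draws at trace −12.
- Model 10.12 crosses a 5% nonembeddable fraction near trace −4.5
  (−4.35 to −4.73 across seeds). The published reference value for this
  experiment is −3.3 ± 0.3; the discrepancy is attributable to the
  sampling distribution over "random" members at fixed trace, which the
  original experiment did not specify in recoverable detail. The
  acceptance assertion keeps the reference band and is an expected,
  documented failure rather than a tuned pass.
- The standardized dependence of nonembeddability on the factor
  difference |Q1 − Q2| (mean group difference over pooled SD, averaged
  over models 6.6, 8.8, 8.10b, 10.12 at ~50% nonembeddability) measures
  0.31–0.35, inside the reference band 0.3 ± 0.15.

Limitation: below roughly trace −20 the matrix logarithm's conditioning
(which grows like the inverse smallest eigenvalue of the transition
product, ~e^(|trace|/2)) amplifies double-precision rounding past the
stochasticity tolerance and produces ~2% spurious nonembeddable calls
even for abelian models whose products are exactly embeddable. Deep
saturation results should be read qualitatively.

## Likelihood engine

Felsenstein pruning over compressed site patterns; leaf partials are
IUPAC bitmask indicators, so ambiguity codes and gaps are marginalized
exactly. Transition matrices come from an eigendecomposition of `Q`
(per-branch `scipy.linalg.expm` fallback when ill-conditioned). The root
is weighted by the equilibrium frequencies of `Q`. Agreement with an
exhaustive state-enumeration oracle on 5-taxon alignments is better
than 1e−10 for all heterogeneity kinds.

Rate heterogeneity: `single`, invariant sites (`I`), discrete gamma
(`G`, 8 categories, category rates are the exact mean of each
probability band via the incomplete gamma function, renormalized so the
variable-rate mean is 1), and `IG`.

Optimization is bounded coordinate-cycling line search (Brent per
coordinate) over model parameters (`b` in (−0.999, 0.999), or
exchangeabilities/frequency weights for the reversible panel), all
branch lengths and heterogeneity parameters, with random restarts and a
convergence tolerance of 1e−6 log-likelihood units. Parameter counts
for BIC/AICc: (dimension − 1) model parameters for Lie models (the
trace is fixed), the documented free count for reversible-panel models,
2T−2 branch lengths for nonreversible models and 2T−3 for reversible
ones (the root-adjacent pair is only jointly identifiable), plus
heterogeneity parameters. Parameter recovery on 10^5 simulated sites
falls within 3 standard errors (observed-information SEs) of the truth
for 1.1, RY2.2b, 3.4, RY5.6b, RY8.8 and 12.12 (acceptance criterion 8).

## Simulation

Counter-based Philox RNG; all uniform variates are drawn up front as an
(n_nodes × n_sites) array, so output is byte-identical for a given seed
regardless of traversal order. The root state is drawn from the
equilibrium frequencies, each branch applies column-cumulative
categorical draws from `exp(Q·t·r)` for the site's rate category, and
invariant sites use rate 0. Optional missing data replaces calls with N
uniformly at a given probability.

## Limitations

- Topology is fixed during fitting; only branch lengths and model
  parameters are optimized. Unrooted input trees must be midpoint
  rooted first (the error message says so).
- Nonreversible likelihoods depend on the root position; results are
  reported for the supplied rooting.
- The coordinate-cycling optimizer is robust but first-order; for the
  12-dimensional general Markov model it can hit the cycle cap before
  the 1e−6 tolerance, in which case `converged` is reported as false
  with the best value found.
- Deep-saturation embeddability classification is precision-limited as
  described above.
- No NEXUS support, codon models, partitioned analyses or topology
  search.
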