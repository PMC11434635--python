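# Methods

## Model

A pairwise comparison matrix is a positive reciprocal n×n matrix of Saaty
judgments: a_ii = 1, a_ji = 1/a_ij, off-diagonal entries drawn from
{1/9, …, 1/2, 1, 2, …, 9}. Criterion weights are extracted either by column
normalization with row averaging (the default: divide each entry by its
column sum, average each row) or by the principal eigenvector via power
iteration (relative tolerance 1e-10, at most 1000 sweeps). The two coincide
exactly on consistent (rank-one) matrices and differ by at most ~0.03 per
component on the inconsistent 4×4 matrices shipped with the package.

λ_max is estimated by default as the mean of (A·w)_i / w_i over the
column-norm weights, the classical pencil-and-paper estimator; a power
iteration variant is available. CI = (λ_max − n)/(n − 1), CR = CI/RI with
Saaty's Random Index table for n = 3…10; orders 1 and 2 are consistent by
construction and reported with CR = 0. CR is rounded to 3 decimal places for
display only — all comparisons use unrounded values. Note that the two λ_max
estimators agree on consistency *verdicts* throughout but can differ in the
third decimal of CR on clearly inconsistent matrices; only the verdict is
contractual.

## Repair objective

The discrepancy index between candidate and original is
DI = [Σ_k (g′_k/g_k + g_k/g′_k)] / (n² − n) − 1 over the n(n−1)/2
lower-triangle judgments. Each summand is ≥ 2 by AM–GM, so DI ≥ 0 with
equality iff the matrices agree; reciprocity makes the upper-triangle terms
identical, which the (n² − n) denominator absorbs. The combined objective is
OI = DI + (λ_max − n), with the eigenvalue gap floored at 0 to absorb −1e-12
round-off on consistent matrices.

## Search space

Only the upper triangle is free: a candidate is the vector of
ln(a_ij), i < j (row-major), boxed to [ln 1/9, ln 9]. The log scale makes a
judgment and its reciprocal symmetric around 0 and the Saaty grid nearly
uniform. Decoding exponentiates, fills the lower triangle with exact
reciprocals and sets the diagonal to 1, so every visited candidate is a valid
reciprocal matrix by construction.

## Optimizer

Standard PSO: velocity v′ = w·v + c1·r1·(pbest − x) + c2·r2·(gbest − x) with
fresh uniform(0,1) draws per component, clamped to ±vmax per dimension;
position x′ = x + v′ reflected at the box walls (2b − x) with the velocity
component sign-flipped on reflection, so particles do not stick to bounds.
Defaults: swarm 30, inertia 0.7, c1 = c2 = 2, 500 iterations, error
threshold 0.05. vmax defaults to one quarter of the box width per dimension
(≈1.10 on the log-Saaty box), a standard fraction-of-range clamp.

Hybrid step: after each generation, if the working global best is still above
the error threshold, `neighborhood_size` (default 10) candidates are drawn
uniformly in a box of half-width ᾱ around it and evaluated. If the best
neighbor improves on the working Gbest it replaces it; otherwise it is
accepted with probability exp(−ΔE/T) — at most one uphill move per
generation. The temperature starts at T0 = 1 and cools geometrically
(γ = 0.9) once per generation after the sweep; the radius starts at ᾱ = 0.5
and decays by 0.95 per generation. Uphill acceptance moves only the *working*
Gbest that steers the swarm; a protected best-ever incumbent is tracked
separately and reported, so the per-iteration trace is non-increasing by
construction. Accepting into the working best buys escape from local basins
without ever degrading the answer. One swarm particle is warm-started at the
original matrix: the objective explicitly rewards closeness to it, so the
do-nothing candidate belongs in the initial population, which also bounds the
final objective by λ_max(M) − n.

These default optimizer parameters are standard practice values; all are
exposed through `SwarmConfig` / `AnnealConfig` and the YAML run
configuration. The hybrid's neighborhood step is exploitation-oriented: on
the smooth matrix-repair objective it dominates plain PSO at every budget we
measured, while on deliberately deceptive multimodal surfaces (e.g.
Rastrigin) the faster convergence can cost exploration — the engine
comparison shipped in the benchmark module is therefore run on the repair
objective itself.

## Snapping

Published refined matrices contain only Saaty-scale values, so by default the
continuous optimum is discretized: each judgment is rounded to the nearest
grid value in log distance (ties toward 1), then polished by greedy
coordinate descent over the 17-value grid minimizing OI (at most 8 sweeps;
each sweep tries every value in every coordinate). The snapped matrix is kept
only if its CR remains ≤ 0.1; otherwise the continuous matrix is returned and
the discrete candidate is still exposed on the result object. On 3×3
instances the polish makes the discrete result match exhaustive 17³ grid
search to within 5%.

A matrix that is already consistent is returned unchanged with an empty
trace: repair is defined on the CR > 0.1 domain.

## Synthetic benchmark

Instances emulate an expert whose latent priorities are consistent but whose
elicited judgments are noisy: draw weights from a symmetric Dirichlet(1)
(log-compressed when a draw's extreme ratio exceeds 9, so the rank-one matrix
a_ij = w_i/w_j is exactly consistent and inside the judgment range), then
multiply each upper-triangle entry by exp(ε), ε ~ uniform(−noise, +noise),
clamp to [1/9, 9], refill reciprocals, optionally snap to the Saaty grid.
At n = 4, noise 0.6 yields ≈14% of instances with CR > 0.1, noise 0.8 ≈32%,
noise 1.2 ≈66%. What this generator does not emulate: systematic human biases
(anchoring, scale compression), structured inconsistency concentrated in one
criterion, or missing judgments — passing the benchmark shows the repair
machinery works on diffuse multiplicative noise, not that it models human
error processes.

The benchmark repairs each instance with plain PSO and the hybrid under an
equal iteration budget (a strict function-evaluation budget is available via
`max_evals`) and reports: mean/sd of final OI (solution quality), mean CR
reduction (consistency improvement), mean iterations until the incumbent
objective certifies consistency (convergence speed; OI ≤ 0.1·RI·(n−1)
implies CR ≤ 0.1 since DI ≥ 0), and the success rate. Everything is
reproducible from the instance and run seeds.

## Problem sizes and test conditions

The shipped client matrices are 4×4. The test suite uses: 100 seeded repairs
(50 seeds × both inconsistent client matrices) for the reliability check; 20
inconsistent n=4 instances × 3 seeds at a 100-iteration budget for the
engine comparison; 20 inconsistent random 3×3 instances against exhaustive
17³ search; and 50 snapped noise-0.6 instances for the fidelity check
(repair must stay closer to the noisy matrix than an unrelated consistent
matrix is). These sizes keep the whole suite around a minute while giving
the stochastic assertions comfortable margins.

## Qualitative meal scoring

The use cases rate meals per criterion as high/moderate/low. The numeric
mapping is not part of the published method, so it is a configurable ordinal
scale (default 3/2/1) whose columns are normalized to sum to one, forming the
option score matrix P; the ranking is v = P·w with ties broken by option
index. When per-criterion pairwise matrices between options are available,
their weight vectors form the columns of P instead
(`score_matrix_from_pairwise`) — the formal AHP path.

## Known limitations

- No global-optimality guarantee: the hybrid is a metaheuristic; the 3×3
  grid-search agreement is evidence, not proof, for larger n.
- The RI table stops at n = 10; larger matrices are rejected.
- The repair preserves the dominant criterion in the shipped cases but does
  not constrain rank order explicitly; a pathological objective trade-off
  could reorder closely weighted criteria.
- Qualitative scoring compresses meal quality to three levels; ties are
  resolved by option order, which is deterministic but arbitrary.
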