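# ahp-refine

Consistency repair for Analytic Hierarchy Process (AHP) judgment matrices
with a particle-swarm / simulated-annealing hybrid, plus the full AHP
weighting-and-ranking stack and a meal-planning front end for nutrition
decision support.

## The problem

AHP derives criterion priorities from a positive reciprocal pairwise
comparison matrix *A* = (*a*<sub>ij</sub>), where *a*<sub>ij</sub> states on
the Saaty 1–9 scale how much more important criterion *i* is than criterion
*j*. Human judgments are rarely transitive: the consistency ratio

CR = CI / RI, CI = (λ<sub>max</sub> − n)/(n − 1)

quantifies the contradiction (λ<sub>max</sub> is the principal eigenvalue,
RI the tabulated Random Index), and judgments with CR > 0.1 are conventionally
sent back for review. Rather than asking the expert — say, a nutritionist who
has just elicited a client's priorities over glycemic control, nutrient
density, palatability and convenience — to redo the elicitation, this package
repairs the matrix automatically while staying as close as possible to the
original judgments.

Closeness is measured by the discrepancy index over the n(n−1)/2 independent
judgments *g* (original) and *g′* (candidate),

DI = [ Σ<sub>k</sub> ( g′<sub>k</sub>/g<sub>k</sub> + g<sub>k</sub>/g′<sub>k</sub> ) ] / (n² − n) − 1 ≥ 0,

which is zero exactly at agreement, and the repair minimizes the objective
index

OI = DI + (λ<sub>max</sub> − n).

The minimizer is a hybrid: a particle swarm explores the log-encoded upper
triangle of the matrix, and whenever the swarm's global best is still above
an error threshold, a simulated-annealing step samples a shrinking
neighborhood around it, accepting a non-improving candidate with probability
exp(−ΔE/T) under geometric cooling T ← γT. The result is snapped back onto
the discrete Saaty scale when that keeps CR ≤ 0.1.

## Worked example

```python
from ahp_refine import SwarmConfig, consistency, refine
from ahp_refine.datasets import client1_initial

M = client1_initial()          # GC/ND/P/C judgments, elicited for a
print(consistency(M).cr)       # diabetic client -> 0.1111... (> 0.1)

res = refine(M, swarm_cfg=SwarmConfig(seed=1))
print(round(res.report_after.cr, 3))   # 0.013  (consistent)
print(round(res.di, 4))                # 0.0751 (distance to the original)
print(res.refined.entries[0])          # [1. 4. 7. 9.] - glycemic control
                                       # still dominates every criterion
```

The refined matrix keeps the client's priority ordering (glycemic control
first) while becoming consistent; `res.di` says how far the judgments moved
(0 would be identical). The same pipeline powers meal ranking:

```python
from ahp_refine import recommend, SwarmConfig
from ahp_refine.datasets import client1_criteria, client1_meals

ranked = recommend(client1_criteria(), client1_meals(),
                   swarm_cfg=SwarmConfig(seed=1))
for i in ranked.order:
    print(ranked.option_labels[i], round(ranked.values[i], 4))
# grilled chicken salad 0.6949
# white pasta alfredo   0.3051
```

Narrative scripts for each capability live in `examples/` (consistency
checking, matrix repair, meal ranking, engine benchmarking), with the input
CSV/JSON files under `examples/data/`. A thin CLI wraps the same library:

```sh
ahp check examples/data/client1_refined.csv     # CR=0.017 -> consistent
ahp refine examples/data/client1_initial.csv --seed 1 --out refined.csv
ahp bench --seed 1 --instances 10
```

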