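# dagbandit

Score-based causal structure learning for continuous data under a linear
structural equation model (SEM), driven by a multi-population multi-armed
bandit hyper-heuristic with soft and hard structural constraints.

## The problem

Given an m × n data matrix whose columns were generated by an unknown
linear SEM

    x_i = w_i^T pa(X_i) + u_i,

recover the directed acyclic graph (DAG) of parent sets.  `dagbandit`
treats this as combinatorial score search: a candidate DAG *G* is scored by
a decomposable BIC,

    Score(G) = Σ_j −( RSS_j / 2 + (k_j / 2) · ln m ),

where RSS_j is the residual sum of squares of the intercept-free OLS
regression of node *j* on its parents and k_j = |pa(X_j)| (higher is
better).  The search is guided by two kinds of structural constraints:

* **soft constraints**, mined from the data by Fisher-z partial-correlation
  tests: three nested search spaces (GSS ⊆ CSS, plus per-node LSS candidate
  lists) and collider (“partial V-structure”) orientations;
* **hard constraints**, expert knowledge in the form of required and
  forbidden edges, enforced in every structure the search ever produces.

The optimizer maintains several sub-populations of candidate DAGs.  Each
sub-population runs an independent FRRMAB bandit (fitness-rate-rank
multi-armed bandit): a sliding window of recent (operator, fitness
improvement rate) records is turned into decayed rank-based credits, and a
UCB rule picks the next of 13 low-level operators — random moves, swarm-style
learning from personal/global bests, greedy single-node improvement, hill
climbing, parent-set restarts, expert-knowledge injection and pruning.
Sub-populations exchange their best and worst structures by ring migration,
gated by an inbreeding-rate cap, and the restart operators widen their
search space from GSS to CSS when the global best stagnates.

## Worked example

```python
import dagbandit as db
from dagbandit import HHConfig, StructureLearner

truth = db.random_dag(10, 12, seed=3)              # ground-truth DAG
data, _ = db.generate_dataset(truth, model=1, m=1000, seed=5)
hard = db.sample_hard_constraints(truth, p=0.1, q=0.5, seed=2)

model = StructureLearner(data, HHConfig(n_pop=20, sn=5, max_it=300, seed=1),
                         hard_constraints=hard, truth=truth)
res = model.fit()
print(res.summary())
```

prints (abridged):

```
Causal structure learning results
=============================================
variables                                  10
samples                                  1000
iterations run                            300
learned edges                              12
BIC score                          -4930.1649
SBS (truth BIC)                    -4930.1649
added edges (AE)                            0
deleted edges (DE)                          0
reversed edges (RE)                         0
F1                                     1.0000
```

The learned network matches the generating one exactly (AE = DE = RE = 0,
F1 = 1) and its BIC equals the truth's score on this dataset (SBS).  On
unfaithful datasets the learned BIC can exceed the SBS: the data then
support a different, higher-scoring structure.

The same pipeline is available from the shell:

```bash
dagbandit simulate --n 10 --edges 12 --model 1 --m 1000 --seed 7 \
    --out data.tsv --out-structure truth.tsv
dagbandit learn --data data.tsv --truth truth.tsv --seed 1
dagbandit benchmark --n 10 --edges 12 --repeats 10 --seed 7
```

## Layout

* `dagbandit.graph` — DAG container, acyclicity, structural metrics, file I/O
  (edge-list TSV, adjacency CSV, structure-only BIF reader).
* `dagbandit.sem` — linear-SEM weight schemes and data simulation.
* `dagbandit.scoring` — decomposable BIC with family-level caching and move deltas.
* `dagbandit.constraints` — Fisher-z mining of CSS/GSS/LSS and V-structures;
  hard-constraint sampling and application.
* `dagbandit.operators` — the 13 low-level heuristics.
* `dagbandit.hyperheuristic` — FRRMAB credit/selection, migration, main loop.
* `dagbandit.model` — `StructureLearner` / `StructureResults` front end.
* `dagbandit.benchmark`, `dagbandit.cli` — repeated-run harness and CLI.

See `docs/methods.md` for the modelling assumptions, parameter defaults and
design choices.
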