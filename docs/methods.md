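# Methods

## Model

`dagbandit` assumes the observed columns were generated by a linear
structural equation model over a DAG: each variable is an intercept-free
weighted sum of its parents plus independent noise,
`x_i = w_i^T pa(X_i) + u_i`.  All variables are mean-zero by construction;
no latent confounders, selection effects or interventions are modelled.
Three generating models are built in:

1. weights `w1 = s + N(0,1)/4` with the sign `s` equiprobably ±1 and
   independent per edge; standard normal noise;
2. weights `w2 ~ U(0.2, 1)` (strictly positive, half-open interval);
   standard normal noise;
3. weights as in model 1; noise uniform on (−1, 1) (non-Gaussian).

Under any of these, the fit of a family is the residual sum of squares of
the OLS projection of the child on its parents, and the network score is
the decomposable BIC `Σ_j −(RSS_j/2 + (k_j/2)·ln m)` with natural
logarithm.  The score's only tuning is the penalty count `k_j = |pa(X_j)|`;
no noise-variance profiling is attempted, so absolute score values are
meaningful only relative to other structures scored on the same dataset
(which is how the search, the pruning rule and the SBS reference use them).
Collinear parent sets are handled by a pseudo-inverse so degenerate
families that arise transiently during search never abort a run.  A family
score is computed from the dataset's Gram matrix `X^T X` in O(k³),
independent of m, and memoised per (node, parent set).

## Constraint mining

Soft constraints come from Fisher-z tests: for a (partial) correlation `r`
with conditioning-set size `s`, `z = atanh(r)·sqrt(m − s − 3)` against a
standard normal, two-sided, at significance `alpha` (default 0.01).

* **CSS** contains every unordered pair that is marginally dependent *or*
  whose full-order partial correlation (off-diagonal of the normalised
  precision matrix) is significant.  The second clause matters: with ±1
  edge weights, parallel directed paths frequently cancel a direct edge's
  marginal correlation almost exactly, and a purely marginal screen would
  drop the edge from the search space for good.  The full-order partial
  correlation detects direct edges robustly; the price is that moral pairs
  (co-parents of a collider) also enter CSS, which is harmless to a
  BIC-greedy search because a co-parent alone never reduces the child's
  RSS.
* **GSS** ⊆ CSS keeps the marginally dependent pairs that stay significant
  when conditioning on each single common CSS-neighbour (order ≤ 1
  screening) — a tight skeleton estimate for the fast early search phase.
* **LSS** ranks, per node, the CSS-neighbours by absolute correlation and
  keeps the top `k_lss = 10` as candidate parents for the perturbation
  operator.
* **Partial V-structures**: for an unshielded triple i–k–j (both pairs in
  GSS) with i, j marginally independent but dependent given k, the collider
  edges i→k and j→k are emitted; mutually contradictory orientations are
  dropped.

Hard constraints are required/forbidden directed edges.  When a ground
truth is available they are sampled at rates `p` (required, among true
edges) and `q` (forbidden, among ordered pairs that are neither an edge nor
a reverse of one — expert knowledge is never wrong), with round-half-up
counts.  Applying them forces required pairs into all masks and removes
pairs forbidden in both directions; V-structure edges that contradict them
are discarded.

## Search

The population of `n_pop` candidate DAGs is seeded with the required and
V-structure edges plus each remaining GSS pair with probability 2/n in a
random legal direction, cycles repaired, and split into `sn` subgroups.
Each subgroup runs an independent FRRMAB bandit over the 13 operators:

* FIR (fitness improvement rate) of a move is the relative score gain,
  floored at 0 and mapped linearly into (0.1, 0.5) against the largest raw
  gain seen so far in the run, so early easy improvements do not dwarf late
  ones.  Individual-level operators measure it on the operated individual;
  population-level operators on the subgroup's best score; restart
  operators against the global best they started from.
* Credit: per-operator FIR sums over a sliding window of length `W`,
  ranked descending (rank 1 best, ties by id), decayed as `D^rank·reward`,
  normalised (FRR).  Operators absent from the window get zero credit; an
  all-zero window yields uniform credit over the operators present.
* Selection: uniformly random among unplayed operators until all have been
  tried, then `argmax FRR_i + C·sqrt(2·ln Σn_j / n_i)`.
* Acceptance: Accept All Moves — the produced structure always replaces its
  parent; personal/local/global bests keep the monotone record.

One iteration applies one selected operator per subgroup.  Individual-level
operators (mutation, perturbation, cognitive, cooperative, chemotactic,
pruning) act on a round-robin member; restart operators (elimination-
dispersal, scout) act on the global best and their product replaces the
subgroup's worst member; the remaining operators act on the whole subgroup.
Greedy move ties break toward the smallest (parent, child) index pair; a
random-move operator retries an illegal draw up to 10 times and then
no-ops.

The learning probability schedules are linear in the global iteration:
0.82 → 0.32 for learning from the personal best (also used by moth-flame),
0.1 → 0.5 for learning from the global best.  The teaching operator's
adoption probability is fixed at 0.5 (no schedule is published for it; a
constant keeps it distinct from the two scheduled learners).  The
elimination-dispersal trigger is `c3 = min(1, 0.1 + 0.9·L/L_max)` and the
scout requires `L > lm`, where `L` counts iterations without global-best
improvement.

The elimination-dispersal rebuild of one node's parents grows the candidate
set by *sequential* greedy addition — each candidate scored against the
growing set — before importance-ordering, clearing and re-adding.  A
singly-vs-empty screen would be blind to exactly the cancellation-masked
parents the CSS clause above preserves.  The scout, after reversing a
recorded parent edge p→X, runs the chemotactic add/delete/reverse sequence
on both X and p: the reversal changes both families, and candidates that
need a compensating addition on the far side are otherwise always rejected.

Migration: once every subgroup has waited `min(100, n)` iterations, the
subgroup bests are compared with the global best; if more than 60% are
close relatives (Hamming distance < 4, counting a reversal as 2) migration
is skipped and those bests are perturbed, otherwise bests replace worsts
around a ring.  When `L` reaches `L_max` the restart operators switch from
GSS to CSS, once per run, and `L` resets.

**Termination** is the iteration budget `t = max_it`.  An additional
early stop at a second stagnation was evaluated and rejected: it starves
the post-switch CSS correction phase, whose whole purpose is to add back
edges the GSS screen missed, and measurably degrades exact recovery.
After the loop the pruning operator removes from the returned global best
every non-required edge contributing less than `mu` to the score,
re-evaluated one edge at a time in ascending contribution order.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `p`, `q` | 0.1, 0.5 | hard-constraint sampling rates (required / forbidden) |
| `W` | 10 | sliding-window length (records) |
| `C` | 10 | UCB exploration weight |
| `D` | 0.5 | credit decay factor, in (0, 1) |
| `n_pop`, `sn` | 50, 5 | population size and subgroup count |
| `L_max` | 2·n | stagnation cap driving restarts and the space switch |
| `max_it` | 5000 | iteration budget (termination) |
| `lm` | 20 | scout stagnation threshold |
| `mu` | ln m | pruning threshold (score units) |
| `zj` | 0.5 | fraction of a subgroup receiving expert guidance |
| `alpha` | 0.01 | Fisher-z significance level |
| `k_lss` | 10 | per-node LSS candidate-list length |

With `L_max = 2n` and `lm = 20` the scout is inactive for n ≤ 10 until the
space switch resets the counter dynamics; this mirrors the published
parameterisation, which targets networks of 37+ nodes.

## Synthetic data: what it does and does not emulate

The bundled generator samples uniform random DAGs with a fixed edge count
(edges consistent with a random permutation) and simulates the three SEMs
above, defaulting to m = 1000 samples per dataset — one dataset per
(structure, SEM) pair is the experiment unit.  It reproduces the two
properties that make this problem non-trivial at small n: near-unfaithful
marginal cancellations (from ±1 weights) and colliders orientable from
observational data.  It does not emulate heavy-tailed or heteroscedastic
noise, measurement error, latent confounding, deterministic relations, or
the in/out-degree skew of curated benchmark networks, so perfect recovery
here bounds, rather than predicts, performance on real regulatory or
clinical data.

Scaled study sizes: the repeated experiments in the test suite and the
acceptance script use 8–15-node instances at m = 1000 with `n_pop = 20`,
`sn = 5` and `max_it` of 300 (exact recovery) or 800 (score dominance) —
small enough for a desk run, large enough that both experiments sit at
their asymptote (raising `max_it` further changes nothing).

## Numerical choices and degenerate inputs

Natural logarithms throughout; RSS clipped at 0; a singular test
submatrix, zero-variance column or |r| = 1 is flagged as dependence
(p = 0) rather than an error; `m ≤ k` raises.  Cycle repair removes the
most recently copied non-protected edge on each detected cycle (falling
back to a uniform choice), so a learning step is disturbed minimally and
required edges are never removed; mutually cyclic protected edges raise a
constraint-conflict error.  A reversed edge counts 2 toward the Hamming
distance and as one false positive plus one false negative in F1, with
F1 = 1 for two empty graphs.  Per-subgroup RNG streams derive from the
master seed; identical (seed, config, data) triples reproduce the output
structure bit-for-bit.

## Known limitations

* Pairs of parents that are informative only jointly (neither helps the
  child's RSS alone) defeat all greedy addition steps; recovering them
  would need pair-wise candidate search.
* The search spaces bound attainable recall: a true edge outside CSS is
  unrecoverable by construction (made rare, not impossible, by the
  full-order clause).
* BIF input is structure-only; conditional-probability tables are ignored,
  and discrete scoring is out of scope.
* Run time grows roughly with `n_pop · max_it ·` (cost of a family score);
  the implementation is single-threaded.
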