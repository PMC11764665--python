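"""The pool of 13 low-level structure-modifying heuristics (LLHs).

Each operator transforms one individual (a candidate DAG with a cached
score and a personal best) or a whole subgroup, under the active search
space, the hard constraints and the score cache.  The pool mixes moves
borrowed from swarm meta-heuristics:

====  =========================  =====================================
id    operator                   origin / role
====  =========================  =====================================
1     mutation                   random single move inside GSS
2     perturbation               random single move, adds inside LSS
3     cognitive                  learn from own personal best
4     cooperative                learn from the global best
5     chemotactic                greedy single-node improvement (GSS)
6     elimination-dispersal      restart one node's parent set (gbest)
7     employed bees              per-individual hill climb (GSS)
8     onlooker bees              roulette-targeted hill climb (GSS)
9     scout                      parent-set shake-up of gbest on stagnation
10    moth-flame                 learn from a permuted personal best
11    teaching                   learn from a random better collaborator
12    expert knowledge           force hard constraints + V-structures
13    pruning                    drop edges contributing less than mu
====  =========================  =====================================

Every operator preserves acyclicity, keeps all required edges, never adds a
forbidden edge, and confines additions to its designated space mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .constraints import HardConstraints, SearchSpaces, parent_importance
from .graph import repair_cycles, would_create_cycle
from .scoring import ScoreCache, delta_adjacency, score_adjacency
from .sem import Dataset

__all__ = [
    "Individual",
    "OperatorContext",
    "learn_from_guide",
    "op_mutation",
    "op_perturbation",
    "op_cognitive",
    "op_cooperative",
    "op_chemotactic",
    "op_elimination_dispersal",
    "op_bees",
    "op_scout",
    "op_moth_flame",
    "op_teaching",
    "op_expert_knowledge",
    "op_pruning",
    "OPERATOR_NAMES",
]

OPERATOR_NAMES = {
    1: "mutation",
    2: "perturbation",
    3: "cognitive",
    4: "cooperative",
    5: "chemotactic",
    6: "elimination_dispersal",
    7: "employed_bees",
    8: "onlooker_bees",
    9: "scout",
    10: "moth_flame",
    11: "teaching",
    12: "expert_knowledge",
    13: "pruning",
}

_RETRY = 10  # draws before a random-move operator gives up and no-ops


class Individual:
    """A candidate DAG with its score and personal-best memory."""

    __slots__ = ("adj", "score", "best_adj", "best_score")

    def __init__(self, adj: np.ndarray, score: float):
        self.adj = adj
        self.score = score
        self.best_adj = adj.copy()
        self.best_score = score

    def note_best(self) -> None:
        if self.score > self.best_score:
            self.best_score = self.score
            self.best_adj = self.adj.copy()

    def copy(self) -> "Individual":
        out = Individual(self.adj.copy(), self.score)
        out.best_adj = self.best_adj.copy()
        out.best_score = self.best_score
        return out


@dataclass
class OperatorContext:
    """Everything an operator needs: data, masks, counters, rng.

    ``active_restart_space`` is the mask the restart operators (scout,
    elimination-dispersal) work in; it starts as GSS and is switched to CSS
    once the search stagnates.
    """

    data: Dataset
    cache: ScoreCache
    spaces: SearchSpaces
    hard: HardConstraints
    rng: np.random.Generator
    t: int = 0
    max_it: int = 1
    L: int = 0
    L_max: int = 1
    lm: int = 20
    mu: float = 0.0
    zj: float = 0.5
    active_restart_space: str = "GSS"
    ed_ptr: int = 0
    scout_ptr: int = 0

    # derived, filled in __post_init__
    required_idx: frozenset = field(default=frozenset(), repr=False)
    forbidden_mask: np.ndarray = field(default=None, repr=False)
    gss_pairs: list = field(default_factory=list, repr=False)
    lss_pairs: list = field(default_factory=list, repr=False)
    vstruct_idx: frozenset = field(default=frozenset(), repr=False)

    def __post_init__(self):
        labels = self.spaces.labels
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        self.required_idx = frozenset(
            (idx[a], idx[b]) for a, b in self.hard.required if a in idx and b in idx
        )
        fm = np.zeros((n, n), dtype=bool)
        for a, b in self.hard.forbidden:
            if a in idx and b in idx:
                fm[idx[a], idx[b]] = True
        self.forbidden_mask = fm
        gss = self.spaces.gss
        self.gss_pairs = [
            (i, j) for i in range(n) for j in range(n)
            if i != j and gss[i, j] and not fm[i, j]
        ]
        self.lss_pairs = [
            (p, c) for c, cands in enumerate(self.spaces.lss)
            for p in cands if not fm[p, c]
        ]
        self.vstruct_idx = frozenset(
            (idx[a], idx[b]) for a, b in self.spaces.vstruct_edges
            if a in idx and b in idx
        )

    @property
    def n(self) -> int:
        return len(self.spaces.labels)

    def restart_mask(self) -> np.ndarray:
        return self.spaces.css if self.active_restart_space == "CSS" else self.spaces.gss

    # -- move legality -----------------------------------------------------
    def can_add(self, adj: np.ndarray, i: int, j: int, mask: np.ndarray) -> bool:
        return (
            not adj[i, j]
            and mask[i, j]
            and not self.forbidden_mask[i, j]
            and not would_create_cycle(adj, i, j)
        )

    def can_delete(self, adj: np.ndarray, i: int, j: int) -> bool:
        return bool(adj[i, j]) and (i, j) not in self.required_idx

    def can_reverse(self, adj: np.ndarray, i: int, j: int) -> bool:
        if not adj[i, j] or (i, j) in self.required_idx or self.forbidden_mask[j, i]:
            return False
        tmp = adj.copy()
        tmp[i, j] = False
        return not would_create_cycle(tmp, j, i)


def _cognitive_prob(t: int, max_it: int) -> float:
    return 0.82 - 0.5 * (t / max(max_it, 1))


def _cooperative_prob(t: int, max_it: int) -> float:
    return 0.1 + 0.4 * (t / max(max_it, 1))


def learn_from_guide(
    ind: Individual, guide: np.ndarray, prob: float, ctx: OperatorContext
) -> Individual:
    """Copy each differing adjacency entry from the guide with probability
    ``prob``, within GSS and the hard constraints; repair cycles afterwards.

    The shared primitive behind the cognitive, cooperative, moth-flame and
    teaching operators.
    """
    if prob <= 0.0:
        return ind.copy()
    adj = ind.adj.copy()
    recent: list[tuple[int, int]] = []
    gss = ctx.spaces.gss
    diff = np.argwhere(adj != guide)
    changed = False
    for i, j in diff:
        i, j = int(i), int(j)
        if ctx.rng.random() >= prob:
            continue
        if guide[i, j]:  # adoption = addition
            if gss[i, j] and not ctx.forbidden_mask[i, j] and not adj[i, j]:
                adj[i, j] = True
                recent.append((i, j))
                changed = True
        else:  # adoption = removal
            if adj[i, j] and (i, j) not in ctx.required_idx:
                adj[i, j] = False
                changed = True
    if not changed:
        return ind.copy()
    present_required = [e for e in ctx.required_idx if adj[e]]
    adj = repair_cycles(adj, present_required, ctx.rng, recent)
    out = ind.copy()
    out.adj = adj
    out.score = score_adjacency(adj, ctx.cache)
    out.note_best()
    return out


def _apply_move(ind: Individual, ctx: OperatorContext, move: tuple[str, int, int]) -> Individual:
    out = ind.copy()
    out.score = ind.score + delta_adjacency(ind.adj, ctx.cache, move)
    adj = ind.adj.copy()
    kind, i, j = move
    if kind == "add":
        adj[i, j] = True
    elif kind == "delete":
        adj[i, j] = False
    else:
        adj[i, j] = False
        adj[j, i] = True
    out.adj = adj
    out.note_best()
    return out


def _random_single_move(
    ind: Individual, ctx: OperatorContext, add_pairs: Sequence[tuple[int, int]]
) -> Individual:
    """One random add/delete/reverse; bounded retries, then no-op."""
    adj = ind.adj
    for _ in range(_RETRY):
        kind = ("add", "delete", "reverse")[int(ctx.rng.integers(3))]
        if kind == "add":
            if not add_pairs:
                continue
            i, j = add_pairs[int(ctx.rng.integers(len(add_pairs)))]
            mask = np.ones_like(adj)  # pair already comes from the space list
            if ctx.can_add(adj, i, j, mask):
                return _apply_move(ind, ctx, ("add", i, j))
        else:
            edges = np.argwhere(adj)
            if edges.shape[0] == 0:
                continue
            i, j = map(int, edges[int(ctx.rng.integers(edges.shape[0]))])
            if kind == "delete" and ctx.can_delete(adj, i, j):
                return _apply_move(ind, ctx, ("delete", i, j))
            if kind == "reverse" and ctx.can_reverse(adj, i, j):
                return _apply_move(ind, ctx, ("reverse", i, j))
    return ind.copy()


def op_mutation(ind: Individual, ctx: OperatorContext) -> Individual:
    """Random single move; additions confined to GSS."""
    return _random_single_move(ind, ctx, ctx.gss_pairs)


def op_perturbation(ind: Individual, ctx: OperatorContext) -> Individual:
    """Random single move; additions confined to per-node LSS candidates."""
    return _random_single_move(ind, ctx, ctx.lss_pairs)


def op_cognitive(ind: Individual, ctx: OperatorContext) -> Individual:
    """Learn from the personal best; probability falls 0.82 -> 0.32 over the run."""
    return learn_from_guide(ind, ind.best_adj, _cognitive_prob(ctx.t, ctx.max_it), ctx)


def op_cooperative(ind: Individual, gbest: np.ndarray, ctx: OperatorContext) -> Individual:
    """Learn from the global best; probability rises 0.1 -> 0.5 over the run."""
    return learn_from_guide(ind, gbest, _cooperative_prob(ctx.t, ctx.max_it), ctx)


def _legal_add_candidates(
    adj: np.ndarray, x: int, ctx: OperatorContext, mask: np.ndarray
) -> list[int]:
    n = adj.shape[0]
    return [
        p for p in range(n)
        if p != x and mask[p, x] and not ctx.forbidden_mask[p, x] and not adj[p, x]
    ]

def _greedy_adds(adj, x, ctx, mask, score):
    while True:
        best, best_d = None, 0.0
        for p in _legal_add_candidates(adj, x, ctx, mask):
            if would_create_cycle(adj, p, x):
                continue
            d = delta_adjacency(adj, ctx.cache, ("add", p, x))
            if d > best_d + 1e-12 or (best is not None and abs(d - best_d) <= 1e-12 and p < best):
                best, best_d = p, d
        if best is None:
            return score
        adj[best, x] = True
        score += best_d


def _greedy_deletes(adj, x, ctx, score):
    while True:
        best, best_d = None, 0.0
        for p in np.flatnonzero(adj[:, x]):
            p = int(p)
            if (p, x) in ctx.required_idx:
                continue
            d = delta_adjacency(adj, ctx.cache, ("delete", p, x))
            if d > best_d + 1e-12 or (best is not None and abs(d - best_d) <= 1e-12 and p < best):
                best, best_d = p, d
        if best is None:
            return score
        adj[best, x] = False
        score += best_d


def _greedy_reversals(adj, x, ctx, score):
    while True:
        best, best_d = None, 0.0
        for p in np.flatnonzero(adj[:, x]):
            p = int(p)
            if not ctx.can_reverse(adj, p, x):
                continue
            d = delta_adjacency(adj, ctx.cache, ("reverse", p, x))
            if d > best_d + 1e-12 or (best is not None and abs(d - best_d) <= 1e-12 and p < best):
                best, best_d = p, d
        if best is None:
            return score
        adj[best, x] = False
        adj[x, best] = True
        score += best_d


def _chemo_node(adj: np.ndarray, x: int, ctx: OperatorContext, mask: np.ndarray, score: float) -> float:
    """Greedy add, then delete, then reverse on the parent set of one node."""
    score = _greedy_adds(adj, x, ctx, mask, score)
    score = _greedy_deletes(adj, x, ctx, score)
    score = _greedy_reversals(adj, x, ctx, score)
    return score


def op_chemotactic(ind: Individual, ctx: OperatorContext) -> Individual:
    """Greedy improvement of one uniformly chosen node's family, in GSS."""
    x = int(ctx.rng.integers(ctx.n))
    adj = ind.adj.copy()
    score = _chemo_node(adj, x, ctx, ctx.spaces.gss, ind.score)
    out = ind.copy()
    out.adj, out.score = adj, score
    out.note_best()
    return out


def op_elimination_dispersal(gbest_ind: Individual, ctx: OperatorContext) -> Individual:
    """Restart the parent set of one node of the global best.

    The node is taken from a persistent rotation; the rebuild is greedy and
    importance-ordered, confined to the active restart space.
    """
    x = ctx.ed_ptr % ctx.n
    ctx.ed_ptr += 1
    mask = ctx.restart_mask()
    adj = gbest_ind.adj.copy()
    # 1. clear the (non-required) parents of x
    for p in np.flatnonzero(adj[:, x]):
        if (int(p), x) not in ctx.required_idx:
            adj[int(p), x] = False
    score = score_adjacency(adj, ctx.cache)
    # 2. grow a candidate parent set greedily (each addition scored against
    # the growing set, so jointly informative parents are found even when
    # marginally uncorrelated), then order it by importance
    probe = adj.copy()
    base_parents = set(map(int, np.flatnonzero(probe[:, x])))
    _greedy_adds(probe, x, ctx, mask, 0.0)
    survivors = [
        int(p) for p in np.flatnonzero(probe[:, x]) if int(p) not in base_parents
    ]
    ordered = parent_importance(
        ctx.data, x, [ctx.data.labels[p] for p in survivors]
    )
    idx = {l: i for i, l in enumerate(ctx.data.labels)}
    # 3. re-add one by one, accepting score-increasing parents
    for label in ordered:
        p = idx[label]
        if adj[p, x] or would_create_cycle(adj, p, x):
            continue
        d = delta_adjacency(adj, ctx.cache, ("add", p, x))
        if d > 0:
            adj[p, x] = True
            score += d
    # 4./5. greedy removal of least-contributing parents, then reversal
    score = _greedy_deletes(adj, x, ctx, score)
    score = _greedy_reversals(adj, x, ctx, score)
    out = gbest_ind.copy()
    out.adj, out.score = adj, score
    out.note_best()
    return out


def _hill_climb(ind: Individual, ctx: OperatorContext, max_steps: int | None = None) -> Individual:
    """Best-improvement climb over all single moves in GSS; stops at a local
    optimum or after ``max_steps`` (default 2n)."""
    max_steps = 2 * ctx.n if max_steps is None else max_steps
    adj = ind.adj.copy()
    score = ind.score
    gss = ctx.spaces.gss
    for _ in range(max_steps):
        best_move, best_d = None, 1e-12
        for (i, j) in ctx.gss_pairs:
            if ctx.can_add(adj, i, j, gss):
                d = delta_adjacency(adj, ctx.cache, ("add", i, j))
                if d > best_d:
                    best_move, best_d = ("add", i, j), d
        for i, j in map(tuple, np.argwhere(adj)):
            i, j = int(i), int(j)
            if ctx.can_delete(adj, i, j):
                d = delta_adjacency(adj, ctx.cache, ("delete", i, j))
                if d > best_d:
                    best_move, best_d = ("delete", i, j), d
            if ctx.can_reverse(adj, i, j):
                d = delta_adjacency(adj, ctx.cache, ("reverse", i, j))
                if d > best_d:
                    best_move, best_d = ("reverse", i, j), d
        if best_move is None:
            break
        kind, i, j = best_move
        if kind == "add":
            adj[i, j] = True
        elif kind == "delete":
            adj[i, j] = False
        else:
            adj[i, j] = False
            adj[j, i] = True
        score += best_d
    out = ind.copy()
    out.adj, out.score = adj, score
    out.note_best()
    return out


def op_bees(
    population: list[Individual], mode: str, ctx: OperatorContext
) -> list[Individual]:
    """Employed bees climb every individual; onlooker bees climb targets
    drawn by rank-based roulette (best rank gets the largest weight)."""
    if mode == "employed":
        return [_hill_climb(ind, ctx) for ind in population]
    if mode != "onlooker":
        raise ValueError(f"unknown bees mode {mode!r}")
    pop = [ind.copy() for ind in population]
    order = sorted(range(len(pop)), key=lambda k: pop[k].score)
    weights = np.zeros(len(pop))
    for rank, k in enumerate(order, start=1):  # worst rank 1 .. best rank nPop
        weights[k] = rank
    weights = weights / weights.sum()
    for _ in range(len(pop)):
        k = int(ctx.rng.choice(len(pop), p=weights))
        pop[k] = _hill_climb(pop[k], ctx)
    return pop


def op_scout(gbest_ind: Individual, ctx: OperatorContext) -> Individual:
    """Shake up the parent set of one node of the global best.

    Only fires after more than ``lm`` stagnant iterations.  Each recorded
    parent edge is reversed in turn and followed by the chemotactic
    add/delete/reverse sequence on both endpoints of the reversed edge (the
    reversal changes both families); a candidate replaces the incumbent only
    if it scores strictly higher.
    """
    if ctx.L <= ctx.lm:
        return gbest_ind.copy()
    x = ctx.scout_ptr % ctx.n
    ctx.scout_ptr += 1
    mask = ctx.restart_mask()
    cur = gbest_ind.adj.copy()
    cur_score = gbest_ind.score
    parents = [int(p) for p in np.flatnonzero(cur[:, x]) if (int(p), x) not in ctx.required_idx]
    for p in parents:
        cand = cur.copy()
        if not cand[p, x]:
            continue  # a previous acceptance already removed this edge
        cand_score = cur_score
        tmp = cand.copy()
        tmp[p, x] = False
        if not ctx.forbidden_mask[x, p] and not would_create_cycle(tmp, x, p):
            cand_score += delta_adjacency(cand, ctx.cache, ("reverse", p, x))
            cand[p, x] = False
            cand[x, p] = True
        cand_score = _chemo_node(cand, x, ctx, mask, cand_score)
        cand_score = _chemo_node(cand, p, ctx, mask, cand_score)
        if cand_score > cur_score:
            cur, cur_score = cand, cand_score
    out = gbest_ind.copy()
    out.adj, out.score = cur, cur_score
    out.note_best()
    return out


def op_moth_flame(
    population: list[Individual], ctx: OperatorContext
) -> list[Individual]:
    """Permute the personal bests as flames; each moth learns from its flame."""
    perm = ctx.rng.permutation(len(population))
    prob = _cognitive_prob(ctx.t, ctx.max_it)
    flames = [population[int(k)].best_adj for k in perm]
    return [
        learn_from_guide(ind, flame, prob, ctx)
        for ind, flame in zip(population, flames)
    ]


def op_teaching(
    population: list[Individual], ctx: OperatorContext, prob: float = 0.5
) -> list[Individual]:
    """Each individual learns from a random collaborator, only when the
    collaborator scores higher."""
    if len(population) < 2:
        return [ind.copy() for ind in population]
    snapshots = [(ind.adj.copy(), ind.score) for ind in population]
    out = []
    for k, ind in enumerate(population):
        other = int(ctx.rng.integers(len(population) - 1))
        if other >= k:
            other += 1
        guide_adj, guide_score = snapshots[other]
        if guide_score > ind.score:
            out.append(learn_from_guide(ind, guide_adj, prob, ctx))
        else:
            out.append(ind.copy())
    return out


def op_expert_knowledge(
    population: list[Individual], ctx: OperatorContext
) -> list[Individual]:
    """Force the hard constraints and the mined V-structures into a random
    ``ceil(zj * nPop)`` subset of the subgroup."""
    k = math.ceil(ctx.zj * len(population))
    if k == 0:
        return [ind.copy() for ind in population]
    chosen = set(int(c) for c in ctx.rng.choice(len(population), size=k, replace=False))
    out = []
    for idx, ind in enumerate(population):
        if idx not in chosen:
            out.append(ind.copy())
            continue
        adj = ind.adj.copy()
        recent: list[tuple[int, int]] = []
        inserts = list(ctx.required_idx) + [
            e for e in ctx.vstruct_idx
            if not ctx.forbidden_mask[e] and (e[1], e[0]) not in ctx.required_idx
        ]
        for (i, j) in inserts:
            if adj[j, i] and (j, i) not in ctx.required_idx:
                adj[j, i] = False  # clear the opposing orientation first
            if not adj[i, j]:
                adj[i, j] = True
                recent.append((i, j))
        for (i, j) in np.argwhere(ctx.forbidden_mask & adj):
            adj[int(i), int(j)] = False
        protect = [e for e in set(ctx.required_idx) | set(inserts) if adj[e]]
        try:
            adj = repair_cycles(adj, protect, ctx.rng, recent)
        except Exception:
            # V-structure edges can be mutually cyclic; required edges win
            protect = [e for e in ctx.required_idx if adj[e]]
            adj = repair_cycles(adj, protect, ctx.rng, recent)
        new = ind.copy()
        new.adj = adj
        new.score = score_adjacency(adj, ctx.cache)
        new.note_best()
        out.append(new)
    return out


def op_pruning(ind: Individual, ctx: OperatorContext) -> Individual:
    """Remove, one at a time in ascending-contribution order, every
    non-required edge contributing less than ``mu`` to the score."""
    adj = ind.adj.copy()
    score = ind.score
    while True:
        worst, worst_contrib = None, math.inf
        for i, j in map(tuple, np.argwhere(adj)):
            i, j = int(i), int(j)
            if (i, j) in ctx.required_idx:
                continue
            contrib = -delta_adjacency(adj, ctx.cache, ("delete", i, j))
            if contrib < worst_contrib:
                worst, worst_contrib = (i, j), contrib
        if worst is None or worst_contrib >= ctx.mu:
            break
        adj[worst] = False
        score -= worst_contrib
    out = ind.copy()
    out.adj, out.score = adj, score
    out.note_best()
    return out
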