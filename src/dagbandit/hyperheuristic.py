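"""FRRMAB high-level strategy and the multi-population main loop.

The high-level strategy is a fitness-rate-rank multi-armed bandit (FRRMAB):
each subgroup keeps a sliding window of the last ``W`` (operator, FIR)
records, turns them into decayed, rank-weighted, normalised credits (FRR),
and picks the next operator by a UCB rule balancing FRR against play counts.
The acceptance criterion is Accept All Moves: the structure an operator
produces always replaces its parent; personal/local/global bests keep the
monotone record of the search.

The population is split into ``sn`` subgroups that run independent bandits
and exchange their best/worst structures through a ring migration, gated by
a minimum interval and an inbreeding-rate cap.  When the global best
stagnates for ``L_max`` iterations the restart operators switch from the
narrow GSS to the wider CSS (once per run); the search then continues until
the iteration budget ``max_it`` is spent.
"""

from __future__ import annotations

import math
import time
from collections import deque
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import yaml

from .constraints import (
    HardConstraints,
    SearchSpaces,
    apply_hard_constraints,
    build_search_spaces,
)
from .graph import DagStructure, repair_cycles, structural_metrics
from .operators import (
    Individual,
    OPERATOR_NAMES,
    OperatorContext,
    op_bees,
    op_chemotactic,
    op_cognitive,
    op_cooperative,
    op_elimination_dispersal,
    op_expert_knowledge,
    op_moth_flame,
    op_mutation,
    op_perturbation,
    op_pruning,
    op_scout,
    op_teaching,
)
from .scoring import ScoreCache, ScoredDag, score_adjacency
from .sem import Dataset

__all__ = [
    "HHConfig",
    "SlidingWindow",
    "CreditState",
    "SubPopulation",
    "compute_fir",
    "credit_assignment",
    "select_operator",
    "migrate",
    "switch_search_space",
    "run",
    "N_OPERATORS",
]

N_OPERATORS = 13


@dataclass
class HHConfig:
    """Run configuration; defaults follow the method's published settings.

    ``l_max`` defaults to ``2 * n`` and ``mu`` to ``ln m`` at run time when
    left as None.
    """

    p: float = 0.1
    q: float = 0.5
    W: int = 10
    C: float = 10.0
    D: float = 0.5
    n_pop: int = 50
    sn: int = 5
    l_max: int | None = None
    max_it: int = 5000
    lm: int = 20
    mu: float | None = None
    zj: float = 0.5
    alpha: float = 0.01
    k_lss: int = 10
    seed: int | None = None

    def __post_init__(self):
        if not (0 < self.D < 1):
            raise ValueError("decay factor D must lie in (0, 1)")
        if self.n_pop < 1 or self.sn < 1 or self.sn > self.n_pop:
            raise ValueError("need 1 <= sn <= n_pop")

    @classmethod
    def from_yaml(cls, path) -> "HHConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


class SlidingWindow:
    """FIFO of (operator id, FIR) pairs with capacity W."""

    def __init__(self, W: int):
        self._q: deque = deque(maxlen=W)
        self.W = W

    def push(self, op_id: int, fir: float) -> None:
        self._q.append((int(op_id), float(fir)))

    def __iter__(self):
        return iter(self._q)

    def __len__(self):
        return len(self._q)


class CreditState:
    """Per-subgroup bandit state: window, rewards, ranks, credits, plays."""

    def __init__(self, n_ops: int = N_OPERATORS, W: int = 10, D: float = 0.5,
                 rng: np.random.Generator | None = None):
        self.n_ops = n_ops
        self.window = SlidingWindow(W)
        self.D = D
        self.reward = np.zeros(n_ops)
        self.rank = np.zeros(n_ops, dtype=int)
        self.decayed = np.zeros(n_ops)
        self.frr = np.zeros(n_ops)
        self.plays = np.zeros(n_ops, dtype=int)
        self.fir_max_seen = 0.0
        self.rng = np.random.default_rng() if rng is None else rng

    def record(self, op_id: int, fir: float) -> None:
        self.window.push(op_id, fir)
        self.plays[op_id - 1] += 1


def compute_fir(parent_score: float, child_score: float, state: CreditState) -> float:
    """Fitness improvement rate of a move, rescaled into (0.1, 0.5).

    The raw rate is the relative score gain; it is mapped linearly into the
    interval against the largest raw rate seen so far in the run, so early
    easy improvements do not dwarf late hard-won ones.  No improvement (or a
    worsening move) yields 0.
    """
    if parent_score == 0:
        return 0.0
    raw = max(0.0, (child_score - parent_score) / abs(parent_score))
    if raw == 0.0:
        return 0.0
    state.fir_max_seen = max(state.fir_max_seen, raw)
    return 0.1 + 0.4 * min(raw / state.fir_max_seen, 1.0)


def credit_assignment(state: CreditState) -> np.ndarray:
    """Decayed rank-based credits (FRR) from the sliding window.

    Rewards are per-operator FIR sums over the window; operators are ranked
    by descending reward (rank 1 best, stable tie-break by id), decayed as
    ``D**rank * reward`` and normalised to sum to one.  Operators absent
    from the window get FRR 0; an all-zero window yields uniform credit over
    the operators present.
    """
    rewards: dict[int, float] = {}
    for op_id, fir in state.window:
        rewards[op_id] = rewards.get(op_id, 0.0) + fir
    state.reward = np.zeros(state.n_ops)
    state.rank = np.zeros(state.n_ops, dtype=int)
    state.decayed = np.zeros(state.n_ops)
    state.frr = np.zeros(state.n_ops)
    if not rewards:
        return state.frr
    for op_id, r in rewards.items():
        state.reward[op_id - 1] = r
    present = sorted(rewards, key=lambda o: (-rewards[o], o))
    total = 0.0
    for rank, op_id in enumerate(present, start=1):
        state.rank[op_id - 1] = rank
        state.decayed[op_id - 1] = (state.D ** rank) * rewards[op_id]
        total += state.decayed[op_id - 1]
    if total > 0:
        state.frr = state.decayed / total
    else:  # all-zero rewards: uniform over operators in the window
        for op_id in present:
            state.frr[op_id - 1] = 1.0 / len(present)
    return state.frr


def select_operator(state: CreditState, C: float,
                    rng: np.random.Generator | None = None) -> int:
    """UCB operator choice: ``FRR_i + C * sqrt(2 ln(sum n_j) / n_i)``.

    While any operator is still unplayed, one of the unplayed ones is chosen
    uniformly at random (cold start).  Ties break toward the smallest id.
    The caller records the play.
    """
    rng = state.rng if rng is None else rng
    unplayed = np.flatnonzero(state.plays == 0)
    if unplayed.size:
        return int(rng.choice(unplayed)) + 1
    total = state.plays.sum()
    values = state.frr + C * np.sqrt(2.0 * math.log(total) / state.plays)
    return int(np.argmax(values)) + 1


@dataclass
class SubPopulation:
    """One subgroup: members, its bandit, and migration bookkeeping."""

    individuals: list
    credit: CreditState
    rng: np.random.Generator
    iterations_since_migration: int = 0
    rr_ptr: int = 0  # round-robin pointer for individual-level operators

    @property
    def local_best(self) -> Individual:
        return max(self.individuals, key=lambda ind: ind.best_score)


def migrate(
    subpops: list[SubPopulation],
    gbest: Individual,
    config: HHConfig,
    n_nodes: int,
    ctx: OperatorContext,
    rng: np.random.Generator,
) -> bool:
    """Ring exchange of best/worst structures between subgroups.

    Eligible only when every subgroup has waited ``min(100, n)`` iterations.
    If more than 60% of the subgroup bests are close relatives of the global
    best (Hamming distance < 4) migration is skipped and those bests are
    perturbed instead.  Returns True when the counters were reset.
    """
    if len(subpops) < 2:
        return False
    interval = min(100, n_nodes)
    if any(sp.iterations_since_migration < interval for sp in subpops):
        return False
    bests = [sp.local_best for sp in subpops]
    dists = [int(np.sum(b.best_adj != gbest.adj)) for b in bests]
    relatives = [k for k, d in enumerate(dists) if d < 4]
    rate = len(relatives) / len(subpops)
    if rate > 0.6:
        for k in relatives:
            sp = subpops[k]
            j = max(range(len(sp.individuals)), key=lambda i: sp.individuals[i].score)
            sp.individuals[j] = op_perturbation(sp.individuals[j], ctx)
    else:
        best_copies = []
        for sp in subpops:
            j = max(range(len(sp.individuals)), key=lambda i: sp.individuals[i].score)
            best_copies.append(sp.individuals[j].copy())
        for k, sp in enumerate(subpops):
            incoming = best_copies[(k - 1) % len(subpops)]
            j = min(range(len(sp.individuals)), key=lambda i: sp.individuals[i].score)
            sp.individuals[j] = incoming
    for sp in subpops:
        sp.iterations_since_migration = 0
    return True


def switch_search_space(ctx: OperatorContext) -> bool:
    """Switch restart operators from GSS to CSS on stagnation; one-way."""
    if ctx.active_restart_space != "GSS" or ctx.L < ctx.L_max:
        return False
    ctx.active_restart_space = "CSS"
    ctx.L = 0
    return True


def _initial_population(
    ctx: OperatorContext, n_pop: int, rng: np.random.Generator
) -> list[Individual]:
    """Seed individuals with the constrained edges plus sparse random GSS edges.

    Every individual starts from the required edges and the non-conflicting
    V-structure edges; each remaining GSS pair is then added (in a random
    legal direction) with probability 2/n, and cycles are repaired.
    """
    n = ctx.n
    base = np.zeros((n, n), dtype=bool)
    for (i, j) in ctx.required_idx:
        base[i, j] = True
    for (i, j) in ctx.vstruct_idx:
        if not ctx.forbidden_mask[i, j] and not base[j, i]:
            base[i, j] = True
    base = repair_cycles(base, list(ctx.required_idx), rng)
    gss = ctx.spaces.gss
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if gss[i, j]]
    out = []
    p_add = 2.0 / max(n, 2)
    for _ in range(n_pop):
        adj = base.copy()
        recent: list[tuple[int, int]] = []
        for (i, j) in pairs:
            if adj[i, j] or adj[j, i] or rng.random() >= p_add:
                continue
            a, b = (i, j) if rng.random() < 0.5 else (j, i)
            if ctx.forbidden_mask[a, b]:
                a, b = b, a
            if ctx.forbidden_mask[a, b]:
                continue
            adj[a, b] = True
            recent.append((a, b))
        adj = repair_cycles(adj, [e for e in ctx.required_idx if adj[e]], rng, recent)
        out.append(Individual(adj, score_adjacency(adj, ctx.cache)))
    return out


_INDIVIDUAL_OPS = {1, 2, 3, 4, 5, 13}
_GBEST_OPS = {6, 9}


def _apply_operator(
    op_id: int,
    sp: SubPopulation,
    ctx: OperatorContext,
    gbest: Individual,
    hook: Callable | None,
) -> tuple[float, float]:
    """Apply one operator to the subgroup; return (parent, child) scores for
    the FIR.  Individual-level operators act on a round-robin member;
    restart operators act on the global best and their product replaces the
    subgroup's worst member; population operators act on the whole subgroup
    and the FIR is measured on the subgroup's best score."""
    pop = sp.individuals
    ctx.rng = sp.rng
    if op_id in _INDIVIDUAL_OPS:
        k = sp.rr_ptr % len(pop)
        sp.rr_ptr += 1
        target = pop[k]
        if op_id == 1:
            new = op_mutation(target, ctx)
        elif op_id == 2:
            new = op_perturbation(target, ctx)
        elif op_id == 3:
            new = op_cognitive(target, ctx)
        elif op_id == 4:
            new = op_cooperative(target, gbest.adj, ctx)
        elif op_id == 5:
            new = op_chemotactic(target, ctx)
        else:
            new = op_pruning(target, ctx)
        pop[k] = new  # Accept All Moves
        if hook is not None:
            hook(new.adj)
        return target.score, new.score
    if op_id in _GBEST_OPS:
        if op_id == 6:
            c3 = min(1.0, 0.1 + 0.9 * ctx.L / max(ctx.L_max, 1))
            if sp.rng.random() >= c3:
                return gbest.score, gbest.score
            new = op_elimination_dispersal(gbest, ctx)
        else:
            if ctx.L <= ctx.lm:
                return gbest.score, gbest.score
            new = op_scout(gbest, ctx)
        j = min(range(len(pop)), key=lambda i: pop[i].score)
        pop[j] = new
        if hook is not None:
            hook(new.adj)
        return gbest.score, new.score
    # population-level
    parent = max(ind.score for ind in pop)
    if op_id == 7:
        new_pop = op_bees(pop, "employed", ctx)
    elif op_id == 8:
        new_pop = op_bees(pop, "onlooker", ctx)
    elif op_id == 10:
        new_pop = op_moth_flame(pop, ctx)
    elif op_id == 11:
        new_pop = op_teaching(pop, ctx)
    elif op_id == 12:
        new_pop = op_expert_knowledge(pop, ctx)
    else:
        raise ValueError(f"unknown operator id {op_id}")
    sp.individuals[:] = new_pop
    if hook is not None:
        for ind in new_pop:
            hook(ind.adj)
    return parent, max(ind.score for ind in new_pop)


def run(
    data: Dataset,
    config: HHConfig | None = None,
    hard: HardConstraints | None = None,
    truth: DagStructure | None = None,
    structure_hook: Callable | None = None,
) -> tuple[ScoredDag, dict]:
    """Full structure-learning pipeline; returns the best DAG and a report.

    Pipeline: mine search spaces, apply hard constraints, seed the
    population, loop the per-subgroup bandits with migration and space
    switching, prune the global best, and package the result.
    """
    config = HHConfig() if config is None else config
    hard = HardConstraints() if hard is None else hard
    n, m = data.n, data.m
    master = np.random.default_rng(config.seed)
    t_start = time.perf_counter()

    cache = ScoreCache(data)
    spaces = build_search_spaces(data, config.alpha, config.k_lss)
    spaces = apply_hard_constraints(spaces, hard)
    L_max = config.l_max if config.l_max is not None else 2 * n
    mu = config.mu if config.mu is not None else math.log(m)

    ctx = OperatorContext(
        data=data, cache=cache, spaces=spaces, hard=hard, rng=master,
        t=0, max_it=config.max_it, L=0, L_max=L_max, lm=config.lm,
        mu=mu, zj=config.zj,
    )

    sn = min(config.sn, config.n_pop)
    size = max(1, config.n_pop // sn)
    sub_rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(
        entropy=int(master.integers(2**31))).spawn(sn)]
    individuals = _initial_population(ctx, size * sn, master)
    if structure_hook is not None:
        for ind in individuals:
            structure_hook(ind.adj)
    subpops = [
        SubPopulation(
            individuals=individuals[k * size:(k + 1) * size],
            credit=CreditState(N_OPERATORS, config.W, config.D, sub_rngs[k]),
            rng=sub_rngs[k],
        )
        for k in range(sn)
    ]

    gbest = max(individuals, key=lambda ind: ind.score).copy()
    initial_best = gbest.score
    score_trace = []
    usage = {op_id: 0 for op_id in OPERATOR_NAMES}
    L = 0
    switched = False
    iterations = 0
    for t in range(1, config.max_it + 1):
        iterations = t
        ctx.t = t
        ctx.L = L
        before = gbest.score
        for sp in subpops:
            op_id = select_operator(sp.credit, config.C)
            parent, child = _apply_operator(op_id, sp, ctx, gbest, structure_hook)
            fir = compute_fir(parent, child, sp.credit)
            sp.credit.record(op_id, fir)
            credit_assignment(sp.credit)
            usage[op_id] += 1
            sp.iterations_since_migration += 1
            best_member = max(sp.individuals, key=lambda ind: ind.best_score)
            if best_member.best_score > gbest.score:
                gbest = Individual(best_member.best_adj.copy(), best_member.best_score)
        L = 0 if gbest.score > before else L + 1
        ctx.L = L
        score_trace.append(gbest.score)
        migrate(subpops, gbest, config, n, ctx, master)
        if L >= L_max and not switched:
            switched = switch_search_space(ctx)
            L = ctx.L

    gbest = op_pruning(gbest, ctx)
    if structure_hook is not None:
        structure_hook(gbest.adj)
    rt = time.perf_counter() - t_start

    structure = DagStructure(data.labels, gbest.adj)
    per_node = np.array(
        [cache.local(j, np.flatnonzero(gbest.adj[:, j])) for j in range(n)]
    )
    scored = ScoredDag(structure, float(per_node.sum()), per_node)

    report = {
        "n": n,
        "m": m,
        "iterations": iterations,
        "score": scored.total_score,
        "initial_best_score": initial_best,
        "score_trace": score_trace,
        "operator_usage": {OPERATOR_NAMES[k]: v for k, v in usage.items()},
        "frr_final": [sp.credit.frr.tolist() for sp in subpops],
        "space_switched": switched,
        "rt_seconds": rt,
        "n_edges": structure.n_edges,
        "per_node_scores": per_node.tolist(),
    }
    if truth is not None:
        met = structural_metrics(structure, truth)
        report["metrics"] = {
            "AE": met.AE, "DE": met.DE, "RE": met.RE, "F1": met.F1,
            "learned_edges": met.learned_edges, "true_edges": met.true_edges,
        }
        from .scoring import network_score

        report["SBS"] = network_score(truth, data, cache).total_score
    return scored, report
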