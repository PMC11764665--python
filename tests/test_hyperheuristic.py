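import math

import numpy as np
import pytest

from conftest import make_ctx
from dagbandit.constraints import HardConstraints, sample_hard_constraints
from dagbandit.graph import random_dag
from dagbandit.hyperheuristic import (
    CreditState,
    HHConfig,
    SubPopulation,
    compute_fir,
    credit_assignment,
    migrate,
    run,
    select_operator,
    switch_search_space,
)
from dagbandit.operators import Individual
from dagbandit.scoring import network_score, score_adjacency
from dagbandit.sem import Dataset, generate_dataset


class TestComputeFir:
    def test_no_improvement_is_zero(self):
        state = CreditState()
        assert compute_fir(-100.0, -100.0, state) == 0.0
        assert compute_fir(-100.0, -150.0, state) == 0.0  # worsening move

    def test_first_improvement_maps_to_top_of_interval(self):
        state = CreditState()
        assert compute_fir(-100.0, -90.0, state) == pytest.approx(0.5)

    def test_raw_rate_is_relative_gain(self):
        state = CreditState()
        compute_fir(-100.0, -90.0, state)  # raw 0.1 becomes the max seen
        assert state.fir_max_seen == pytest.approx(0.1)
        # half the max raw rate sits mid-interval
        assert compute_fir(-100.0, -95.0, state) == pytest.approx(0.3)

    def test_degenerate_parent_score(self):
        assert compute_fir(0.0, 5.0, CreditState()) == 0.0


class TestCreditAssignment:
    def test_single_operator_gets_full_credit(self):
        state = CreditState(W=10)
        state.record(3, 0.2)
        frr = credit_assignment(state)
        assert frr[2] == pytest.approx(1.0)
        assert frr.sum() == pytest.approx(1.0)

    def test_hand_executed_trace(self):
        """window [(1,0.2),(2,0.4),(1,0.1)], D=0.5:
        Reward=(0.3,0.4), ranks op2=1 op1=2, Decay=(0.075,0.2),
        FRR=(0.2727..., 0.7272...)."""
        state = CreditState(W=10, D=0.5)
        for op, fir in [(1, 0.2), (2, 0.4), (1, 0.1)]:
            state.record(op, fir)
        frr = credit_assignment(state)
        assert state.reward[0] == pytest.approx(0.3)
        assert state.reward[1] == pytest.approx(0.4)
        assert (state.rank[0], state.rank[1]) == (2, 1)
        assert state.decayed[0] == pytest.approx(0.075)
        assert state.decayed[1] == pytest.approx(0.2)
        assert frr[0] == pytest.approx(0.075 / 0.275)
        assert frr[1] == pytest.approx(0.2 / 0.275)

    def test_scale_invariance(self):
        s1, s2 = CreditState(), CreditState()
        for op, fir in [(1, 0.2), (2, 0.4), (1, 0.1)]:
            s1.record(op, fir)
            s2.record(op, 2 * fir)
        assert np.allclose(credit_assignment(s1), credit_assignment(s2))

    def test_all_zero_rewards_give_uniform_credit(self):
        state = CreditState()
        state.record(4, 0.0)
        state.record(9, 0.0)
        frr = credit_assignment(state)
        assert frr[3] == pytest.approx(0.5)
        assert frr[8] == pytest.approx(0.5)

    def test_operators_absent_from_window_get_zero(self):
        state = CreditState(W=2)
        state.record(1, 0.3)
        state.record(2, 0.2)
        state.record(3, 0.1)  # evicts op 1's record
        frr = credit_assignment(state)
        assert frr[0] == 0.0


class TestSelectOperator:
    def test_cold_start_prefers_unplayed(self):
        state = CreditState(n_ops=3, rng=np.random.default_rng(0))
        state.plays = np.array([0, 5, 7])
        assert select_operator(state, C=10.0) == 1

    def test_pure_exploitation(self):
        state = CreditState(n_ops=2, rng=np.random.default_rng(0))
        state.plays = np.array([5, 5])
        state.frr = np.array([0.7, 0.3])
        assert select_operator(state, C=0.0) == 1

    def test_hand_evaluated_ucb(self):
        state = CreditState(n_ops=2, rng=np.random.default_rng(0))
        state.plays = np.array([10, 5])
        state.frr = np.array([0.7, 0.3])
        total = 15
        v1 = 0.7 + math.sqrt(2 * math.log(total) / 10)
        v2 = 0.3 + math.sqrt(2 * math.log(total) / 5)
        assert v1 == pytest.approx(1.436, abs=1e-3)
        assert v2 == pytest.approx(1.341, abs=1e-3)
        assert select_operator(state, C=1.0) == 1

    def test_always_rewarded_operator_dominates(self):
        """A stubbed operator returning FIR 0.5 on every play ends up played
        more than any other after 200 rounds."""
        state = CreditState(n_ops=3, W=10, D=0.5, rng=np.random.default_rng(1))
        for _ in range(200):
            op = select_operator(state, C=0.5)
            fir = 0.5 if op == 2 else 0.0
            state.record(op, fir)
            credit_assignment(state)
        assert state.plays[1] > state.plays[0]
        assert state.plays[1] > state.plays[2]


def _subpop(ctx, adjs, rng):
    inds = [Individual(a.copy(), score_adjacency(a, ctx.cache)) for a in adjs]
    return SubPopulation(
        individuals=inds, credit=CreditState(rng=rng), rng=rng,
        iterations_since_migration=1000,
    )


class TestMigration:
    def _setup(self, seed=0, n=6):
        dag, data, ctx = make_ctx(seed=seed, n=n, e=7, unrestricted=True)
        rng = np.random.default_rng(seed)
        return dag, ctx, rng

    def test_below_interval_no_change(self):
        dag, ctx, rng = self._setup()
        a = dag.adjacency
        subs = [_subpop(ctx, [a], rng) for _ in range(2)]
        subs[0].iterations_since_migration = 0
        before = [s.individuals[0].adj.copy() for s in subs]
        assert not migrate(subs, subs[0].individuals[0], HHConfig(), 6, ctx, rng)
        for s, b in zip(subs, before):
            assert np.array_equal(s.individuals[0].adj, b)

    def test_inbreeding_skips_migration(self):
        dag, ctx, rng = self._setup(1)
        a = dag.adjacency
        gbest = Individual(a.copy(), score_adjacency(a, ctx.cache))
        subs = [_subpop(ctx, [a], rng) for _ in range(3)]
        assert migrate(subs, gbest, HHConfig(), 6, ctx, rng)
        # identical bests: rate 1 > 0.6, so no swap happened; counters reset
        for s in subs:
            assert s.iterations_since_migration == 0

    def test_ring_swap_best_replaces_worst(self):
        dag, ctx, rng = self._setup(2)
        good = dag.adjacency
        bad = np.zeros_like(good)
        gbest = Individual(good.copy(), score_adjacency(good, ctx.cache))
        # distinct local bests far from gbest: use empty + different graphs
        g2 = random_dag(6, 3, 99).adjacency
        subs = [_subpop(ctx, [good, bad], rng), _subpop(ctx, [g2, bad], rng)]
        s_good = score_adjacency(good, ctx.cache)
        assert migrate(subs, gbest, HHConfig(), 6, ctx, rng)
        # best of subgroup 0 must now sit in subgroup 1 (and vice versa)
        assert any(np.array_equal(i.adj, good) for i in subs[1].individuals)
        assert any(np.array_equal(i.adj, g2) for i in subs[0].individuals)
        _ = s_good


class TestSwitchSearchSpace:
    def test_trigger_and_one_way(self):
        _, _, ctx = make_ctx(seed=3)
        ctx.L, ctx.L_max = 3, 12
        assert not switch_search_space(ctx)
        assert ctx.active_restart_space == "GSS"
        ctx.L = 12
        assert switch_search_space(ctx)
        assert ctx.active_restart_space == "CSS"
        assert ctx.L == 0
        ctx.L = 12
        assert not switch_search_space(ctx)  # one-way
        assert ctx.active_restart_space == "CSS"


class TestRun:
    def test_single_variable(self):
        rng = np.random.default_rng(0)
        data = Dataset(rng.standard_normal((100, 1)), ("only",))
        scored, report = run(data, HHConfig(n_pop=4, sn=2, max_it=5, seed=1))
        assert scored.structure.n_edges == 0
        assert scored.total_score == pytest.approx(-(data.values**2).sum() / 2)

    def test_reproducible_per_seed(self):
        dag = random_dag(7, 9, 5)
        data, _ = generate_dataset(dag, 1, 400, seed=6)
        cfg = HHConfig(n_pop=10, sn=2, max_it=30, seed=11)
        s1, r1 = run(data, cfg)
        s2, r2 = run(data, cfg)
        assert s1.structure == s2.structure
        assert r1["score_trace"] == r2["score_trace"]

    def test_best_score_trace_is_monotone(self):
        dag = random_dag(8, 10, 6)
        data, _ = generate_dataset(dag, 2, 500, seed=7)
        _, report = run(data, HHConfig(n_pop=10, sn=2, max_it=40, seed=3))
        trace = report["score_trace"]
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_output_beats_initial_best_and_truth(self):
        dag = random_dag(8, 10, 8)
        data, _ = generate_dataset(dag, 1, 1000, seed=9)
        hc = sample_hard_constraints(dag, 0.1, 0.5, 10)
        scored, report = run(
            data, HHConfig(n_pop=12, sn=3, max_it=80, seed=4), hc, truth=dag
        )
        assert scored.total_score >= report["initial_best_score"]
        assert scored.total_score >= report["SBS"] - 1e-6

    def test_output_respects_hard_constraints(self):
        dag = random_dag(7, 9, 12)
        data, _ = generate_dataset(dag, 3, 400, seed=13)
        hc = sample_hard_constraints(dag, 0.3, 0.5, 14)
        scored, _ = run(data, HHConfig(n_pop=8, sn=2, max_it=30, seed=5), hc)
        edges = set(scored.structure.edges())
        assert hc.required <= edges
        assert not (hc.forbidden & edges)

    def test_report_carries_metrics_and_usage(self):
        dag = random_dag(6, 7, 20)
        data, _ = generate_dataset(dag, 1, 300, seed=21)
        _, report = run(data, HHConfig(n_pop=8, sn=2, max_it=20, seed=6), truth=dag)
        assert set(report["metrics"]) == {
            "AE", "DE", "RE", "F1", "learned_edges", "true_edges"
        }
        assert sum(report["operator_usage"].values()) == report["iterations"] * 2
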