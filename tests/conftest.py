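import math

import numpy as np
import pytest

from dagbandit.constraints import (
    HardConstraints,
    SearchSpaces,
    apply_hard_constraints,
    build_search_spaces,
    sample_hard_constraints,
)
from dagbandit.graph import random_dag
from dagbandit.operators import Individual, OperatorContext
from dagbandit.scoring import ScoreCache, score_adjacency
from dagbandit.sem import generate_dataset


def full_spaces(labels):
    """Unrestricted search spaces: every pair in CSS and GSS, full LSS."""
    n = len(labels)
    allp = ~np.eye(n, dtype=bool)
    lss = tuple(tuple(i for i in range(n) if i != j) for j in range(n))
    return SearchSpaces(labels, allp, allp, lss, frozenset())


def make_ctx(
    dag=None,
    n=6,
    e=6,
    model=1,
    m=300,
    seed=0,
    alpha=0.01,
    p=0.0,
    q=0.0,
    unrestricted=False,
    hard=None,
    **ctx_kw,
):
    """A ready-to-use operator context over simulated data.

    Returns (truth dag, dataset, ctx).
    """
    if dag is None:
        dag = random_dag(n, e, seed)
    data, _ = generate_dataset(dag, model, m, seed + 1)
    cache = ScoreCache(data)
    if hard is None:
        if p > 0 or q > 0:
            hard = sample_hard_constraints(dag, p, q, seed + 2)
        else:
            hard = HardConstraints()
    if unrestricted:
        spaces = full_spaces(data.labels)
    else:
        spaces = apply_hard_constraints(build_search_spaces(data, alpha), hard)
    kw = dict(
        data=data,
        cache=cache,
        spaces=spaces,
        hard=hard,
        rng=np.random.default_rng(seed + 3),
        t=0,
        max_it=100,
        L=0,
        L_max=2 * dag.n,
        lm=3,
        mu=math.log(m),
        zj=0.5,
    )
    kw.update(ctx_kw)
    return dag, data, OperatorContext(**kw)


def make_individual(ctx, adj=None):
    n = ctx.n
    if adj is None:
        adj = np.zeros((n, n), dtype=bool)
        for (i, j) in ctx.required_idx:
            adj[i, j] = True
    return Individual(adj.copy(), score_adjacency(adj, ctx.cache))


def assert_respects_constraints(adj, ctx):
    from dagbandit.graph import is_acyclic

    assert is_acyclic(adj)
    for e in ctx.required_idx:
        assert adj[e], f"required edge {e} missing"
    assert not np.any(adj & ctx.forbidden_mask), "forbidden edge present"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
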