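"""Decomposable BIC scoring of a DAG under the linear SEM.

The score of a graph is the sum over nodes of a local family score

    score(j | pa) = -( RSS_j / 2 + (k/2) * ln m ),        k = |pa(X_j)|

where ``RSS_j`` is the residual sum of squares of the intercept-free
ordinary-least-squares regression of column ``j`` on its parent columns.
Higher is better.  Because the score decomposes over families, single-edge
moves (add / delete / reverse) can be evaluated by rescoring only the one or
two affected families; :class:`ScoreCache` memoises family scores and holds
the dataset Gram matrix so a local score costs O(k^3) independent of m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import (
    IncompatibleStructuresError,
    InsufficientDataError,
    InvalidMoveError,
)
from .graph import DagStructure, would_create_cycle
from .sem import Dataset

__all__ = ["ScoreCache", "ScoredDag", "local_score", "network_score", "delta_score"]


class ScoreCache:
    """Family-score memo bound to one dataset.

    Stores ``G = X^T X`` once; a family score then needs only the relevant
    submatrix of ``G``.  Collinear parent sets are handled with the
    pseudo-inverse, so degenerate families that arise transiently during
    search never abort a run.
    """

    def __init__(self, data: Dataset):
        X = data.values
        self.m = X.shape[0]
        self.n = X.shape[1]
        self.labels = data.labels
        self.gram = X.T @ X
        self._log_m = float(np.log(self.m))
        self._memo: dict[tuple[int, tuple[int, ...]], float] = {}
        self.hits = 0
        self.misses = 0

    def fingerprint(self) -> tuple:
        return (self.labels, self.m, float(self.gram.sum()))

    def local(self, node: int, parents: Iterable[int]) -> float:
        pa = tuple(sorted(int(p) for p in parents))
        if node in pa:
            raise InvalidMoveError(f"node {node} cannot be its own parent")
        key = (int(node), pa)
        cached = self._memo.get(key)
        if cached is not None:
            self.hits += 1
            return cached
        self.misses += 1
        k = len(pa)
        if self.m <= k:
            raise InsufficientDataError(
                f"m={self.m} samples cannot fit {k} parents for node {node}"
            )
        G = self.gram
        if k == 0:
            rss = G[node, node]
        else:
            idx = list(pa)
            Gpp = G[np.ix_(idx, idx)]
            Gpj = G[idx, node]
            try:
                theta = np.linalg.solve(Gpp, Gpj)
            except np.linalg.LinAlgError:
                theta = np.linalg.pinv(Gpp) @ Gpj
            rss = max(G[node, node] - Gpj @ theta, 0.0)
        score = -(rss / 2.0 + (k / 2.0) * self._log_m)
        self._memo[key] = score
        return score


def _check_cache(data: Dataset, cache: ScoreCache | None) -> ScoreCache:
    if cache is None:
        return ScoreCache(data)
    if cache.labels != data.labels or cache.m != data.m:
        raise IncompatibleStructuresError("score cache was built for a different dataset")
    return cache


def local_score(
    node: int, parents: Iterable[int], data: Dataset, cache: ScoreCache | None = None
) -> float:
    """BIC family score of ``node`` given ``parents`` (column indices)."""
    return _check_cache(data, cache).local(node, parents)


@dataclass(frozen=True)
class ScoredDag:
    """A DAG with its total BIC score and the per-node decomposition."""

    structure: DagStructure
    total_score: float
    per_node_scores: np.ndarray = field(repr=False)

    def __post_init__(self):
        s = np.asarray(self.per_node_scores, dtype=float)
        if abs(s.sum() - self.total_score) > 1e-9 * max(1.0, abs(self.total_score)):
            raise ValueError("total_score inconsistent with per-node scores")
        s = s.copy()
        s.setflags(write=False)
        object.__setattr__(self, "per_node_scores", s)


def network_score(
    dag: DagStructure, data: Dataset, cache: ScoreCache | None = None
) -> ScoredDag:
    """Total BIC score of ``dag`` on ``data``: the sum of family scores."""
    if dag.labels != data.labels:
        raise IncompatibleStructuresError("structure and dataset label mismatch")
    cache = _check_cache(data, cache)
    adj = dag.adjacency
    per = np.array(
        [cache.local(j, np.flatnonzero(adj[:, j])) for j in range(dag.n)]
    )
    return ScoredDag(dag, float(per.sum()), per)


def score_adjacency(adj: np.ndarray, cache: ScoreCache) -> float:
    """Total score of a raw boolean adjacency matrix (internal fast path)."""
    return float(
        sum(cache.local(j, np.flatnonzero(adj[:, j])) for j in range(adj.shape[1]))
    )


def delta_adjacency(
    adj: np.ndarray, cache: ScoreCache, move: tuple[str, int, int]
) -> float:
    """Score change of a single move on a raw adjacency matrix.

    ``move`` is ``(kind, i, j)`` with kind in {'add','delete','reverse'} for
    the edge ``i -> j``.  Only the affected families are rescored; legality
    (acyclicity, existence) is the caller's responsibility on this fast path.
    """
    kind, i, j = move
    pa_j = np.flatnonzero(adj[:, j])
    old_j = cache.local(j, pa_j)
    if kind == "add":
        return cache.local(j, np.append(pa_j, i)) - old_j
    if kind == "delete":
        return cache.local(j, pa_j[pa_j != i]) - old_j
    if kind == "reverse":
        pa_i = np.flatnonzero(adj[:, i])
        old_i = cache.local(i, pa_i)
        new_j = cache.local(j, pa_j[pa_j != i])
        new_i = cache.local(i, np.append(pa_i, j))
        return (new_j + new_i) - (old_j + old_i)
    raise InvalidMoveError(f"unknown move kind {kind!r}")


def delta_score(
    dag: DagStructure,
    data: Dataset,
    cache: ScoreCache | None,
    move: tuple[str, str, str],
) -> float:
    """Validated score delta for a move named by labels ``(kind, parent, child)``.

    Equals ``network_score(after) - network_score(before)`` but touches only
    the one (add/delete) or two (reverse) affected families.
    """
    cache = _check_cache(data, cache)
    kind, a, b = move
    try:
        i, j = dag.labels.index(a), dag.labels.index(b)
    except ValueError as exc:
        raise InvalidMoveError(f"unknown node in move: {exc}") from exc
    adj = dag.adjacency
    if kind == "add":
        if adj[i, j]:
            raise InvalidMoveError(f"edge {a}->{b} already present")
        if would_create_cycle(adj, i, j):
            raise InvalidMoveError(f"adding {a}->{b} would create a cycle")
    elif kind == "delete":
        if not adj[i, j]:
            raise InvalidMoveError(f"edge {a}->{b} not present")
    elif kind == "reverse":
        if not adj[i, j]:
            raise InvalidMoveError(f"edge {a}->{b} not present")
        tmp = adj.copy()
        tmp[i, j] = False
        if would_create_cycle(tmp, j, i):
            raise InvalidMoveError(f"reversing {a}->{b} would create a cycle")
    else:
        raise InvalidMoveError(f"unknown move kind {kind!r}")
    return delta_adjacency(adj, cache, (kind, i, j))
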