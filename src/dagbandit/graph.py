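"""DAG representation, acyclicity maintenance, structural metrics and I/O.

The hypothesis object of the whole package is a directed acyclic graph over
named variables, stored as a dense boolean adjacency matrix: entry ``(i, j)``
is ``True`` iff the graph has the directed edge ``i -> j``.  Learned graphs
are compared against a ground truth with the added / deleted / reversed edge
counts (AE, DE, RE) and the directed-edge F1 score.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    FormatError,
    IncompatibleStructuresError,
    InvalidStructureError,
    ConstraintConflictError,
)

__all__ = [
    "DagStructure",
    "StructuralMetrics",
    "is_acyclic",
    "would_create_cycle",
    "repair_cycles",
    "hamming_distance",
    "structural_metrics",
    "f1_from_counts",
    "topological_order",
    "random_dag",
    "load_structure",
    "write_structure",
]


def _check_adjacency(adjacency: np.ndarray) -> np.ndarray:
    adj = np.asarray(adjacency, dtype=bool)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise InvalidStructureError(f"adjacency must be square, got shape {adj.shape}")
    if np.any(np.diag(adj)):
        raise InvalidStructureError("adjacency has a self-loop (true diagonal entry)")
    return adj


def is_acyclic(adjacency: np.ndarray) -> bool:
    """True iff the boolean adjacency matrix has no directed cycle.

    Uses Kahn's algorithm (iterative zero-indegree elimination); pure function.
    """
    adj = _check_adjacency(adjacency).copy()
    n = adj.shape[0]
    alive = np.ones(n, dtype=bool)
    while alive.any():
        indeg = adj[alive][:, alive].sum(axis=0)
        sources = np.flatnonzero(alive)[indeg == 0]
        if sources.size == 0:
            return False
        alive[sources] = False
        adj[sources, :] = False
    return True


def would_create_cycle(adjacency: np.ndarray, u: int, v: int) -> bool:
    """Would adding the edge ``u -> v`` create a directed cycle?

    Equivalent to asking whether ``u`` is reachable from ``v``.
    """
    if u == v:
        return True
    n = adjacency.shape[0]
    seen = np.zeros(n, dtype=bool)
    frontier = np.zeros(n, dtype=bool)
    frontier[v] = True
    while frontier.any():
        if frontier[u]:
            return True
        seen |= frontier
        frontier = adjacency[frontier].any(axis=0) & ~seen
    return False


def _find_cycle(adj: np.ndarray) -> list[tuple[int, int]]:
    """Return the edges of one directed cycle, or [] if acyclic (DFS)."""
    n = adj.shape[0]
    color = np.zeros(n, dtype=np.int8)  # 0 white, 1 grey, 2 black
    parent_edge: dict[int, int] = {}
    for start in range(n):
        if color[start]:
            continue
        stack = [(start, iter(np.flatnonzero(adj[start])))]
        color[start] = 1
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                nxt = int(nxt)
                if color[nxt] == 1:
                    # back edge: unwind the grey path nxt -> ... -> node
                    cycle = [(node, nxt)]
                    cur = node
                    while cur != nxt:
                        prev = parent_edge[cur]
                        cycle.append((prev, cur))
                        cur = prev
                    cycle.reverse()
                    return cycle
                if color[nxt] == 0:
                    color[nxt] = 1
                    parent_edge[nxt] = node
                    stack.append((nxt, iter(np.flatnonzero(adj[nxt]))))
                    advanced = True
                    break
            if not advanced:
                color[node] = 2
                stack.pop()
    return []


def repair_cycles(
    adjacency: np.ndarray,
    protected_edges: Iterable[tuple[int, int]] = (),
    rng: np.random.Generator | None = None,
    recent: Sequence[tuple[int, int]] = (),
) -> np.ndarray:
    """Break every directed cycle by deleting non-protected edges.

    ``recent`` is an ordered record of edges just copied into the graph by a
    learning step; when a cycle contains one of them the most recently copied
    such edge is removed first, which minimally disturbs that step.  Otherwise
    a uniformly random non-protected edge of the cycle is removed.  Protected
    edges are never removed; if the protected edges are themselves cyclic a
    :class:`ConstraintConflictError` is raised.
    """
    adj = _check_adjacency(adjacency).copy()
    protected = set(protected_edges)
    if protected:
        prot_adj = np.zeros_like(adj)
        for (i, j) in protected:
            prot_adj[i, j] = True
        if not is_acyclic(prot_adj):
            raise ConstraintConflictError("protected edges themselves form a cycle")
    rng = np.random.default_rng() if rng is None else rng
    recent_index = {e: k for k, e in enumerate(recent)}
    while True:
        cycle = _find_cycle(adj)
        if not cycle:
            return adj
        removable = [e for e in cycle if e not in protected]
        if not removable:
            raise ConstraintConflictError("cycle consists entirely of protected edges")
        tagged = [e for e in removable if e in recent_index]
        if tagged:
            victim = max(tagged, key=lambda e: recent_index[e])
        else:
            victim = removable[int(rng.integers(len(removable)))]
        adj[victim] = False


@dataclass(frozen=True)
class DagStructure:
    """A directed acyclic graph over named variables.

    Parameters
    ----------
    labels : tuple of str
        Ordered, unique node names; column/row order of ``adjacency``.
    adjacency : ndarray of bool
        ``adjacency[i, j]`` is True iff the edge ``labels[i] -> labels[j]``
        is present.  Validated to be square, self-loop free and acyclic.
    """

    labels: tuple[str, ...]
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        if len(labels) < 1:
            raise InvalidStructureError("a DAG needs at least one node")
        if len(set(labels)) != len(labels):
            raise InvalidStructureError("duplicate node labels")
        adj = _check_adjacency(self.adjacency)
        if adj.shape[0] != len(labels):
            raise InvalidStructureError("adjacency size does not match label count")
        if not is_acyclic(adj):
            raise InvalidStructureError("graph contains a directed cycle")
        adj = adj.copy()
        adj.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "adjacency", adj)

    @classmethod
    def from_edges(cls, labels: Sequence[str], edges: Iterable[tuple[str, str]]) -> "DagStructure":
        labels = tuple(labels)
        index = {l: i for i, l in enumerate(labels)}
        adj = np.zeros((len(labels), len(labels)), dtype=bool)
        for (a, b) in edges:
            try:
                adj[index[a], index[b]] = True
            except KeyError as exc:
                raise InvalidStructureError(f"edge endpoint {exc} not in labels") from exc
        return cls(labels, adj)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def edges(self) -> list[tuple[str, str]]:
        return [
            (self.labels[i], self.labels[j])
            for i, j in zip(*np.nonzero(self.adjacency))
        ]

    def parents(self, label: str) -> list[str]:
        j = self.labels.index(label)
        return [self.labels[i] for i in np.flatnonzero(self.adjacency[:, j])]

    def __eq__(self, other) -> bool:
        if not isinstance(other, DagStructure):
            return NotImplemented
        return self.labels == other.labels and bool(
            np.array_equal(self.adjacency, other.adjacency)
        )

    def __hash__(self):
        return hash((self.labels, self.adjacency.tobytes()))


@dataclass(frozen=True)
class StructuralMetrics:
    """Edge-level accuracy of a learned DAG against the ground truth.

    AE: edges added (present in learned, absent in truth in either direction).
    DE: edges deleted (present in truth, absent in learned in either direction).
    RE: truth edges recovered with the opposite orientation.
    F1: directed-edge F1, ``2*TP / (2*TP + FP + FN)`` with ``TP = E - DE - RE``,
    ``FP = AE + RE``, ``FN = DE + RE`` where ``E`` is the truth edge count.
    """

    AE: int
    DE: int
    RE: int
    F1: float
    learned_edges: int
    true_edges: int


def f1_from_counts(true_edges: int, AE: int, DE: int, RE: int) -> float:
    """Directed-edge F1 from error counts; a reversed edge counts as one
    false positive and one false negative.  Defined as 1.0 for two empty
    graphs."""
    tp = true_edges - DE - RE
    fp = AE + RE
    fn = DE + RE
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


def _require_same_labels(g1: DagStructure, g2: DagStructure) -> None:
    if g1.labels != g2.labels:
        if set(g1.labels) == set(g2.labels):
            raise IncompatibleStructuresError(
                "label sets match but order differs; reorder before comparing"
            )
        raise IncompatibleStructuresError("structures are over different label sets")


def hamming_distance(g1: DagStructure, g2: DagStructure) -> int:
    """Number of ordered node pairs whose adjacency entries differ.

    A single reversed edge therefore contributes 2.
    """
    _require_same_labels(g1, g2)
    return int(np.sum(g1.adjacency != g2.adjacency))


def _align(truth: DagStructure, learned: DagStructure) -> DagStructure:
    """Reorder ``learned`` to the label order of ``truth`` (by name)."""
    if learned.labels == truth.labels:
        return learned
    if set(learned.labels) != set(truth.labels):
        raise IncompatibleStructuresError("structures are over different label sets")
    perm = [learned.labels.index(l) for l in truth.labels]
    adj = learned.adjacency[np.ix_(perm, perm)]
    return DagStructure(truth.labels, adj)


def structural_metrics(learned: DagStructure, truth: DagStructure) -> StructuralMetrics:
    """AE/DE/RE counts and directed-edge F1 of ``learned`` vs ``truth``.

    Labels are matched by name; orderings may differ.
    """
    learned = _align(truth, learned)
    la, ta = learned.adjacency, truth.adjacency
    # skeleton (either-direction) presence
    l_sk = la | la.T
    t_sk = ta | ta.T
    AE = int(np.sum(la & ~t_sk))
    DE = int(np.sum(ta & ~l_sk))
    RE = int(np.sum(ta & ~la & la.T))
    E = int(ta.sum())
    return StructuralMetrics(
        AE=AE,
        DE=DE,
        RE=RE,
        F1=f1_from_counts(E, AE, DE, RE),
        learned_edges=int(la.sum()),
        true_edges=E,
    )


def topological_order(dag: DagStructure) -> list[str]:
    """Node labels in a topological order; ties broken by label sort order."""
    adj = dag.adjacency
    n = dag.n
    indeg = adj.sum(axis=0).astype(int)
    by_label = sorted(range(n), key=lambda i: dag.labels[i])
    order: list[int] = []
    used = np.zeros(n, dtype=bool)
    while len(order) < n:
        pick = next((i for i in by_label if not used[i] and indeg[i] == 0), None)
        if pick is None:  # unreachable on validated DagStructure
            raise InvalidStructureError("graph contains a directed cycle")
        used[pick] = True
        order.append(pick)
        indeg[adj[pick]] -= 1
    return [dag.labels[i] for i in order]


def random_dag(n: int, e: int, seed: int | np.random.Generator | None = None) -> DagStructure:
    """A uniformly seeded random DAG with exactly ``e`` edges on ``n`` nodes.

    Edges are sampled consistent with a uniformly random node permutation, so
    acyclicity holds by construction.  Node labels are ``X1..Xn``.
    """
    max_e = n * (n - 1) // 2
    if not (0 <= e <= max_e):
        raise ValueError(f"edge count {e} out of range [0, {max_e}] for n={n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    pairs = [(int(perm[i]), int(perm[j])) for i in range(n) for j in range(i + 1, n)]
    chosen = rng.choice(len(pairs), size=e, replace=False) if e else []
    adj = np.zeros((n, n), dtype=bool)
    for k in chosen:
        i, j = pairs[int(k)]
        adj[i, j] = True
    labels = tuple(f"X{i + 1}" for i in range(n))
    return DagStructure(labels, adj)


# ---------------------------------------------------------------------------
# structure file I/O


def write_structure(dag: DagStructure, path, format: str = "edge_list") -> None:
    """Write a structure as an edge-list TSV or a 0/1 adjacency CSV."""
    if format == "edge_list":
        with open(path, "w") as fh:
            fh.write("# parent\tchild\n")
            for l in dag.labels:
                fh.write(f"# node\t{l}\n")
            for a, b in dag.edges():
                fh.write(f"{a}\t{b}\n")
    elif format == "adjacency_csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([""] + list(dag.labels))
            for i, l in enumerate(dag.labels):
                w.writerow([l] + [int(x) for x in dag.adjacency[i]])
    else:
        raise ValueError(f"unknown structure format {format!r}")


def _load_edge_list(path) -> DagStructure:
    labels: list[str] = []
    edges: list[tuple[str, str]] = []
    seen: set[str] = set()

    def note(label: str):
        if label not in seen:
            seen.add(label)
            labels.append(label)

    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*node\s+(\S+)", line)
                if m:
                    note(m.group(1))
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 'parent<TAB>child', got {raw!r}")
            note(parts[0])
            note(parts[1])
            edges.append((parts[0], parts[1]))
    if not labels:
        raise FormatError(f"{path}: no nodes found")
    return DagStructure.from_edges(labels, edges)


def _load_adjacency_csv(path) -> DagStructure:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or len(rows[0]) < 2:
        raise FormatError(f"{path}: missing label header row")
    labels = [x for x in rows[0][1:]]
    adj = np.zeros((len(labels), len(labels)), dtype=bool)
    if len(rows) - 1 != len(labels):
        raise FormatError(f"{path}: expected {len(labels)} data rows, got {len(rows) - 1}")
    for i, row in enumerate(rows[1:], 1):
        if row[0] != labels[i - 1]:
            raise FormatError(f"{path}: row label {row[0]!r} does not match header order")
        for j, cell in enumerate(row[1:]):
            try:
                adj[i - 1, j] = bool(int(cell))
            except ValueError as exc:
                raise FormatError(f"{path}: non 0/1 cell {cell!r} at row {i}") from exc
    return DagStructure(tuple(labels), adj)


_BIF_VAR = re.compile(r"variable\s+([\w.\-]+)\s*\{")
_BIF_PROB = re.compile(r"probability\s*\(\s*([\w.\-]+)\s*(?:\|\s*([^)]+))?\)")


def _load_bif(path) -> DagStructure:
    """Structure-only reader for the bnlearn BIF dialect.

    Extracts variable names from ``variable X {`` blocks and parent sets from
    ``probability ( X | P1, P2 )`` headers; all tables are ignored.
    """
    with open(path) as fh:
        text = fh.read()
    labels = _BIF_VAR.findall(text)
    if not labels:
        raise FormatError(f"{path}: no 'variable' declarations found")
    if len(set(labels)) != len(labels):
        raise FormatError(f"{path}: duplicate variable declarations")
    edges: list[tuple[str, str]] = []
    for child, parents in _BIF_PROB.findall(text):
        if parents:
            for p in parents.split(","):
                edges.append((p.strip(), child))
    try:
        return DagStructure.from_edges(labels, edges)
    except InvalidStructureError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def load_structure(path, format: str = "edge_list") -> DagStructure:
    """Load a DAG from an edge-list TSV, an adjacency CSV, or a BIF file."""
    loaders = {
        "edge_list": _load_edge_list,
        "adjacency_csv": _load_adjacency_csv,
        "bif": _load_bif,
    }
    try:
        loader = loaders[format]
    except KeyError:
        raise ValueError(f"unknown structure format {format!r}") from None
    return loader(path)
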