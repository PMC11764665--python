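"""Soft and hard structural constraints.

Soft constraints are mined from the data with Fisher-z tests on (partial)
correlations and take the form of three nested search spaces plus a set of
collider orientations:

* **CSS** (candidate search space): all unordered pairs whose marginal
  correlation is significant at ``alpha``, plus the pairs whose full-order
  partial correlation (precision matrix) is significant — the latter keeps
  direct edges whose marginal correlation is cancelled along parallel paths.
* **GSS** (global search space): the marginally dependent pairs whose
  partial correlation stays significant when conditioning on every single
  common CSS-neighbour (an order-<=1 screening); GSS is a subset of CSS.
* **LSS** (local search space): per node, the CSS-neighbours ranked by
  absolute correlation, truncated to the top ``k_lss`` candidates.
* **partial V-structures**: for an unshielded triple i - k - j (both pairs in
  GSS, (i, j) not in CSS) where conditioning on k *creates* dependence
  between i and j, the collider edges i -> k and j -> k.

Hard constraints are expert knowledge: edges required to exist and ordered
pairs forbidden to exist.  They are enforced in every structure the search
produces and also narrow the mined search spaces.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ConstraintConflictError, FormatError
from .graph import DagStructure, is_acyclic
from .sem import Dataset

__all__ = [
    "HardConstraints",
    "SearchSpaces",
    "fisher_z_test",
    "build_search_spaces",
    "find_partial_v_structures",
    "sample_hard_constraints",
    "apply_hard_constraints",
    "parent_importance",
]


Edge = tuple[str, str]


@dataclass(frozen=True)
class HardConstraints:
    """Expert knowledge: required directed edges and forbidden directed edges."""

    required: frozenset = frozenset()
    forbidden: frozenset = frozenset()

    def __post_init__(self):
        required = frozenset((str(a), str(b)) for a, b in self.required)
        forbidden = frozenset((str(a), str(b)) for a, b in self.forbidden)
        clash = required & forbidden
        if clash:
            raise ConstraintConflictError(f"edges both required and forbidden: {sorted(clash)}")
        labels = sorted({x for e in required for x in e})
        if labels:
            idx = {l: i for i, l in enumerate(labels)}
            adj = np.zeros((len(labels), len(labels)), dtype=bool)
            for a, b in required:
                if a == b:
                    raise ConstraintConflictError(f"required self-loop {a}->{b}")
                adj[idx[a], idx[b]] = True
            if not is_acyclic(adj):
                raise ConstraintConflictError("required edges form a directed cycle")
        object.__setattr__(self, "required", required)
        object.__setattr__(self, "forbidden", forbidden)

    @classmethod
    def empty(cls) -> "HardConstraints":
        return cls()

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("[required]\n")
            for a, b in sorted(self.required):
                fh.write(f"{a}\t{b}\n")
            fh.write("[forbidden]\n")
            for a, b in sorted(self.forbidden):
                fh.write(f"{a}\t{b}\n")

    @classmethod
    def from_file(cls, path) -> "HardConstraints":
        section = None
        req, forb = set(), set()
        with open(path) as fh:
            for ln, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if line.lower() in ("[required]", "[forbidden]"):
                    section = line.lower()
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) != 2 or section is None:
                    raise FormatError(f"{path}:{ln}: malformed constraint line {raw!r}")
                (req if section == "[required]" else forb).add((parts[0], parts[1]))
        return cls(frozenset(req), frozenset(forb))


@dataclass(frozen=True)
class SearchSpaces:
    """Nested edge masks mined from data (see module docstring).

    ``css``/``gss`` are symmetric boolean pair masks over ``labels``;
    ``lss`` holds, per node, the candidate parent indices in importance
    order; ``vstruct_edges`` is a set of directed (parent, child) label pairs.
    """

    labels: tuple[str, ...]
    css: np.ndarray = field(repr=False)
    gss: np.ndarray = field(repr=False)
    lss: tuple[tuple[int, ...], ...] = ()
    vstruct_edges: frozenset = frozenset()

    def __post_init__(self):
        css = np.asarray(self.css, dtype=bool).copy()
        gss = np.asarray(self.gss, dtype=bool).copy()
        n = len(self.labels)
        for name, m in (("css", css), ("gss", gss)):
            if m.shape != (n, n) or not np.array_equal(m, m.T) or np.any(np.diag(m)):
                raise ValueError(f"{name} mask must be symmetric n x n with false diagonal")
        if np.any(gss & ~css):
            raise ValueError("GSS must be a subset of CSS")
        lss = tuple(tuple(int(i) for i in cands) for cands in self.lss)
        if len(lss) != n:
            raise ValueError("lss must have one candidate list per node")
        for j, cands in enumerate(lss):
            for i in cands:
                if not css[i, j]:
                    raise ValueError("LSS candidates must be CSS pairs")
        css.setflags(write=False)
        gss.setflags(write=False)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        object.__setattr__(self, "css", css)
        object.__setattr__(self, "gss", gss)
        object.__setattr__(self, "lss", lss)
        object.__setattr__(self, "vstruct_edges", frozenset(self.vstruct_edges))

    def to_json(self, path=None) -> str:
        n = len(self.labels)
        payload = {
            "labels": list(self.labels),
            "css_pairs": [
                [self.labels[i], self.labels[j]]
                for i in range(n)
                for j in range(i + 1, n)
                if self.css[i, j]
            ],
            "gss_pairs": [
                [self.labels[i], self.labels[j]]
                for i in range(n)
                for j in range(i + 1, n)
                if self.gss[i, j]
            ],
            "lss": {
                self.labels[j]: [self.labels[i] for i in cands]
                for j, cands in enumerate(self.lss)
            },
            "vstruct_edges": sorted(list(e) for e in self.vstruct_edges),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _fisher_p(r: float, m: int, n_cond: int) -> float:
    df = m - n_cond - 3
    if df <= 0:
        return 1.0
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0 - 1e-12:
        return 0.0
    z = 0.5 * math.log((1 + r) / (1 - r)) * math.sqrt(df)
    return float(2.0 * stats.norm.sf(abs(z)))


def fisher_z_test(
    data: Dataset,
    i: int | str,
    j: int | str,
    cond: Iterable[int | str] = (),
) -> tuple[float, float]:
    """Partial correlation of columns i and j given ``cond`` plus the
    two-sided Fisher-z p-value.

    The partial correlation is obtained by inverting the correlation
    submatrix over ``{i, j} | cond``.  A singular submatrix is a degenerate
    test and is flagged as dependence (r = 1, p = 0).
    """

    def as_index(x):
        return data.labels.index(x) if isinstance(x, str) else int(x)

    i, j = as_index(i), as_index(j)
    cond = [as_index(c) for c in cond]
    if i == j or i in cond or j in cond:
        raise ValueError("test variables must be distinct from the conditioning set")
    if len(cond) > data.m - 3:
        raise ValueError("conditioning set too large for the sample size")
    sub = data.values[:, [i, j] + cond]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub.T)
    if not np.all(np.isfinite(corr)):
        return 1.0, 0.0  # zero-variance column: degenerate, treated as dependent
    if not cond:
        r = float(corr[0, 1])
    else:
        try:
            prec = np.linalg.inv(corr)
        except np.linalg.LinAlgError:
            return 1.0, 0.0
        denom = prec[0, 0] * prec[1, 1]
        if denom <= 0 or not np.isfinite(denom):
            return 1.0, 0.0
        r = float(-prec[0, 1] / math.sqrt(denom))
    return r, _fisher_p(r, data.m, len(cond))


def _order0_pvalues(corr: np.ndarray, m: int) -> np.ndarray:
    r = np.clip(corr, -1 + 1e-12, 1 - 1e-12)
    z = np.abs(np.arctanh(r)) * math.sqrt(m - 3)
    return 2.0 * stats.norm.sf(z)


def build_search_spaces(
    data: Dataset, alpha: float = 0.01, k_lss: int = 10
) -> SearchSpaces:
    """Mine CSS, GSS, LSS and partial V-structures from the data.

    Requires at least 10 samples.  Empty spaces are legitimate output (e.g.
    on independent columns nothing may survive screening).
    """
    if data.m < 10:
        raise ValueError("need at least 10 samples to mine constraints")
    n = data.n
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data.values.T)
    corr = np.nan_to_num(corr, nan=0.0)
    if n == 1:
        empty = np.zeros((1, 1), dtype=bool)
        return SearchSpaces(data.labels, empty, empty, ((),), frozenset())
    p0 = _order0_pvalues(corr, data.m)
    marg = p0 < alpha
    np.fill_diagonal(marg, False)

    # a pair belongs to CSS when it is marginally dependent OR its
    # full-order partial correlation (precision matrix) is significant;
    # the latter catches direct edges whose marginal correlation is
    # cancelled along parallel paths
    css = marg.copy()
    if data.m - (n - 2) - 3 > 0 and n > 2:
        try:
            prec = np.linalg.inv(corr)
            d = np.sqrt(np.outer(np.diag(prec), np.diag(prec)))
            with np.errstate(invalid="ignore", divide="ignore"):
                pcorr_full = -prec / d
            pcorr_full = np.nan_to_num(pcorr_full, nan=0.0)
            np.fill_diagonal(pcorr_full, 0.0)
            p_full = np.vectorize(lambda r: _fisher_p(r, data.m, n - 2))(pcorr_full)
            css |= p_full < alpha
        except np.linalg.LinAlgError:
            pass  # singular correlation matrix: fall back to the marginal mask
    np.fill_diagonal(css, False)
    css &= css.T  # symmetric by construction, defensive

    # order-1 screening: a marginally dependent pair stays in GSS only if it
    # survives conditioning on each single common CSS-neighbour
    gss = marg & css
    for i in range(n):
        for j in range(i + 1, n):
            if not gss[i, j]:
                continue
            common = np.flatnonzero(css[i] & css[j])
            for k in common:
                if k in (i, j):
                    continue
                num = corr[i, j] - corr[i, k] * corr[j, k]
                den = (1 - corr[i, k] ** 2) * (1 - corr[j, k] ** 2)
                if den <= 0:
                    continue  # degenerate: treated as dependent, keep the pair
                r1 = num / math.sqrt(den)
                if _fisher_p(r1, data.m, 1) >= alpha:
                    gss[i, j] = gss[j, i] = False
                    break

    lss = []
    for j in range(n):
        neigh = np.flatnonzero(css[:, j])
        ranked = sorted(neigh, key=lambda i: (-abs(corr[i, j]), data.labels[i]))
        lss.append(tuple(ranked[:k_lss]))

    spaces = SearchSpaces(data.labels, css, gss, tuple(lss), frozenset())
    vstructs = find_partial_v_structures(data, spaces, alpha)
    return SearchSpaces(data.labels, css, gss, tuple(lss), frozenset(vstructs))


def find_partial_v_structures(
    data: Dataset, spaces: SearchSpaces, alpha: float = 0.01
) -> set[Edge]:
    """Collider orientations from unshielded triples.

    For an unshielded triple i - k - j (both pairs in GSS, i and j not
    directly linked): if i and j are marginally independent but become
    dependent conditioning on k, the triple is a collider and contributes
    i -> k and j -> k.  Conflicting orientations (both directions of one
    edge) are dropped.
    """
    n = len(spaces.labels)
    if n < 3:
        return set()
    gss = spaces.gss
    out: set[Edge] = set()
    for k in range(n):
        neigh = np.flatnonzero(gss[:, k])
        for a in range(len(neigh)):
            for b in range(a + 1, len(neigh)):
                i, j = int(neigh[a]), int(neigh[b])
                if gss[i, j]:
                    continue
                _, p_marg = fisher_z_test(data, i, j)
                if p_marg < alpha:
                    continue
                _, p_cond = fisher_z_test(data, i, j, [k])
                if p_cond < alpha:
                    out.add((spaces.labels[i], spaces.labels[k]))
                    out.add((spaces.labels[j], spaces.labels[k]))
    conflicted = {(a, b) for (a, b) in out if (b, a) in out}
    return out - conflicted


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def sample_hard_constraints(
    truth: DagStructure,
    p: float,
    q: float,
    seed: int | np.random.Generator | None = None,
) -> HardConstraints:
    """Sample expert knowledge from a ground-truth DAG.

    ``round(p * |E|)`` true edges become required; ``round(q * |N|)`` ordered
    pairs that are neither an edge nor the reverse of an edge become
    forbidden — expert knowledge is always correct.
    """
    if not (0 <= p <= 1 and 0 <= q <= 1):
        raise ValueError("constraint rates must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    adj = truth.adjacency
    n = truth.n
    edges = list(zip(*np.nonzero(adj)))
    n_req = _round_half_up(p * len(edges))
    req_idx = rng.choice(len(edges), size=n_req, replace=False) if n_req else []
    required = {
        (truth.labels[int(edges[k][0])], truth.labels[int(edges[k][1])]) for k in req_idx
    }
    skeleton = adj | adj.T
    non_edges = [
        (i, j) for i in range(n) for j in range(n) if i != j and not skeleton[i, j]
    ]
    n_forb = _round_half_up(q * len(non_edges))
    forb_idx = rng.choice(len(non_edges), size=n_forb, replace=False) if n_forb else []
    forbidden = {
        (truth.labels[non_edges[int(k)][0]], truth.labels[non_edges[int(k)][1]])
        for k in forb_idx
    }
    return HardConstraints(frozenset(required), frozenset(forbidden))


def apply_hard_constraints(spaces: SearchSpaces, hc: HardConstraints) -> SearchSpaces:
    """Narrow mined spaces with expert knowledge.

    Required pairs are forced into every mask; pairs forbidden in both
    directions are removed everywhere; V-structure edges that contradict the
    hard constraints are dropped.  Idempotent.
    """
    labels = spaces.labels
    idx = {l: i for i, l in enumerate(labels)}
    css = spaces.css.copy()
    gss = spaces.gss.copy()
    lss = [list(c) for c in spaces.lss]
    for a, b in hc.required:
        if a not in idx or b not in idx:
            continue
        i, j = idx[a], idx[b]
        css[i, j] = css[j, i] = True
        gss[i, j] = gss[j, i] = True
        if i not in lss[j]:
            lss[j].append(i)
    for a, b in hc.forbidden:
        if a not in idx or b not in idx:
            continue
        i, j = idx[a], idx[b]
        if (b, a) in hc.forbidden and (b, a) not in hc.required:
            # both directions impossible: drop the pair everywhere
            css[i, j] = css[j, i] = False
            gss[i, j] = gss[j, i] = False
            if j in lss[i]:
                lss[i].remove(j)
        # a can never be a parent of b, in any case
        if i in lss[j]:
            lss[j].remove(i)
    vstructs = {
        (a, b)
        for (a, b) in spaces.vstruct_edges
        if (a, b) not in hc.forbidden and (b, a) not in hc.required
    }
    return SearchSpaces(labels, css, gss, tuple(tuple(c) for c in lss), frozenset(vstructs))


def parent_importance(
    data: Dataset, node: int | str, candidates: Sequence[int | str]
) -> list[str]:
    """Candidates sorted by decreasing |correlation| with ``node``; stable
    tie-break by label."""
    j = data.labels.index(node) if isinstance(node, str) else int(node)
    idxs = [data.labels.index(c) if isinstance(c, str) else int(c) for c in candidates]
    x = data.values[:, j]
    scores = []
    for i in idxs:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(x, data.values[:, i])[0, 1]
        scores.append(0.0 if not np.isfinite(r) else abs(float(r)))
    order = sorted(range(len(idxs)), key=lambda k: (-scores[k], data.labels[idxs[k]]))
    return [data.labels[idxs[k]] for k in order]
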