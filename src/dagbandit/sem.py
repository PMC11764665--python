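"""Linear structural equation model (SEM) data generation.

Each variable is a weighted sum of its parents plus independent noise:
``x_i = w_i^T pa(X_i) + u_i``.  Three generating models are supported:

1. weights ``w1 = s + N(0,1)/4`` with ``s`` uniform on {-1,+1}; noise N(0,1)
2. weights ``w2 ~ U(0.2, 1)``; noise N(0,1)
3. weights ``w1`` as in model 1; noise uniform on (-1, 1)

Models 1 and 2 are Gaussian, model 3 non-Gaussian.  There is no intercept;
all variables are mean-zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError
from .graph import DagStructure, topological_order

__all__ = [
    "SemSpec",
    "WeightedDag",
    "Dataset",
    "draw_weights",
    "simulate",
    "generate_dataset",
    "MODEL_SCHEME",
]

#: weight scheme each generating model requires
MODEL_SCHEME = {1: "w1", 2: "w2", 3: "w1"}


@dataclass(frozen=True)
class SemSpec:
    """Which generating model to use, the sample count, and the seed."""

    model: int
    m: int
    seed: int | None = None

    def __post_init__(self):
        if self.model not in (1, 2, 3):
            raise ValueError(f"model must be 1, 2 or 3, got {self.model}")
        if self.m < 1:
            raise ValueError("need at least one sample")


@dataclass(frozen=True)
class WeightedDag:
    """A DAG plus real edge weights; weights are nonzero exactly on edges."""

    structure: DagStructure
    weights: np.ndarray = field(repr=False)
    scheme: str | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        adj = self.structure.adjacency
        if w.shape != adj.shape:
            raise ValueError("weight matrix shape does not match structure")
        if np.any(w[~adj] != 0.0):
            raise ValueError("nonzero weight off the edge support")
        if np.any(w[adj] == 0.0):
            raise ValueError("zero weight on an edge")
        w = w.copy()
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# parent\tchild\tweight\n")
            for l in self.structure.labels:
                fh.write(f"# node\t{l}\n")
            adj = self.structure.adjacency
            for i, j in zip(*np.nonzero(adj)):
                fh.write(
                    f"{self.structure.labels[i]}\t{self.structure.labels[j]}\t"
                    f"{self.weights[i, j]!r}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "WeightedDag":
        import re

        labels: list[str] = []
        rows: list[tuple[str, str, float]] = []
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    m = re.match(r"#\s*node\s+(\S+)", line)
                    if m and m.group(1) not in labels:
                        labels.append(m.group(1))
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise FormatError(f"{path}: expected parent<TAB>child<TAB>weight")
                rows.append((parts[0], parts[1], float(parts[2])))
        for a, b, _ in rows:
            for l in (a, b):
                if l not in labels:
                    labels.append(l)
        structure = DagStructure.from_edges(labels, [(a, b) for a, b, _ in rows])
        w = np.zeros((len(labels), len(labels)))
        idx = {l: i for i, l in enumerate(labels)}
        for a, b, wt in rows:
            w[idx[a], idx[b]] = wt
        return cls(structure, w)


@dataclass(frozen=True)
class Dataset:
    """An m x n real data matrix with named columns."""

    values: np.ndarray = field(repr=False)
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if not np.all(np.isfinite(vals)):
            raise ValueError("dataset contains non-finite entries")
        labels = tuple(str(x) for x in self.labels)
        if len(labels) != vals.shape[1]:
            raise ValueError("label count does not match column count")
        vals = vals.copy()
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", labels)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.labels))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Dataset":
        return cls(df.to_numpy(dtype=float), tuple(str(c) for c in df.columns))

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Dataset":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"))


def draw_weights(
    dag: DagStructure,
    scheme: str = "w1",
    seed: int | np.random.Generator | None = None,
) -> WeightedDag:
    """Draw edge weights under scheme ``w1`` (``+-1 + N(0,1)/4``, sign
    equiprobable and independent per edge) or ``w2`` (uniform on (0.2, 1))."""
    if scheme not in ("w1", "w2"):
        raise ValueError(f"unknown weight scheme {scheme!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    adj = dag.adjacency
    e = int(adj.sum())
    w = np.zeros(adj.shape)
    if e:
        if scheme == "w1":
            signs = rng.choice([-1.0, 1.0], size=e)
            vals = signs + rng.standard_normal(e) / 4.0
        else:
            vals = rng.uniform(0.2, 1.0, size=e)
        # the pathological exact zero would break the support invariant
        vals[vals == 0.0] = 1e-12
        w[adj] = vals
    return WeightedDag(dag, w, scheme=scheme)


def simulate(wdag: WeightedDag, spec: SemSpec) -> Dataset:
    """Sample ``spec.m`` observations ancestrally from the weighted DAG.

    Nodes are generated in topological order as the weighted sum of their
    parents plus noise: standard normal for models 1 and 2, uniform on
    (-1, 1) for model 3.
    """
    needed = MODEL_SCHEME[spec.model]
    if wdag.scheme is not None and wdag.scheme != needed:
        raise ValueError(
            f"model {spec.model} requires weight scheme {needed!r}, "
            f"got {wdag.scheme!r}"
        )
    rng = np.random.default_rng(spec.seed)
    return _simulate_with_rng(wdag, spec.model, spec.m, rng)


def _simulate_with_rng(
    wdag: WeightedDag, model: int, m: int, rng: np.random.Generator
) -> Dataset:
    dag = wdag.structure
    X = np.empty((m, dag.n))
    index = {l: i for i, l in enumerate(dag.labels)}
    for label in topological_order(dag):
        j = index[label]
        u = rng.standard_normal(m) if model in (1, 2) else rng.uniform(-1.0, 1.0, size=m)
        pa = np.flatnonzero(dag.adjacency[:, j])
        X[:, j] = u if pa.size == 0 else X[:, pa] @ wdag.weights[pa, j] + u
    return Dataset(X, dag.labels)


def generate_dataset(
    dag: DagStructure,
    model: int,
    m: int = 1000,
    seed: int | None = None,
) -> tuple[Dataset, WeightedDag]:
    """Draw model-appropriate weights and simulate in one step.

    The weight draw and the noise draw use independent streams derived from
    ``seed`` so the same structure/seed pair is fully reproducible.
    """
    w_ss, x_ss = np.random.SeedSequence(seed).spawn(2)
    wdag = draw_weights(dag, MODEL_SCHEME[model], np.random.default_rng(w_ss))
    data = _simulate_with_rng(wdag, model, m, np.random.default_rng(x_ss))
    return data, wdag
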