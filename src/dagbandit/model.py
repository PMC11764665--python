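"""Model / Results surface for causal structure learning.

:class:`StructureLearner` is built from a dataset (optionally with expert
knowledge and a ground truth for evaluation); ``fit()`` runs the
multi-population bandit hyper-heuristic and returns a
:class:`StructureResults` carrying the learned DAG, its BIC decomposition,
the run diagnostics and — when a truth DAG was supplied — the structural
accuracy metrics, all summarised by ``summary()``.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .constraints import HardConstraints
from .graph import DagStructure, StructuralMetrics, write_structure
from .hyperheuristic import HHConfig, run
from .scoring import ScoredDag
from .sem import Dataset

__all__ = ["StructureLearner", "StructureResults"]


class StructureLearner:
    """Score-based DAG learner for continuous data under a linear SEM.

    Parameters
    ----------
    data : Dataset, DataFrame or (m, n) array
        Observations; columns are the variables.
    config : HHConfig, optional
        Search configuration; defaults follow the published settings.
    hard_constraints : HardConstraints, optional
        Required / forbidden edges enforced in the output.
    truth : DagStructure, optional
        Ground truth; enables AE/DE/RE/F1 in the results.
    """

    def __init__(self, data, config: HHConfig | None = None,
                 hard_constraints: HardConstraints | None = None,
                 truth: DagStructure | None = None):
        if isinstance(data, Dataset):
            self.data = data
        elif isinstance(data, pd.DataFrame):
            self.data = Dataset.from_dataframe(data)
        else:
            arr = np.asarray(data, dtype=float)
            labels = tuple(f"X{i + 1}" for i in range(arr.shape[1]))
            self.data = Dataset(arr, labels)
        self.config = config if config is not None else HHConfig()
        self.hard_constraints = hard_constraints
        self.truth = truth

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "StructureLearner":
        return cls(df, **kwargs)

    def fit(self, seed: int | None = None,
            structure_hook=None) -> "StructureResults":
        """Run the search and return a results object.

        ``seed`` overrides the configured seed for this fit only.
        """
        config = self.config
        if seed is not None:
            config = dataclasses.replace(config, seed=seed)
        scored, report = run(
            self.data, config, self.hard_constraints, self.truth,
            structure_hook=structure_hook,
        )
        return StructureResults(self, scored, report)


class StructureResults:
    """Outcome of a :meth:`StructureLearner.fit` call."""

    def __init__(self, model: StructureLearner, scored: ScoredDag, report: dict):
        self.model = model
        self.structure: DagStructure = scored.structure
        self.score: float = scored.total_score
        self.per_node_scores = scored.per_node_scores
        self.report = report
        self.sbs = report.get("SBS")
        m = report.get("metrics")
        self.metrics: StructuralMetrics | None = (
            StructuralMetrics(
                AE=m["AE"], DE=m["DE"], RE=m["RE"], F1=m["F1"],
                learned_edges=m["learned_edges"], true_edges=m["true_edges"],
            )
            if m else None
        )

    @property
    def n_edges(self) -> int:
        return self.structure.n_edges

    def summary(self) -> str:
        """Human-readable fit summary table."""
        rep = self.report
        lines = [
            "Causal structure learning results",
            "=" * 45,
            f"{'variables':<28}{rep['n']:>17}",
            f"{'samples':<28}{rep['m']:>17}",
            f"{'iterations run':<28}{rep['iterations']:>17}",
            f"{'learned edges':<28}{self.n_edges:>17}",
            f"{'BIC score':<28}{self.score:>17.4f}",
        ]
        if self.sbs is not None:
            lines.append(f"{'SBS (truth BIC)':<28}{self.sbs:>17.4f}")
        if self.metrics is not None:
            met = self.metrics
            lines += [
                f"{'added edges (AE)':<28}{met.AE:>17}",
                f"{'deleted edges (DE)':<28}{met.DE:>17}",
                f"{'reversed edges (RE)':<28}{met.RE:>17}",
                f"{'F1':<28}{met.F1:>17.4f}",
            ]
        lines += [
            f"{'search space switched':<28}{str(rep['space_switched']):>17}",
            f"{'run time (s)':<28}{rep['rt_seconds']:>17.2f}",
            "-" * 45,
            "operator usage:",
        ]
        for name, count in sorted(
            rep["operator_usage"].items(), key=lambda kv: -kv[1]
        ):
            if count:
                lines.append(f"  {name:<26}{count:>17}")
        return "\n".join(lines)

    def save_structure(self, path, format: str = "edge_list") -> None:
        write_structure(self.structure, path, format)

    def save_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report, fh, indent=2)

    def plot_score_trace(self, ax=None):
        """Global-best score against iteration (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.report["score_trace"])
        ax.set_xlabel("iteration")
        ax.set_ylabel("global best BIC")
        return ax
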