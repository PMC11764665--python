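"""Repeated-run experiment harness.

For each repeat a fresh dataset is simulated from the truth DAG, fresh hard
constraints are drawn at the configured rates, and a full search is run.
Each record carries the learned network's BIC, the truth's score on the
same data (SBS), the AE/DE/RE/F1 structural errors and the wall-clock run
time (RT) of the learning phase only; the report aggregates mean and
standard deviation over repeats.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constraints import sample_hard_constraints
from .graph import DagStructure
from .hyperheuristic import HHConfig, run

__all__ = ["ExperimentReport", "run_benchmark"]

_FIELDS = ("BIC", "SBS", "AE", "DE", "RE", "RT", "F1")


@dataclass
class ExperimentReport:
    """Per-run records plus mean/std aggregates over repeats."""

    records: list = field(default_factory=list)

    def aggregates(self) -> dict:
        out = {}
        for f in _FIELDS:
            vals = np.array([r[f] for r in self.records], dtype=float)
            out[f] = {"mean": float(vals.mean()), "std": float(vals.std(ddof=0))}
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_json(self, path=None) -> str:
        payload = {"records": self.records, "aggregates": self.aggregates()}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def run_benchmark(
    truth: DagStructure,
    config: HHConfig | None = None,
    repeats: int = 10,
    model: int = 1,
    m: int = 1000,
    seed: int | None = None,
) -> ExperimentReport:
    """Repeat (simulate, constrain, learn, evaluate) and aggregate.

    RT measures the learning phase only, excluding simulation and
    constraint sampling.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    config = HHConfig() if config is None else config
    master = np.random.SeedSequence(seed)
    report = ExperimentReport()
    for rep, ss in enumerate(master.spawn(repeats)):
        data_seed, hc_seed, run_seed = ss.spawn(3)
        data, _ = _gen(truth, model, m, data_seed)
        hc = sample_hard_constraints(
            truth, config.p, config.q, np.random.default_rng(hc_seed)
        )
        run_cfg = dataclasses.replace(
            config, seed=int(np.random.default_rng(run_seed).integers(2**31))
        )
        t0 = time.perf_counter()
        scored, rep_report = run(data, run_cfg, hc, truth)
        rt = time.perf_counter() - t0
        met = rep_report["metrics"]
        report.records.append(
            {
                "repeat": rep,
                "BIC": scored.total_score,
                "SBS": rep_report["SBS"],
                "AE": met["AE"],
                "DE": met["DE"],
                "RE": met["RE"],
                "RT": rt,
                "F1": met["F1"],
            }
        )
    return report


def _gen(truth, model, m, data_seed):
    from .sem import MODEL_SCHEME, draw_weights, _simulate_with_rng

    w_ss, x_ss = data_seed.spawn(2)
    wdag = draw_weights(truth, MODEL_SCHEME[model], np.random.default_rng(w_ss))
    data = _simulate_with_rng(wdag, model, m, np.random.default_rng(x_ss))
    return data, wdag
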