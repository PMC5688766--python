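"""Simulation study drivers: repeated simulate -> reconstruct -> evaluate runs,
batch statistics, and one-parameter sweeps.

Success rates are reported both per category and cumulatively (a run counts for
a category if it passes that measure or any stricter one, the way stacked
success-rate bars are usually drawn), with batch means and the median / IQR /
standard deviation of those means across batches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import evaluate_solution
from .reconstruct import KaryotypeModel, SolverError
from .simulate import ScenarioParams, simulate_instance

_CATEGORIES = ["correct", "ecn", "ebs", "eob"]
_CUMULATIVE = ["correct", "cum_ecn", "cum_ebs", "cum_eob"]

#: sweepable parameter name -> ScenarioParams field
PARAM_FIELDS = {
    "N": "n_operations",
    "eps": "cn_noise",
    "p": "drop_prob",
    "C": "n_chromosomes",
    "ploidy": "ploidy",
    "normal_fraction": "normal_fraction",
}


@dataclass
class BatchSummary:
    """Per-run records and per-batch success fractions for one scenario."""

    params: ScenarioParams
    alpha: float
    per_run: pd.DataFrame
    batch: pd.DataFrame

    def medians(self) -> dict[str, float]:
        """Cross-batch medians of the cumulative batch fractions (plus the
        overall CN-score mean and median)."""
        out = {c: float(self.batch[c].median()) for c in _CUMULATIVE}
        out["cn_score_mean"] = float(self.per_run["cn_score"].mean())
        out["cn_score_median"] = float(self.per_run["cn_score"].median())
        return out

    def means(self) -> dict[str, float]:
        return {c: float(self.batch[c].mean()) for c in _CUMULATIVE}

    def iqr(self) -> dict[str, float]:
        return {
            c: float(self.batch[c].quantile(0.75) - self.batch[c].quantile(0.25))
            for c in _CUMULATIVE
        }

    def std(self) -> dict[str, float]:
        return {c: float(self.batch[c].std(ddof=1)) for c in _CUMULATIVE}

    def summary(self) -> pd.DataFrame:
        rows = {
            "median": self.medians(),
            "mean": self.means(),
            "iqr": self.iqr(),
            "std": self.std(),
        }
        return pd.DataFrame(rows).T


def _run_one(params: ScenarioParams, alpha: float, seed) -> dict:
    inst, obs = simulate_instance(params, seed=seed)
    model = KaryotypeModel(inst.segmentation, obs)
    res = model.fit(alpha=alpha)
    report = evaluate_solution(
        res.solution,
        model.graph,
        inst.tumor,
        inst.cn_true,
        inst.bridges_true,
        inst.segmentation,
        alpha,
    )
    rec = report.as_dict()
    rec["n_intervals"] = inst.segmentation.n_intervals
    rec["n_bridges_true"] = len(inst.bridges_true)
    rec["n_bridges_observed"] = len(obs.bridges)
    rec["n_cycles"] = len(res.cycles)
    return rec


def run_scenario(
    params: ScenarioParams,
    n_karyotypes: int,
    batch_size: int = 100,
    alpha: float = 0.1,
    seed: int | None = None,
    on_solver_error: str = "flag",
) -> BatchSummary:
    """Simulate, reconstruct and evaluate ``n_karyotypes`` runs.

    Runs are grouped into batches of ``batch_size`` (``n_karyotypes`` must be a
    multiple); batch fractions and their cross-batch spread summarize the
    scenario.  Per-run seeds are spawned deterministically from ``seed``.
    Solver failures are flagged and excluded from fractions (or re-raised with
    ``on_solver_error="raise"``).
    """
    if n_karyotypes % batch_size:
        raise ValueError("n_karyotypes must be divisible by batch_size")
    children = np.random.SeedSequence(seed).spawn(n_karyotypes)
    records = []
    for i, child in enumerate(children):
        try:
            rec = _run_one(params, alpha, child)
            rec["solver_failed"] = False
        except SolverError:
            if on_solver_error == "raise":
                raise
            rec = {k: np.nan for k in _CATEGORIES + ["cn_score"]}
            rec["solver_failed"] = True
        rec["run"] = i
        rec["batch"] = i // batch_size
        records.append(rec)
    per_run = pd.DataFrame(records)

    ok = per_run[~per_run["solver_failed"]].copy()
    ok["cum_ecn"] = ok["correct"] | ok["ecn"]
    ok["cum_ebs"] = ok["cum_ecn"] | ok["ebs"]
    ok["cum_eob"] = ok["cum_ebs"] | ok["eob"]
    grouped = ok.groupby("batch")
    batch = grouped[list(dict.fromkeys(_CATEGORIES + _CUMULATIVE))].mean()
    batch["cn_score_mean"] = grouped["cn_score"].mean()
    batch["n_runs"] = grouped.size()
    return BatchSummary(params=params, alpha=alpha, per_run=per_run, batch=batch)


def sweep(
    param_name: str,
    values,
    fixed: ScenarioParams,
    n_per_value: int = 100,
    alpha: float = 0.1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Vary one parameter, keeping the others at ``fixed``; one batch per value.

    ``param_name`` is one of N, eps, p, C, ploidy, normal_fraction or alpha.
    """
    if param_name != "alpha" and param_name not in PARAM_FIELDS:
        raise ValueError(f"unknown sweep parameter {param_name!r}")
    values = list(values)
    rows = []
    children = np.random.SeedSequence(seed).spawn(len(values))
    for value, child in zip(values, children):
        if param_name == "alpha":
            params, a = fixed, float(value)
        else:
            params = fixed.with_(**{PARAM_FIELDS[param_name]: value})
            a = alpha
        summary = run_scenario(
            params,
            n_per_value,
            batch_size=n_per_value,
            alpha=a,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        row = {"param": param_name, "value": value}
        row.update({c: float(summary.batch[c].iloc[0]) for c in _CATEGORIES})
        row.update({c: float(summary.batch[c].iloc[0]) for c in _CUMULATIVE})
        row["cn_score_mean"] = float(summary.per_run["cn_score"].mean())
        row["cn_score_median"] = float(summary.per_run["cn_score"].median())
        rows.append(row)
    return pd.DataFrame(rows)
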