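"""Multi-run experiment orchestration and statistical comparison.

Runs (algorithm x problem x run) cells with deterministically derived seeds,
aggregates mean/std/best of the final objective values, ranks algorithms per
problem by mean (smaller std breaks ties), and compares run distributions
with the two-sided Wilcoxon rank-sum test at the 5% level using the usual
benchmarking convention: '+' when the reference algorithm is significantly
better (lower mean), '-' when significantly worse, '=' otherwise; degenerate
all-constant comparisons are reported as '=' with an NaN p-value.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .imgo import imgo_minimize
from .mgo import OptimizerConfig, OptResult, mgo_minimize
from .problems import ProblemSpec, get_problem

__all__ = [
    "RunSummary",
    "derive_seed",
    "run_experiment",
    "wilcoxon_ranksum",
    "exact_ranksum_pvalue",
    "rank_by_mean",
    "tally",
    "report",
]

_ALGORITHMS: dict[str, Callable[[ProblemSpec, OptimizerConfig], OptResult]] = {
    "mgo": mgo_minimize,
    "imgo": imgo_minimize,
}


@dataclass
class RunSummary:
    """Aggregate of R independent runs of one algorithm on one problem."""

    algorithm: str
    problem: str
    per_run_finals: np.ndarray
    rank: int = 0
    traces: Optional[np.ndarray] = None  # (R, max_iter), optional

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_run_finals))

    @property
    def std(self) -> float:
        return float(np.std(self.per_run_finals, ddof=1)) if len(self.per_run_finals) > 1 else 0.0

    @property
    def best(self) -> float:
        return float(np.min(self.per_run_finals))


def derive_seed(root_seed: int, algorithm: str, problem: str, run: int) -> int:
    """Deterministic per-cell seed below 2^31, hashed from the cell identity."""
    key = f"{root_seed}|{algorithm}|{problem}|{run}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "little") % (2**31)


def rank_by_mean(summaries: Sequence[RunSummary]) -> None:
    """Assign ranks in place within each problem: smaller mean wins, smaller
    std breaks mean ties, exact (mean, std) ties share the better rank."""
    by_problem: dict[str, list[RunSummary]] = {}
    for s in summaries:
        by_problem.setdefault(s.problem, []).append(s)
    for group in by_problem.values():
        keys = sorted((s.mean, s.std) for s in group)
        for s in group:
            s.rank = 1 + keys.index((s.mean, s.std))


def run_experiment(
    problems: Sequence[Union[str, ProblemSpec]],
    algorithms: Sequence[str],
    runs: int,
    cfg: OptimizerConfig,
    keep_traces: bool = False,
) -> list[RunSummary]:
    """Execute every (algorithm, problem, run) cell and aggregate.

    Per-cell seeds derive from ``cfg.seed`` and the cell identity, so the full
    experiment is replayable from one root seed and invariant to run order.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    summaries = []
    for prob in problems:
        spec = get_problem(prob) if isinstance(prob, str) else prob
        for algo in algorithms:
            minimize = _ALGORITHMS[algo]
            finals = np.empty(runs)
            traces = np.empty((runs, cfg.max_iter)) if keep_traces else None
            for r in range(runs):
                seed = derive_seed(cfg.seed, algo, spec.name, r)
                res = minimize(spec, OptimizerConfig(
                    pop_size=cfg.pop_size,
                    max_iter=cfg.max_iter,
                    seed=seed,
                    spiral_constant=cfg.spiral_constant,
                    fs_bounds=cfg.fs_bounds,
                ))
                finals[r] = res.best_value
                if keep_traces:
                    traces[r] = res.trace
            summaries.append(RunSummary(algo, spec.name, finals, traces=traces))
    rank_by_mean(summaries)
    return summaries


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def exact_ranksum_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided p by full enumeration of the permutation null of the rank sum.

    Enumerates all C(n+m, n) assignments of the pooled midranks to group a and
    reports P(|W - E[W]| >= |w_obs - E[W]|). Exact under ties; intended for
    min(n, m) <= 8.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    ranks = _midranks(np.concatenate([a, b]))
    w_obs = ranks[:n].sum()
    e_w = n * (n + m + 1) / 2.0
    dev = abs(w_obs - e_w) - 1e-12  # tolerate float fuzz in midrank sums
    hits = 0
    total = 0
    for idx in combinations(range(n + m), n):
        w = ranks[list(idx)].sum()
        if abs(w - e_w) >= dev:
            hits += 1
        total += 1
    return hits / total


def _approx_ranksum_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Normal approximation with midrank tie correction and continuity correction."""
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w = ranks[:n].sum()
    e_w = n * (n + m + 1) / 2.0
    nn = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / ((nn) * (nn - 1))
    var_w = n * m / 12.0 * ((nn + 1) - tie_term)
    if var_w <= 0:
        return math.nan
    z = (abs(w - e_w) - 0.5) / math.sqrt(var_w)
    z = max(z, 0.0)
    return math.erfc(z / math.sqrt(2.0))


def wilcoxon_ranksum(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alpha: float = 0.05,
) -> tuple[float, str]:
    """5% two-sided Wilcoxon rank-sum comparison of two run distributions.

    Returns ``(p_value, verdict)`` where the verdict is '+' if the difference
    is significant and sample a's mean is better (lower), '-' if significant
    and worse, '=' otherwise. Two identical constant samples are degenerate:
    the p-value is NaN and the verdict '='. Exact enumeration is used when
    min(n, m) <= 8, the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return math.nan, "="
    if min(len(a), len(b)) <= 8:
        p = exact_ranksum_pvalue(a, b)
    else:
        p = _approx_ranksum_pvalue(a, b)
    if not (p < alpha):
        return p, "="
    return p, "+" if a.mean() < b.mean() else "-"


def tally(verdicts: Sequence[str]) -> str:
    """'+/=/-' tally row, e.g. ('+', '+', '=') -> '2/1/0'."""
    return f"{sum(v == '+' for v in verdicts)}/{sum(v == '=' for v in verdicts)}/{sum(v == '-' for v in verdicts)}"


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report(
    summaries: Sequence[RunSummary],
    comparisons: Optional[dict[str, tuple[float, str]]] = None,
    outdir: Union[str, Path] = "results",
) -> dict[str, Path]:
    """Write per-problem CSV tables, a JSON summary with the +/=/- tally and
    average ranks, and per-cell convergence traces when available."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    table_path = outdir / "summary.csv"
    with open(table_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["problem", "algorithm", "mean", "std", "best", "rank"])
        for s in summaries:
            w.writerow([s.problem, s.algorithm, repr(s.mean), repr(s.std), repr(s.best), s.rank])
    paths["summary"] = table_path

    algos = sorted({s.algorithm for s in summaries})
    avg_rank = {
        algo: float(np.mean([s.rank for s in summaries if s.algorithm == algo]))
        for algo in algos
    }
    blob = {
        "average_rank": avg_rank,
        "cells": [
            {
                "problem": s.problem,
                "algorithm": s.algorithm,
                "mean": s.mean,
                "std": s.std,
                "best": s.best,
                "rank": s.rank,
                "per_run_finals": [float(v) for v in s.per_run_finals],
            }
            for s in summaries
        ],
    }
    if comparisons is not None:
        blob["wilcoxon"] = {
            key: {"p": None if math.isnan(p) else p, "verdict": v, "degenerate": math.isnan(p)}
            for key, (p, v) in comparisons.items()
        }
        blob["tally"] = tally([v for _, v in comparisons.values()])
    json_path = outdir / "summary.json"
    json_path.write_text(json.dumps(blob, indent=2))
    paths["json"] = json_path

    for s in summaries:
        if s.traces is None:
            continue
        trace_path = outdir / f"trace_{s.problem}_{s.algorithm}.csv"
        with open(trace_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["iteration"] + [f"run{r}" for r in range(s.traces.shape[0])])
            for t in range(s.traces.shape[1]):
                w.writerow([t + 1] + [repr(float(v)) for v in s.traces[:, t]])
        paths[f"trace_{s.problem}_{s.algorithm}"] = trace_path
    return paths
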