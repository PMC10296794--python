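"""Study orchestration: benchmark convergence, topology search, and the
multi-optimizer training comparison, each with repeated-run statistics.

Every study derives one seed per run from a root seed, so results are
reproducible end to end.  Run statistics (avg / min / max / std / var) use
the population (n) denominator, so the reported variance is exactly the
square of the reported standard deviation.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import benchmarks
from .model import SWARM_METHODS, SwarmMLP
from .gradients import GRADIENT_METHODS
from .network import Topology
from .swarm import SwarmConfig, optimize

__all__ = [
    "StudyConfig",
    "RunSummary",
    "summarize_runs",
    "run_convergence_study",
    "topology_search",
    "run_training_study",
    "write_report",
    "ALL_OPTIMIZERS",
]

ALL_OPTIMIZERS = ("hms_pso", "hms", "pso", "grad", "adadelta", "sgd",
                  "rmsprop", "adam")


def spawn_seeds(root_seed: Optional[int], n: int) -> np.ndarray:
    """n reproducible child seeds (each < 2**31) from one root seed."""
    ss = np.random.SeedSequence(root_seed if root_seed is not None else 0)
    return ss.generate_state(n) % (2 ** 31)


@dataclass(frozen=True)
class RunSummary:
    """avg/min/max/std/var of one metric over independent runs (population
    denominator, so std**2 == var exactly)."""

    metric: str
    avg: float
    min: float
    max: float
    std: float
    var: float
    values: tuple

    def to_dict(self) -> dict:
        return {"metric": self.metric, "avg": self.avg, "min": self.min,
                "max": self.max, "std": self.std, "var": self.var}


def summarize_runs(values: Sequence[float], metric: str = "value") -> RunSummary:
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("summarize_runs needs at least one value")
    var = float(np.var(vals))  # population denominator
    return RunSummary(metric=metric, avg=float(np.mean(vals)),
                      min=float(np.min(vals)), max=float(np.max(vals)),
                      std=float(np.sqrt(var)), var=var,
                      values=tuple(vals.tolist()))


@dataclass
class StudyConfig:
    """Shared study settings: repeat count, swarm size, iteration budget,
    root seed.  The published protocol uses 30 runs with population 50 and
    100 (benchmarks) / 500 (topology) / 2000 (dataset training) iterations;
    smaller values give scaled-down studies."""

    runs: int = 30
    population: int = 50
    iterations: int = 100
    root_seed: int = 0
    algorithms: tuple = ("hms_pso", "pso", "hms")
    dimension_override: Optional[int] = None
    w: object = (0.729, 0.4)
    c1: float = 1.49
    c2: float = 1.49

    def __post_init__(self):
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


# ---------------------------------------------------------------------------
# benchmark convergence study
# ---------------------------------------------------------------------------

def run_convergence_study(config: StudyConfig,
                          functions: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Repeated swarm runs per (function, algorithm) cell.

    Returns a tidy DataFrame with one row per cell holding the run summary
    of the best fitness, plus a per-function digest of the winning
    algorithm(s) in ``df.attrs['digest']``.
    """
    if functions is None:
        functions = benchmarks.list_suite()
    rows = []
    for fid in functions:
        spec = benchmarks.get_spec(fid)
        dim = spec.dimension
        if config.dimension_override is not None and spec.dimension > 2:
            dim = config.dimension_override  # scale down the 30-D functions
        objective, lo, hi = benchmarks.make_objective(fid, dimension=dim)
        for algo in config.algorithms:
            seeds = spawn_seeds(_cell_seed(config.root_seed, fid, algo),
                                config.runs)
            best = []
            for s in seeds:
                swarm_cfg = SwarmConfig(
                    dimension=lo.shape[0], bounds=(lo, hi),
                    population_size=config.population,
                    max_iterations=config.iterations,
                    w=config.w, c1=config.c1, c2=config.c2, seed=int(s))
                best.append(optimize(objective, swarm_cfg, algorithm=algo).best_fitness)
            summ = summarize_runs(best, metric="best_fitness")
            rows.append({"function": fid, "algorithm": algo,
                         **{k: v for k, v in summ.to_dict().items()
                            if k != "metric"}})
    df = pd.DataFrame(rows)
    digest = []
    for fid in functions:
        sub = df[df["function"] == fid]
        mn = sub["min"].min()
        winners = sub.loc[sub["min"] <= mn + 1e-12, "algorithm"].tolist()
        digest.append({"function": fid, "best_algorithm": ", ".join(winners),
                       "min_value": mn})
    df.attrs["digest"] = pd.DataFrame(digest)
    return df


def _cell_seed(root: int, *labels) -> int:
    """Stable per-cell root seed from the study root and cell labels."""
    h = hashlib.sha256(("|".join([str(root), *map(str, labels)])).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# topology search
# ---------------------------------------------------------------------------

def topology_search(candidates: Sequence, X, y,
                    config: Optional[StudyConfig] = None) -> pd.DataFrame:
    """Train each candidate topology with the hybrid optimizer and report
    held-out MSE and AUC; the minimal-MSE row is flagged ``selected``.

    ``candidates`` holds hidden-layer size sequences, e.g. ``[(18, 9, 3)]``,
    or '18-9-3' strings.
    """
    if config is None:
        config = StudyConfig(runs=1, iterations=500)
    rows = []
    for k, cand in enumerate(candidates):
        hidden = tuple(int(h) for h in
                       (cand.split("-") if isinstance(cand, str) else cand))
        if any(h < 1 for h in hidden) or not hidden:
            raise ValueError(f"invalid hidden-layer candidate {cand!r}")
        model = SwarmMLP(X, y, hidden=hidden, seed=config.root_seed)
        res = model.fit("hms_pso", iterations=config.iterations,
                        population=config.population,
                        seed=_cell_seed(config.root_seed, "topology", k))
        rows.append({"hidden_layers": "-".join(map(str, hidden)),
                     "mse": res.mse_test, "auc": res.auc_test})
    df = pd.DataFrame(rows)
    df["selected"] = df["mse"] == df["mse"].min()
    return df


# ---------------------------------------------------------------------------
# training comparison study
# ---------------------------------------------------------------------------

def run_training_study(X, y, hidden: Sequence[int] = (18, 9, 3),
                       optimizers: Sequence[str] = ALL_OPTIMIZERS,
                       config: Optional[StudyConfig] = None) -> dict:
    """Repeated independent trainings of one topology per optimizer.

    Returns ``{"mse": DataFrame, "rmse": DataFrame, "per_run": DataFrame}``
    with avg/min/max/std/var of the held-out test MSE and RMSE per
    optimizer.  Runs whose loss diverged (non-finite) are excluded from the
    summaries and counted in the ``failed`` column with a warning.
    """
    if config is None:
        config = StudyConfig(runs=30, iterations=2000)
    model = SwarmMLP(X, y, hidden=tuple(hidden), seed=config.root_seed)
    mse_rows, rmse_rows, per_run = [], [], []
    for opt in optimizers:
        seeds = spawn_seeds(_cell_seed(config.root_seed, "train", opt),
                            config.runs)
        mses = []
        failed = 0
        for s in seeds:
            res = model.fit(opt, iterations=config.iterations,
                            population=config.population, seed=int(s))
            per_run.append({"optimizer": opt, "seed": int(s),
                            "mse": res.mse_test, "rmse": res.rmse_test,
                            "auc": res.auc_test,
                            "converged": res.converged})
            if res.converged and np.isfinite(res.mse_test):
                mses.append(res.mse_test)
            else:
                failed += 1
        if failed:
            warnings.warn(f"{opt}: {failed} of {config.runs} runs diverged "
                          "and were excluded from the summary", RuntimeWarning)
        if not mses:
            continue
        m = summarize_runs(mses, metric="mse")
        r = summarize_runs(np.sqrt(mses), metric="rmse")
        mse_rows.append({"optimizer": opt, **{k: v for k, v in m.to_dict().items()
                                              if k != "metric"}, "failed": failed})
        rmse_rows.append({"optimizer": opt, **{k: v for k, v in r.to_dict().items()
                                               if k != "metric"}, "failed": failed})
    return {"mse": pd.DataFrame(mse_rows), "rmse": pd.DataFrame(rmse_rows),
            "per_run": pd.DataFrame(per_run)}


# ---------------------------------------------------------------------------
# report writer
# ---------------------------------------------------------------------------

def _df_to_markdown(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    header = "| " + " | ".join(str(c) for c in cols) + " |"
    sep = "| " + " | ".join("---" for _ in cols) + " |"
    lines = [header, sep]
    for _, row in df.iterrows():
        cells = [f"{v:.8g}" if isinstance(v, (float, np.floating)) else str(v)
                 for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def write_report(tables: dict, outdir, formats: Sequence[str] = ("csv", "md"),
                 metadata: Optional[dict] = None) -> list:
    """Write each named table as CSV and/or Markdown under ``outdir``,
    embedding run metadata (seeds, config hash) as a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        if "csv" in formats:
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)
        if "md" in formats:
            p = outdir / f"{name}.md"
            p.write_text(_df_to_markdown(df) + "\n")
            written.append(p)
    if metadata is not None:
        blob = json.dumps(metadata, indent=2, sort_keys=True, default=str)
        meta = dict(metadata)
        meta["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:12]
        p = outdir / "run_metadata.json"
        p.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
        written.append(p)
    return written
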