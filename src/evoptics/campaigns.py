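"""Multi-run optimization campaigns and structure-regularity analysis.

A campaign runs one problem with one or more algorithms for ``n_runs``
independent seeded runs (seed of run ``i`` is ``base_seed + i``), collects
best scores/genomes/traces, and can persist results to a directory
(``runs.csv`` + ``traces/``) from which completed runs are resumed.

The regularity classifiers turn qualitative statements about emergent
structures ("the optimum is a quarterwave Bragg mirror", "the first layer is
half a wavelength", "thicknesses vary monotonically with depth") into
testable predicates on a decoded :class:`~evoptics.multilayer.Stack`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .multilayer import Stack
from .genomes import Bounds
from .optimizers import (
    ALGORITHMS,
    AlgorithmUnavailableError,
    OptimizationResult,
    OptimizerConfig,
    minimize,
)

__all__ = [
    "CampaignSpec",
    "CampaignResult",
    "RegularityReport",
    "run_campaign",
    "sorted_profile",
    "classify_quarterwave",
    "detect_halfwave_first_layer",
    "chirp_direction",
]

log = logging.getLogger("evoptics.campaigns")


@dataclass
class CampaignSpec:
    """A (problem x algorithms x n_runs) experiment definition.

    ``objective_factory(problem)`` must return the scalar objective; run
    seeds are ``base_seed + run_index`` so any run can be reproduced alone.
    """

    problem: object
    objective_factory: object
    algorithms: tuple = ("DE",)
    n_runs: int = 100
    budget: int = 10_000
    base_seed: int = 0
    population: int = 30
    params: dict = field(default_factory=dict)


@dataclass
class CampaignResult:
    """Per-run records plus summary statistics.

    ``runs`` columns: algorithm, run, seed, score, evaluations, v_1..v_D.
    """

    spec: CampaignSpec
    runs: pd.DataFrame
    traces: dict  # (algorithm, run) -> list[(eval, best)]

    def scores(self, algorithm: str) -> np.ndarray:
        sel = self.runs[self.runs.algorithm == algorithm]
        return sel.sort_values("run").score.to_numpy()

    def best_run(self, algorithm: str | None = None) -> pd.Series:
        sel = self.runs if algorithm is None else self.runs[self.runs.algorithm == algorithm]
        return sel.loc[sel.score.idxmin()]

    def best_genome(self, algorithm: str | None = None) -> np.ndarray:
        row = self.best_run(algorithm)
        cols = [c for c in self.runs.columns if c.startswith("v_")]
        return row[cols].to_numpy(dtype=float)

    def genome_of(self, row: pd.Series) -> np.ndarray:
        cols = [c for c in self.runs.columns if c.startswith("v_")]
        return row[cols].to_numpy(dtype=float)

    def summary(self) -> pd.DataFrame:
        return (
            self.runs.groupby("algorithm")
            .score.agg(["min", "median", "max"])
            .reset_index()
        )


def run_campaign(spec: CampaignSpec, out_dir: str | Path | None = None) -> CampaignResult:
    """Execute every (algorithm, run) cell; optionally persist and resume.

    With ``out_dir`` set, per-run rows are appended to ``runs.csv`` and
    convergence traces written under ``traces/``; cells already present in
    ``runs.csv`` are skipped on re-entry, so an interrupted campaign resumes
    where it stopped. Algorithms whose backing implementation is unavailable
    are skipped with a warning.
    """
    objective = spec.objective_factory(spec.problem)
    bounds: Bounds = spec.problem.bounds()
    out_dir = Path(out_dir) if out_dir is not None else None
    done = set()
    rows = []
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "traces").mkdir(exist_ok=True)
        runs_csv = out_dir / "runs.csv"
        if runs_csv.exists():
            prev = pd.read_csv(runs_csv)
            rows = prev.to_dict("records")
            done = {(r["algorithm"], int(r["run"])) for r in rows}

    traces = {}
    for algo in spec.algorithms:
        for run in range(spec.n_runs):
            if (algo, run) in done:
                continue
            seed = spec.base_seed + run
            cfg = OptimizerConfig(
                algorithm=algo,
                budget=spec.budget,
                population=spec.population,
                seed=seed,
                params=dict(spec.params),
            )
            try:
                res = minimize(objective, bounds, cfg)
            except AlgorithmUnavailableError as exc:
                log.warning("skipping %s: %s", algo, exc)
                break
            log.info(
                "run=%s/%d seed=%d evals=%d best=%.6g",
                algo, run, seed, res.evaluations, res.f_best,
            )
            row = {
                "algorithm": algo,
                "run": run,
                "seed": seed,
                "score": res.f_best,
                "evaluations": res.evaluations,
            }
            row.update({f"v_{j + 1}": v for j, v in enumerate(res.x_best)})
            rows.append(row)
            traces[(algo, run)] = res.trace
            if out_dir is not None:
                pd.DataFrame(rows).to_csv(out_dir / "runs.csv", index=False)
                trace_df = pd.DataFrame(res.trace, columns=["eval_index", "best_score"])
                trace_df.to_csv(out_dir / "traces" / f"{algo}_{run}.csv", index=False)
    return CampaignResult(spec, pd.DataFrame(rows), traces)


def sorted_profile(campaign: CampaignResult, algorithm: str) -> np.ndarray:
    """Run scores sorted descending (worst first, best run last)."""
    return np.sort(campaign.scores(algorithm))[::-1]


# ---------------------------------------------------------------------------
# Regularity classifiers
# ---------------------------------------------------------------------------

@dataclass
class RegularityReport:
    """Outcome of the structure-regularity classifiers for one stack."""

    is_quarterwave: bool = False
    quarterwave_deviation_nm: np.ndarray | None = None
    alternation_ok: bool = False
    first_layer_halfwave: bool = False
    chirp_direction: str = "non-monotone"
    monotone_fraction: float = 0.0


def classify_quarterwave(
    stack: Stack,
    lambda0: float,
    tol: float = 2.0,
    index_tol: float = 0.005,
    index_extremes: tuple = (1.4, 1.7),
) -> RegularityReport:
    """Is the stack an ideal high-first quarterwave Bragg mirror at lambda0?

    Layer ``i`` passes the thickness test iff
    ``|t_i - lambda0 / (4 n_i)| <= tol``; ``alternation_ok`` requires the
    real indices to strictly alternate between the two extreme allowed values
    (within ``index_tol``) with the *higher* index on top.
    """
    n = np.array([m.refractive_index(lambda0).real for m, _ in stack.layers])
    t = stack.thicknesses()
    dev = np.abs(t - lambda0 / (4.0 * n))
    n_lo, n_hi = min(index_extremes), max(index_extremes)
    expected = np.array([n_hi if j % 2 == 0 else n_lo for j in range(len(n))])
    alternation_ok = bool(len(n) > 0 and np.all(np.abs(n - expected) <= index_tol))
    return RegularityReport(
        is_quarterwave=bool(len(t) > 0 and np.all(dev <= tol)),
        quarterwave_deviation_nm=dev,
        alternation_ok=alternation_ok,
        first_layer_halfwave=detect_halfwave_first_layer(stack, lambda0, tol),
    )


def detect_halfwave_first_layer(stack: Stack, lambda0: float, tol: float = 2.0) -> bool:
    """True iff the top layer is a half-wave ("absent") layer at lambda0."""
    if not stack.layers:
        return False
    mat, t = stack.layers[0]
    if t <= 0:
        return False
    n = mat.refractive_index(lambda0).real
    return bool(abs(t - lambda0 / (2.0 * n)) <= tol)


def chirp_direction(stack: Stack, threshold: float = 0.8, at_wavelength: float = 650.0):
    """Monotonicity of the per-period optical thickness with depth.

    Consecutive layers are grouped into bilayer periods (1,2), (3,4), ...;
    the per-period optical thickness is ``sum n_i t_i`` over the pair. The
    monotone fraction is the share of consecutive period differences whose
    sign matches the majority sign (zero differences count toward neither,
    and a stack with no nonzero differences reports fraction 0). A direction
    is assigned when the fraction reaches ``threshold``.

    Returns ``(direction, monotone_fraction)`` with direction one of
    "increasing", "decreasing", "non-monotone".
    """
    n = np.array([m.refractive_index(at_wavelength).real for m, _ in stack.layers])
    t = stack.thicknesses()
    opt = n * t
    n_pairs = len(opt) // 2
    if n_pairs < 2:
        return "non-monotone", 0.0
    periods = opt[: 2 * n_pairs].reshape(n_pairs, 2).sum(axis=1)
    diffs = np.diff(periods)
    n_up = int(np.sum(diffs > 0))
    n_dn = int(np.sum(diffs < 0))
    total = diffs.size
    if n_up == n_dn == 0:
        return "non-monotone", 0.0
    if n_up >= n_dn:
        frac = n_up / total
        direction = "increasing"
    else:
        frac = n_dn / total
        direction = "decreasing"
    if frac < threshold:
        return "non-monotone", float(frac)
    return direction, float(frac)
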