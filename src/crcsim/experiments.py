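"""Experiment drivers: baseline strategy comparison and compliance sweeps.

``run_baseline`` compares a set of strategies against the no-screening arm
using common random numbers (all arms of a replicate share one
natural-history seed), reporting discounted mean cost, QALYs, lifetime
diagnosed-CRC fraction, ICER and ICPCP versus no screening with
replicate-level Monte-Carlo standard errors.

``run_one_way_sensitivity`` and ``run_two_way_sensitivity`` sweep the three
compliance rates (FIT, first colonoscopy, follow-up colonoscopy) over grids
and tabulate ICER/ICPCP per strategy per grid point, locating ranking
crossovers by sign change between adjacent grid points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import run_arm
from .economics import CohortResult, aggregate_cohort, icer, icpcp
from .params import ModelParams, StrategyConfig, default_params

__all__ = ["ExperimentSpec", "SensitivityGrid", "run_arms", "compare",
           "run_baseline", "run_one_way_sensitivity", "run_two_way_sensitivity",
           "find_crossovers", "AXES"]

#: Compliance axes: name -> (strategy-field keyword, default sweep lo/hi in %).
AXES = {
    "fit": ("fit", 40, 100),
    "colo1": ("first", 30, 100),
    "colo2": ("followup", 50, 100),
}


@dataclass(frozen=True)
class ExperimentSpec:
    """Run settings shared by the experiment drivers."""

    n: int = 20_000
    replicates: int = 10
    seed: int = 0
    params: ModelParams = field(default_factory=default_params)

    def __post_init__(self) -> None:
        if self.n < 1 or self.replicates < 1:
            raise ValueError("cohort size and replicates must be >= 1")


@dataclass(frozen=True)
class SensitivityGrid:
    """Grid of compliance levels, in percent, per axis."""

    step: int = 10
    ranges: dict = field(default_factory=lambda: {
        "fit": (40, 100), "colo1": (30, 100), "colo2": (50, 100)})

    def points(self, axis: str) -> np.ndarray:
        lo, hi = self.ranges[axis]
        return np.arange(lo, hi + 1, self.step)


def _seeds(spec: ExperimentSpec, rep: int, arm: int) -> tuple:
    """Deterministic (natural-history, screening) seeds for one replicate/arm.

    The natural-history seed depends only on the replicate, giving common
    random numbers across arms; the screening seed additionally depends on
    the arm so different strategies draw independent screening randomness.
    """
    nh_seed = np.random.SeedSequence([spec.seed, rep, 0])
    scr_seed = np.random.SeedSequence([spec.seed, rep, 1, arm])
    return nh_seed, scr_seed


def run_arms(spec: ExperimentSpec,
             strategies: dict[str, StrategyConfig | None],
             ) -> dict[str, CohortResult]:
    """Run each named arm (None = no screening) over all replicates."""
    results: dict[str, CohortResult] = {}
    for arm_idx, (name, strat) in enumerate(strategies.items()):
        costs, qalys, flags, ages = [], [], [], []
        for rep in range(spec.replicates):
            nh_seed, scr_seed = _seeds(spec, rep, arm_idx)
            out = run_arm(spec.n, spec.params, strat,
                          nh_seed=nh_seed, scr_seed=scr_seed)
            costs.append(out.cost)
            qalys.append(out.qalys)
            flags.append(out.crc)
            ages.append(out.crc_age)
        results[name] = aggregate_cohort(name, costs, qalys, flags, ages)
    return results


def compare(results: dict[str, CohortResult],
            baseline: str = "no_screening") -> pd.DataFrame:
    """Cost/QALY summary with ICER and ICPCP of every arm vs the baseline."""
    base = results[baseline]
    rows = []
    for name, res in results.items():
        row = res.to_row()
        row["crc_per_person"] = res.crc_per_person
        if name != baseline:
            row["icer"] = icer(res.mean_cost, res.mean_qalys,
                               base.mean_cost, base.mean_qalys)
            row["icpcp"] = icpcp(res.mean_cost, base.mean_cost,
                                 res.crc_per_person, base.crc_per_person)
            rep_icer = (res.rep_cost - base.rep_cost) / (res.rep_qalys
                                                         - base.rep_qalys)
            row["se_icer"] = (float(rep_icer.std(ddof=1)
                                    / np.sqrt(len(rep_icer)))
                              if len(rep_icer) > 1 else float("nan"))
        else:
            row["icer"] = row["icpcp"] = row["se_icer"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("strategy")


def run_baseline(spec: ExperimentSpec,
                 strategies: dict[str, StrategyConfig],
                 ) -> tuple[pd.DataFrame, dict[str, CohortResult]]:
    """Baseline comparison of all strategies against no screening."""
    arms: dict[str, StrategyConfig | None] = {"no_screening": None}
    arms.update(strategies)
    results = run_arms(spec, arms)
    return compare(results), results


def _with_axis(strategy: StrategyConfig, axis: str, pct: float) -> StrategyConfig:
    kw = {AXES[axis][0]: pct / 100.0}
    return strategy.with_compliance(**kw)


def run_one_way_sensitivity(spec: ExperimentSpec,
                            strategies: dict[str, StrategyConfig],
                            axis: str,
                            grid: SensitivityGrid | None = None) -> pd.DataFrame:
    """ICER/ICPCP of each strategy vs no screening along one compliance axis.

    All grid points share natural-history seeds and per-strategy screening
    seeds, so curves vary smoothly in compliance (coupled uniform draws).
    """
    grid = grid or SensitivityGrid()
    pts = grid.points(axis)
    arm_index = {name: i + 1 for i, name in enumerate(strategies)}

    base_res = run_arms(spec, {"no_screening": None})["no_screening"]
    rows = []
    for pct in pts:
        for name, strat in strategies.items():
            varied = _with_axis(strat, axis, pct)
            costs, qalys, flags, ages = [], [], [], []
            for rep in range(spec.replicates):
                nh_seed, scr_seed = _seeds(spec, rep, arm_index[name])
                out = run_arm(spec.n, spec.params, varied,
                              nh_seed=nh_seed, scr_seed=scr_seed)
                costs.append(out.cost)
                qalys.append(out.qalys)
                flags.append(out.crc)
                ages.append(out.crc_age)
            res = aggregate_cohort(name, costs, qalys, flags, ages)
            rows.append({
                "axis": axis, "compliance_pct": int(pct), "strategy": name,
                "cost": res.mean_cost, "qalys": res.mean_qalys,
                "crc_per_person": res.crc_per_person,
                "icer": icer(res.mean_cost, res.mean_qalys,
                             base_res.mean_cost, base_res.mean_qalys),
                "icpcp": icpcp(res.mean_cost, base_res.mean_cost,
                               res.crc_per_person, base_res.crc_per_person),
            })
    return pd.DataFrame(rows)


def find_crossovers(oneway: pd.DataFrame, strategy_a: str, strategy_b: str,
                    metric: str = "icer") -> list[tuple[int, int]]:
    """Grid intervals where the A-vs-B ranking flips (sign change of A - B)."""
    a = oneway[oneway.strategy == strategy_a].sort_values("compliance_pct")
    b = oneway[oneway.strategy == strategy_b].sort_values("compliance_pct")
    pts = a.compliance_pct.to_numpy()
    diff = a[metric].to_numpy() - b[metric].to_numpy()
    out = []
    for i in range(len(diff) - 1):
        if np.sign(diff[i]) != np.sign(diff[i + 1]) and diff[i] != 0:
            out.append((int(pts[i]), int(pts[i + 1])))
    return out


def run_two_way_sensitivity(spec: ExperimentSpec,
                            strategies: dict[str, StrategyConfig],
                            fixed_axis: str, swept_axis: str,
                            fixed_levels: list[int] | None = None,
                            grid: SensitivityGrid | None = None) -> pd.DataFrame:
    """Two-way compliance sweep: ICER range over the swept axis per fixed level.

    For each level of ``fixed_axis`` the swept axis runs over its grid; the
    result reports the ICER at the sweep endpoints and its (min, max) across
    the sweep for each strategy, one row per (fixed level, strategy).
    """
    grid = grid or SensitivityGrid()
    levels = fixed_levels or list(grid.points(fixed_axis))
    arm_index = {name: i + 1 for i, name in enumerate(strategies)}
    base_res = run_arms(spec, {"no_screening": None})["no_screening"]

    rows = []
    for fixed_pct in levels:
        curves: dict[str, list[float]] = {name: [] for name in strategies}
        for swept_pct in grid.points(swept_axis):
            for name, strat in strategies.items():
                varied = _with_axis(_with_axis(strat, fixed_axis, fixed_pct),
                                    swept_axis, swept_pct)
                costs, qalys = [], []
                for rep in range(spec.replicates):
                    nh_seed, scr_seed = _seeds(spec, rep, arm_index[name])
                    out = run_arm(spec.n, spec.params, varied,
                                  nh_seed=nh_seed, scr_seed=scr_seed)
                    costs.append(out.cost.mean())
                    qalys.append(out.qalys.mean())
                curves[name].append(icer(float(np.mean(costs)),
                                         float(np.mean(qalys)),
                                         base_res.mean_cost,
                                         base_res.mean_qalys))
        for name, vals in curves.items():
            rows.append({
                "fixed_axis": fixed_axis, "fixed_pct": int(fixed_pct),
                "swept_axis": swept_axis, "strategy": name,
                "icer_at_low": vals[0], "icer_at_high": vals[-1],
                "icer_min": float(np.min(vals)), "icer_max": float(np.max(vals)),
            })
    return pd.DataFrame(rows)
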