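"""Generic calibration harness for natural-history parameters.

Re-fits a named subset of :class:`NaturalHistoryParams` fields so that
simulated summaries (adenoma counts by age, CRC counts by age, or any
user-supplied summary function) match user-supplied targets in weighted
least squares. The simulator noise is frozen (fixed seed) so the objective
is deterministic and a derivative-free optimizer applies; a staged mode
fits adenoma-pathway parameters first and cancer-pathway parameters second.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import optimize

from .cohort import run_arm
from .params import ModelParams

__all__ = ["CalibrationTarget", "CalibrationResult", "fit", "fit_staged",
           "simulated_summaries", "load_targets_csv"]


@dataclass(frozen=True)
class CalibrationTarget:
    """One calibration target: a named simulated summary and its value."""

    quantity: str  # key into the summary dict, e.g. "crc_per_person"
    value: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("target weights must be positive")


@dataclass
class CalibrationResult:
    params: ModelParams
    fitted: dict[str, float]
    loss: float
    loss_trace: list[float] = field(default_factory=list)
    n_evaluations: int = 0


def simulated_summaries(params: ModelParams, n: int = 5_000,
                        seed: int = 12345,
                        ages: Sequence[int] = (50, 60, 70)) -> dict[str, float]:
    """Default summary set from a fixed-seed no-screening cohort.

    Returns the discounted mean cost and QALYs, lifetime diagnosed-CRC
    fraction, and cumulative diagnosed-CRC counts per person by the given
    ages — the kinds of quantities natural-history models are calibrated to.
    """
    out = run_arm(n, params, strategy=None,
                  nh_seed=np.random.SeedSequence([seed, 0]),
                  scr_seed=np.random.SeedSequence([seed, 1]))
    s = {
        "mean_cost": float(out.cost.mean()),
        "mean_qalys": float(out.qalys.mean()),
        "crc_per_person": float(out.crc.mean()),
    }
    for a in ages:
        s[f"crc_by_age_{a}"] = float((out.crc & (out.crc_age <= a)).mean())
    return s


def _apply(params: ModelParams, values: Mapping[str, float]) -> ModelParams:
    return replace(params, natural_history=replace(params.natural_history,
                                                   **dict(values)))


def fit(params: ModelParams,
        free: Mapping[str, tuple[float, tuple[float, float]]],
        targets: Sequence[CalibrationTarget],
        summary_fn: Callable[[ModelParams], Mapping[str, float]] | None = None,
        maxiter: int = 60) -> CalibrationResult:
    """Weighted least-squares fit of the free parameters to the targets.

    ``free`` maps NaturalHistoryParams field names to ``(initial, (lo, hi))``.
    With zero free parameters the input is returned unchanged with its loss.
    The summary function must be deterministic (frozen seed); the default is
    :func:`simulated_summaries`. Nelder-Mead within box bounds; the recorded
    loss trace is the sequence of best-so-far losses.
    """
    summary_fn = summary_fn or simulated_summaries
    if len(free) > len(targets):
        warnings.warn("more free parameters than targets: "
                      "the fit may not be identifiable", stacklevel=2)

    names = list(free)
    trace: list[float] = []
    n_eval = 0

    def loss_of(values: Mapping[str, float]) -> float:
        p = _apply(params, values)
        s = summary_fn(p)
        return float(sum(t.weight * (s[t.quantity] - t.value) ** 2
                         for t in targets))

    if not names:
        l0 = loss_of({})
        return CalibrationResult(params=params, fitted={}, loss=l0,
                                 loss_trace=[l0], n_evaluations=1)

    x0 = np.array([free[k][0] for k in names], dtype=float)
    bounds = [free[k][1] for k in names]

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        for xi, (lo, hi) in zip(x, bounds):
            if not lo <= xi <= hi:
                return 1e12 * (1.0 + float(np.sum(np.abs(x))))
        val = loss_of(dict(zip(names, x)))
        trace.append(min(val, trace[-1]) if trace else val)
        return val

    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"maxiter": maxiter, "xatol": 1e-4,
                                     "fatol": 1e-8})
    fitted = dict(zip(names, (float(v) for v in res.x)))
    return CalibrationResult(params=_apply(params, fitted), fitted=fitted,
                             loss=float(res.fun), loss_trace=trace,
                             n_evaluations=n_eval)


def fit_staged(params: ModelParams,
               stages: Sequence[tuple[Mapping[str, tuple[float, tuple[float, float]]],
                                      Sequence[CalibrationTarget]]],
               summary_fn: Callable[[ModelParams], Mapping[str, float]] | None = None,
               maxiter: int = 60) -> CalibrationResult:
    """Step-by-step calibration: each stage refits on top of the previous one.

    The canonical use is a first stage freeing adenoma-pathway parameters
    against adenoma-count targets and a second stage freeing cancer-pathway
    parameters against CRC-count targets.
    """
    current = params
    fitted: dict[str, float] = {}
    trace: list[float] = []
    n_eval = 0
    loss = float("nan")
    for free, targets in stages:
        res = fit(current, free, targets, summary_fn=summary_fn, maxiter=maxiter)
        current = res.params
        fitted.update(res.fitted)
        trace.extend(res.loss_trace)
        n_eval += res.n_evaluations
        loss = res.loss
    return CalibrationResult(params=current, fitted=fitted, loss=loss,
                             loss_trace=trace, n_evaluations=n_eval)


def load_targets_csv(path) -> list[CalibrationTarget]:
    """Read targets from a CSV with columns quantity,age,value,weight.

    A non-empty ``age`` suffixes the quantity (``crc_by_age_60``-style keys,
    matching :func:`simulated_summaries`).
    """
    df = pd.read_csv(path)
    targets = []
    for _, r in df.iterrows():
        q = str(r["quantity"])
        if "age" in df.columns and not pd.isna(r.get("age")):
            q = f"{q}_{int(r['age'])}"
        targets.append(CalibrationTarget(quantity=q, value=float(r["value"]),
                                         weight=float(r.get("weight", 1.0))))
    return targets
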