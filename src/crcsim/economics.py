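"""Discounted cost and QALY accounting, ICER and ICPCP.

Costs and quality-adjusted life years accrue over the accounting window
[T_s, T_n] (default ages 45-90) with continuous discounting
``e^{-lambda (t - T_s)}``. The yearly cost is the sum of the screening and
treatment events of that year: FIT, colonoscopy plus pathology, per-adenoma
polypectomy, one-off curative-resection treatment, and annual
advanced-cancer treatment while that state persists. The yearly utility is
that of the person's most severe concurrent health state.

Three cost mappings for colonoscopy with polypectomy are supported. The
"listed" default charges every exam the colonoscopy plus pathology list
prices and each removed adenoma the full polypectomy list price; "itemized"
prices an exam at the bare colonoscopy price, adds pathology only when
something is found and a per-adenoma increment equal to the difference
between the polypectomy and plain-colonoscopy prices; "bundled" charges the
flat polypectomy-colonoscopy price for any exam that removes lesions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import AGE_MAX, EconParams, Utilities

__all__ = ["discount_factor", "YearRecord", "PersonLedger", "year_cost",
           "cumulative_cost", "cumulative_qalys", "icer", "icpcp",
           "utility_by_state", "CohortResult", "aggregate_cohort"]


def discount_factor(t: float, t_start: float, rate: float) -> float:
    """``e^{-rate (t - t_start)}``; ages before the window contribute 0."""
    if t < t_start:
        return 0.0
    return math.exp(-rate * (t - t_start))


@dataclass(frozen=True)
class YearRecord:
    """One accounting year of a single person's history."""

    age: int
    fit: bool = False  # FIT taken this year
    colonoscopy: bool = False
    n_removed: int = 0  # adenomas removed by this year's colonoscopy
    early_treatment: bool = False  # curative resection performed
    advanced_treatment: bool = False  # advanced-cancer treatment charged
    utility: float = 0.0

    def __post_init__(self) -> None:
        if self.n_removed > 0 and not self.colonoscopy:
            raise ValueError("adenomas can only be removed by a colonoscopy")
        if self.n_removed < 0:
            raise ValueError("n_removed must be non-negative")


@dataclass
class PersonLedger:
    """A person's yearly event/utility records over the accounting window."""

    records: list[YearRecord] = field(default_factory=list)

    def append(self, record: YearRecord) -> None:
        self.records.append(record)


def year_cost(rec: YearRecord, params: EconParams) -> float:
    """Undiscounted cost of one year's events under the configured mapping."""
    c = 0.0
    if rec.fit:
        c += params.c_fit
    if rec.colonoscopy:
        found = rec.n_removed > 0
        if params.cost_mapping == "itemized":
            c += params.c_colonoscopy + rec.n_removed * params.c_polypectomy
            if found:
                c += params.c_pathology
        elif params.cost_mapping == "listed":
            c += (params.c_colonoscopy + params.c_pathology
                  + rec.n_removed * params.c_colo_with_polypectomy)
        else:  # bundled
            c += params.c_colo_with_polypectomy if found else params.c_colonoscopy
            if found:
                c += params.c_pathology
    if rec.early_treatment:
        c += params.c_early_treatment
    if rec.advanced_treatment:
        c += params.c_advanced_treatment
    return c


def cumulative_cost(ledger: PersonLedger, params: EconParams) -> float:
    """Discounted lifetime cost of one person's ledger."""
    return sum(discount_factor(r.age, params.t_start, params.discount_rate)
               * year_cost(r, params) for r in ledger.records)


def cumulative_qalys(ledger: PersonLedger, params: EconParams) -> float:
    """Discounted lifetime QALYs of one person's ledger."""
    return sum(discount_factor(r.age, params.t_start, params.discount_rate)
               * r.utility for r in ledger.records)


def icer(cost_a: float, qaly_a: float, cost_b: float, qaly_b: float) -> float:
    """Incremental cost-effectiveness ratio of A versus comparator B."""
    de = qaly_a - qaly_b
    if de == 0.0:
        raise ZeroDivisionError("ICER undefined: equal QALYs in both arms")
    return (cost_a - cost_b) / de


def icpcp(cost_a: float, cost_b: float, crc_a: float, crc_b: float) -> float:
    """Incremental cost per CRC case prevented, A versus comparator B.

    ``crc_*`` are lifetime diagnosed-CRC cases per person; the comparator is
    expected to have more cases (screening prevents cases).
    """
    prevented = crc_b - crc_a
    if prevented == 0.0:
        raise ZeroDivisionError("ICPCP undefined: no difference in CRC cases")
    if prevented < 0.0:
        raise ValueError("comparator has fewer CRC cases: ICPCP not meaningful")
    return (cost_a - cost_b) / prevented


# Cancer-state utilities indexed by CancerState code. Preclinical and
# clinical early cancer share the early-cancer utility; curative resection
# restores full utility (Table-style single-state values).
def _cancer_utility_table(u: Utilities) -> np.ndarray:
    return np.array([u.healthy, u.early_cancer, u.early_cancer,
                     u.healthy, u.advanced_cancer, u.death])


def utility_by_state(cancer: np.ndarray, any_adenoma: np.ndarray,
                     any_advanced: np.ndarray, alive: np.ndarray,
                     utilities: Utilities) -> np.ndarray:
    """Annual utility of each person's most severe concurrent state."""
    lesion_u = np.where(any_advanced, utilities.advanced_adenoma,
                        np.where(any_adenoma, utilities.small_adenoma,
                                 utilities.healthy))
    u = np.minimum(_cancer_utility_table(utilities)[cancer], lesion_u)
    return np.where(alive, u, utilities.death)


@dataclass
class CohortResult:
    """Per-strategy aggregates over persons and replicates."""

    strategy: str
    n_persons: int
    replicates: int
    mean_cost: float
    mean_qalys: float
    crc_per_person: float  # lifetime diagnosed-CRC fraction
    se_cost: float
    se_qalys: float
    se_crc: float
    crc_by_age: np.ndarray  # diagnosed cases per person by age 0..90
    rep_cost: np.ndarray  # per-replicate means, for paired comparisons
    rep_qalys: np.ndarray
    rep_crc: np.ndarray

    def to_row(self) -> dict:
        return {"strategy": self.strategy, "n": self.n_persons,
                "replicates": self.replicates, "cost": self.mean_cost,
                "qalys": self.mean_qalys, "crc_per_person": self.crc_per_person,
                "se_cost": self.se_cost, "se_qalys": self.se_qalys}


def aggregate_cohort(strategy: str, rep_costs: list[np.ndarray],
                     rep_qalys: list[np.ndarray],
                     rep_crc_flags: list[np.ndarray],
                     rep_crc_ages: list[np.ndarray]) -> CohortResult:
    """Pool per-person outcomes of R replicates into a CohortResult."""
    if not rep_costs:
        raise ValueError("at least one replicate is required")
    reps = len(rep_costs)
    n = sum(len(c) for c in rep_costs)
    rc = np.array([c.mean() for c in rep_costs])
    rq = np.array([q.mean() for q in rep_qalys])
    rf = np.array([f.mean() for f in rep_crc_flags])
    hist = np.zeros(AGE_MAX + 1)
    for flags, ages in zip(rep_crc_flags, rep_crc_ages):
        a = ages[flags]
        np.add.at(hist, a, 1.0)
    hist /= n

    def se(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / np.sqrt(reps)) if reps > 1 else float("nan")

    return CohortResult(
        strategy=strategy, n_persons=n, replicates=reps,
        mean_cost=float(rc.mean()), mean_qalys=float(rq.mean()),
        crc_per_person=float(rf.mean()),
        se_cost=se(rc), se_qalys=se(rq), se_crc=se(rf),
        crc_by_age=hist, rep_cost=rc, rep_qalys=rq, rep_crc=rf)


def results_frame(results: list[CohortResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
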