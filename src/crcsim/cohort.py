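"""Per-year cohort engine: natural history + screening + accounting.

``run_arm`` advances a cohort of asymptomatic 20-year-olds to age 90 on a
one-year cycle. Within each year the order is: other-cause death check,
cancer-pathway step, new-adenoma incidence, adenoma progression, screening
(within the screening window), then cost/utility accrual on the post-update
state. Transitions stop after age 89; the final year contributes utility
(and any ongoing advanced-cancer treatment cost) only.

Two independent RNG streams drive an arm: the natural-history stream, which
consumes fixed-shape draws every year so that arms sharing a seed share
disease histories exactly (common random numbers), and a screening stream
used only by the screening layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import natural_history as nh
from . import screening as scr
from .economics import PersonLedger, YearRecord, utility_by_state
from .params import (
    AGE_MAX,
    AGE_MIN,
    CancerState,
    ModelParams,
    StrategyConfig,
)

__all__ = ["ArmOutcome", "run_arm"]


@dataclass
class ArmOutcome:
    """Per-person lifetime outcomes of one simulated arm."""

    cost: np.ndarray  # discounted yuan
    qalys: np.ndarray  # discounted quality-adjusted life years
    crc: np.ndarray  # bool: ever clinically diagnosed with CRC
    crc_age: np.ndarray  # age at diagnosis, -1 if never
    n_colonoscopies: np.ndarray
    n_fits: np.ndarray
    only_clear_findings: np.ndarray  # every colonoscopy found nothing
    ledgers: list[PersonLedger] | None = None  # only when record_ledgers


def run_arm(n: int, params: ModelParams,
            strategy: StrategyConfig | None = None,
            nh_seed=None, scr_seed=None,
            record_ledgers: bool = False) -> ArmOutcome:
    """Simulate one arm (a strategy, or no screening when `strategy` is None).

    ``nh_seed`` seeds the natural-history stream: two arms run with the same
    ``nh_seed`` see identical frailties, adenoma histories and cancer-path
    randomness wherever screening has not altered the state. ``scr_seed``
    seeds the screening stream. ``record_ledgers`` additionally returns a
    per-person :class:`PersonLedger` (intended for small cohorts; used by the
    replay cross-check of the inline accounting).
    """
    rng = np.random.default_rng(nh_seed)
    rng_s = np.random.default_rng(scr_seed)
    nhp, sens, econ = params.natural_history, params.sensitivities, params.economics

    cohort = nh.Cohort.initial(n, nhp, rng)
    schedule = scr.ScheduleState.initial(n, first_fit_age=econ.t_start)

    cost = np.zeros(n)
    qalys = np.zeros(n)
    ledgers = [PersonLedger() for _ in range(n)] if record_ledgers else None

    disc = np.exp(-econ.discount_rate
                  * (np.arange(AGE_MAX + 1) - econ.t_start))

    for age in range(AGE_MIN, AGE_MAX + 1):
        cohort.age = age
        events = None
        resection = np.zeros(n, dtype=bool)
        entered_cac = np.zeros(n, dtype=bool)
        if age < AGE_MAX:
            nh.step_other_cause_mortality(cohort, nhp, rng)
            cancer_events = nh.step_cancer(cohort, nhp, rng)
            resection = cancer_events.entered_resection
            entered_cac = cancer_events.entered_cac
            nh.sample_new_adenomas(cohort, nhp, rng)
            nh.step_adenomas(cohort, nhp, rng)
            if strategy is not None and econ.t_start <= age <= econ.t_end:
                events = scr.screening_step(cohort, schedule, strategy,
                                            sens, nhp, rng_s)

        if age < econ.t_start:
            continue

        # Accrual on the post-update state.
        in_cac = cohort.alive & (cohort.cancer == CancerState.CLINICAL_ADVANCED)
        adv_charge = (entered_cac if econ.advanced_cost_mode == "once"
                      else in_cac)
        ycost = np.where(resection & cohort.alive, econ.c_early_treatment, 0.0)
        ycost += np.where(adv_charge, econ.c_advanced_treatment, 0.0)
        if events is not None:
            fit_c = np.where(events.fit_taken, econ.c_fit, 0.0)
            found = events.n_removed > 0
            if econ.cost_mapping == "itemized":
                colo_c = np.where(events.colonoscopy,
                                  econ.c_colonoscopy
                                  + events.n_removed * econ.c_polypectomy, 0.0)
                path_c = np.where(events.colonoscopy & found,
                                  econ.c_pathology, 0.0)
            elif econ.cost_mapping == "listed":
                colo_c = np.where(events.colonoscopy,
                                  econ.c_colonoscopy + events.n_removed
                                  * econ.c_colo_with_polypectomy, 0.0)
                path_c = np.where(events.colonoscopy, econ.c_pathology, 0.0)
            else:
                colo_c = np.where(events.colonoscopy,
                                  np.where(found, econ.c_colo_with_polypectomy,
                                           econ.c_colonoscopy), 0.0)
                path_c = np.where(events.colonoscopy & found,
                                  econ.c_pathology, 0.0)
            ycost += fit_c + colo_c + path_c

        any_aden = (cohort.sizes > 0).any(axis=1)
        any_adv = nh.advanced_mask(cohort, nhp).any(axis=1)
        util = utility_by_state(cohort.cancer, any_aden, any_adv,
                                cohort.alive, econ.utilities)

        cost += disc[age] * ycost
        qalys += disc[age] * util

        if ledgers is not None:
            for i in range(n):
                if not (cohort.alive[i] or ycost[i] > 0):
                    continue
                ledgers[i].append(YearRecord(
                    age=age,
                    fit=bool(events.fit_taken[i]) if events is not None else False,
                    colonoscopy=(bool(events.colonoscopy[i])
                                 if events is not None else False),
                    n_removed=(int(events.n_removed[i])
                               if events is not None else 0),
                    early_treatment=bool(resection[i] & cohort.alive[i]),
                    advanced_treatment=bool(adv_charge[i]),
                    utility=float(util[i]),
                ))

    return ArmOutcome(cost=cost, qalys=qalys,
                      crc=cohort.diagnosed_crc.copy(),
                      crc_age=cohort.crc_age.copy(),
                      n_colonoscopies=schedule.n_colonoscopies.copy(),
                      n_fits=schedule.n_fits.copy(),
                      only_clear_findings=schedule.only_clear_findings.copy(),
                      ledgers=ledgers)
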