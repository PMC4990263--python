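"""FIT-plus-colonoscopy screening with observation-based surveillance.

Everyone is offered a FIT at the starting screening age. A positive FIT
(per-lesion faecal shedding detection) leads to a same-year colonoscopy
offer; the colonoscopy removes the adenomas it detects, converts detected
preclinical early cancer into a clinical diagnosis, and classifies its
findings into five classes (no adenoma / 1-2 small / 3-10 small / advanced
adenoma / early cancer). The finding class sets the surveillance interval
T_c of the next colonoscopy; a None interval terminates all screening, so
such strategies perform at most one colonoscopy per lifetime for persons
who never show adenomas. Negative FITs and refused tests re-enter the
waiting cycle with period T_f.

Compliance gates apply separately to FIT, the first colonoscopy ever, and
follow-up colonoscopies. All draws come from a dedicated screening RNG
stream so that natural-history randomness is shared across arms (common
random numbers); at zero compliance a screened arm reproduces the
no-screening arm person by person.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .natural_history import Cohort, advanced_mask
from .params import (
    AdenomaSize,
    CancerState,
    FindingClass,
    NaturalHistoryParams,
    StrategyConfig,
    TestSensitivities,
)

#: Sentinel age meaning "no appointment pending".
NEVER = -1

__all__ = ["NEVER", "ScheduleState", "ScreeningEvents", "perform_fit",
           "perform_colonoscopy", "classify_findings", "schedule_next",
           "screening_step"]


@dataclass
class ScheduleState:
    """Per-person screening appointments and lifetime screening flags."""

    next_fit_age: np.ndarray  # int16 (n,), NEVER when no FIT pending
    next_colo_age: np.ndarray  # int16 (n,), NEVER when no colonoscopy pending
    had_first_colo: np.ndarray  # bool (n,)
    terminated: np.ndarray  # bool (n,): all screening permanently stopped
    n_colonoscopies: np.ndarray  # int16 (n,)
    n_fits: np.ndarray  # int16 (n,)
    only_clear_findings: np.ndarray  # bool (n,): every finding was NO_ADENOMA
    last_colo_age: np.ndarray  # int16 (n,), NEVER before the first colonoscopy
    last_finding: np.ndarray  # int8 (n,), finding class of the last colonoscopy
    # Persistent compliance traits (per-person uniforms drawn at the first
    # screening offer; attend iff uniform < rate, so sweeps over compliance
    # levels are monotone per person). None until drawn.
    u_fit: np.ndarray | None = None
    u_colo_first: np.ndarray | None = None
    u_colo_follow: np.ndarray | None = None

    @classmethod
    def initial(cls, n: int, first_fit_age: int) -> "ScheduleState":
        return cls(
            next_fit_age=np.full(n, first_fit_age, dtype=np.int16),
            next_colo_age=np.full(n, NEVER, dtype=np.int16),
            had_first_colo=np.zeros(n, dtype=bool),
            terminated=np.zeros(n, dtype=bool),
            n_colonoscopies=np.zeros(n, dtype=np.int16),
            n_fits=np.zeros(n, dtype=np.int16),
            only_clear_findings=np.ones(n, dtype=bool),
            last_colo_age=np.full(n, NEVER, dtype=np.int16),
            last_finding=np.zeros(n, dtype=np.int8),
        )


@dataclass
class ScreeningEvents:
    """Cost-bearing events emitted by one year of screening."""

    fit_taken: np.ndarray  # bool (n,)
    colonoscopy: np.ndarray  # bool (n,)
    n_removed: np.ndarray  # int (n,): adenomas removed this year
    cancer_detected: np.ndarray  # bool (n,): preclinical cancer diagnosed
    finding: np.ndarray  # int8 (n,), finding class where colonoscopy done


def perform_fit(cohort: Cohort, sens: TestSensitivities,
                rng: np.random.Generator,
                mask: np.ndarray | None = None) -> np.ndarray:
    """One FIT per person in `mask`; returns the positive/negative result.

    Every lesion sheds independently: adenomas test positive with their
    size-class sensitivity and preclinical early cancer with the cancer
    sensitivity. Lesion-free persons test positive with probability
    ``1 - fit_specificity``. Random draws use fixed shapes for the whole
    cohort; the mask only selects whose results count.
    """
    u_lesion = rng.random(cohort.sizes.shape)
    u_cancer = rng.random(cohort.n)
    u_fp = rng.random(cohort.n)

    hit = (cohort.sizes > 0) & (u_lesion < sens.fit_by_size()[cohort.sizes])
    pec = cohort.cancer == CancerState.PRECLINICAL_EARLY
    cancer_hit = pec & (u_cancer < sens.fit_cancer)
    lesion_free = (cohort.sizes == 0).all(axis=1) & ~pec
    false_pos = lesion_free & (u_fp < 1.0 - sens.fit_specificity)

    positive = hit.any(axis=1) | cancer_hit | false_pos
    if mask is not None:
        positive = positive & mask
    return positive


def classify_findings(n_small_detected: np.ndarray, advanced_detected: np.ndarray,
                      cancer_detected: np.ndarray) -> np.ndarray:
    """Most-severe-wins classification of a colonoscopy's detected set.

    Early cancer outranks advanced adenoma, which outranks the count classes
    for non-advanced diminutive/small adenomas (1-2 vs 3-10).
    """
    n_small_detected = np.asarray(n_small_detected)
    finding = np.full(n_small_detected.shape, FindingClass.NO_ADENOMA,
                      dtype=np.int8)
    finding[n_small_detected >= 1] = FindingClass.SMALL_1_2
    finding[n_small_detected >= 3] = FindingClass.SMALL_3_10
    finding[np.asarray(advanced_detected)] = FindingClass.ADVANCED_ADENOMA
    finding[np.asarray(cancer_detected)] = FindingClass.EARLY_CANCER
    return finding


def perform_colonoscopy(cohort: Cohort, sens: TestSensitivities,
                        rng: np.random.Generator,
                        mask: np.ndarray,
                        nh_params: NaturalHistoryParams,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Colonoscopy with polypectomy for the persons in `mask`.

    Each lesion is detected independently with its size-class sensitivity;
    detected adenomas are removed on the spot while missed lesions persist
    and keep progressing. Detected preclinical early cancer becomes a
    clinical early-cancer diagnosis. Returns ``(n_removed, cancer_detected,
    finding)`` arrays over the whole cohort (zeros outside `mask`).
    """
    u_lesion = rng.random(cohort.sizes.shape)
    u_cancer = rng.random(cohort.n)

    detected = (mask[:, None] & (cohort.sizes > 0)
                & (u_lesion < sens.colo_by_size()[cohort.sizes]))
    adv = advanced_mask(cohort, nh_params)
    advanced_detected = (detected & adv).any(axis=1)
    n_small = (detected & ~adv
               & ((cohort.sizes == AdenomaSize.DIMINUTIVE)
                  | (cohort.sizes == AdenomaSize.SMALL))).sum(axis=1)

    cancer_detected = (mask & (cohort.cancer == CancerState.PRECLINICAL_EARLY)
                       & (u_cancer < sens.colonoscopy_cancer))

    n_removed = detected.sum(axis=1)
    cohort.remove_adenomas(detected)
    # Clinical diagnosis of screen-detected cancer.
    cohort.cancer[cancer_detected] = CancerState.CLINICAL_EARLY
    newly = cancer_detected & ~cohort.diagnosed_crc
    cohort.diagnosed_crc[newly] = True
    cohort.crc_age[newly] = cohort.age

    finding = classify_findings(n_small, advanced_detected, cancer_detected)
    finding[~mask] = FindingClass.NO_ADENOMA
    return n_removed, cancer_detected, finding


def schedule_next(schedule: ScheduleState, strategy: StrategyConfig,
                  finding: np.ndarray, mask: np.ndarray, age: int) -> None:
    """Set the post-colonoscopy surveillance state for persons in `mask`.

    A None interval terminates all future screening in either flow. With a
    finite interval, the colonoscopy-cycle flow books the next colonoscopy
    and suspends the FIT cycle; the FIT-cycle flow records the finding and
    returns the person to the FIT waiting cycle, where T_c acts as the
    minimum spacing before a new positive FIT can trigger a colonoscopy.
    """
    sentinel = 10_000
    t_c = strategy.t_colo_array(sentinel)[finding]
    stop = mask & (t_c >= sentinel)
    cont = mask & ~stop

    schedule.terminated[stop] = True
    schedule.next_colo_age[stop] = NEVER
    schedule.next_fit_age[stop] = NEVER
    schedule.had_first_colo[mask] = True
    schedule.last_colo_age[mask] = age
    schedule.last_finding[mask] = finding[mask]
    schedule.only_clear_findings[mask & (finding != FindingClass.NO_ADENOMA)] = False
    if strategy.flow == "colonoscopy_cycle":
        schedule.next_fit_age[mask] = NEVER
        schedule.next_colo_age[cont] = age + t_c[cont]
    elif strategy.flow == "hybrid":
        clear = cont & (finding == FindingClass.NO_ADENOMA)
        watch = cont & ~clear
        schedule.next_fit_age[mask] = NEVER
        schedule.next_colo_age[watch] = age + t_c[watch]
        schedule.next_colo_age[clear] = NEVER
        schedule.next_fit_age[clear] = age + t_c[clear]
    else:  # fit_cycle
        schedule.next_colo_age[cont] = NEVER
        schedule.next_fit_age[cont] = age + strategy.t_fit


def screening_step(cohort: Cohort, schedule: ScheduleState,
                   strategy: StrategyConfig, sens: TestSensitivities,
                   nh_params: NaturalHistoryParams,
                   rng: np.random.Generator) -> ScreeningEvents:
    """Run one year of the screening flow at the cohort's current age.

    Due FITs and due colonoscopies each pass a compliance gate; refusals
    re-enter the waiting cycle after T_f years. A compliant positive FIT
    triggers a same-year colonoscopy offer (first-ever vs follow-up
    compliance as appropriate); a refused colonoscopy is re-offered after
    T_f years with the FIT cycle suspended.
    """
    n = cohort.n
    age = cohort.age
    comp = strategy.compliance
    active = cohort.alive & ~schedule.terminated

    due_colo = active & (schedule.next_colo_age == age)
    due_fit = active & (schedule.next_fit_age == age) & ~due_colo

    if comp.mode == "per_person":
        if schedule.u_fit is None:
            schedule.u_fit = rng.random(n)
            schedule.u_colo_first = rng.random(n)
            schedule.u_colo_follow = rng.random(n)
        u_comp = np.where(due_colo,
                          np.where(schedule.had_first_colo,
                                   schedule.u_colo_follow, schedule.u_colo_first),
                          schedule.u_fit)
        u_colo = np.where(schedule.had_first_colo,
                          schedule.u_colo_follow, schedule.u_colo_first)
    else:
        u_comp = rng.random(n)
        u_colo = rng.random(n)
    colo_comp_rate = np.where(schedule.had_first_colo,
                              comp.followup_colonoscopy, comp.first_colonoscopy)

    # --- FIT arm of the flow ---
    fit_taken = due_fit & (u_comp < comp.fit)
    fit_refused = due_fit & ~fit_taken
    schedule.next_fit_age[fit_refused] = age + strategy.t_fit
    schedule.n_fits[fit_taken] += 1

    fit_positive = perform_fit(cohort, sens, rng, mask=fit_taken)
    fit_negative = fit_taken & ~fit_positive
    schedule.next_fit_age[fit_negative] = age + strategy.t_fit

    # Same-year colonoscopy offer for FIT-positives.
    if strategy.flow == "fit_cycle":
        # T_c gates how soon after the last colonoscopy a new positive FIT
        # may trigger the next one; ineligible positives keep FIT-cycling.
        t_c_last = strategy.t_colo_array()[schedule.last_finding]
        eligible = (~schedule.had_first_colo
                    | (age - schedule.last_colo_age >= t_c_last))
        ineligible_pos = fit_positive & ~eligible
        schedule.next_fit_age[ineligible_pos] = age + strategy.t_fit
        offered = fit_positive & eligible
        colo_from_fit = offered & (u_colo < colo_comp_rate)
        colo_deferred = offered & ~colo_from_fit
        schedule.next_fit_age[colo_deferred] = age + strategy.t_fit
    else:
        colo_from_fit = fit_positive & (u_colo < colo_comp_rate)
        colo_deferred = fit_positive & ~colo_from_fit
        schedule.next_colo_age[colo_deferred] = age + strategy.t_fit
        schedule.next_fit_age[colo_deferred] = NEVER

    # --- scheduled surveillance colonoscopies (colonoscopy-cycle flow) ---
    colo_scheduled = due_colo & (u_comp < colo_comp_rate)
    colo_refused = due_colo & ~colo_scheduled
    schedule.next_colo_age[colo_refused] = age + strategy.t_fit

    do_colo = colo_from_fit | colo_scheduled
    n_removed, cancer_detected, finding = perform_colonoscopy(
        cohort, sens, rng, do_colo, nh_params)
    schedule.n_colonoscopies[do_colo] += 1
    schedule_next(schedule, strategy, finding, do_colo, age)

    return ScreeningEvents(fit_taken=fit_taken, colonoscopy=do_colo,
                           n_removed=np.where(do_colo, n_removed, 0),
                           cancer_detected=cancer_detected, finding=finding)
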