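"""Adenoma-carcinoma natural history on a one-year cycle.

The disease model tracks, per person, up to ten concurrent adenomas (size
class, villous architecture, dysplasia grade) and a cancer-pathway state
machine (none -> preclinical early cancer -> clinical advanced cancer /
death, with clinical early cancer and curative resection reachable only
through screening detection). New adenomas arrive as a Poisson process whose
annual rate is an age-specific baseline plus a lifelong lognormal frailty;
they start diminutive, tubular and low-grade. Only advanced adenomas (large,
villous, or high-grade) can seed preclinical cancer, and no more than one
cancer-pathway transition happens per person per year.

State is held as a struct-of-arrays :class:`Cohort` so that a whole cohort
advances through each year with vectorized numpy operations. All stochastic
kernels draw fixed-shape random arrays every year from the cohort's
natural-history stream regardless of who they apply to; this makes the
stream consumption identical across screening arms and gives exact common
random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    AGE_MAX,
    AGE_MIN,
    AdenomaSize,
    CancerState,
    NaturalHistoryParams,
)

MAX_ADENOMAS = 10

__all__ = [
    "MAX_ADENOMAS",
    "Cohort",
    "sample_frailty",
    "incidence_rate",
    "sample_new_adenomas",
    "step_adenomas",
    "advanced_mask",
    "is_advanced_adenoma",
    "step_cancer",
    "step_other_cause_mortality",
    "CancerEvents",
]


def sample_frailty(params: NaturalHistoryParams, rng: np.random.Generator,
                   n: int = 1) -> np.ndarray:
    """Draw per-person lifelong extra adenoma-incidence rates.

    The draw is lognormal on the natural scale with mean ``frailty_mean`` and
    standard deviation ``frailty_sd_factor * frailty_mean`` (or explicit
    ``(frailty_mu, frailty_sigma)`` when configured). Draws are strictly
    positive and held constant for a person's lifetime.
    """
    mu, sigma = params.frailty_lognormal()
    if not (np.isfinite(mu) and np.isfinite(sigma)) or sigma < 0:
        raise ValueError("frailty lognormal parameters must be finite, sigma >= 0")
    if sigma == 0.0:
        return np.full(n, np.exp(mu))
    return rng.lognormal(mean=mu, sigma=sigma, size=n)


def incidence_rate(params: NaturalHistoryParams, age: int,
                   frailty: np.ndarray) -> np.ndarray:
    """Annual new-adenoma rate at `age` given each person's frailty.

    Additive mode adds the frailty (a rate) to the age baseline;
    multiplicative mode scales the baseline by the (unitless) frailty.
    """
    if not AGE_MIN <= age <= AGE_MAX:
        raise ValueError(f"age {age} outside the simulated range")
    base = params.baseline_rate_table()[age]
    f = np.asarray(frailty, dtype=float)
    rate = base * f if params.frailty_mode == "multiplicative" else base + f
    if (rate < 0).any():
        raise ValueError("negative adenoma incidence rate")
    return rate


@dataclass
class Cohort:
    """Struct-of-arrays state for ``n`` simulated persons of a common age.

    Adenoma slots use size code 0 for "no lesion"; codes 1..3 follow
    :class:`AdenomaSize`. ``alive`` is False for both cancer deaths (cancer
    state DEAD) and other-cause deaths (cancer state unchanged).
    """

    age: int
    sizes: np.ndarray  # int8 (n, 10)
    villous: np.ndarray  # bool (n, 10)
    high_grade: np.ndarray  # bool (n, 10)
    cancer: np.ndarray  # int8 (n,)
    alive: np.ndarray  # bool (n,)
    frailty: np.ndarray  # float (n,)
    diagnosed_crc: np.ndarray  # bool (n,)
    crc_age: np.ndarray  # int16 (n,), -1 until first clinical diagnosis
    # Recurrence fate drawn at curative resection under recurrence_mode
    # "once": 0 undecided, 1 durably cured, 2 recur to PEC, 3 recur to CAC.
    recur_fate: np.ndarray  # int8 (n,)

    @classmethod
    def initial(cls, n: int, params: NaturalHistoryParams,
                rng: np.random.Generator, age: int = AGE_MIN) -> "Cohort":
        """A disease-free cohort with freshly drawn frailties."""
        return cls(
            age=age,
            sizes=np.zeros((n, MAX_ADENOMAS), dtype=np.int8),
            villous=np.zeros((n, MAX_ADENOMAS), dtype=bool),
            high_grade=np.zeros((n, MAX_ADENOMAS), dtype=bool),
            cancer=np.full(n, CancerState.NONE, dtype=np.int8),
            alive=np.ones(n, dtype=bool),
            frailty=sample_frailty(params, rng, n),
            diagnosed_crc=np.zeros(n, dtype=bool),
            crc_age=np.full(n, -1, dtype=np.int16),
            recur_fate=np.zeros(n, dtype=np.int8),
        )

    @property
    def n(self) -> int:
        return self.sizes.shape[0]

    def adenoma_count(self) -> np.ndarray:
        return (self.sizes > 0).sum(axis=1)

    def lesion_growth_allowed(self) -> np.ndarray:
        """Adenomas arise and progress only outside clinical care."""
        return self.alive & np.isin(
            self.cancer, (int(CancerState.NONE), int(CancerState.PRECLINICAL_EARLY)))

    def remove_adenomas(self, mask: np.ndarray) -> None:
        """Clear lesion slots flagged in the (n, 10) boolean mask."""
        self.sizes[mask] = 0
        self.villous[mask] = False
        self.high_grade[mask] = False


def advanced_mask(cohort: Cohort, params: NaturalHistoryParams) -> np.ndarray:
    """(n, 10) boolean: which lesion slots hold an advanced adenoma."""
    occupied = cohort.sizes > 0
    large = cohort.sizes == AdenomaSize.LARGE
    if params.advanced_definition == "any":
        adv = large | cohort.villous | cohort.high_grade
    else:  # strict: large OR (villous AND high-grade)
        adv = large | (cohort.villous & cohort.high_grade)
    return adv & occupied


def is_advanced_adenoma(size: AdenomaSize, villous: bool, high_grade: bool,
                        definition: str = "any") -> bool:
    """Scalar advanced-adenoma test (large OR villous OR high-grade)."""
    if definition == "any":
        return size == AdenomaSize.LARGE or villous or high_grade
    return size == AdenomaSize.LARGE or (villous and high_grade)


def sample_new_adenomas(cohort: Cohort, params: NaturalHistoryParams,
                        rng: np.random.Generator,
                        draws: np.ndarray | None = None) -> np.ndarray:
    """Poisson new-adenoma arrivals for one year, truncated at ten lesions.

    New lesions enter as diminutive, tubular, low-grade with onset at the
    cohort's current age. Returns the number actually added per person.
    Arrivals are drawn for everyone (fixed stream shape) and applied only to
    live persons outside clinical cancer states.
    """
    rate = incidence_rate(params, cohort.age, cohort.frailty)
    k = rng.poisson(rate) if draws is None else np.asarray(draws)
    eligible = cohort.lesion_growth_allowed()
    free = MAX_ADENOMAS - cohort.adenoma_count()
    add = np.where(eligible, np.minimum(k, free), 0)
    if add.any():
        empty = cohort.sizes == 0
        slot_rank = empty.cumsum(axis=1)  # 1-based rank among empty slots
        new = empty & (slot_rank <= add[:, None])
        cohort.sizes[new] = AdenomaSize.DIMINUTIVE
    return add


def step_adenomas(cohort: Cohort, params: NaturalHistoryParams,
                  rng: np.random.Generator) -> None:
    """One year of size progression/regression and histology switches.

    Each lesion moves at most one size category (competing up/down moves in
    a single categorical draw); villosity and dysplasia switch irreversibly
    with per-size annual rates, evaluated on the pre-move size and
    independently of the size move.
    """
    u_size = rng.random(cohort.sizes.shape)
    u_vill = rng.random(cohort.sizes.shape)
    u_dysp = rng.random(cohort.sizes.shape)

    act = (cohort.sizes > 0) & cohort.lesion_growth_allowed()[:, None]
    old = cohort.sizes.copy()

    dim = act & (old == AdenomaSize.DIMINUTIVE)
    small = act & (old == AdenomaSize.SMALL)
    large = act & (old == AdenomaSize.LARGE)

    cohort.sizes[dim & (u_size < params.diminutive_to_small)] = AdenomaSize.SMALL
    up = small & (u_size < params.small_to_large)
    down = small & ~up & (u_size < params.small_to_large + params.small_to_diminutive)
    cohort.sizes[up] = AdenomaSize.LARGE
    cohort.sizes[down] = AdenomaSize.DIMINUTIVE
    cohort.sizes[large & (u_size < params.large_to_small)] = AdenomaSize.SMALL

    vill_rate = np.array([0.0, *params.villosity])[old]
    dysp_rate = np.array([0.0, *params.dysplasia])[old]
    cohort.villous |= act & (u_vill < vill_rate)
    cohort.high_grade |= act & (u_dysp < dysp_rate)


@dataclass
class CancerEvents:
    """Per-person booleans emitted by one cancer-pathway step."""

    entered_resection: np.ndarray  # curative resection performed (cost C_te)
    entered_cac: np.ndarray  # newly in clinical advanced cancer
    died_cancer: np.ndarray


def step_cancer(cohort: Cohort, params: NaturalHistoryParams,
                rng: np.random.Generator) -> CancerEvents:
    """One year of the cancer pathway: at most one transition per person.

    From NONE, preclinical early cancer arises with probability
    ``1 - (1 - adv_adenoma_to_pec)**A`` where A counts the person's advanced
    adenomas (independent per-lesion hazards). Preclinical early cancer
    deteriorates to clinical advanced cancer or death (detection to clinical
    early cancer happens only in the screening module). Clinical early cancer
    resolves to curative resection or death; resection carries annual
    recurrence hazards; advanced cancer is incurable and only exits to death.
    """
    u = rng.random(cohort.n)
    st = cohort.cancer
    alive = cohort.alive
    p = params

    entered_resection = np.zeros(cohort.n, dtype=bool)
    entered_cac = np.zeros(cohort.n, dtype=bool)
    died = np.zeros(cohort.n, dtype=bool)

    # NONE -> PEC, person-level onset from A advanced adenomas.
    none = alive & (st == CancerState.NONE)
    if none.any():
        a_count = advanced_mask(cohort, p).sum(axis=1)
        p_onset = 1.0 - (1.0 - p.adv_adenoma_to_pec) ** a_count
        st[none & (u < p_onset)] = CancerState.PRECLINICAL_EARLY

    # Persons who just entered PEC this step must not transition again this
    # year (one transition per step): masks below exclude this step's movers.
    pec = alive & (st == CancerState.PRECLINICAL_EARLY) & ~none
    to_cac = pec & (u < p.pec_to_cac)
    to_dead = pec & ~to_cac & (u < p.pec_to_cac + p.pec_to_death)
    st[to_cac] = CancerState.CLINICAL_ADVANCED
    entered_cac |= to_cac
    died |= to_dead

    cec = alive & (st == CancerState.CLINICAL_EARLY)
    res = cec & (u < p.cec_to_resection)
    cdead = cec & ~res & (u < p.cec_to_resection + p.cec_to_death)
    st[res] = CancerState.CURATIVE_RESECTION
    entered_resection |= res
    died |= cdead

    # Recurrence after curative resection. u_rec is drawn every year in both
    # modes to keep the stream consumption identical across configurations.
    u_rec = rng.random(cohort.n)
    cure = alive & (st == CancerState.CURATIVE_RESECTION) & ~res
    if p.recurrence_mode == "annual":
        rec_pec = cure & (u_rec < p.resection_to_pec)
        rec_cac = cure & ~rec_pec & (u_rec < p.resection_to_pec
                                     + p.resection_to_cac)
    else:  # "once": fate fixed at resection, realized the following year
        fate = cohort.recur_fate
        fate[res & (u_rec < p.resection_to_pec)] = 2
        fate[res & (u_rec >= p.resection_to_pec)
             & (u_rec < p.resection_to_pec + p.resection_to_cac)] = 3
        fate[res & (fate == 0)] = 1
        rec_pec = cure & (fate == 2)
        rec_cac = cure & (fate == 3)
        fate[rec_pec | rec_cac] = 0  # consumed; redrawn on any later resection
    st[rec_pec] = CancerState.PRECLINICAL_EARLY
    st[rec_cac] = CancerState.CLINICAL_ADVANCED
    entered_cac |= rec_cac

    cac = alive & (st == CancerState.CLINICAL_ADVANCED) & ~to_cac & ~rec_cac
    died |= cac & (u < p.cac_to_death)

    st[died] = CancerState.DEAD
    cohort.alive[died] = False

    newly_clinical = entered_cac & ~cohort.diagnosed_crc
    cohort.diagnosed_crc[newly_clinical] = True
    cohort.crc_age[newly_clinical] = cohort.age
    return CancerEvents(entered_resection=entered_resection,
                        entered_cac=entered_cac, died_cancer=died)


def step_other_cause_mortality(cohort: Cohort, params: NaturalHistoryParams,
                               rng: np.random.Generator) -> np.ndarray:
    """Apply the (optional) age-specific background mortality for one year."""
    u = rng.random(cohort.n)  # always drawn: keeps stream parity across configs
    q = params.mortality_table()[cohort.age]
    dies = cohort.alive & (u < q)
    cohort.alive[dies] = False
    return dies
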