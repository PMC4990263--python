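"""Model parameters: disease dynamics, test characteristics, strategies, economics.

All defaults correspond to the published base case for average-risk Chinese
adults: age-specific adenoma incidence, adenoma size/histology transition
rates, cancer-pathway rates, FIT and colonoscopy per-lesion sensitivities,
costs in yuan and annual state utilities. The same values ship as YAML
(``crcsim/data/params_basecase.yaml``) so runs can be configured from files;
a unit test keeps the two in sync.

The one quantity the source base case does not pin down is the location of
the lognormal frailty that spreads adenoma risk across the population (only
its coefficient of variation, 1.7, is given). ``frailty_mean`` is therefore
the model's single calibrated parameter; see ``docs/methods.md``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

AGE_MIN = 20
AGE_MAX = 90

__all__ = [
    "AGE_MIN",
    "AGE_MAX",
    "AdenomaSize",
    "CancerState",
    "FindingClass",
    "NaturalHistoryParams",
    "TestSensitivities",
    "EconParams",
    "Utilities",
    "Compliance",
    "StrategyConfig",
    "ModelParams",
    "default_params",
    "load_params",
    "load_strategies",
    "default_strategies",
    "BASELINE_COMPLIANCE",
]


class AdenomaSize(enum.IntEnum):
    """Adenoma size class. 0 is reserved for 'no lesion' in array slots."""

    DIMINUTIVE = 1  # < 6 mm
    SMALL = 2  # 6-9 mm
    LARGE = 3  # >= 10 mm


class CancerState(enum.IntEnum):
    NONE = 0
    PRECLINICAL_EARLY = 1
    CLINICAL_EARLY = 2
    CURATIVE_RESECTION = 3
    CLINICAL_ADVANCED = 4
    DEAD = 5


class FindingClass(enum.IntEnum):
    """Colonoscopy finding classes; higher value = more severe (precedence)."""

    NO_ADENOMA = 0
    SMALL_1_2 = 1  # 1-2 diminutive or small adenomas
    SMALL_3_10 = 2  # 3-10 diminutive or small adenomas
    ADVANCED_ADENOMA = 3
    EARLY_CANCER = 4


# Residual non-CRC mortality, co-calibrated with the frailty location to
# the published base case (a full national life table is incompatible with
# the published no-screening QALYs; see docs/methods.md).
_OTHER_CAUSE_MORTALITY = (
    (20, 24, 0.00008), (25, 29, 0.00009), (30, 34, 0.00011),
    (35, 39, 0.00015), (40, 44, 0.0002), (45, 49, 0.0003),
    (50, 54, 0.0005), (55, 59, 0.0008), (60, 64, 0.0012),
    (65, 69, 0.0019), (70, 74, 0.0032), (75, 79, 0.0054),
    (80, 84, 0.009), (85, 90, 0.015),
)

# Age bands are inclusive on both ends.
_BASELINE_INCIDENCE = (
    (20, 39, 0.003),
    (40, 49, 0.007),
    (50, 54, 0.019),
    (55, 59, 0.022),
    (60, 64, 0.024),
    (65, 69, 0.028),
    (70, 74, 0.033),
    (75, 90, 0.035),
)


def _band_table(bands: Sequence[tuple[int, int, float]]) -> np.ndarray:
    """Expand (lo, hi, rate) bands into a dense per-age lookup over 20..90."""
    table = np.full(AGE_MAX + 1, np.nan)
    for lo, hi, rate in bands:
        table[lo : hi + 1] = rate
    if np.isnan(table[AGE_MIN : AGE_MAX + 1]).any():
        raise ValueError("age bands do not cover the full 20-90 range")
    return table


@dataclass(frozen=True)
class NaturalHistoryParams:
    """Annual transition rates of the adenoma-carcinoma natural history.

    All rates are annual probabilities on a one-year cycle; at most one
    cancer-pathway transition happens per person per year, and each adenoma
    makes at most one size move per year.
    """

    baseline_incidence: tuple[tuple[int, int, float], ...] = _BASELINE_INCIDENCE
    # Frailty: additive extra annual adenoma-incidence rate, constant over a
    # lifetime, lognormal across persons with mean `frailty_mean` and
    # SD `frailty_sd_factor * frailty_mean` (CV fixed at the published 1.7).
    # `frailty_mean` is the calibrated location parameter (see methods note).
    frailty_mean: float = 0.0225
    frailty_sd_factor: float = 1.7
    # Explicit (mu, sigma) of log-frailty override the mean/CV parameterization
    # when both are given; used for calibration experiments.
    frailty_mu: float | None = None
    frailty_sigma: float | None = None
    # "additive": rate(a) = baseline(a) + frailty (frailty in rate units);
    # "multiplicative": rate(a) = baseline(a) * frailty (frailty unitless,
    # mean 1 natural). The published wording supports either reading.
    frailty_mode: str = "additive"
    # Adenoma size moves (annual; at most one step per year).
    diminutive_to_small: float = 0.03
    small_to_large: float = 0.05
    small_to_diminutive: float = 0.195
    large_to_small: float = 0.05
    # Irreversible histology switches, by current size class (D, S, L).
    villosity: tuple[float, float, float] = (0.003, 0.015, 0.07)
    dysplasia: tuple[float, float, float] = (0.004, 0.006, 0.007)
    # Cancer pathway (annual).
    adv_adenoma_to_pec: float = 0.016
    pec_to_cac: float = 0.3
    pec_to_death: float = 0.18
    cec_to_resection: float = 0.96
    cec_to_death: float = 0.04
    resection_to_pec: float = 0.1137
    resection_to_cac: float = 0.1439
    # "once": the recurrence fate is decided once at curative resection
    # (recur to preclinical cancer / recur to advanced cancer / durably
    # cured) and realized the following year; "annual": the recurrence
    # probabilities act as competing annual hazards for life.
    recurrence_mode: str = "once"
    cac_to_death: float = 0.13
    # Advanced adenoma = large OR villous OR high-grade (standard clinical
    # definition); "strict" requires large OR (villous AND high-grade).
    advanced_definition: str = "any"
    # Age-banded annual other-cause mortality ((lo, hi, rate) bands); None
    # disables background mortality entirely. The default is a light
    # residual-mortality table calibrated with the frailty location.
    other_cause_mortality: tuple[tuple[int, int, float], ...] | None = \
        _OTHER_CAUSE_MORTALITY

    def __post_init__(self) -> None:
        rates = [
            self.diminutive_to_small,
            self.small_to_large,
            self.small_to_diminutive,
            self.large_to_small,
            *self.villosity,
            *self.dysplasia,
            self.adv_adenoma_to_pec,
            self.pec_to_cac,
            self.pec_to_death,
            self.cec_to_resection,
            self.cec_to_death,
            self.resection_to_pec,
            self.resection_to_cac,
            self.cac_to_death,
        ]
        if not all(0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all transition rates must lie in [0, 1]")
        for pair, label in [
            ((self.small_to_large, self.small_to_diminutive), "small adenoma"),
            ((self.pec_to_cac, self.pec_to_death), "preclinical early cancer"),
            ((self.cec_to_resection, self.cec_to_death), "clinical early cancer"),
            ((self.resection_to_pec, self.resection_to_cac), "curative resection"),
        ]:
            if sum(pair) > 1.0 + 1e-12:
                raise ValueError(f"competing probabilities for {label} exceed 1")
        if self.advanced_definition not in ("any", "strict"):
            raise ValueError("advanced_definition must be 'any' or 'strict'")
        if self.frailty_mode not in ("additive", "multiplicative"):
            raise ValueError("frailty_mode must be 'additive' or 'multiplicative'")
        if self.recurrence_mode not in ("annual", "once"):
            raise ValueError("recurrence_mode must be 'annual' or 'once'")
        if not (math.isfinite(self.frailty_mean) and self.frailty_mean >= 0):
            raise ValueError("frailty_mean must be finite and non-negative")
        if not math.isfinite(self.frailty_sd_factor):
            raise ValueError("frailty_sd_factor must be finite")

    def baseline_rate_table(self) -> np.ndarray:
        """Dense baseline incidence indexed by integer age (20..90 valid)."""
        return _band_table(self.baseline_incidence)

    def mortality_table(self) -> np.ndarray:
        """Dense other-cause mortality by age; zeros when disabled."""
        if self.other_cause_mortality is None:
            return np.zeros(AGE_MAX + 1)
        return _band_table(self.other_cause_mortality)

    def frailty_lognormal(self) -> tuple[float, float]:
        """(mu, sigma) of the log of the frailty distribution."""
        if self.frailty_mu is not None and self.frailty_sigma is not None:
            return float(self.frailty_mu), float(self.frailty_sigma)
        m, cv = self.frailty_mean, self.frailty_sd_factor
        if m == 0.0:
            raise ValueError("frailty_mean = 0 has no lognormal parameterization")
        sigma2 = math.log1p(cv * cv)
        return math.log(m) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass(frozen=True)
class TestSensitivities:
    """Per-lesion detection probabilities of colonoscopy and FIT."""

    colonoscopy: tuple[float, float, float] = (0.74, 0.87, 0.979)  # D, S, L
    colonoscopy_cancer: float = 0.99
    fit: tuple[float, float, float] = (0.0014, 0.12, 0.29)  # D, S, L
    fit_cancer: float = 0.79
    # Probability a lesion-free person tests FIT-negative. Not printed in
    # the source cost table; defaults to the 95% typical of the FIT
    # cost-effectiveness literature.
    fit_specificity: float = 0.95

    def __post_init__(self) -> None:
        vals = (*self.colonoscopy, self.colonoscopy_cancer, *self.fit,
                self.fit_cancer, self.fit_specificity)
        if not all(0.0 <= v <= 1.0 for v in vals):
            raise ValueError("sensitivities must lie in [0, 1]")

    def colo_by_size(self) -> np.ndarray:
        """Detection probability indexed by size code 0..3 (0 = empty slot)."""
        return np.array([0.0, *self.colonoscopy])

    def fit_by_size(self) -> np.ndarray:
        return np.array([0.0, *self.fit])


@dataclass(frozen=True)
class Utilities:
    """Annual utility U(S) by health state; most severe concurrent state wins."""

    healthy: float = 1.0  # no adenoma, or post curative resection
    small_adenoma: float = 0.955  # any diminutive/small, none advanced
    advanced_adenoma: float = 0.8
    early_cancer: float = 0.6  # preclinical or clinical early cancer
    advanced_cancer: float = 0.25
    death: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.healthy, self.small_adenoma, self.advanced_adenoma,
                self.early_cancer, self.advanced_cancer, self.death)
        if not all(0.0 <= v <= 1.0 for v in vals):
            raise ValueError("utilities must lie in [0, 1]")


@dataclass(frozen=True)
class EconParams:
    """Costs (yuan), utilities, discounting and the accounting window."""

    c_fit: float = 9.0
    c_colonoscopy: float = 290.0  # screening colonoscopy, no polypectomy
    c_pathology: float = 150.0  # charged once per colonoscopy with findings
    c_colo_with_polypectomy: float = 500.0  # bundled price incl. one polypectomy
    c_early_treatment: float = 4650.0  # curative resection, charged once
    c_advanced_treatment: float = 26750.0  # per year in advanced cancer
    # How a colonoscopy removing N adenomas is priced:
    #   "itemized": 290 + 150 pathology (if any finding) + N*(500-290);
    #   "bundled":  flat 500 + 150 pathology for any polypectomy exam;
    #   "listed":   290 + 150 pathology on every exam + N*500 (each list
    #               price charged as printed, per the cost-equation reading
    #               C_c I_c + N C_p I_p with C_c = colonoscopy + pathology).
    cost_mapping: str = "listed"
    # Advanced-cancer treatment charging: "once" charges C_ta at entry into
    # the advanced state (treatment initiation as a one-off action, the
    # reading consistent with the published cost table); "annual" charges it
    # every year spent in the state.
    advanced_cost_mode: str = "once"
    discount_rate: float = 0.03
    t_start: int = 45  # first screening / accounting age T_s
    t_end: int = 90  # last accounting age T_n
    utilities: Utilities = field(default_factory=Utilities)

    def __post_init__(self) -> None:
        costs = (self.c_fit, self.c_colonoscopy, self.c_pathology,
                 self.c_colo_with_polypectomy, self.c_early_treatment,
                 self.c_advanced_treatment)
        if not all(c >= 0 for c in costs):
            raise ValueError("costs must be non-negative")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError("discount rate must lie in [0, 1)")
        if self.cost_mapping not in ("itemized", "bundled", "listed"):
            raise ValueError(
                "cost_mapping must be 'itemized', 'bundled' or 'listed'")
        if self.advanced_cost_mode not in ("once", "annual"):
            raise ValueError("advanced_cost_mode must be 'once' or 'annual'")
        if not AGE_MIN <= self.t_start <= self.t_end <= AGE_MAX:
            raise ValueError("accounting window must lie within [20, 90]")

    @property
    def c_polypectomy(self) -> float:
        """Per-adenoma polypectomy increment under the itemized mapping."""
        return self.c_colo_with_polypectomy - self.c_colonoscopy


BASELINE_COMPLIANCE = (0.4537, 0.3732, 0.50)


@dataclass(frozen=True)
class Compliance:
    """Probability an offered test is actually taken.

    ``mode`` controls how the probability is realized: "per_person" treats
    compliance as a persistent behavioural trait (a fixed fraction of the
    population attends every offer of a modality, the rest never do), while
    "per_offer" draws an independent coin for every offer. Either way the
    long-run fraction of offers taken equals the configured rate.
    """

    fit: float = BASELINE_COMPLIANCE[0]
    first_colonoscopy: float = BASELINE_COMPLIANCE[1]
    followup_colonoscopy: float = BASELINE_COMPLIANCE[2]
    mode: str = "per_offer"

    def __post_init__(self) -> None:
        if not all(0.0 <= c <= 1.0 for c in
                   (self.fit, self.first_colonoscopy, self.followup_colonoscopy)):
            raise ValueError("compliance rates must lie in [0, 1]")
        if self.mode not in ("per_person", "per_offer"):
            raise ValueError("compliance mode must be 'per_person' or 'per_offer'")


@dataclass(frozen=True)
class StrategyConfig:
    """A FIT-plus-colonoscopy screening strategy.

    ``t_fit`` is the FIT interval in years; ``t_colo`` maps each colonoscopy
    finding class to the surveillance interval, with None meaning "no further
    colonoscopy ever" (at most one colonoscopy in a lifetime for persons whose
    findings always map to None — all screening stops).
    """

    name: str
    t_fit: int
    t_colo: Mapping[FindingClass, int | None]
    compliance: Compliance = field(default_factory=Compliance)
    # How T_c is applied after a colonoscopy:
    #   "hybrid": adenoma/cancer findings put the person under scheduled
    #     colonoscopy surveillance every T_c[finding] years, while a clear
    #     (no-adenoma) exam returns them to the FIT waiting cycle after
    #     T_c[no adenoma] years;
    #   "colonoscopy_cycle": every finding class, clear included, leads to
    #     scheduled surveillance colonoscopies every T_c[finding] years;
    #   "fit_cycle": the person always returns to the FIT waiting cycle and
    #     a new positive FIT can trigger the next colonoscopy once at least
    #     T_c[last finding] years have elapsed since the previous one.
    # A None interval terminates all screening in every flow.
    flow: str = "hybrid"

    def __post_init__(self) -> None:
        if self.t_fit < 1:
            raise ValueError("t_fit must be >= 1 year")
        if self.flow not in ("hybrid", "fit_cycle", "colonoscopy_cycle"):
            raise ValueError(
                "flow must be 'hybrid', 'fit_cycle' or 'colonoscopy_cycle'")
        missing = [f for f in FindingClass if f not in self.t_colo]
        if missing:
            raise ValueError(f"t_colo missing finding classes: {missing}")
        for f, t in self.t_colo.items():
            if t is not None and t < 1:
                raise ValueError(f"t_colo[{f.name}] must be >= 1 or None")

    def t_colo_array(self, sentinel: int = 10_000) -> np.ndarray:
        """Interval lookup indexed by FindingClass; None encoded as sentinel."""
        arr = np.full(len(FindingClass), sentinel, dtype=np.int32)
        for f, t in self.t_colo.items():
            arr[int(f)] = sentinel if t is None else int(t)
        return arr

    def with_compliance(self, fit: float | None = None,
                        first: float | None = None,
                        followup: float | None = None) -> "StrategyConfig":
        c = self.compliance
        return replace(self, compliance=Compliance(
            fit=c.fit if fit is None else fit,
            first_colonoscopy=c.first_colonoscopy if first is None else first,
            followup_colonoscopy=(c.followup_colonoscopy
                                  if followup is None else followup)))


@dataclass(frozen=True)
class ModelParams:
    """Bundle of everything a simulation run needs besides the strategy."""

    natural_history: NaturalHistoryParams = field(default_factory=NaturalHistoryParams)
    sensitivities: TestSensitivities = field(default_factory=TestSensitivities)
    economics: EconParams = field(default_factory=EconParams)


def default_params() -> ModelParams:
    """The published base-case parameter set."""
    return ModelParams()


_FINDING_KEYS = {
    "no_adenoma": FindingClass.NO_ADENOMA,
    "small_1_2": FindingClass.SMALL_1_2,
    "small_3_10": FindingClass.SMALL_3_10,
    "advanced": FindingClass.ADVANCED_ADENOMA,
    "early_cancer": FindingClass.EARLY_CANCER,
}


def _strategy_from_dict(d: Mapping) -> StrategyConfig:
    t_colo = {_FINDING_KEYS[k]: v for k, v in d["t_colo"].items()}
    comp = d.get("compliance")
    compliance = Compliance(**comp) if comp else Compliance()
    kw = {"flow": d["flow"]} if "flow" in d else {}
    return StrategyConfig(name=str(d["name"]), t_fit=int(d["t_fit"]),
                          t_colo=t_colo, compliance=compliance, **kw)


def load_strategies(path: str | Path | None = None) -> dict[str, StrategyConfig]:
    """Load strategies from YAML; defaults to the bundled ten-strategy table."""
    if path is None:
        text = resources.files("crcsim.data").joinpath(
            "strategies_basecase.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    out = {}
    for d in raw["strategies"]:
        s = _strategy_from_dict(d)
        out[s.name] = s
    return out


def default_strategies() -> dict[str, StrategyConfig]:
    return load_strategies(None)


def _tuple_bands(bands) -> tuple[tuple[int, int, float], ...]:
    return tuple((int(lo), int(hi), float(r)) for lo, hi, r in bands)


def load_params(path: str | Path | None = None) -> ModelParams:
    """Load a ModelParams bundle from YAML; defaults to the bundled base case."""
    if path is None:
        text = resources.files("crcsim.data").joinpath(
            "params_basecase.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)

    nh_raw = dict(raw.get("natural_history", {}))
    if "baseline_incidence" in nh_raw:
        nh_raw["baseline_incidence"] = _tuple_bands(nh_raw["baseline_incidence"])
    if nh_raw.get("other_cause_mortality") is not None:
        nh_raw["other_cause_mortality"] = _tuple_bands(
            nh_raw["other_cause_mortality"])
    for key in ("villosity", "dysplasia"):
        if key in nh_raw:
            nh_raw[key] = tuple(nh_raw[key])
    nh = NaturalHistoryParams(**nh_raw)

    s_raw = dict(raw.get("sensitivities", {}))
    for key in ("colonoscopy", "fit"):
        if key in s_raw:
            s_raw[key] = tuple(s_raw[key])
    sens = TestSensitivities(**s_raw)

    e_raw = dict(raw.get("economics", {}))
    if "utilities" in e_raw:
        e_raw["utilities"] = Utilities(**e_raw["utilities"])
    econ = EconParams(**e_raw)
    return ModelParams(natural_history=nh, sensitivities=sens, economics=econ)
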