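# Methods

`crcsim` is a discrete-time stochastic microsimulation of colorectal-cancer
(CRC) natural history in average-risk adults, with a FIT-plus-colonoscopy
screening layer and a cost-effectiveness layer. This note records the model,
its assumptions, the choices made where the design was genuinely open, and
what the bundled defaults do and do not reproduce.

## Natural history

Each simulated person ages from 20 to 90 on a one-year cycle. Per year, in
fixed order: other-cause death check, one cancer-pathway transition at most,
new-adenoma arrivals, adenoma progression, screening (ages 45–90), then cost
and utility accrual on the post-update state. Transitions stop after age 89;
age 90 contributes the final year's utility (and any ongoing treatment
charge) only.

**Adenomas.** A person carries up to ten concurrent adenomas, each with a
size class (diminutive <6 mm, small 6–9 mm, large ≥10 mm), a villosity flag
and a dysplasia-grade flag. New adenomas arrive as a Poisson process,
truncated at the ten-lesion cap, and start diminutive/tubular/low-grade.
Each lesion moves at most one size class per year (up/down as a single
categorical draw: diminutive→small 0.03; small→large 0.05, small→diminutive
0.195; large→small 0.05) and switches irreversibly to villous (0.003 / 0.015
/ 0.07 per year by size) and to high-grade (0.004 / 0.006 / 0.007).
Adenomas never vanish on their own — regression stops at diminutive — and
lesion growth is suspended while the person is under clinical cancer care.
An *advanced adenoma* is large OR villous OR high-grade (the standard
clinical OR-of-three; a stricter large-OR-(villous-AND-high-grade) variant
is configurable).

**Heterogeneous risk.** The annual new-adenoma rate is an age-specific
baseline (0.003/yr at 20–39 rising to 0.035/yr at 75–90) plus a lifelong
individual frailty drawn from a lognormal distribution. Only the frailty's
coefficient of variation (1.7) is externally fixed; its location is the
model's calibrated parameter (see *Calibration*). A multiplicative frailty
mode is available.

**Cancer pathway.** Only advanced adenomas seed cancer: with A advanced
lesions, preclinical early cancer (PEC) arises with probability
1−(1−0.016)^A per year (independent per-lesion hazards). PEC deteriorates
to clinical advanced cancer (0.3/yr) or death (0.18/yr); it becomes
*clinical early* cancer only through screening detection. Clinical early
cancer resolves within the year to curative resection (0.96) or death
(0.04). Advanced cancer is incurable and exits only to death (0.13/yr).
At most one cancer-pathway transition happens per person per year.

**Recurrence.** After curative resection the printed recurrence
probabilities (0.1137 to preclinical cancer, 0.1439 to advanced cancer) are
applied **once**, as a fate drawn at resection and realized the following
year; the remaining 74% are durably cured. The alternative — treating them
as competing annual hazards for life — is configurable, but it implies that
virtually every resected patient eventually recurs, contradicting the
premise that early cancer is curable and erasing any benefit of early
detection; comparison against the published strategy table confirmed the
one-off reading.

**Other-cause mortality.** The source is silent on background mortality.
A realistic national life table is incompatible with the published
no-screening QALYs (23.23): with any such table, discounted healthy
life-expectancy from 45 at 3%/yr is ≈18–19 QALYs, below the published value
before any disease drag. The default is therefore a light *residual*
mortality table (about one tenth of typical all-cause rates,
0.00008–0.015/yr by age band), co-calibrated with the frailty location; a
full synthetic life table ships in `crcsim/data/life_table_synthetic.yaml`
for scenario analyses, and `other_cause_mortality: null` disables background
mortality entirely.

## Screening

All strategies are FIT-plus-colonoscopy with two intervals: T_f between
FITs and T_c between colonoscopies, T_c depending on the previous
colonoscopy's finding class (no adenoma / 1–2 small / 3–10 small / advanced
adenoma / early cancer; most severe detected finding wins). The bundled
`strategies_basecase.yaml` holds the ten strategies compared in the base
case; an interval of `null` (∞) means screening stops — such strategies
perform at most one colonoscopy in the lifetime of a person whose exams
stay clear.

**Tests.** Every lesion is detected independently with its class
sensitivity (FIT: 0.0014/0.12/0.29 by adenoma size, 0.79 for preclinical
cancer; colonoscopy: 0.74/0.87/0.979, 0.99 for cancer). FIT specificity for
lesion-free persons is not printed in the source cost table; the default is
the literature-typical 0.95. Detected adenomas are removed at colonoscopy
(missed lesions persist and keep progressing); detected preclinical cancer
becomes a clinical early-cancer diagnosis.

**Flow.** A due FIT passes a compliance gate (non-compliers re-enter the
waiting cycle after T_f); a compliant positive FIT triggers a same-year
colonoscopy offer under the first-ever or follow-up colonoscopy compliance
rate; a refused colonoscopy is re-offered after T_f. After a colonoscopy,
the default **hybrid** flow applies: a finding puts the person under
scheduled colonoscopy surveillance every T_c[finding] years, while a clear
exam returns them to the FIT cycle after T_c[no adenoma] years — the usual
clinical division between polyp surveillance and population re-screening.
Two alternative flows are configurable: pure colonoscopy-cycle surveillance
(every finding class, clear included, books the next colonoscopy) and pure
FIT-cycle gating (T_c only sets the minimum spacing between
FIT-triggered colonoscopies). Both were rejected as defaults after
comparison with the published strategy table: the first doubles the
colonoscopy load of annual-FIT strategies, the second collapses colonoscopy
volume to ~0.2 per lifetime and erases the differences between strategies.

**Compliance** (baseline 45.37% FIT, 37.32% first colonoscopy, 50%
follow-up) is realized as independent per-offer draws. A persistent
per-person trait mode exists (`Compliance(mode="per_person")`) but caps the
ever-scoped fraction of the population at the first-colonoscopy rate, which
is incompatible with the published prevented-case counts.

## Economics

Costs (¥) and QALYs accrue over ages 45–90 with continuous discounting
e^{−λ(t−45)}, λ = 3%. Yearly cost sums the events of that year: FIT ¥9;
colonoscopy ¥290 + pathology ¥150 per exam + ¥500 per adenoma removed (the
default "listed" mapping — each list price charged as printed; an
"itemized" mapping with a ¥210 per-adenoma increment and pathology only on
positive exams, and a flat "bundled" ¥500 mapping, are configurable);
curative resection ¥4650, charged once; advanced-cancer treatment ¥26,750,
charged **once at entry** into the advanced state. The one-off reading of
the advanced-treatment indicator is load-bearing: charging it annually for
the ~7.7-year mean dwell makes every screening strategy strongly
cost-saving, with incremental cost-effectiveness ratios near −2500 ¥/QALY
instead of the published +116…+352; only treatment *initiation* charging
reproduces their sign and scale. The annual mode remains configurable.

Utility each year is that of the most severe concurrent state: healthy or
post-resection 1.0, diminutive/small adenoma 0.955, advanced adenoma 0.8,
early cancer (preclinical or clinical) 0.6, advanced cancer 0.25, death 0.

ICER(A,B) = (C_A−C_B)/(E_A−E_B); ICPCP(A,B) = (C_A−C_B)/(cases_B−cases_A),
with lifetime diagnosed-CRC cases per person (first entry into a clinical
cancer state) as the case definition. Degenerate comparisons (equal QALYs,
no or negative case difference) raise instead of returning silently.

## Monte-Carlo design

State is struct-of-arrays NumPy; a cohort advances one vectorized step per
year (~0.1 s per 20,000-person arm-lifetime). Each arm uses two RNG
streams. The natural-history stream consumes fixed-shape draws every year
regardless of who they apply to, so arms sharing a seed share frailties,
adenoma histories and cancer-path randomness exactly — common random
numbers across strategies, and a zero-compliance arm is bit-identical to
the no-screening arm. The screening stream is arm-specific. Replicate r of
an experiment with seed s derives its streams from SeedSequence([s, r, 0])
and SeedSequence([s, r, 1, arm]).

## Calibration

The published model was calibrated to external adenoma- and CRC-count data
that are not reproduced here; the generic harness in `crcsim.calibration`
(weighted least squares on fixed-seed simulated summaries, derivative-free
Nelder-Mead, optional staged fitting) stands in for that step and is
exercised by parameter-recovery tests. For the bundled defaults, the two
quantities the source leaves open — the frailty location and the residual
mortality level — were fitted to the published no-screening base case
(cost ¥1656, 23.23 QALYs) jointly with the level of the leading strategies'
ICERs, giving frailty mean 0.0225/yr (CV 1.7) and the residual mortality
table above. These defaults were frozen before the acceptance suite was
written and not revisited.

## What the defaults reproduce, and what they do not

At the scaled-down study conditions (20,000 persons × 10 replicates,
baseline compliance, common random numbers) the defaults reproduce: the
no-screening QALY level (22.1 vs 23.23); the ICER block of the annual-FIT
strategies 5–10 within ±15% (e.g. strategy 10: ≈120 vs 116.2 ¥/QALY;
strategy 8: ≈126 vs 122.3); strategy 10 as the lowest-ICER and
lowest-ICPCP strategy; positive QALY gains for all ten strategies; the
decline of ICER with first-colonoscopy compliance; the strategy-9/10
ranking crossover inside the 40–50% FIT-compliance band; and a
strategy-10 prevented-case fraction (~0.024/person) inside the
0.01–0.06 band implied by the published incremental cost per case
prevented.

Known residual discrepancies, stable across every structural variant we
constructed (three screening flows, three cost mappings, two recurrence and
two advanced-charging modes, additive/multiplicative frailty, 0–100%
background-mortality scaling): the no-screening mean cost plateaus ~33%
below ¥1656 at any frailty level compatible with the QALY and ICER targets;
the biennial-FIT strategies 1–4 come out more favourable (ICERs ≈125–150)
than published (243–352), so the annual-beats-biennial ordering and the
FIT-compliance sweep direction are not reproduced; and the strategy-10
ICPCP is ≈3400 vs 1823 (both its numerator and denominator off in the
unfavourable direction). These point to undocumented details of the
original screening flow and cost accounting rather than to parameter
choices; the corresponding acceptance tests are left failing rather than
loosened.

## Limitations

Beyond the discrepancies above: no colonoscopy complications (no rates
given); no anatomic lesion location or molecular subtype; compliance is
independent of screening history; the synthetic cohorts are all
asymptomatic 20-year-olds, so the model says nothing about screening
started mid-life with prevalent disease; and the utility weights apply to
undetected states (an unnoticed adenoma reduces quality of life), which is
a modelling convention inherited from the state-based accounting rather
than a clinical claim.
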