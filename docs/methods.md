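# Methods

This note documents the statistical model behind `excurves`, the
defaults of every parameter that matters, what the synthetic cohort
does and does not emulate, and the numerical conventions.

## The exposure model

The unit of analysis is the resident. An *exposure event* is an
attributed encounter together with the set of taxonomy topics its note
maps to. Exposure is binary at the encounter level: mentioning a
condition twice in one note adds nothing, and an encounter whose note
maps to no topic contributes an empty set (it still counts as a
patient). For resident *r* with events at training days
d₁ ≤ d₂ ≤ …, the cumulative curve is

    C_r(d) = | ∪ {T_e : d_e ≤ d} |

which is non-decreasing and bounded by the catalog size (895 in the
default taxonomy). Training time is resident-relative: day 0 is the
resident's start date and postgraduate year *n* is days
[(n−1)·365, n·365). The alternative — calendar academic years starting
July 1 — differs only for off-cycle starters; the resident-relative
rule keeps curves comparable across classes and is what the package
uses throughout.

### Window rates and plateaus

New-topic rates are measured on windows tiling [0, last event day]:
half-open [k·step, k·step + window) with window = step = 30 days by
default. With tiling windows the per-window new-topic counts sum
exactly to the final cumulative count, a conservation law the tests
assert. "Sliding" overlapping windows (step < window) are supported but
break that conservation and make "3 consecutive windows" ambiguous,
which is why tiling is the default. A window's rate is
100 · (first-ever topics in window) / (patients in window); a window
with zero patients has an *undefined* rate, never zero — treating it as
zero would manufacture plateaus out of vacations.

A **plateau** is the earliest run of `consecutive = 3` windows, each
with a defined rate strictly below `threshold = 1.0` new topics per
100 patients. The reported plateau day is the start of the run's first
window, and plateau months are day/30. Undefined windows break runs.
The strict inequality matters at the boundary: a window at exactly 1.0
does not qualify.

### Attribution

Primary credit goes to the earliest treatment-team documenter whose
timestamp falls inside one of their clinical shifts, with a
`shift_grace` of 30 min absorbing documentation that straddles shift
ends (set it to 0 for strict containment). Ties are broken by
lexicographic resident id — arbitrary but deterministic. An encounter
whose only documenters are off-shift is excluded entirely, which is how
nonclinical/administrative work drops out. A supervisory record goes to
the resident with strictly higher PGY (at their own documentation time)
documenting within `coattribution_window = 60 min` of the primary; when
several qualify, the smallest |Δt| wins, so an encounter carries at
most one supervisor. Sixty minutes is a judgment call — nothing in the
data model pins down "close temporal proximity" — hence it is a policy
field, not a constant. Counting then follows two deliberate policies:
resident-level analyses credit both roles
(`per_resident_exposure`), while encounter/patient-level denominators
count each encounter once under the primary resident's PGY
(`unique_encounter`).

### Note mapping

The mapper is a deterministic stand-in with the same three-stage shape
as retrieval-augmented clinical NLP: retrieval, extraction/filtering,
classification. Retrieval is longest-match, left-to-right,
case-insensitive token matching of lexicon synonyms over the HPI, MDM
and ED-course sections (other sections are ignored). Context
classification is trigger scoping: a mention is negated / historical /
uncertain iff a trigger ("no", "denies", "negative for", "without" /
"history of", "prior" / "possible", "questionable") occurs earlier in
the same sentence with no terminator ("but", "however", ";") between
trigger and mention; precedence is negated > historical > uncertain.
Sentences split on `.`, `!`, `?` and newlines — a deliberately
simple, testable scoping unit. The inclusion policy defaults to
{affirmed, uncertain}: a condition evaluated is exposure even if ruled
out later, but a condition explicitly negated or merely historical is
not. Both sets are configurable. The whole mapper is pluggable: any
callable producing per-encounter topic sets (e.g. an LLM-backed
classifier) can replace it upstream of the curves.

Validation statistics: percent agreement (reported to 2 decimals) and
Cohen's κ = (p_o − p_e)/(1 − p_e) with chance agreement from marginal
products; κ is undefined when both raters use a single category, and
multi-rater panels reduce to the mean of pairwise κ.

## The synthetic cohort

The generator emulates a 62-resident, 4-class academic ED program over
seven calendar years:

| parameter | default | role |
| --- | --- | --- |
| class sizes | 15/16/15/16 | 62 residents, classes one year apart |
| annual volume means | 445.7 / 772.1 / 1193.4 / 1528.4 | per-PGY encounters per resident |
| volume CVs | 24.6 / 17 / 18 / 25.4 % | lognormal inter-resident spread |
| ESI means by PGY | 2.94 / 2.87 / 2.85 / 2.79 | exponential tilt of the marginal ESI mix (1.2/24.1/65.7/8.2/0.8%, 1.8% missing) |
| admission prob. | 0.31 / 0.383 / 0.355 / 0.375 | Bernoulli per encounter |
| topics/encounter | min(1 + Poisson(2), 8) | mentions per note; nothing in ED documentation pins this down, 3 is a realistic mean |
| topic frequencies | power law p_k ∝ k^−s over 895 ranks, s calibrated | heavy-tailed case mix |
| distractor rates | 0.30 / 0.20 / 0.15 | negated / historical / uncertain injected mentions |
| senior coattribution | 0.5 | probability a junior's encounter gets a senior documenter when one shares the slot |

Annual volumes are lognormal parameterized by (mean, CV) — positive,
right-skewed, and exactly reproducing the configured mean. Encounters
are placed in 8-hour shift slots on a common day grid so seniors
sharing a slot can document within the coattribution window; the
generator guarantees the junior documents first and the senior inside
the window and their own shift, which is what makes attribution
recovery exact (100%) and a meaningful end-to-end check. The ESI tilt
solves for θ in w_e ∝ base_e·e^{θe} by bracketing, hitting each PGY's
target mean exactly in expectation.

The power-law exponent is calibrated by deterministic grid search
(step 0.01 on [0, 3], refined at 0.0005) minimizing the squared error
between the expected topic-count bucket fractions (>100 / 10–100 / <10
occurrences) and the configured targets (5.5% / 31.7% / 62.9%), at the
generator's own expected draw count. One structural fact is worth
stating plainly: those three bucket fractions overdetermine a
single-exponent power law. The two bucket boundaries force
s = ln 10 / ln(333/49) ≈ 1.20, and that exponent reproduces the target
buckets only at ≈46k total draws; at the ~730k draws implied by the
cohort's volumes the best compromise exponent (s ≈ 1.8) yields roughly
(96, 250, 549) instead of (49, 284, 562). The calibrator therefore
returns the least-squares compromise (and raises a calibration error,
carrying the best exponent found, if the residual exceeds its
threshold). Tests assert that the realized histogram matches the
calibrated law's own expectation — computed with a dedup-aware oracle,
since within-encounter draws are deduplicated — not the unreachable
target triple.

What the generator does **not** emulate, and hence what passing tests
do not show about real data: topic draws are i.i.d. across encounters
(no patient-level correlation, no seasonality, no per-resident case-mix
niches), notes are templated (real negation scoping is far messier than
the trigger grammar), documentation is complete and timely, volumes
carry no pandemic-era shocks, and patient demographics are reduced to a
repeat-visit probability (0.452, matching a ~55% unique-patient
share). In particular the i.i.d. topic model yields late-training
new-topic rates above the plateau threshold, so default synthetic
cohorts typically show *no* plateau — real plateau timing depends on
saturation dynamics the generator does not claim to reproduce, which is
why plateau detection is validated on dedicated streams with a known
stop day instead (recovery within one window of the true stop day).

## Numerical conventions

- Gini: population (ordered-pair) form G = Σᵢⱼ|xᵢ−xⱼ|/(2n²x̄), computed
  via the sorted-weights identity in O(n log n); equals the
  Lorenz-trapezoid definition (tested to 1e−12) and is bounded by
  (n−1)/n. All-zero input is an error, not 0. A sample-corrected
  variant (× n/(n−1)) is available. For topic-distribution inequality
  both readings are reported: the mean over residents of each
  resident's per-topic-count Gini, and the Gini of pooled counts.
- CV: 100·sd/mean with the n−1 denominator; needs n ≥ 2 and a nonzero
  mean.
- Kruskal–Wallis H uses midrank tie correction (scipy), p from
  χ²(k−1), and η² = (H−k+1)/(n−k) floored at 0.
- Proportion intervals are Wilson score intervals; mean intervals are
  t-based normal approximations. Neither choice is forced by the data
  model; both are stated so results are comparable.
- Frequency buckets partition all catalog topics: >100 strict,
  10–100 inclusive, <10 strict with zero-count topics in the last
  bucket; percentages use the catalog size as denominator, 1 decimal.
- Missing ESI stays missing and is excluded from ESI numerators and
  denominators; it never becomes a sentinel value.
- All timestamps are timezone-naive local time (single-site model).
- Determinism: every stochastic step draws from one seeded
  `numpy.random.Generator`; identical config + seed gives
  byte-identical files and manifest checksums.

## Problem sizes used by the test suite and acceptance script

The closed-loop and distribution checks run on the full default cohort
(62 residents, ≈240k encounters, ≈730k topic draws). Plateau recovery
uses 150 seeded streams (3 stop days × 50 replicates). Pipeline
determinism and the worked example use an 8-resident cohort with
reduced volumes, which exercises every stage in a few seconds.
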