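# Methods

## Task and data model

The package analyses per-response data from a Brown–Peterson complex-span
task: each trial presents four letters in four screen boxes, four
arithmetic verification problems fill the retention interval, and memory
is tested by four sequential position probes (yes/no local recognition).
The default geometry is 70 trials × 8 responses = 560 responses per
participant; the final 10 trials form a verbal-disruption block in which
participants utter task-irrelevant syllables ("mamma mia") instead of
rehearsing. 48.2% of memory probes are items from the studied list and
50% of arithmetic problems are correct; both rates are geometry
parameters. A participant's complete response set is a *data pattern*,
the unit of every quality decision.

All I/O uses one tidy CSV (one row per response) with booleans as 0/1 and
lowercase string enums, so that write→read→write round-trips
byte-identically. RTs are stored in milliseconds, uncapped at ingest:
screening rules must see raw values.

## Sequential quality filter

**Part 1 — anomalous patterns.** Extreme RTs are identified *within* each
pattern: small means < 400 ms (absolute fence; near the physiological
floor for a decision keypress), large means above the pattern's own
Q2 + 1.5·(Q3−Q1). A Q3 + 1.5·IQR dialect is selectable
(`large_fence_rule`) because both anchors are in circulation for this
fence; the Q2 anchor is the default and the fences differ by at most
Q3−Q2. Quantiles interpolate linearly between order statistics; under
alternative quantile definitions the fences move by less than one sample
spacing. By default only the 480 regular-trial responses are profiled
(`profile_scope="regular_only"`); the disruption block is excluded
because its instructions change the behaviour being profiled.

Anomaly detection is cohort-relative and univariate. For one dimension
(count of small RTs, count of large RTs, median RT, regular accuracy),
the cohort's values are split into two groups by exact 1-D 2-means
(exhaustive minimisation of within-group sum of squares over contiguous
splits of the sorted values, computed with prefix sums; a two-component
Gaussian mixture is available as `cluster_method="gaussian_mixture_2"`).
The group on the extreme side (high for counts and median RT, low for
accuracy) is flagged only if

* it holds at most `max_flag_fraction` (default 0.25) of the cohort —
  anomalies are by definition a minority; and
* the empty interval between the two groups is wider than
  `separation_ratio` (default 3.5) standard deviations of the bulk group.

The boundary-gap guard is what lets homogeneous cohorts pass untouched: a
unimodal sample's optimal 2-means split lands in a dense region, so the
inter-group gap is a fraction of the bulk spread (ratio ≲ 1.5 in
simulation), whereas planted contaminants sit across gaps 10–100× the
bulk spread. A centroid-distance guard was tried first and discarded: on
clean unimodal cohorts of ~40 the centroid separation routinely reaches
3–4 within-SDs, making false alarms unavoidable at any threshold that
still catches moderate outliers. If no qualifying split exists, nothing
is flagged; all values identical flags nothing and logs.

Screening runs in three sequential sub-stages, each clustering only the
previous stage's survivors, pooled across all participant pools at once:
(i) the two extreme-RT counts; (ii) accuracy and median RT; (iii) a fixed
floor on disruption-trial memory accuracy (< .425 flags), which catches
patterns that guessed or disengaged precisely on the disruption block.
Accuracy in (ii) is the mean over regular-trial responses by default
(`accuracy_stat="median"` selectable; the median of 0/1 responses is too
coarse to separate moderate low performers).

**Part 2 — verbal disruption.** Memory accuracy on disruption trials must
be *strictly* lower than on regular trials, computed over memory-phase
responses only (the processing task does not engage rehearsal). Ties
count as absent: the conservative reading of "lower". For a compliant
participant the effect is near-ubiquitous; a participant who never
rehearsed shows no decrement and passes or fails at chance.

**Part 3 — rehearsal primacy.** On the probe-present, correct,
regular-trial memory responses, the per-serial-position median RTs are
computed; the effect is present iff median(SP1) < mean of the other
positions' medians, again strict. A pattern with an empty
serial-position cell is *ineligible*, reported separately and excluded
from the step's denominator rather than counted as failing — the
criterion cannot be evaluated on it.

Cohort serial-position curves average the per-pattern medians and attach
symmetric t-based 95% confidence intervals.

**Reporting.** Per pool and step: N, flagged percentage, and a 95% Wilson
score interval (no continuity correction — the plain score interval
reproduces published small-sample intervals exactly, e.g.
3/40 → [2.6, 19.9]). Adjacent pools are compared with two-sided Fisher
exact tests under the sum-of-at-most-as-probable-tables convention, the
definition used by standard implementations. The text rendering prints
significance at the granularity ≈ / p < .05 / p < .001; CSV/JSON carry
raw p-values and unrounded percentages. Display percentages round
half-up to one decimal. Because screening thresholds are cohort-relative,
classification is intentionally *not* idempotent under cohort changes:
re-screening only the flagged patterns yields different (typically no)
flags. This is a property of the method, not a defect.

## Synthetic participant generator

RTs follow an ex-Gaussian — Normal(μ, σ) plus an exponential tail with
mean τ — the standard phenomenological RT family; the heavy right tail
exercises the upper fence. RTs are floored at 150 ms. Each response may
independently be a *fast guess* (probability `p_guess`: RT uniform on
[150, 350] ms — strictly below the 400 ms fence, so planted guessers are
detectable by construction — and coin-flip correctness) or suffer a
*distraction lapse* (probability `p_lapse`: an exponential delay with
mean `lapse_scale` is added). Correctness is Bernoulli(`acc_regular`),
reduced by `disruption_decrement` on disruption-trial memory responses.
A memory response at serial position 1 is faster by `sp1_advantage` ms.

Six archetypes parameterise behaviour. The compliant baseline uses
μ=700, σ=120, τ=250 ms, accuracy .90, disruption decrement .20, primacy
advantage 120 ms, 1% guesses and lapses. The `non_complier` ignores the
rehearsal instructions, so it gets decrement 0 *and* primacy advantage
0: with strict-inequality criteria its presence rate on either benchmark
is chance (~0.5), which is exactly why absence of the disruption effect
reads as evidence of non-compliance. Non-compliance is modelled as "no
effect", not a reversed effect. Contaminant archetypes: `fast_guesser`
(85% guesses), `distracted` (22% lapses with 3 s mean delay),
`slow_responder` (μ=1800, τ=600), `low_performer` (accuracy .55).
Accuracy-based primacy is deliberately not generated: only the RT
criterion is evaluated downstream.

Preset per-pool mixtures are calibration choices, not measured facts:
the lab preset has no non-compliers (monitored testing enforces
compliance) and 7% mild contaminants; the web-student and Prolific
presets carry ~30% non-compliers and ~8–9% contaminants; the MTurk preset
70% non-compliers and 14% contaminants. Weights follow from the
coin-flip presence logic (a pool failing the disruption benchmark at
rate r needs ≈ 2r non-compliers) applied to the flag-rate ordering the
pipeline is meant to reproduce: lab ≥ web students ≈ Prolific ≫ MTurk.
Default pool sizes are 40 / 215 / 300 / 196.

Reproducibility: every generator takes a seed; a pool scenario draws
archetype assignments and per-participant child seeds from one seeded
generator, so identical seeds give identical datasets across runs and
platforms (exact for integers and enums, bit-reproducible floats from
the same numpy generator stream).

### What the generator does not emulate

Browser/OS keystroke-timing jitter, stimulus content (letters, operands),
practice/training dynamics, fatigue or learning trends across trials, and
accuracy-based primacy. Participants are i.i.d. within archetype; real
pools mix behaviours continuously rather than in six discrete types, and
real "non-compliers" often comply partially. Passing tests on this
generator therefore show that the pipeline recovers *planted, archetypal*
contamination and that its statistics are internally consistent — not
that the specific preset rates match any particular real pool. One known
consequence: because the large-RT fence adapts within-pattern, heavy
lapse contamination widens a pattern's own fence and `distracted`
participants are only partially caught by screening (they are
under-represented in the recovery guarantees for that reason).

## Numerical and design notes

* Quantiles: linear interpolation (`numpy.quantile` default).
* 2-means split ties: first optimum in sorted order wins (deterministic).
* Wilson bounds are clamped to contain the point estimate (guards
  ~1e-15 float noise from the closed form) and to [0, 100].
* Fisher tests require strictly positive margins; pipeline comparisons
  with a degenerate margin (nobody flagged in either pool) report p = 1.
* Percentages display half-up at one decimal (`decimal`-based, avoiding
  banker's rounding); unrounded values are retained everywhere
  internally. A published table that prints 87.6% for 35/40 will be
  reported here as 87.5.
* Profiling requires ≥ 4 RTs (quartiles); patterns failing this are
  excluded with status `unprofiled` and surface in the report's
  conservation identity: initial N = anomalous + unprofiled +
  no-disruption + ineligible + no-primacy + retained.

## Problem sizes used in the test suite

Monte-Carlo checks run at 300–500 simulated participants (≥ 10⁴ responses
for accuracy calibration, 3·SE bands), contamination recovery at the
preset Prolific scale (n = 300, fixed seed), and the full-pipeline checks
at the four preset pools (751 participants). Property-based tests
(clustering vs brute-force split, Fisher vs exact rational enumeration)
run derandomised on cohorts ≤ 20 and margins ≤ 30.
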