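# Methods

`repstream` implements the full behavioural pipeline of a repetition-
detection RSVP experiment: design generation, a generative observer model,
detection and memory scoring, and the statistical layer. This note records
the model, its parameters, and the design choices made where the published
procedure leaves the details open.

## Experimental design

Images are abstract integer identifiers (image content plays no role in any
computation, so no image files are involved). A *block* is one continuous
15 Hz stream: each image is shown for 7 refreshes of a 120 Hz display
(58.33 ms) followed by a one-refresh blank (8.33 ms), giving an SOA of
1000/15 ms. Durations are stored as exact refresh multiples and every onset
is computed as `index * SOA` from a zero origin, so no rounding can
accumulate; the commonly quoted 58.3/8.3 ms are the same quantities at
one-decimal precision.

Twenty repetition sequences are embedded per block. A sequence shows one
target six times with 1–5 never-repeated distractors in each of its five
gaps — either the same count in every gap (*regular*, d ∈ 1..5) or a
permutation of (1, 2, 3, 4, 5) (*irregular*). A session comprises 12 blocks
covering 24 copies of each regular condition plus each of the 120 irregular
permutations exactly once; the 240-condition ledger is shuffled globally
and chunked into blocks, so conditions are deliberately not balanced per
block.

Open details were fixed as follows:

- **Gap distribution.** Inter-sequence gaps are uniform over the integer
  image counts {37..52}; only the range is documented, and the uniform is
  the simplest distribution consistent with it.
- **Lead-in and tail.** One gap from the same distribution precedes the
  first sequence (20 gaps per block in total) and a fixed tail of 22
  distractors follows the last one. This is a reconstruction calibrated so
  the expected stream length, 20·21 + 20·44.5 + 22 = 1332 images, matches
  the documented mean; where the padding actually sat in the original
  streams is not recorded.
- **Image identifiers.** Allocated sequentially per session, making the
  global uniqueness invariants (each distractor exactly once, each target
  exactly six times) checkable by exhaustive counting.
- **Session image count.** A session presents ≈14,800 distinct images; the
  documented ≈16,000 evidently includes the six practice blocks. Practice
  is represented only as a deterministic expected image count
  (`expected_practice_image_count`, ≈1,430, from 6 blocks of 5–6 sequences
  at 2/8/15 Hz with gaps of 2.5–3.5 s scaled by rate), not simulated.
- **Target rate arithmetic.** Consecutive target onsets in a regular-d
  sequence are (d+1)·SOA apart, i.e. 15/(d+1) Hz = 7.5, 5, 3.75, 3, 2.5 Hz
  for d = 1..5; the generator follows this arithmetic.

## The synthetic observer

The observer exists so that every downstream analysis can be exercised and
audited against known generative truth. Per sequence it emits, with a
condition-group-dependent *hit probability*, exactly one press at the
second-presentation onset plus a reaction time drawn from a shifted
lognormal (shift 200 ms, scale 600 ms, sigma 0.5; median ≈ 0.8 s) truncated
to the response window; with probability 0.015 a detected sequence receives
a second in-window press. False alarms are a homogeneous Poisson process
(0.01 presses/s) over the stream plus the trailing window — the minimal
assumption that still exercises the scoring rule's rejection of
out-of-window presses.

Default hit probabilities decrease with the distractor count (regular:
0.79 → 0.45; irregular groups keyed by first interval: 0.67 → 0.57, mean
0.615 in both halves). Together with the extra-press and false-alarm rates
this analytically reproduces the two calibration anchors of the observed
behaviour: 20·0.615·1.015 + 0.94 ≈ 13.4 presses per block, and ≈2% of
trials with more than one in-window response.

Memory responses choose the target with a condition-group accuracy
(defaults 0.80 → 0.52 regular, 0.70 → 0.61 irregular; chance is 0.25),
otherwise one of the three foils uniformly. Foils are single-presentation
images from the same stream, disjoint across the 20 probes. Probe order is
a plain uniform permutation (the original description that probe order "did
not match" the stream is read as a property of randomisation, not a
rejection rule). Confidence (0–4) is drawn from separate distributions for
correct and incorrect choices, the former stochastically larger. An
optional `mem_recency_slope` tilts accuracy with stream position on the
logit scale; it defaults to zero and exists so the delay analysis can be
validated against an injected, known recency effect.

What the generator does *not* model: attentional blink, repetition
blindness, learning or fatigue across blocks, foil similarity, and any
dependence of memory on whether the sequence was detected. Passing tests
therefore demonstrate that the pipeline recovers the structure this model
generates, not that it would capture every feature of human data.

## Detection scoring

A sequence counts as detected when *exactly one* press falls strictly
inside (200, 2500) ms after the second-presentation onset; that onset is
also RT = 0. Windows in generated designs can never overlap (the shortest
possible separation exceeds the window length), but as a guard a press
falling inside two windows is assigned to the earlier sequence only.

Chance level re-scores the same press *counts* after replacing all
timestamps with i.i.d. uniforms on [0, last image offset + 2500 ms] — the
domain must reach past the final window. One scramble reproduces the
original procedure; `n_scrambles > 1` averages to reduce Monte-Carlo noise.
Under non-overlapping windows the scrambled per-sequence detection
probability has the closed form k·(w/T)·(1 − w/T)^(k−1), which serves as an
independent oracle in the tests. The chance-corrected measure is the
percentage-point difference between real and scrambled rates.

Two paired contrasts compare spacing regularity per participant, both
reported as Irregular − Regular: regular-3 trials against a seeded random
irregular subsample of equal size (equal sequence length, ~24 trials per
session per arm), and all 120 regular against all 120 irregular trials
(equal interval distribution). Irregular trials are grouped by first
interval (`I1`..`I5`) for per-condition summaries but pooled in the
contrasts.

## Memory scoring and the delay split

Accuracy, RT and confidence are aggregated per condition group, first
within then across participants. The stream-to-probe delay of a trial with
stream position i and probe position j (both 1-based) is `20 − i + j` —
the number of intervening targets in the stream and the memory task plus
one, the only reading consistent with the documented bin ranges. Delays
3–20 are *short*, 21–37 *long*, and the rare extremes (1–2, 38–39) are
excluded. The split compares per-participant bin means with a 95% BCa CI of
the short-minus-long difference; the pooling is condition-unbalanced by
construction. Participants lacking one bin are dropped with a warning.

## Statistical layer

- **BCa bootstrap** (default 2000 resamples) backs all CIs, via
  `scipy.stats.bootstrap`; constant input degenerates to a point interval
  with a warning, and in the pathological case where the resampled bounds
  exclude the point estimate the interval is widened to include it.
- **One-way ANOVA** is an explicit between/within sum-of-squares
  decomposition (so the SS identity can be asserted to machine precision),
  with p from the F distribution; five groups of 19 participant means give
  df = (4, 90). All-identical input defines F = 0 with a warning.
- **Tukey-Kramer** post-hoc comparisons use `scipy.stats.tukey_hsd`
  (studentized range with pooled variance; the Kramer harmonic form for
  unequal n), validated in the tests against a Monte-Carlo studentized-range
  null.
- **JZS Bayes factor** for paired differences is authored here: a
  Cauchy(0, r) prior on the standardised effect size with r = √2/2 (the
  conventional default; the exact prior used originally is not recorded, so
  r is exposed as a parameter), marginalised through the equivalent
  g ~ InverseGamma(1/2, 1/2) integral with `scipy.integrate.quad` in log
  space. Contrasts are two-sided one-sample tests on participant-wise
  differences. Evidence labels use the conventional bands (anecdotal < 3,
  moderate 3–10, strong > 10, applied to BF10 or its reciprocal).

No multiple-testing correction is applied beyond Tukey-Kramer, and no
signal-detection d′ analysis is attempted — the continuous, uncued stream
makes trial-wise false-alarm bookkeeping ill-defined, which is exactly what
the scrambled null sidesteps.

## Numerical and validation choices

Problem sizes in the validation suite are chosen for statistical stability
rather than faithfulness to any particular lab timetable: stream statistics
use 228 streams (19 sessions × 12 blocks); parameter recovery uses 100
single-participant sessions with a 20-scramble chance level and checks that
the generative hit probability falls inside the 95% BCa CI of the
chance-corrected estimate in ≥90% of (session, group) checks; the null
contrast uses 100 datasets of 45 participants (BCa is well calibrated at
that size, with ≈94.5% true coverage measured on normal data); bootstrap
coverage is audited over 2000 normal replicates of n = 50; the delay
analysis uses 20 null and 10 recency-injected datasets of 8 participants.
Reaction-time draws use rejection sampling with a uniform fallback after
200 rounds (relevant only for pathological parameters). Seeds are threaded
through `numpy.random.SeedSequence` everywhere, so every simulation,
scramble, subsample and bootstrap is exactly reproducible.

## Known limitations

- The lead-in/tail placement and the practice-block image count are
  reconstructions from aggregate summary numbers, not directly documented
  facts.
- The observer's RT law is condition-independent by default, whereas human
  RTs lengthen with distractor count; analyses that need that trend should
  set per-group RT parameters.
- `n_scrambles = 1` reproduces the original chance procedure but is noisy;
  summaries in this package default to it only where fidelity matters more
  than variance.
- BCa intervals on fewer than ~20 values undercover slightly (≈93% at
  n = 19); this is a property of the method, inherited by any analysis run
  at small participant counts.
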