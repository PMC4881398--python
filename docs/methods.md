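# Methods

## The retrieval model

`cuebind` models exactly one subprocess of sentence comprehension: the
declarative-memory retrieval triggered at a reflexive pronoun. It does not
parse; the surrounding sentence enters only through (i) which discourse
referents are in memory with which features, and (ii) when they were
mentioned. A retrieval is a race among chunks for a cue bundle
`{gender, category = noun, role = subject, clause = current}`, with
activation

    A_i = B_i + Σ_j W_j·S_ji + Σ_k P·M_ki + ε_i .

Assumptions worth making explicit:

- **One chunk per referent.** Only the two candidate NPs populate memory;
  other sentence NPs (hospital, needle, nurses) are excluded by default.
  They mismatch almost every cue and would only add fan; `extra_nps` in
  `encode_condition` re-adds them for sensitivity analyses.
- **Recency tracks the surface mention.** A referent's age is the word
  distance from its most recent mention to the reflexive, times
  `per_word_time`. In the pronoun-distractor design the distractor's age
  is that of the pronoun, not the sentence-1 name; `multi_mention=True`
  instead gives the chunk both mentions (the base level then sums both
  power-law terms).
- **Stereotypical gender is encoded like definitional gender.** A
  stereotypically masculine noun ("surgeon") carries `gender = masc`
  outright. This simplification tends to inflate predicted effects
  relative to human data.
- **Noise is retrieval-time only.** One independent logistic draw per
  chunk per retrieval; there is no permanent encoding noise.
- **Unmatched cues spread nothing.** A cue a chunk fails contributes zero
  spreading (never negative); mismatches are penalised only through the
  partial-matching term. The two summations stay separable.
- **No reanalysis.** Whatever chunk wins the race is the antecedent; an
  error is never repaired, and error trials' latencies enter the condition
  mean alongside correct ones.
- **Failures.** A retrieval with no chunk at threshold takes
  `F·e^(−τ)` seconds, is counted in `failure_count`, and is excluded from
  latency statistics. At the defaults failures are essentially absent
  (well under 0.1% of runs).

## Parameters

| name | symbol | default | units | provenance |
|---|---|---|---|---|
| `decay_d` | d | 0.5 | — | conventional base-level decay |
| `max_assoc_strength_S` | S | 1.5 | — | conventional associative strength |
| `max_difference` | — | −1.0 | — | conventional mismatch similarity |
| `retrieval_threshold_tau` | τ | −1.5 | — | conventional threshold |
| `match_scale_P` | P | 0.25 | — | calibrated (see below) |
| `noise_scale_s` | s | 0.15 | — | calibrated; a common choice in this literature |
| `total_source_W` | W | 0.4 | — | calibrated |
| `latency_factor_F` | F | 0.313 | s | calibrated |
| `per_word_time` | — | 0.3 | s/word | typical reading rate |
| `fixed_cost` | — | 0.0 | s | optional constant offset, off by default |

The first four are the fixed conventions of this model family and are
never tuned here. The remaining constants are not published for the
original simulations, so they were calibrated **once**, jointly, against
the four published condition means of the classic design
(194/198/274/295 ms at 1000 runs/condition) and then frozen; nothing
downstream (tests, sweeps, other designs) feeds back into them. Two notes
on that calibration:

- The published means pin the *effective* activation differentials between
  conditions. With `W = 1, P = 1` the mismatch conditions come out at
  600–770 ms — the differentials are roughly three times too large — so the
  published predictions imply a substantially smaller source activation
  and penalty scale than the textbook `W = P = 1`. `W = 0.4, P = 0.25`
  reproduces all four means to within ~10 ms.
- F is calibrated so the *noisy* match-condition mean is 194 ms. The mean
  of `F·e^(−A)` under logistic noise exceeds the noise-free value (by
  ~6% at s = 0.15), so calibrating noise-free and then simulating with
  noise would overshoot every condition by that factor.

At these defaults the five effects for the classic design at 1000 runs are
roughly E1 ≈ +6 pp, E2 ≈ +6 pp, E3 ≈ +84 ms, E4 ≈ +13 ms, E5 ≈ −7 ms, with
the same sign pattern for the other two designs. One known fine-structure
deviation: the original report describes the match-interference effect
(E4) as *stronger* for the modified design than for the classic one at the
default penalty, whereas here it is weaker (≈ +6 ms vs ≈ +13 ms) — a
consequence of the smaller calibrated penalty scale, under which fast
misretrievals of the high-activation distractor partly offset the fan
slowdown. The orderings the package asserts (larger |E2| and |E5| for the
modified design; all-design sign pattern) are unaffected.

## Designs and timelines

Word positions are read off the example stimuli: classic design —
distractor pronoun at word 0, accessible antecedent at word 4, reflexive
at word 7; relative-clause-object design — accessible at word 1,
distractor at word 4 (role = object), reflexive at word 7; modified
design — accessible at word 2, distractor at word 4 (role = subject),
reflexive at word 11. Only the critical sentence clocks ages; the
preceding-sentence mention of the distractor is available through
`multi_mention` (at word −8) rather than a multi-sentence clock. Both
non-clause-mate positions are encoded as `clause = other`; the encoding
does not distinguish matrix from embedded non-current clauses.

## Monte-Carlo engine

`simulate_condition` vectorises the race over runs: the deterministic
activation vector is computed once per condition and only the noise matrix
is sampled. Every (design, condition, sweep-cell) triple gets its own
`numpy` substream derived from the user seed, so sweeps are
order-independent and bit-reproducible. Latencies are kept in seconds
internally and reported in ms, rounded only at display. The sweep grid
follows the published ranges (noise 0.05–0.4 by 0.05, S 1–4 by 0.25,
penalty −1–0 by 0.1; 1144 cells), with `include_zero_noise` prepending a
zero-noise level (1287 cells) since the published cell count matches the
9-level noise axis.

## Eye-movement measures

Fixations are assigned to words by the experiment's screening rule: a
fixation counts if it falls in a word box extended 30 px above and below
the line; space fixations split at the midpoint; everything else is
discarded. First pass on a region is the run of consecutive fixations from
its first fixation until the first exit, *provided* no word to the right
was fixated earlier (the standard first-pass definition; the source
experiment does not spell this out). A region first reached after a later
word has only re-reading measures (FFD/FPRT missing, not zero); TRT is
FPRT + RRT with a missing FPRT contributing zero. A trial that ends inside
the region has no exit saccade and FPRP = 0.

Cumulative progressions ignore word boundaries: from the onset of the
first fixation in the critical region, the curve at each 2 ms timestamp is
the largest rightward pixel displacement reached by any fixation started
by then (clamped at 0, carried forward between fixations — including
across a saccade, whose in-flight samples keep the pre-saccade value).
Curves are 501 samples over 1 s. Effect curves difference per-timestamp
condition means (averaging the two match and two mismatch conditions first
for the mismatch effect); the 95% band pools trials within condition and
therefore understates participant/item variance — it is exploratory, as in
the source analysis.

The nested contrast matrix codes mismatch (a=b=−½, c=d=+½),
match-interference (a=+½, b=−½) and mismatch-interference (c=−½, d=+½;
positive = predicted direction, i.e. mismatch-interference *faster*).
The exact numeric coding is not published; this one satisfies the two
published constraints (nesting; positive coefficient = predicted
direction), and any rescaling would change only the coefficient scale of a
downstream regression. `model_ready_table` exports log-transformed
measures with contrasts attached; model fitting itself is out of scope.

## Synthetic fixation generator

The generator emulates the study's structure — 40 participants × 24 items,
four lists in a Latin square — with minimal oculomotor structure: a
left-to-right sweep, log-normal fixation durations (220 ms mean, σ = 0.25
on the log scale), 30% refixations, instantaneous saccades (1 ms
bookkeeping gap), and per-condition injected effects (FFD shift,
first-pass regression probability, re-reading probability and duration,
post-region progression delay/reach). It deliberately does *not* model
skipping, landing-position distributions, saccade dynamics, or
participant/item random effects. Passing recovery tests therefore shows
that the measure extraction faithfully recovers effects present in the
fixation stream — not that the generator resembles human reading, nor that
effects of this size are detectable in human data with these ns.

## Numerical choices and degenerate inputs

- Activation ties (possible only at s = 0) resolve to the first chunk in
  encoding order, i.e. the accessible antecedent.
- A cue matched by zero chunks contributes no spreading to anyone; its
  would-be `ln(0)` never arises because strengths are only evaluated for
  matching chunks.
- Negative associative strengths (fan > e^S) are allowed, not floored.
- Chunk ages must be strictly positive; a non-positive age raises
  `InvalidTimelineError`.
- Conditions with zero successful runs report NaN latencies.
- Problem sizes: simulations default to 1000 runs/condition (the published
  convention); sweeps in the test suite and acceptance script use 200
  runs/cell over the full grid, which keeps marginal trends stable while
  completing in seconds.

## Known limitations

- The calibrated `W, P, s, F` are one solution to an under-determined
  inversion of four published means; other combinations (e.g. larger P
  with larger s) fit nearly as well and would shift the E4/E5 fine
  structure.
- Working-memory-span differences, encoding interference and feature
  overwriting, reanalysis, and retrieval-history boosts (e.g. a subject
  re-retrieved at the verb) are not modeled.
- The eye-measure module assumes single-line displays and half-open word
  boxes; multi-line reading would need line assignment first.
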