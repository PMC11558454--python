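# Methods

This note documents the models, conventions and design decisions behind
`chorusnet`, in the order the pipeline runs.

## Interaction segmentation

A rival interaction is defined on the *pooled* call sequence of the dyad: a
"pause" is a dyad silence — an interval in which neither male's call covers
the timeline — not a per-male gap. Coverage is accumulated as the maximum
call offset seen so far, so a long call can bridge what would otherwise be a
gap between its neighbours. Bouts are split wherever dyad silence exceeds
`max_pause` (default 10 s), then filtered: both males must contribute at
least one call, and the span from the first call's onset to the last call's
offset must reach `min_length` (default 20 s). The both-males rule filters
whole bouts; it never trims them. Boundary convention: a gap of exactly
`max_pause` does **not** split (the rule is "pauses lasting a maximum of
10 s", so 10.0 s is an admissible pause).

Per session, the longest interaction is selected among those starting at or
after `session_interaction_start + 120 s` — the first two minutes in which
the pair could interact are discarded to avoid carry-over effects. Ties on
length break toward the earlier start (deterministic). The session
interaction start defaults to recording start and can be supplied from
session metadata.

Pair exclusion takes the pair's two condition interactions (forest, urban)
and drops the pair if either has fewer than 8 calls or a mean measured whine
RMS below 60 dB. Both thresholds are strict inequalities: exactly 8 calls
and exactly 60.0 dB are kept. Two readings were left open by the protocol:
call counts are taken as *pair totals* and the amplitude criterion as the
*mean* whine RMS of the measured calls; both are parameters, not silent
choices.

## Amplitude measurement

Waveforms are normalized to full scale [−1, 1] on read; times are seconds
from file start. The band-pass (300–4500 Hz) is a 2nd-order Butterworth
applied forward–backward (`sosfiltfilt`): zero-phase, with a net
24 dB/octave skirt (12 per pass). A tone two octaves below the low edge is
therefore attenuated by ≈ 48 dB, which the tests verify spectrally.

Call amplitude is measured on the window [onset, offset]: raw RMS and raw
peak-to-peak. Background is estimated from the two flank windows
[onset − 0.1, onset − 0.02] and [offset + 0.02, offset + 0.1] s; the two
flanks' *statistics* are averaged (not their pooled samples — an
interpretation, stated here because the protocol's "average RMS of the
background" is ambiguous). Correction subtracts linear amplitudes
(RMS − RMS, P2P − P2P), not powers, mirroring the stated procedure; a
negative difference floors to zero and sets a `floored` flag, a degenerate
case the protocol does not address. Calls within 0.1 s of the waveform edge
raise a measurement error rather than returning a biased value.

Calibration: `dB = 114 + 20·log₁₀(linear / tone)`, where the tone value is
the RMS (or P2P) of the channel's recorded 1 kHz reference tone at 114 dB
SPL. dB values are defined only for positive corrected amplitudes; linear
values are the modeling currency, dB the reporting currency. Missing
calibration is an error, never a silent pass-through.

## Pair metrics

* Overlap: a call overlaps iff its half-open [onset, offset) interval
  intersects any rival call interval; touching endpoints do not count
  (avoids double counting at sample boundaries). The rate is symmetric in
  the two males. Any-intersection is the default; a minimum-overlap
  threshold is exposed but defaults to zero.
* Call rate = 60 · n_calls / interaction length (calls/min); complexity =
  mean chucks/call.
* Whine amplitude: up to 3 calls per male, ranked by raw P2P descending
  (ties to the earlier call) — "loudest first", as the original selection
  was done on oscillograms — keeping only calls that do not overlap the
  rival, have ≥ 0.1 s dyad silence on both flanks, and are not among that
  male's first or last 3 calls of the interaction (edge calls are
  systematically quieter). If no call qualifies the amplitude fields are
  absent and flagged, never imputed.
* Pair level: mean (a+b)/2, absolute difference |a−b|, proportional
  (Weber-scaled) difference |a−b| / max(a,b), defined as 0 (with a flag)
  when both values are 0. Proportional differences are invariant to common
  rescaling; absolute differences are not.
* The transforms used by downstream mixed models (log interaction length;
  square roots of selected difference metrics) are *export options*
  (`pair_metrics_frame(..., transformed=True)`); stored metrics are never
  transformed in place.

## Stimulus rules

An interaction qualifies as a playback stimulus when: length ≥ 30 s; length
≤ 150 s; and no dyad silence > 5 s intersects the first or last 30 s of the
interaction, nor do two such silences start within 30 s of each other.
"Intersects" is the default edge reading (a flag switches to
wholly-within); the two-silence window slides, anchored at each silence
onset — the strictest consistent reading, since the anchoring was left
unstated. A pair enters the stimulus set only if the interactions from both
sensory conditions pass; every violation carries a machine-readable reason
(`min_length`, `max_length`, `silence_rule`). Exactly 30 s and exactly
150 s pass; a silence of exactly 5 s never triggers the rule ("more than
5 s").

The manual audio-editing steps of stimulus preparation (silencing
background between calls, appending 10 s of silence, normalizing by the
calibration-tone RMS) are implemented as a deterministic export transform
of the event timeline, not as audio editing.

## Preference strength and its null

For a cell of n choices with majority count k (k ≥ n − k), the equal-choice
point is e = n/2 for even n and e = (n+1)/2 for odd n — the first possible
count above 50 %. PS = (k − e)/(n − e), computed in exact rational
arithmetic. Worked table for small n:

| n | e | PS values for k = e..n |
|---|---|------------------------|
| 2 | 1 | 0, 1 |
| 3 | 2 | 0, 1 |
| 4 | 2 | 0, ½, 1 |
| 5 | 3 | 0, ½, 1 |
| 6 | 3 | 0, ⅓, ⅔, 1 |
| 10 | 5 | 0, 0.2, 0.4, 0.6, 0.8, 1 |

Cells with a single choice carry no information about deviation from equal
choice (n − e = 0) and are excluded, but tracked; no-choice trials are
excluded from counts and conserved in the bookkeeping identity
Σ cell n + Σ excluded + n_no_choice = total trials. Two collation schemes
are built in: per stimulus × female origin × female treatment (direct
effects) and per rival pair × male treatment (indirect effects). The
binomial response (deviation, max deviation) reproduces PS exactly as a
success/trial fraction; e is an integer for both parities, so both entries
are integers.

The random-choice null conditions on the observed cell sizes: per
replicate, each cell's n choices are independent fair coins, the cell PS is
computed from the folded Binomial(n, ½) majority, and the (un)weighted mean
across cells is taken; 1,000 replicates by default, 95 % interval as the
empirical 2.5/97.5 percentiles with linear interpolation (the interval
estimator was unstated; the percentile method is the simplest consistent
choice, and conditioning on cell sizes is the only reading under which
asymmetric, nonzero lower bounds arise). Simulating at trial level or cell
level is equivalent given fixed cell sizes. An exact oracle enumerates each
cell's PS distribution and convolves across cells (support capped at 10⁶
points); the Monte-Carlo percentiles are tested against its exact
quantiles, and `compare_observed` reports the exact upper-tail probability
when the oracle is available. Exceedance is strict: observed equal to the
upper bound does not count.

## Synthetic world

The generator emulates the statistical structure the pipeline assumes, not
túngara-frog acoustics:

* **Timing.** Call onsets per male follow a gamma renewal process (default
  mean 2 s, shape 4 — moderately regular; shape 1 recovers Poisson-like
  timing, large shapes metronomic calling). No quantitative call-timing
  distributions are published for this system; these defaults are a stated
  world, documented once and not tuned. Antiphony is approximated by a
  fixed 0.5 s lag of male B; true interactive timing is out of scope.
* **Bout structure.** Both males share a bout/rest schedule (bouts
  gamma-distributed, default mean 60 s; rests uniform on 12–25 s, i.e.
  longer than the 10 s pause threshold). The rests are *shared* because
  only simultaneous silence of the dyad breaks an interaction — independent
  per-male pauses would never segment a session while the rival keeps
  calling. Urban condition halves the mean bout (shorter interactions under
  sensory pollution) and raises mean amplitude by 10 % (more conspicuous
  signaling); these effect directions follow the study system, the sizes
  are design choices.
* **Waveforms.** A whine is a 900→400 Hz downward sweep inside the
  ~0.4–1 kHz whine band with a Tukey envelope; chucks are 50 ms bursts at
  2.5 kHz. White Gaussian background noise is added after the ground-truth
  table (clean per-call RMS and P2P) is recorded, making round-trip
  measurement tests exact at zero background.
* **Choices.** P(choose the faster-calling male) =
  logistic(slope × proportional call-rate difference); slope 0 is a fair
  coin, the positive default reproduces the observed direction of the
  preference–call-rate association. Latencies are lognormal around 60 s.
* **Determinism.** One seed; numpy `Generator.spawn` substreams in
  documented order (bout schedule, male A, male B, waveform noise,
  choices). Fixed seed ⇒ byte-identical tables.

What a green test does **not** establish: realism of the timing and
spectral models, interactive (stimulus-driven) antiphony, multi-male
choruses, or effect sizes of the condition covariates — only that the
pipeline's rules and statistics behave exactly as specified on data with
this structure.

## Testing strategy

Every non-trivial rule is checked against an independent oracle computed by
a different route: an exhaustive-window brute-force bout finder for
segmentation (maximality as global containment among all valid windows),
pairwise interval enumeration for overlap, exhaustive eligibility search
for amplitude-call selection, closed forms for sine amplitudes and dB
steps, and exact binomial enumeration/convolution for the null
distribution. Monte-Carlo percentile agreement is asserted in CDF terms
(the empirical endpoint must be a valid exact quantile within 3σ binomial
error), which is robust on discrete, atom-heavy null distributions. The
slope-recovery test reuses one seed across slope arms, giving common random
numbers: each trial's choice is monotone in slope, so the comparison is
paired rather than independent — a variance-reduction design chosen a
priori.

## Known limitations

* Antiphony is phenomenological (fixed lag), so overlap rates in synthetic
  data are higher and less structured than in real antiphonal interactions.
* The amplitude pipeline assumes the supplied event times are correct;
  there is no call detector.
* The exact null oracle is limited to configurations whose convolved
  support stays under 10⁶ points; beyond that only Monte-Carlo is
  available.
* Downstream mixed-model fitting (GLMMs, post-hoc contrasts, AICc
  averaging) is deliberately out of scope; the package exports
  model-ready tables instead.
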