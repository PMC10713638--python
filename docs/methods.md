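# Methods

## Data model and conventions

A *bout* is a maximal contiguous episode of one behaviour by one fly,
stored as an inclusive, 0-based frame interval `[start_frame,
end_frame]`; a one-frame bout has `start == end`. Eight canonical labels
cover the egg-laying repertoire (`egg_expulsion`, `ovipositor_contact`,
`burrowing`, `egg_pushing`, `abdomen_curling`, `grooming_terminalia`,
`abdominal_contortions`, `proboscis_extension`); unknown labels are
accepted and flagged as warnings. Two bouts of the same behaviour for
the same fly may neither overlap nor abut (they would be one bout);
bouts of *different* behaviours may co-occur freely — ovipositor
extrusion during abdominal contortions, burrowing during ovipositor
contact. Same-behaviour overlap is a data error by default, with an
opt-in merge policy at read time.

Frame rate lives on each recording (experiments mix 20 and 15 fps), and
every frame↔second conversion goes through it. Bout *duration* is
`(end_frame − start_frame)/fps` — the last-minus-first-frame
subtraction — even though the inclusive convention would suggest
`+1`; the subtraction definition is the one the downstream metrics are
defined with, and it makes a one-frame bout 0 s. Bout *length in
frames* (`n_frames = end − start + 1`) is a separate quantity used only
for frame-count variants.

## Bout metrics

All metrics are per fly. Inter-egg intervals are
`start(egg i+1) − end(egg i)` over expulsions sorted by start frame; n
expulsions yield n−1 intervals. Binned counts assign a bout to the bin
containing its start frame (bouts are seconds long against 5-minute
bins, so proportional splitting would change nothing but the code), and
a trailing partial bin is excluded. Per-egg normalisations are undefined
for flies that laid no eggs; undefined is an explicit value (`None`, a
`defined=False` row in the tidy table), never a silent drop, and such
flies are excluded from group summaries with a logged warning.

The published per-5-min and per-egg formulas write "sum # behaviour
frames" in their numerators while naming and plotting the quantities as
bout counts. We default to counting bouts (label over typo) and expose
`count_frames=True` for the literal frame-sum reading.

Egg burial uses a per-expulsion `buried ∈ {yes, no, unknown}` attribute;
unknown-status eggs leave both numerator and denominator. Population
proportions (% females laying, % reproductive systems with jammed eggs)
share one `k/n` helper that rejects `n = 0`.

## Peri-event probability

Reference frame r = the *last* frame of each egg-expulsion bout (offset
0); the expulsion's own earlier frames appear at negative offsets.
Events with `r < W` or `r > n_frames − 1 − W` are excluded so every
retained event contributes a complete ±W window (default W = 1200
frames = 1 min at 20 fps). The pooled curve normalises the per-offset
activity counts by the total number of retained expulsions across all
flies; a non-default per-fly variant averages per-fly curves and
reports an across-fly s.e.m. — the s.e.m. definition is an
interpretation, since a pooled proportion has no unique event-level
s.e.m. No smoothing is applied.

## Phase sequences and the transition matrix

Three phases with representative elements: egg expulsion → deposition,
abdominal contortions → contortions, and ovipositor contacts that do
not progress to egg expulsion → exploration. Proboscis extension is
excluded because it occurs continuously across phases and outside
egg-laying; burrowing because it shadows ovipositor contact at lower
frequency.

"Progressing" is decided by a chain rule: a contact progresses when a
forward chain of deposition-sequence bouts (contact, burrowing, egg
pushing, expulsion) reaches an expulsion with every inter-bout gap at
most `linkage_gap` frames and no abdominal-contortion bout starting
inside the chain (contortions terminate a deposition attempt, since a
female never moves from exploration back to contortions without laying
an egg). The gap is a convention, not a measurement; the default is 2 s
at the recording frame rate, and `linkage_gap_sensitivity` recomputes
the matrix across candidate gaps so users can check how little it
matters on their data. Gaps count empty frames between bouts
(`next.start − prev.end − 1`), so overlapping or abutting bouts always
chain.

Per-fly event streams are sorted by onset and run-length collapsed
(consecutive same-phase events merge, keeping the earliest onset), which
makes self-transitions structurally impossible. Transition counts pool
adjacent pairs across flies, never across fly boundaries; probabilities
are row-normalised, with all-NaN rows where a phase has no outgoing
transition (a trailing phase contributes no transition — no censoring
correction is attempted). Pooling across flies is the default; a
per-fly matrix average (`per_fly_average_matrix`) is provided because
either reading of "computed over the whole video per fly" is defensible.

## Stimulation protocols

Protocols tile time with epochs and convert boundaries to half-open
frame windows `[round(t₀·fps), round(t₁·fps))`, so every frame belongs
to exactly one epoch. Two styles: pulsed (baseline, then n alternating
stim/ISI epochs; no trailing ISI unless requested; the canonical
activation protocol is 60 s baseline + 6 × 10 s stimuli with 20 s
ISIs) and constant light (pre / ON block / post, e.g. 10 min / 15 min /
5 min for silencing; the ON block is a single stimulus window, and
per-stimulus metrics on an unstructured 16-h constant protocol are
simply a single whole-period window).

A stimulus "has behaviour" when at least `min_overlap_frames` (default
1) of a bout overlap its ON window; `require_onset_inside` optionally
demands the bout start within the window. The published definition
gives no minimum-duration rule, so ≥1 frame is the default and both
knobs are explicit. Egg allocation assigns each expulsion to the epoch
containing its end frame (the expulsion moment used throughout the
event-aligned analyses); percentages are over eggs inside the protocol
period and sum to 100. Latency is `(start of the first expulsion at or
after the first stimulus onset − that onset)/fps`, undefined when no
expulsion follows.

## The synthetic-data generator

The simulator is a semi-Markov chain over the three phases with
per-phase dwell distributions and an explicit motor template for
deposition. It exists because raw annotation datasets for this
behaviour are not generally deposited; it generates data *with known
ground truth* so every estimator in the package can be validated as a
recovery problem.

Structure and defaults:

* **transition matrix** (deposition, contortions, exploration):
  deposition→contortions = 1, contortions→{deposition, exploration} =
  0.5/0.5, exploration→deposition = 1 — the observed cycle structure.
  Zero diagonal is enforced (phases alternate by definition).
* **dwell/duration distributions** are log-normal by default (positive,
  right-skewed, matching the long-tailed interval scatter of real
  inter-egg intervals); gamma and fixed families are available.
  Contortions dwell: median 90 s (σ = 0.5); exploration dwell: median
  70 s (σ = 0.6). Template element medians: contact 2.5 s, burrowing
  5 s, egg pushing 3.5 s, expulsion 1 s, curling 2.5 s, grooming 4 s;
  inter-element gaps median 0.5 s, clipped at 1.5 s so a template
  always chains under the 2-s linkage rule.
* the dwell medians were calibrated by Monte-Carlo so that per-fly
  **median inter-egg intervals** over 200 simulated flies fall in the
  2–3 min band reported for wild-type females; with these defaults the
  median of per-fly medians is ≈ 2.5 min and a 45-min recording yields
  a median of ≈ 16 eggs.
* **grooming** follows expulsion with probability 0.5 (it is the
  optional element of the sequence); **eggs are buried** with
  probability 0.94 among determinable eggs, with a 5 % unknown-status
  rate to exercise the exclusion path; **exploration** emits probing
  contacts (median 2.5 s) separated by pauses (median 8 s, floored at
  3 s), 30 % of them with accompanying burrowing; **proboscis
  extension** is an independent background renewal process
  (rate 2/min, ~1-s bouts) overlapping all phases, reflecting its
  continuous, phase-unspecific occurrence.

Generator-side spacing guarantees keep the emitted data unambiguous for
the analysis side: template gaps stay below the chain linkage gap,
exploration keeps a 3-s trailing margin before the next phase (so
probing contacts never chain into a subsequent deposition), and a
deposition template that does not fit before the recording end is not
emitted at all — a truncated template would read as a spurious trailing
exploration contact. The first phase is exploration (a fly introduced
into an arena probes before laying); no initial-phase distribution is
claimed beyond that choice.

Determinism: per-fly seeds derive from the master seed via a seed
sequence; frame emission is integer arithmetic; identical
(config, seed) produce byte-identical annotation tables.

What the generator does **not** emulate: spatial structure (no arena
geometry or substrate preference), kinematics, inter-fly variability in
rate parameters (all flies share one configuration), correlation
between dwell times, or annotation noise (frame jitter, missed bouts).
Passing recovery tests therefore show that the estimators are correct
on data satisfying the declared conventions — not that real annotations
satisfy them.

The optogenetic overlay plants, per fly and stimulus, a response bout
with probability `p_respond` at onset + log-normal latency, lasting to
the window end (latencies beyond the window clip to its last frame, or
drop the response when clipping is disabled). Planted outcomes are
recorded in the ground truth so recovered response percentages can be
compared to what was actually planted, not just to the nominal rate.

## Statistics

Test selection mirrors common practice in this literature: Shapiro–Wilk
*and* D'Agostino's K² on each sample (both must fail to reject at
α = 0.05; K² is skipped below n = 8, where it is undefined, leaving
Shapiro alone; constant samples are treated as non-normal); for normal
data, Bartlett's test gates Student's *t* vs Welch's *t*; any normality
failure routes to the two-sided Mann–Whitney U. The gate α is not a
published constant; 0.05 is the default and configurable. Samples below
n = 3 are rejected rather than silently tested. Fisher's exact test
(two-sided, via scipy) handles 2×2 contingency endpoints; the test
suite checks it against full hypergeometric enumeration in exact
rational arithmetic. Stars: `*` < 0.05, `**` < 0.01, `***` < 0.001,
`****` < 0.0001, `ns` otherwise. **No multiple-testing correction is
applied anywhere** — outputs are per-comparison p-values, and users
running many comparisons must account for that themselves.

## Numerical and design notes

* Validation reports are data (a list of located violations), not
  exceptions; readers raise only on request. Planted-defect tests
  check each violation is reported exactly once.
* Row normalisation of transition counts uses exact integer counts;
  row-stochasticity holds to 1e-12 in tests.
* Peri-event coverage uses clipped interval addition (valid because
  same-behaviour bouts are disjoint), checked against a per-frame
  membership scan oracle.
* `run-all` writes a deterministic plain-text log (stage names and row
  counts; wall-clock timestamps go to stderr only) so that identically
  seeded runs produce byte-identical output trees — end-to-end
  determinism is an acceptance property and is checksummed in tests.
* Problem sizes in tests and the acceptance script (200 random small
  datasets for oracle agreement, 200 simulated flies for calibration,
  ~60 flies / ≥2000 transitions for recovery, 1000 null replicates for
  type-I error) were chosen as the smallest sizes at which the checked
  statistics are stable to well within their asserted tolerances.

## Known limitations

* The chain-rule linkage gap and the ≥1-frame stimulus-overlap rule are
  conventions; both are parameters, and the sensitivity report exists
  because the right values are not derivable from first principles.
* Pooled peri-event curves and pooled transition matrices weight flies
  by their event counts; the per-fly variants weight flies equally.
  Both are provided; neither is "the" correct choice.
* The simulator's calibration targets the inter-egg interval
  distribution, not egg totals; simulated 45-min egg counts (~16)
  run higher than typical published wild-type medians (~11–12), which
  is consistent with the shorter-interval end of the calibration band
  and irrelevant to the estimator-recovery results the simulator backs.
* Constant-light protocols expose only whole-period metrics; there is
  no per-stimulus structure to score.
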