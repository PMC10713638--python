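# ovibout

Bout-level analysis of *Drosophila melanogaster* egg-laying (oviposition)
ethograms, for behavioural neuroscientists who annotate video frame by
frame and need the downstream quantification to be reproducible.

Egg-laying is a cyclic behaviour with three phases — an **egg deposition
phase** (a stereotyped motor sequence: ovipositor contact → burrowing →
egg pushing → egg expulsion → abdomen curling, with optional grooming of
the terminalia), a post-expulsion **abdominal contortions** phase
associated with ovulation, and an **exploration** phase of substrate
probing that does not culminate in an egg. `ovibout` takes manual
annotations (one CSV row per behaviour bout, as inclusive frame
intervals) and computes:

* **per-fly bout metrics** — inter-egg expulsion intervals
  (`start_frame(egg i+1) − end_frame(egg i)`, in frames or seconds),
  eggs and bouts per 5-min bin, bouts per egg, mean bout duration
  (`(last − first frame)/fps`), and the proportion of eggs not buried in
  the substrate;
* **peri-event probability curves** — for each frame offset *o* in
  ±W (default W = 1200 frames), `P(behaviour at o) = (# expulsions with
  the behaviour active at r + o) / n`, where *r* is the last frame of
  each egg expulsion and events within W frames of either recording end
  are excluded;
* **phase-transition matrices** — per-fly phase sequences (expulsion →
  deposition, contortions bout → contortions, non-progressing ovipositor
  contact → exploration; proboscis extension and burrowing are never
  phase evidence), run-length collapsed and pooled into a first-order
  Markov estimate `P̂(i→j) = n(i→j) / Σ_k n(i→k)`;
* **optogenetic stimulus-locked metrics** — % stimulations with a
  behaviour, % eggs per stimulus/ISI epoch, and latency from stimulus
  onset to the first egg expulsion, for pulsed (baseline + n × stim/ISI)
  and constant-light protocols;
* **automated pairwise statistics** — Shapiro–Wilk + D'Agostino
  normality gates, Bartlett variance gate, then Student's *t* / Welch's
  *t* / Mann–Whitney, plus Fisher's exact test for contingency tables;
* a **seeded semi-Markov simulator** that generates whole ethogram
  datasets with known ground truth (phase sequences, burial statuses,
  planted optogenetic responses), used throughout the test suite to
  validate the estimators by parameter recovery.

## Worked example

```python
import numpy as np
from ovibout import (SimulatorConfig, simulate_dataset, inter_egg_intervals,
                     extract_phase_sequence, transition_matrix)

config = SimulatorConfig(seed=1, n_flies=10)       # 45 min at 20 fps
dataset, truth = simulate_dataset(config)

medians = [np.median(inter_egg_intervals(dataset, fly, unit="seconds"))
           for fly in dataset.fly_ids()]
print(f"median inter-egg interval: {np.median(medians) / 60:.2f} min")

seqs = [extract_phase_sequence(dataset, fly) for fly in dataset.fly_ids()]
tm = transition_matrix(seqs)
print(np.round(tm.probabilities, 2))
```

prints

```
median inter-egg interval: 2.47 min
[[0.   1.   0.  ]
 [0.57 0.   0.43]
 [1.   0.   0.  ]]
```

The per-fly median interval between consecutive egg expulsions sits in
the 2–3 minute range typical of well-fed mated wild-type females, and
the transition matrix (rows/columns ordered deposition, contortions,
exploration) recovers the generative cycle: every egg deposition is
followed by abdominal contortions, contortions resolve into another
deposition or into exploration, and exploration always returns to
deposition — with the structural certainties estimated exactly.

The same analyses are available from the shell:

```bash
ovibout run-all --seed 1 --out runs/demo     # simulate + all stages
ovibout metrics events.csv recordings.csv --out metrics.csv
ovibout perievent events.csv recordings.csv --behaviour egg_pushing --out curve.csv
```

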