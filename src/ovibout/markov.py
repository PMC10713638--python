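"""Egg-laying phase sequences and first-order Markov transition estimates.

The cycle is described by three phases, each identified by a
representative motor element:

* ``deposition`` — egg expulsion bouts;
* ``contortions`` — abdominal-contortion bouts (the post-expulsion
  "rest" phase associated with ovulation);
* ``exploration`` — ovipositor contacts that do **not** progress to an
  egg expulsion.

Proboscis extension and burrowing are never phase evidence: the former
occurs continuously across phases and outside egg-laying, the latter
accompanies ovipositor contact at lower frequency.

Whether an ovipositor contact "progresses" to expulsion is decided by a
chain rule: the contact must connect to a subsequent expulsion through
deposition-sequence bouts (contact, burrowing, egg pushing, expulsion)
whose consecutive gaps are at most ``linkage_gap`` frames, with no
abdominal-contortion bout intervening (contortions terminate a deposition
attempt).  The default gap is 2 s at the recording frame rate.

Per-fly phase streams are run-length collapsed and adjacent-pair counts
are pooled across flies — never across fly boundaries — then row-normalised
into the transition probability matrix.  Self-transitions are structurally
impossible (the diagonal is always zero) because collapsed sequences never
repeat a phase.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .io import Bout, EthogramDataset

__all__ = [
    "Phase",
    "PhaseSequence",
    "TransitionMatrix",
    "classify_ovipositor_contact",
    "extract_phase_sequence",
    "transition_matrix",
    "linkage_gap_sensitivity",
]

#: Behaviours that may form a deposition chain, in stereotyped order.
CHAIN_BEHAVIOURS = ("ovipositor_contact", "burrowing", "egg_pushing", "egg_expulsion")


class Phase(str, enum.Enum):
    DEPOSITION = "deposition"
    CONTORTIONS = "contortions"
    EXPLORATION = "exploration"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


PHASES = (Phase.DEPOSITION, Phase.CONTORTIONS, Phase.EXPLORATION)
_PHASE_INDEX = {p: i for i, p in enumerate(PHASES)}


@dataclass
class PhaseSequence:
    """Run-length-collapsed ordered phases of one fly.

    ``entries`` is a list of ``(phase, onset_frame)`` with strictly
    increasing onsets and no two consecutive equal phases.
    """

    fly_id: str
    entries: list = field(default_factory=list)

    def phases(self) -> list:
        return [p for p, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class TransitionMatrix:
    """First-order transition counts and row-normalised probabilities.

    Rows/columns follow ``PHASES`` order (deposition, contortions,
    exploration).  A row with no outgoing transition is all-NaN in
    ``probabilities``.
    """

    counts: np.ndarray
    n_transitions: int

    @property
    def probabilities(self) -> np.ndarray:
        row_sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = self.counts / row_sums
        probs[row_sums[:, 0] == 0] = np.nan
        return probs

    def probability(self, source: Phase, target: Phase) -> float:
        return float(self.probabilities[_PHASE_INDEX[source], _PHASE_INDEX[target]])

    def to_dataframe(self) -> pd.DataFrame:
        probs = self.probabilities
        rows = []
        for i, src in enumerate(PHASES):
            for j, dst in enumerate(PHASES):
                rows.append(
                    {
                        "from_phase": src.value,
                        "to_phase": dst.value,
                        "count": int(self.counts[i, j]),
                        "probability": probs[i, j],
                    }
                )
        return pd.DataFrame(rows)


def default_linkage_gap(fps: float) -> int:
    """Default chain gap: 2 seconds at the recording frame rate."""
    return int(round(2.0 * fps))


def classify_ovipositor_contact(
    dataset: EthogramDataset,
    fly_id: str,
    contact_bout: Bout,
    linkage_gap: Optional[int] = None,
) -> str:
    """``"progressing"`` or ``"non_progressing"`` for one ovipositor contact.

    The contact progresses when a forward chain of deposition-sequence
    bouts reaches an egg expulsion with every inter-bout gap at most
    ``linkage_gap`` frames and no abdominal-contortion bout starting
    inside the chain.
    """
    if contact_bout.behaviour != "ovipositor_contact":
        raise ValueError(f"expected an ovipositor_contact bout, got {contact_bout.behaviour!r}")
    rec = dataset.recordings[fly_id]
    if linkage_gap is None:
        linkage_gap = default_linkage_gap(rec.fps)

    chain = sorted(
        (b for b in dataset.bouts_for(fly_id) if b.behaviour in CHAIN_BEHAVIOURS),
        key=lambda b: (b.start_frame, b.end_frame),
    )
    contortion_onsets = [
        b.start_frame for b in dataset.bouts_for(fly_id, "abdominal_contortions")
    ]
    try:
        idx = chain.index(contact_bout)
    except ValueError:
        raise ValueError(
            f"bout {contact_bout} does not belong to fly {fly_id!r}"
        ) from None

    chain_end = contact_bout.end_frame
    for b in chain[idx + 1 :]:
        gap = b.start_frame - chain_end - 1  # empty frames between; <0 when overlapping
        if gap > linkage_gap:
            break
        # contortions starting between the chain so far and the next link break it
        if any(chain_end < t <= b.start_frame for t in contortion_onsets):
            break
        if b.behaviour == "egg_expulsion":
            return "progressing"
        chain_end = max(chain_end, b.end_frame)
    return "non_progressing"


def extract_phase_sequence(
    dataset: EthogramDataset,
    fly_id: str,
    linkage_gap: Optional[int] = None,
) -> PhaseSequence:
    """Time-ordered, run-length-collapsed phase sequence of one fly.

    Events: each egg expulsion → deposition; each abdominal-contortion
    bout → contortions; each non-progressing ovipositor contact →
    exploration.  Consecutive same-phase events collapse to one entry
    keeping the earliest onset.
    """
    events = []
    for b in dataset.bouts_for(fly_id, "egg_expulsion"):
        events.append((b.start_frame, Phase.DEPOSITION))
    for b in dataset.bouts_for(fly_id, "abdominal_contortions"):
        events.append((b.start_frame, Phase.CONTORTIONS))
    for b in dataset.bouts_for(fly_id, "ovipositor_contact"):
        if classify_ovipositor_contact(dataset, fly_id, b, linkage_gap) == "non_progressing":
            events.append((b.start_frame, Phase.EXPLORATION))
    events.sort()

    entries = []
    for onset, phase in events:
        if not entries or entries[-1][0] != phase:
            entries.append((phase, onset))
    return PhaseSequence(fly_id, entries)


def transition_matrix(sequences: Iterable[PhaseSequence]) -> TransitionMatrix:
    """Pooled adjacent-pair transition counts over per-fly sequences.

    Pairs never span fly boundaries; a trailing phase contributes no
    outgoing transition.  Raises ``ValueError`` when no sequence has two
    entries (no transition to count).
    """
    counts = np.zeros((3, 3), dtype=np.int64)
    for seq in sequences:
        phases = seq.phases()
        for src, dst in zip(phases, phases[1:]):
            counts[_PHASE_INDEX[src], _PHASE_INDEX[dst]] += 1
    n = int(counts.sum())
    if n == 0:
        raise ValueError("no phase transitions found in any sequence")
    return TransitionMatrix(counts, n)


def linkage_gap_sensitivity(
    dataset: EthogramDataset,
    gaps: Iterable[int],
) -> pd.DataFrame:
    """Transition probabilities recomputed across candidate linkage gaps.

    The chain gap is a convention, not a measured quantity; this report
    shows how (in)sensitive the estimated matrix is to it.
    """
    rows = []
    for gap in gaps:
        seqs = [extract_phase_sequence(dataset, fly, linkage_gap=gap) for fly in dataset.fly_ids()]
        try:
            tm = transition_matrix(seqs)
        except ValueError:
            continue
        df = tm.to_dataframe()
        df.insert(0, "linkage_gap_frames", gap)
        rows.append(df)
    if not rows:
        return pd.DataFrame(
            columns=["linkage_gap_frames", "from_phase", "to_phase", "count", "probability"]
        )
    return pd.concat(rows, ignore_index=True)


def per_fly_average_matrix(sequences: Iterable[PhaseSequence]) -> np.ndarray:
    """Across-fly mean of per-fly transition matrices (non-default variant).

    Each fly with at least one transition contributes its own
    row-normalised matrix; entries undefined for a fly (no outgoing
    transition from a phase) are excluded from that entry's mean via
    NaN-aware averaging.
    """
    mats = []
    for seq in sequences:
        phases = seq.phases()
        if len(phases) < 2:
            continue
        counts = np.zeros((3, 3))
        for src, dst in zip(phases, phases[1:]):
            counts[_PHASE_INDEX[src], _PHASE_INDEX[dst]] += 1
        row_sums = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = counts / row_sums
        probs[row_sums[:, 0] == 0] = np.nan
        mats.append(probs)
    if not mats:
        raise ValueError("no fly has a phase transition")
    return np.nanmean(np.stack(mats), axis=0)
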