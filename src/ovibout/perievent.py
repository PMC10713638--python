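"""Behaviour probability aligned to egg expulsion.

For every egg-expulsion event the alignment reference is the *last* frame
of the expulsion bout (offset 0); the curve gives, at each frame offset in
``[-W, +W]``, the fraction of expulsions during which a bout of the target
behaviour covered that frame.  Events closer than W frames to either end
of their recording are excluded so that every retained event contributes a
full window.  The default half-width is 1200 frames (one minute at
20 fps).  No smoothing is applied: the values are raw per-frame
proportions.

Normalisation pools events across flies by default; the per-fly variant
averages per-fly curves and reports an across-fly s.e.m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io import EthogramDataset

__all__ = ["PerieventCurve", "perievent_probability"]


@dataclass
class PerieventCurve:
    """Event-aligned probability of one behaviour.

    ``probability[i]`` corresponds to ``offsets[i]`` ∈ [-W, +W];
    ``n_events`` is the number of pooled expulsions after edge exclusion.
    ``sem`` is present only for the per-fly variant (across-fly standard
    error of the mean).
    """

    behaviour: str
    window_half_width: int
    offsets: np.ndarray
    probability: np.ndarray
    n_events: int
    n_flies: int
    sem: Optional[np.ndarray] = None

    def to_dataframe(self, fps: Optional[float] = None) -> pd.DataFrame:
        """Tidy frame; ``offset_seconds`` included when fps is given."""
        df = pd.DataFrame(
            {
                "behaviour": self.behaviour,
                "offset_frames": self.offsets,
                "probability": self.probability,
                "n_events": self.n_events,
            }
        )
        if fps is not None:
            df.insert(2, "offset_seconds", self.offsets / fps)
        if self.sem is not None:
            df["sem"] = self.sem
        return df


def _included_references(dataset: EthogramDataset, fly_id: str, W: int) -> list:
    """Expulsion end-frames at least W frames from both recording ends."""
    n_frames = dataset.recordings[fly_id].n_frames
    refs = []
    for b in dataset.bouts_for(fly_id, "egg_expulsion"):
        r = b.end_frame
        if r >= W and r <= n_frames - 1 - W:
            refs.append(r)
    return refs


def _coverage(dataset: EthogramDataset, fly_id: str, behaviour: str, refs: list, W: int):
    """Sum over events of the behaviour's 0/1 coverage at each offset.

    Bouts of one behaviour never overlap (validated), so adding clipped
    bout windows is an exact indicator sum per event.
    """
    counts = np.zeros(2 * W + 1, dtype=np.int64)
    bouts = dataset.bouts_for(fly_id, behaviour)
    for r in refs:
        lo, hi = r - W, r + W
        for b in bouts:
            if b.end_frame < lo:
                continue
            if b.start_frame > hi:
                break
            counts[max(b.start_frame, lo) - lo : min(b.end_frame, hi) - lo + 1] += 1
    return counts


def perievent_probability(
    dataset: EthogramDataset,
    behaviour: str,
    W: int = 1200,
    *,
    per_fly: bool = False,
) -> PerieventCurve:
    """Probability of ``behaviour`` at each offset around egg expulsion.

    Pooled (default): counts over all retained expulsions of all flies,
    normalised by the total number of retained expulsions.  ``per_fly``:
    each fly contributes its own curve; the result is the across-fly mean
    with an across-fly s.e.m. (flies without retained events are skipped).

    Raises ``ValueError`` when W < 1 or when every expulsion falls in the
    edge-exclusion zones.
    """
    if W < 1:
        raise ValueError(f"window half-width must be >= 1 frame, got {W}")
    offsets = np.arange(-W, W + 1)
    per_fly_curves = []
    total_counts = np.zeros(2 * W + 1, dtype=np.int64)
    n_events = 0
    for fly in dataset.fly_ids():
        refs = _included_references(dataset, fly, W)
        if not refs:
            continue
        counts = _coverage(dataset, fly, behaviour, refs, W)
        total_counts += counts
        n_events += len(refs)
        per_fly_curves.append(counts / len(refs))
    if n_events == 0:
        raise ValueError(
            f"no egg expulsion is at least {W} frames from both recording ends; "
            "all events fell in the edge-exclusion zones"
        )
    if per_fly:
        stack = np.vstack(per_fly_curves)
        probability = stack.mean(axis=0)
        sem = (
            stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
            if stack.shape[0] > 1
            else np.zeros_like(probability)
        )
        return PerieventCurve(
            behaviour, W, offsets, probability, n_events, stack.shape[0], sem
        )
    return PerieventCurve(
        behaviour, W, offsets, total_counts / n_events, n_events, len(per_fly_curves)
    )


def pooled_fps(dataset: EthogramDataset) -> float:
    """The single fps shared by all recordings; error on mixed frame rates.

    Peri-event offsets are in frames; converting the time axis to seconds
    is only meaningful when pooled recordings share one frame rate.
    """
    rates = {r.fps for r in dataset.recordings.values()}
    if len(rates) != 1:
        raise ValueError(f"recordings mix frame rates {sorted(rates)}; cannot pool a time axis")
    return rates.pop()
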