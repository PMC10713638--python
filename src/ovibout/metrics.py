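"""Per-fly quantification of egg-laying bouts.

All metrics operate on one fly's validated bouts and return plain numbers,
with ``None`` standing for *undefined* (e.g. a per-egg normalisation for a
fly that laid no eggs).  Undefined values are never silently dropped: the
tidy :func:`metric_table` carries them as rows with ``defined = False``,
and group-level summaries exclude them with a logged warning.

Two of the published formulas ("# Bouts/5 min", "# Bouts/Egg") write
"sum # behaviour frames" in the numerator while the quantity is named and
plotted as a bout count; the bout-count reading is the default here and
``count_frames=True`` gives the literal frame-sum reading.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .io import EthogramDataset

__all__ = [
    "TimeBinSpec",
    "inter_egg_intervals",
    "counts_per_bin",
    "bouts_per_egg",
    "mean_bout_duration",
    "proportion_eggs_not_buried",
    "proportion_with_flag",
    "metric_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TimeBinSpec:
    """Fixed-width time bins aligned to the recording start.

    The default 300 s matches the 5-min bins of the per-bin rate metrics.
    A trailing partial bin is excluded from per-bin counts.
    """

    bin_length_s: float = 300.0

    def __post_init__(self) -> None:
        if self.bin_length_s <= 0:
            raise ValueError(f"bin_length_s must be > 0, got {self.bin_length_s}")

    def n_complete_bins(self, n_frames: int, fps: float) -> int:
        return int(n_frames / (self.bin_length_s * fps))

    def bin_length_frames(self, fps: float) -> float:
        return self.bin_length_s * fps


def _fly(dataset: EthogramDataset, fly_id: str):
    if fly_id not in dataset.recordings:
        raise KeyError(f"unknown fly {fly_id!r}")
    return dataset.recordings[fly_id]


def inter_egg_intervals(dataset: EthogramDataset, fly_id: str, unit: str = "frames") -> list:
    """Intervals between consecutive egg expulsions of one fly.

    Interval *i* is the first frame of expulsion *i+1* minus the last frame
    of expulsion *i* (so ``n`` expulsions yield ``n − 1`` intervals; fewer
    than two yield an empty list).  ``unit`` is ``"frames"`` or
    ``"seconds"`` (divide by the recording fps).
    """
    if unit not in ("frames", "seconds"):
        raise ValueError(f"unit must be 'frames' or 'seconds', got {unit!r}")
    rec = _fly(dataset, fly_id)
    expulsions = dataset.bouts_for(fly_id, "egg_expulsion")
    intervals = [
        nxt.start_frame - prev.end_frame for prev, nxt in zip(expulsions, expulsions[1:])
    ]
    if unit == "seconds":
        return [x / rec.fps for x in intervals]
    return intervals


def counts_per_bin(
    dataset: EthogramDataset,
    fly_id: str,
    behaviour: str,
    bins: TimeBinSpec = TimeBinSpec(),
    *,
    count_frames: bool = False,
) -> list:
    """Bout counts (or frame sums) of one behaviour per complete time bin.

    A bout belongs to the bin containing its start frame, even when it
    straddles a bin boundary.  Only complete bins are returned; bouts
    starting in a trailing partial bin are not counted.
    """
    rec = _fly(dataset, fly_id)
    n_bins = bins.n_complete_bins(rec.n_frames, rec.fps)
    if n_bins == 0:
        raise ValueError(
            f"bin length {bins.bin_length_s} s exceeds the "
            f"{rec.duration_seconds:.1f} s recording of fly {fly_id!r}"
        )
    width = bins.bin_length_frames(rec.fps)
    counts = [0] * n_bins
    for b in dataset.bouts_for(fly_id, behaviour):
        idx = int(b.start_frame / width)
        if idx < n_bins:
            counts[idx] += b.n_frames if count_frames else 1
    return counts


def bouts_per_egg(
    dataset: EthogramDataset,
    fly_id: str,
    behaviour: str,
    *,
    count_frames: bool = False,
) -> Optional[float]:
    """Bouts of a behaviour normalised by the fly's egg count.

    Undefined (``None``) when the fly laid no eggs — the normalisation has
    no value at zero and such flies are excluded from group summaries.
    """
    n_eggs = len(dataset.bouts_for(fly_id, "egg_expulsion"))
    if n_eggs == 0:
        logger.warning("fly %s laid no eggs; bouts_per_egg(%s) undefined", fly_id, behaviour)
        return None
    bouts = dataset.bouts_for(fly_id, behaviour)
    numerator = sum(b.n_frames for b in bouts) if count_frames else len(bouts)
    return numerator / n_eggs


def mean_bout_duration(dataset: EthogramDataset, fly_id: str, behaviour: str) -> Optional[float]:
    """Mean bout duration in seconds; ``None`` when the fly has no bout.

    Duration of one bout is (last frame − first frame)/fps, so a one-frame
    bout contributes 0 s.
    """
    rec = _fly(dataset, fly_id)
    bouts = dataset.bouts_for(fly_id, behaviour)
    if not bouts:
        return None
    return sum(b.duration_seconds(rec.fps) for b in bouts) / len(bouts)


def proportion_eggs_not_buried(dataset: EthogramDataset, fly_id: str) -> Optional[float]:
    """Fraction of a fly's eggs left unburied, among eggs of known status.

    Expulsion bouts carry a ``buried`` attribute in {yes, no, unknown};
    unknown-status eggs are excluded from numerator and denominator, and
    the result is ``None`` when no egg has a determined status.
    """
    _fly(dataset, fly_id)
    statuses = [
        b.attributes.get("buried", "unknown")
        for b in dataset.bouts_for(fly_id, "egg_expulsion")
    ]
    determined = [s for s in statuses if s in ("yes", "no")]
    if not determined:
        return None
    return determined.count("no") / len(determined)


def proportion_with_flag(counts_flagged: int, counts_total: int) -> float:
    """Population-level proportion k/n in [0, 1].

    Shared helper for endpoints like "% females laying eggs" and
    "% eggs jammed" (flies with eggs retained in the oviducts).
    """
    if counts_total <= 0:
        raise ValueError(f"counts_total must be positive, got {counts_total}")
    if not 0 <= counts_flagged <= counts_total:
        raise ValueError(
            f"counts_flagged must be in [0, counts_total], got {counts_flagged}/{counts_total}"
        )
    return counts_flagged / counts_total


def metric_table(
    dataset: EthogramDataset,
    *,
    behaviours: Optional[list] = None,
    bins: TimeBinSpec = TimeBinSpec(),
    count_frames: bool = False,
) -> pd.DataFrame:
    """Tidy per-fly metric table over the whole dataset.

    One row per (fly, metric, window); columns ``fly_id, group, metric,
    window, value, defined``.  Windowed rows are the per-bin egg and bout
    counts; whole-recording rows are the medians/means and per-egg
    normalisations.  Undefined metrics appear with ``defined = False`` and
    a NaN value rather than being dropped.
    """
    if behaviours is None:
        behaviours = sorted({b.behaviour for b in dataset.bouts})
    rows = []

    def add(fly, group, metric, window, value):
        rows.append(
            {
                "fly_id": fly,
                "group": group,
                "metric": metric,
                "window": window,
                "value": math.nan if value is None else value,
                "defined": value is not None,
            }
        )

    for fly in dataset.fly_ids():
        group = dataset.recordings[fly].group
        ieis = inter_egg_intervals(dataset, fly, unit="seconds")
        add(fly, group, "median_inter_egg_interval_s", "whole",
            float(pd.Series(ieis).median()) if ieis else None)
        add(fly, group, "n_eggs", "whole", len(dataset.bouts_for(fly, "egg_expulsion")))
        add(fly, group, "proportion_eggs_not_buried", "whole",
            proportion_eggs_not_buried(dataset, fly))
        try:
            egg_bins = counts_per_bin(dataset, fly, "egg_expulsion", bins)
        except ValueError:
            egg_bins = []
        for i, c in enumerate(egg_bins):
            add(fly, group, "eggs_per_bin", f"bin{i}", c)
        for behaviour in behaviours:
            add(fly, group, f"bouts_per_egg[{behaviour}]", "whole",
                bouts_per_egg(dataset, fly, behaviour, count_frames=count_frames))
            add(fly, group, f"mean_bout_duration_s[{behaviour}]", "whole",
                mean_bout_duration(dataset, fly, behaviour))
            try:
                beh_bins = counts_per_bin(
                    dataset, fly, behaviour, bins, count_frames=count_frames
                )
            except ValueError:
                beh_bins = []
            for i, c in enumerate(beh_bins):
                add(fly, group, f"bouts_per_bin[{behaviour}]", f"bin{i}", c)
    return pd.DataFrame(
        rows, columns=["fly_id", "group", "metric", "window", "value", "defined"]
    )
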