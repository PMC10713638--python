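"""Optogenetic stimulation protocols and stimulus-locked behaviour metrics.

A protocol is an ordered tiling of epochs (baseline / stim / ISI, or
pre / constant-stim / post for silencing experiments).  Epoch boundaries
are converted to half-open frame windows ``[round(t0·fps), round(t1·fps))``
so that every frame belongs to exactly one epoch.

The metrics mirror the standard stimulus-locked quantifications:

* % stimulations with behaviour — fraction of light-ON windows overlapped
  by at least one bout of the behaviour, pooled over flies of a group;
* egg allocation — percentage of eggs expelled in each epoch (an egg is
  assigned to the epoch containing the end frame of its expulsion bout);
* latency to egg expulsion — seconds from the first stimulus onset to the
  first expulsion starting at or after it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "StimulationProtocol",
    "StimulusOutcome",
    "build_protocol",
    "build_constant_protocol",
    "pct_stimulations_with_behaviour",
    "egg_allocation",
    "latency_to_expulsion",
    "read_protocols",
    "write_protocols",
]

_CSV_COLUMNS = (
    "protocol_id",
    "baseline_s",
    "n_stimuli",
    "stim_s",
    "isi_s",
    "pre_s",
    "constant_s",
    "post_s",
    "trailing_isi",
)


@dataclass(frozen=True)
class StimulationProtocol:
    """Light-stimulation schedule; exactly one of two styles is populated.

    Pulsed style (channelrhodopsin activation): ``baseline_s``,
    ``n_stimuli``, ``stim_s``, ``isi_s`` (ISIs separate consecutive stimuli;
    a trailing ISI after the last stimulus only when ``trailing_isi``).

    Constant style (e.g. GtACR1 silencing): ``pre_s``, ``constant_s``,
    ``post_s`` — one continuous light-ON block, treated as a single
    stimulus window for per-stimulus metrics.
    """

    protocol_id: str
    baseline_s: Optional[float] = None
    n_stimuli: Optional[int] = None
    stim_s: Optional[float] = None
    isi_s: Optional[float] = None
    pre_s: Optional[float] = None
    constant_s: Optional[float] = None
    post_s: Optional[float] = None
    trailing_isi: bool = False

    def __post_init__(self) -> None:
        pulsed = self.stim_s is not None and self.n_stimuli is not None
        constant = self.constant_s is not None
        if pulsed == constant:
            raise ValueError(
                f"protocol {self.protocol_id!r}: exactly one of pulsed "
                "(n_stimuli/stim_s/isi_s) or constant (constant_s) style required"
            )
        for name in ("baseline_s", "stim_s", "isi_s", "pre_s", "constant_s", "post_s"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"protocol {self.protocol_id!r}: {name} must be > 0, got {v}")
        if pulsed and self.n_stimuli < 1:
            raise ValueError(f"protocol {self.protocol_id!r}: n_stimuli must be >= 1")
        if pulsed and self.n_stimuli > 1 and self.isi_s is None:
            raise ValueError(f"protocol {self.protocol_id!r}: isi_s required for n_stimuli > 1")

    @property
    def style(self) -> str:
        return "pulsed" if self.constant_s is None else "constant"

    def epochs(self) -> list:
        """Ordered (kind, label, duration_s) tiles covering the protocol."""
        out = []
        if self.style == "pulsed":
            if self.baseline_s:
                out.append(("pre", "baseline", float(self.baseline_s)))
            for i in range(1, self.n_stimuli + 1):
                out.append(("stim", f"stim{i}", float(self.stim_s)))
                if self.isi_s is not None and (i < self.n_stimuli or self.trailing_isi):
                    out.append(("isi", f"isi{i}", float(self.isi_s)))
        else:
            if self.pre_s:
                out.append(("pre", "pre", float(self.pre_s)))
            out.append(("stim", "stim1", float(self.constant_s)))
            if self.post_s:
                out.append(("post", "post", float(self.post_s)))
        return out

    @property
    def total_duration_s(self) -> float:
        return sum(d for _, _, d in self.epochs())

    def windows(self, fps: float) -> list:
        """Epochs as (kind, label, start_frame, end_frame) half-open windows."""
        out, t = [], 0.0
        for kind, label, dur in self.epochs():
            start, t = round(t * fps), t + dur
            out.append((kind, label, start, round(t * fps)))
        return out

    def stim_windows(self, fps: float) -> list:
        """Light-ON windows only, as (start_frame, end_frame) half-open pairs."""
        return [(s, e) for kind, _, s, e in self.windows(fps) if kind == "stim"]


@dataclass(frozen=True)
class StimulusOutcome:
    """Whether one fly displayed a behaviour during one stimulus window."""

    fly_id: str
    stimulus_index: int
    behaviour: str
    responded: bool
    response_onset_frame: Optional[int] = None

    def __post_init__(self) -> None:
        if self.responded != (self.response_onset_frame is not None):
            raise ValueError("responded must be True iff response_onset_frame is present")


def build_protocol(
    baseline_s: float,
    n_stimuli: int,
    stim_s: float,
    isi_s: float,
    *,
    trailing_isi: bool = False,
    protocol_id: str = "pulsed",
) -> StimulationProtocol:
    """Pulsed activation protocol: baseline, then n alternating stim/ISI.

    The canonical activation protocol is ``build_protocol(60, 6, 10, 20)``:
    1 min baseline then six 10-s stimuli separated by 20-s intervals
    (total 60 + 6·10 + 5·20 = 220 s).
    """
    return StimulationProtocol(
        protocol_id,
        baseline_s=baseline_s,
        n_stimuli=n_stimuli,
        stim_s=stim_s,
        isi_s=isi_s,
        trailing_isi=trailing_isi,
    )


def build_constant_protocol(
    pre_s: Optional[float],
    stim_s: float,
    post_s: Optional[float],
    *,
    protocol_id: str = "constant",
) -> StimulationProtocol:
    """Constant-light protocol (e.g. 10 min pre, 15 min ON, 5 min post)."""
    return StimulationProtocol(protocol_id, pre_s=pre_s, constant_s=stim_s, post_s=post_s)


def _group_flies(dataset, group: str) -> list:
    flies = dataset.flies_in_group(group)
    if not flies:
        raise ValueError(f"no flies in group {group!r}")
    return flies


def pct_stimulations_with_behaviour(
    dataset,
    group: str,
    behaviour: str,
    protocol: StimulationProtocol,
    *,
    min_overlap_frames: int = 1,
    require_onset_inside: bool = False,
):
    """Fraction of stimuli with ≥1 overlapping bout, pooled over a group.

    A stimulus "has behaviour" when a bout of ``behaviour`` overlaps its
    light-ON window by at least ``min_overlap_frames`` frames; with
    ``require_onset_inside`` the bout must also start inside the window.
    Returns ``(proportion, outcomes)`` where outcomes has one
    :class:`StimulusOutcome` per (fly, stimulus).
    """
    flies = _group_flies(dataset, group)
    outcomes = []
    for fly in flies:
        rec = dataset.recordings[fly]
        bouts = dataset.bouts_for(fly, behaviour)
        for idx, (on, off) in enumerate(protocol.stim_windows(rec.fps), start=1):
            onset = None
            for b in bouts:
                # overlap of inclusive [start, end] with half-open [on, off)
                overlap = min(b.end_frame, off - 1) - max(b.start_frame, on) + 1
                if overlap < min_overlap_frames:
                    continue
                if require_onset_inside and not (on <= b.start_frame < off):
                    continue
                onset = b.start_frame
                break
            outcomes.append(StimulusOutcome(fly, idx, behaviour, onset is not None, onset))
    if not outcomes:
        raise ValueError(f"protocol {protocol.protocol_id!r} defines no stimulus windows")
    proportion = sum(o.responded for o in outcomes) / len(outcomes)
    return proportion, outcomes


def egg_allocation(dataset, group: str, protocol: StimulationProtocol) -> pd.DataFrame:
    """Percentage of eggs expelled in each protocol epoch (sums to 100).

    Each expulsion is assigned to the epoch whose half-open frame window
    contains its end frame; eggs outside the protocol period are ignored.
    """
    flies = _group_flies(dataset, group)
    counts: dict = {}
    labels = [label for _, label, _ in protocol.epochs()]
    kinds = {label: kind for kind, label, _ in protocol.epochs()}
    for label in labels:
        counts[label] = 0
    total = 0
    for fly in flies:
        rec = dataset.recordings[fly]
        windows = protocol.windows(rec.fps)
        for b in dataset.bouts_for(fly, "egg_expulsion"):
            for _, label, start, end in windows:
                if start <= b.end_frame < end:
                    counts[label] += 1
                    total += 1
                    break
    if total == 0:
        raise ValueError(f"no egg expulsions within protocol period for group {group!r}")
    return pd.DataFrame(
        {
            "epoch": labels,
            "kind": [kinds[l] for l in labels],
            "n_eggs": [counts[l] for l in labels],
            "pct_eggs": [100.0 * counts[l] / total for l in labels],
        }
    )


def latency_to_expulsion(dataset, fly_id: str, protocol: StimulationProtocol):
    """Seconds from the first stimulus onset to the fly's first expulsion
    starting at or after it; ``None`` when no such expulsion exists."""
    rec = dataset.recordings[fly_id]
    stims = protocol.stim_windows(rec.fps)
    if not stims:
        raise ValueError(f"protocol {protocol.protocol_id!r} has no stimulus window")
    onset = stims[0][0]
    for b in dataset.bouts_for(fly_id, "egg_expulsion"):
        if b.start_frame >= onset:
            return (b.start_frame - onset) / rec.fps
    return None


def read_protocols(path: str) -> dict:
    """Read a protocols.csv into ``{protocol_id: StimulationProtocol}``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _CSV_COLUMNS[:-1] if c not in df.columns]
    if missing:
        from .io import FormatError

        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    def opt_float(v: str):
        return float(v) if v != "" else None

    protocols = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        n_stimuli = int(float(d["n_stimuli"])) if d["n_stimuli"] != "" else None
        protocols[d["protocol_id"]] = StimulationProtocol(
            d["protocol_id"],
            baseline_s=opt_float(d["baseline_s"]),
            n_stimuli=n_stimuli,
            stim_s=opt_float(d["stim_s"]),
            isi_s=opt_float(d["isi_s"]),
            pre_s=opt_float(d["pre_s"]),
            constant_s=opt_float(d["constant_s"]),
            post_s=opt_float(d["post_s"]),
            trailing_isi=d.get("trailing_isi", "") in ("True", "true", "1"),
        )
    return protocols


def write_protocols(protocols: dict, path: str) -> None:
    rows = []
    for pid in sorted(protocols):
        p = protocols[pid]
        # durations serialize as floats so a write/read cycle is byte-stable
        rows.append(
            {
                "protocol_id": p.protocol_id,
                "baseline_s": "" if p.baseline_s is None else float(p.baseline_s),
                "n_stimuli": "" if p.n_stimuli is None else int(p.n_stimuli),
                "stim_s": "" if p.stim_s is None else float(p.stim_s),
                "isi_s": "" if p.isi_s is None else float(p.isi_s),
                "pre_s": "" if p.pre_s is None else float(p.pre_s),
                "constant_s": "" if p.constant_s is None else float(p.constant_s),
                "post_s": "" if p.post_s is None else float(p.post_s),
                "trailing_isi": p.trailing_isi,
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
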