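"""Ethogram data model and annotation-table I/O.

The unit of analysis is the *bout*: a maximal contiguous episode of one
behaviour by one fly, stored as an inclusive, 0-based frame interval
``[start_frame, end_frame]`` (a one-frame bout has ``start == end``).
Frame-to-second conversion always goes through the per-recording frame
rate, because experiments mix 20 fps and 15 fps videos.

Annotations arrive as CSV event tables (one row per bout) produced by a
manual video annotator; this module reads, validates and re-serialises
them.  Overlap of two bouts of the *same* behaviour is a data error
(they would be a single bout); bouts of different behaviours may
co-occur freely, e.g. ovipositor extrusion during abdominal contortions.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "CANONICAL_BEHAVIOURS",
    "Bout",
    "Recording",
    "EthogramDataset",
    "ValidationIssue",
    "ValidationReport",
    "FormatError",
    "ValidationError",
    "read_annotations",
    "write_annotations",
    "validate_dataset",
]

#: The eight canonical egg-laying motor-element labels.  Unknown labels are
#: accepted but flagged in validation reports.
CANONICAL_BEHAVIOURS = frozenset(
    {
        "egg_expulsion",
        "ovipositor_contact",
        "burrowing",
        "egg_pushing",
        "abdomen_curling",
        "grooming_terminalia",
        "abdominal_contortions",
        "proboscis_extension",
    }
)

#: Motor elements of the egg-deposition sequence, in their stereotyped order.
DEPOSITION_SEQUENCE = (
    "ovipositor_contact",
    "burrowing",
    "egg_pushing",
    "egg_expulsion",
    "abdomen_curling",
)

_EVENT_COLUMNS = ("fly_id", "behaviour", "start_frame", "end_frame")
_RECORDING_COLUMNS = ("fly_id", "fps", "n_frames", "group")


class FormatError(ValueError):
    """A file does not conform to the documented CSV dialect."""


class ValidationError(ValueError):
    """A dataset violates a structural invariant."""


@dataclass(frozen=True)
class Bout:
    """One behaviour bout: inclusive frame interval for one fly.

    ``attributes`` carries optional per-bout annotations such as
    ``buried`` on egg-expulsion bouts (values ``yes``/``no``/``unknown``).
    """

    fly_id: str
    behaviour: str
    start_frame: int
    end_frame: int
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", dict(self.attributes))

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def duration_seconds(self, fps: float) -> float:
        """Bout duration as (last frame − first frame) / fps.

        This is the subtraction convention used throughout the metrics;
        a one-frame bout has duration 0 s.
        """
        return (self.end_frame - self.start_frame) / fps

    def overlaps(self, other: "Bout") -> bool:
        return self.start_frame <= other.end_frame and other.start_frame <= self.end_frame

    def sort_key(self) -> tuple:
        return (self.fly_id, self.behaviour, self.start_frame, self.end_frame)


@dataclass(frozen=True)
class Recording:
    """Per-fly recording metadata anchoring all frame↔second conversions."""

    fly_id: str
    fps: float
    n_frames: int
    group: str = ""
    protocol_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValidationError(f"recording {self.fly_id!r}: fps must be positive, got {self.fps}")
        if self.n_frames < 1:
            raise ValidationError(
                f"recording {self.fly_id!r}: n_frames must be >= 1, got {self.n_frames}"
            )

    @property
    def duration_seconds(self) -> float:
        return self.n_frames / self.fps


@dataclass
class EthogramDataset:
    """A set of recordings, their bouts and optional stimulation protocols.

    Bouts are kept sorted by (fly_id, behaviour, start_frame); row order in
    input files carries no meaning.
    """

    recordings: dict  # fly_id -> Recording
    bouts: list  # list[Bout], sorted
    protocols: dict = field(default_factory=dict)  # protocol_id -> StimulationProtocol

    def __post_init__(self) -> None:
        self.bouts = sorted(self.bouts, key=Bout.sort_key)

    def fly_ids(self) -> list:
        return sorted(self.recordings)

    def bouts_for(self, fly_id: str, behaviour: Optional[str] = None) -> list:
        """Bouts of one fly (optionally one behaviour), sorted by start frame."""
        sel = [b for b in self.bouts if b.fly_id == fly_id]
        if behaviour is not None:
            sel = [b for b in sel if b.behaviour == behaviour]
        return sorted(sel, key=lambda b: (b.start_frame, b.end_frame))

    def groups(self) -> list:
        return sorted({r.group for r in self.recordings.values()})

    def flies_in_group(self, group: str) -> list:
        return sorted(f for f, r in self.recordings.items() if r.group == group)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EthogramDataset):
            return NotImplemented
        return (
            self.recordings == other.recordings
            and self.bouts == other.bouts
            and self.protocols == other.protocols
        )


@dataclass(frozen=True)
class ValidationIssue:
    """One invariant violation, with enough location detail to find the row."""

    kind: str
    fly_id: Optional[str]
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f" [fly {self.fly_id}]" if self.fly_id else ""
        return f"{self.kind}{where}: {self.message}"


@dataclass
class ValidationReport:
    issues: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    @property
    def errors(self) -> list:
        return [i for i in self.issues if i.kind != "unknown_behaviour"]

    @property
    def warnings(self) -> list:
        return [i for i in self.issues if i.kind == "unknown_behaviour"]

    def __len__(self) -> int:
        return len(self.issues)

    def raise_if_invalid(self) -> None:
        if not self.ok:
            lines = "; ".join(str(i) for i in self.errors[:10])
            more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
            raise ValidationError(f"{len(self.errors)} invariant violation(s): {lines}{more}")


def validate_dataset(dataset: EthogramDataset) -> ValidationReport:
    """Check every structural invariant; violations are data, not exceptions.

    Reported kinds: ``frame_order`` (start > end), ``negative_frame``,
    ``out_of_range`` (end ≥ n_frames), ``overlap`` (same-behaviour overlap or
    frame-adjacency), ``dangling_fly`` (bout without recording),
    ``dangling_protocol``, and the warning ``unknown_behaviour``.
    """
    report = ValidationReport()
    for bout in dataset.bouts:
        loc = f"{bout.behaviour} [{bout.start_frame}, {bout.end_frame}]"
        if bout.start_frame < 0:
            report.issues.append(
                ValidationIssue("negative_frame", bout.fly_id, f"{loc}: start_frame < 0")
            )
        if bout.start_frame > bout.end_frame:
            report.issues.append(
                ValidationIssue("frame_order", bout.fly_id, f"{loc}: start_frame > end_frame")
            )
        rec = dataset.recordings.get(bout.fly_id)
        if rec is None:
            report.issues.append(
                ValidationIssue("dangling_fly", bout.fly_id, f"{loc}: no recording for fly")
            )
        elif bout.end_frame >= rec.n_frames:
            report.issues.append(
                ValidationIssue(
                    "out_of_range",
                    bout.fly_id,
                    f"{loc}: end_frame >= n_frames ({rec.n_frames})",
                )
            )
        if bout.behaviour not in CANONICAL_BEHAVIOURS:
            report.issues.append(
                ValidationIssue(
                    "unknown_behaviour", bout.fly_id, f"non-canonical label {bout.behaviour!r}"
                )
            )

    # same-behaviour overlap / adjacency within each (fly, behaviour) track
    by_track: dict = {}
    for bout in dataset.bouts:
        by_track.setdefault((bout.fly_id, bout.behaviour), []).append(bout)
    for (fly_id, behaviour), track in by_track.items():
        track.sort(key=lambda b: (b.start_frame, b.end_frame))
        for prev, cur in zip(track, track[1:]):
            if cur.start_frame <= prev.end_frame + 1:
                word = "overlapping" if cur.start_frame <= prev.end_frame else "adjacent"
                report.issues.append(
                    ValidationIssue(
                        "overlap",
                        fly_id,
                        f"{word} {behaviour} bouts "
                        f"[{prev.start_frame}, {prev.end_frame}] and "
                        f"[{cur.start_frame}, {cur.end_frame}]",
                    )
                )

    for rec in dataset.recordings.values():
        if rec.protocol_id is not None and rec.protocol_id not in dataset.protocols:
            report.issues.append(
                ValidationIssue(
                    "dangling_protocol",
                    rec.fly_id,
                    f"protocol_id {rec.protocol_id!r} not in protocol table",
                )
            )
    return report


def merge_same_behaviour_overlaps(bouts: Sequence[Bout]) -> list:
    """Merge overlapping or frame-adjacent bouts of the same (fly, behaviour).

    Used by the opt-in ``merge_overlaps`` read policy.  Attributes of merged
    bouts are combined, with the earlier bout winning on key conflicts.
    """
    by_track: dict = {}
    for bout in bouts:
        by_track.setdefault((bout.fly_id, bout.behaviour), []).append(bout)
    out = []
    for track in by_track.values():
        track.sort(key=lambda b: (b.start_frame, b.end_frame))
        current = track[0]
        attrs = dict(current.attributes)
        start, end = current.start_frame, current.end_frame
        for nxt in track[1:]:
            if nxt.start_frame <= end + 1:
                end = max(end, nxt.end_frame)
                for k, v in nxt.attributes.items():
                    attrs.setdefault(k, v)
            else:
                out.append(Bout(current.fly_id, current.behaviour, start, end, attrs))
                start, end, attrs = nxt.start_frame, nxt.end_frame, dict(nxt.attributes)
        out.append(Bout(current.fly_id, current.behaviour, start, end, attrs))
    return sorted(out, key=Bout.sort_key)


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_annotations(
    events_path: str,
    recordings_path: str,
    protocol_path: Optional[str] = None,
    *,
    merge_overlaps: bool = False,
) -> EthogramDataset:
    """Read event, recording and optional protocol tables into a dataset.

    The events table needs columns ``fly_id, behaviour, start_frame,
    end_frame``; any extra columns become per-bout attributes (empty cells
    mean "attribute absent").  The result is validated: same-behaviour
    overlaps are merged when ``merge_overlaps`` is set and rejected
    otherwise; any other invariant violation raises ``ValidationError``.
    """
    from .optostim import read_protocols  # local import to avoid a cycle

    events = pd.read_csv(events_path, dtype=str, keep_default_na=False)
    _require_columns(events, _EVENT_COLUMNS, events_path)
    recs = pd.read_csv(recordings_path, dtype=str, keep_default_na=False)
    _require_columns(recs, _RECORDING_COLUMNS, recordings_path)

    attr_cols = [c for c in events.columns if c not in _EVENT_COLUMNS]
    bouts = []
    for row in events.itertuples(index=False):
        d = row._asdict()
        try:
            start, end = int(d["start_frame"]), int(d["end_frame"])
        except ValueError as exc:
            raise FormatError(
                f"{events_path}: non-integer frame for fly {d['fly_id']!r}: {exc}"
            ) from None
        attrs = {c: d[c] for c in attr_cols if d[c] != ""}
        bouts.append(Bout(d["fly_id"], d["behaviour"], start, end, attrs))

    recordings = {}
    for row in recs.itertuples(index=False):
        d = row._asdict()
        fly = d["fly_id"]
        if fly in recordings:
            raise FormatError(f"{recordings_path}: duplicate recording for fly {fly!r}")
        protocol_id = d.get("protocol_id", "") or None
        try:
            recordings[fly] = Recording(
                fly, float(d["fps"]), int(d["n_frames"]), d["group"], protocol_id
            )
        except ValueError as exc:
            raise FormatError(f"{recordings_path}: fly {fly!r}: {exc}") from None

    protocols = read_protocols(protocol_path) if protocol_path else {}

    if merge_overlaps:
        bouts = merge_same_behaviour_overlaps(bouts)
    dataset = EthogramDataset(recordings, bouts, protocols)
    validate_dataset(dataset).raise_if_invalid()
    return dataset


def write_annotations(dataset: EthogramDataset, out_dir: str) -> dict:
    """Write events/recordings/protocols CSVs; inverse of ``read_annotations``.

    Returns ``{"events": path, "recordings": path, "protocols": path}``.
    A read→write cycle is byte-stable: tables are emitted in the canonical
    sort order with a deterministic attribute-column order.
    """
    from .optostim import write_protocols

    os.makedirs(out_dir, exist_ok=True)
    attr_cols = sorted({k for b in dataset.bouts for k in b.attributes})
    events = pd.DataFrame(
        [
            {
                "fly_id": b.fly_id,
                "behaviour": b.behaviour,
                "start_frame": b.start_frame,
                "end_frame": b.end_frame,
                **{c: b.attributes.get(c, "") for c in attr_cols},
            }
            for b in sorted(dataset.bouts, key=Bout.sort_key)
        ],
        columns=list(_EVENT_COLUMNS) + attr_cols,
    )
    recs = pd.DataFrame(
        [
            {
                "fly_id": r.fly_id,
                "fps": r.fps,
                "n_frames": r.n_frames,
                "group": r.group,
                "protocol_id": r.protocol_id or "",
            }
            for _, r in sorted(dataset.recordings.items())
        ],
        columns=["fly_id", "fps", "n_frames", "group", "protocol_id"],
    )
    paths = {
        "events": os.path.join(out_dir, "events.csv"),
        "recordings": os.path.join(out_dir, "recordings.csv"),
        "protocols": os.path.join(out_dir, "protocols.csv"),
    }
    events.to_csv(paths["events"], index=False)
    recs.to_csv(paths["recordings"], index=False)
    write_protocols(dataset.protocols, paths["protocols"])
    return paths
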