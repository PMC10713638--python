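"""Seeded semi-Markov generator of egg-laying ethograms.

The generator emulates the cyclic three-phase structure of *Drosophila*
oviposition: an egg-deposition phase instantiates the stereotyped motor
template (ovipositor contact → burrowing → egg pushing → egg expulsion →
abdomen curling, with optional grooming of the terminalia), every
deposition is followed by abdominal contortions, and contortions resolve
into either another deposition or an exploration phase of substrate
probing that never chains into an expulsion.  Phase dwell times and
element durations are drawn from right-skewed (log-normal by default)
distributions; proboscis extension runs as an independent background
renewal process across all phases.

Default parameters are calibrated so that per-fly median inter-egg
expulsion intervals fall in the 2–3 min band reported for wild-type
females, at 45-min recordings and 20 fps.  Everything is driven by a
single integer seed: identical ``(config, seed)`` give byte-identical
annotation tables.

Each simulated fly also returns its ground truth — the emitted phase
sequence, per-egg burial status and (after :func:`overlay_stimulation`)
planted stimulus responses — so that downstream estimators can be tested
as recovery problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .io import (
    Bout,
    EthogramDataset,
    Recording,
    merge_same_behaviour_overlaps,
)
from .markov import PHASES, Phase, PhaseSequence
from .optostim import StimulationProtocol

__all__ = [
    "DurationDist",
    "SimulatorConfig",
    "ResponseModel",
    "GroundTruth",
    "simulate_fly",
    "simulate_dataset",
    "overlay_stimulation",
]

# Generator-internal spacing constants (seconds).  The analysis-side chain
# rule links deposition bouts separated by <= 2 s, so template gaps are kept
# safely below it and exploration keeps a trailing margin safely above it.
_MAX_TEMPLATE_GAP_S = 1.5
_EXPLORATION_LEAD_S = 1.0
_EXPLORATION_TRAIL_S = 3.0
_INTER_PHASE_GAP_S = 1.0


@dataclass(frozen=True)
class DurationDist:
    """A positive duration distribution: log-normal, gamma or fixed.

    ``median`` is in seconds.  For the log-normal family ``sigma`` is the
    log-scale standard deviation; for gamma, shape = 1/sigma² with the
    scale chosen so the mean equals ``median``; ``fixed`` ignores sigma.
    """

    median: float
    sigma: float = 0.5
    family: str = "lognormal"

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError(f"duration median must be > 0, got {self.median}")
        if self.family not in ("lognormal", "gamma", "fixed"):
            raise ValueError(f"unknown duration family {self.family!r}")
        if self.family != "fixed" and self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            return self.median
        if self.family == "lognormal":
            return float(rng.lognormal(math.log(self.median), self.sigma))
        shape = 1.0 / self.sigma**2
        return float(rng.gamma(shape, self.median / shape))


def _default_transition() -> np.ndarray:
    # rows/cols in PHASES order: deposition, contortions, exploration
    return np.array(
        [
            [0.0, 1.0, 0.0],  # deposition -> contortions, always
            [0.5, 0.0, 0.5],  # contortions -> deposition or exploration
            [1.0, 0.0, 0.0],  # exploration -> deposition
        ]
    )


def _default_template() -> dict:
    return {
        "ovipositor_contact": DurationDist(2.5, 0.4),
        "burrowing": DurationDist(5.0, 0.4),
        "egg_pushing": DurationDist(3.5, 0.4),
        "egg_expulsion": DurationDist(1.0, 0.3),
        "abdomen_curling": DurationDist(2.5, 0.4),
        "grooming_terminalia": DurationDist(4.0, 0.4),
    }


@dataclass
class SimulatorConfig:
    """All knobs of the generative model, with study-condition defaults.

    The default transition matrix encodes the observed cycle structure:
    deposition is always followed by contortions; contortions resolve to
    deposition or exploration with equal probability; exploration returns
    to deposition.  Dwell medians (contortions 90 s, exploration 70 s) are
    calibrated to the 2–3 min per-fly median inter-egg interval; 94 % of
    determinable eggs are buried; recordings default to 45 min at 20 fps.
    """

    phase_transition: np.ndarray = field(default_factory=_default_transition)
    contortions_dwell: DurationDist = DurationDist(90.0, 0.5)
    exploration_dwell: DurationDist = DurationDist(70.0, 0.6)
    deposition_template: dict = field(default_factory=_default_template)
    template_gap: DurationDist = DurationDist(0.5, 0.3)
    exploration_contact: DurationDist = DurationDist(2.5, 0.4)
    exploration_pause: DurationDist = DurationDist(8.0, 0.5)
    exploration_burrow: DurationDist = DurationDist(3.0, 0.4)
    proboscis_duration: DurationDist = DurationDist(1.0, 0.3)
    p_grooming_after_expulsion: float = 0.5
    p_burrow_in_exploration: float = 0.3
    p_buried: float = 0.94
    p_buried_unknown: float = 0.05
    proboscis_rate_per_s: float = 1.0 / 30.0
    fps: float = 20.0
    recording_length_s: float = 45.0 * 60.0
    n_flies: int = 10
    group: str = "sim"
    seed: int = 0

    def validate(self) -> None:
        t = np.asarray(self.phase_transition, dtype=float)
        if t.shape != (3, 3):
            raise ValueError(f"phase_transition must be 3x3, got {t.shape}")
        if (t < 0).any() or (t > 1).any():
            raise ValueError("phase_transition entries must lie in [0, 1]")
        if not np.allclose(np.diag(t), 0.0):
            raise ValueError("phase_transition diagonal must be zero (phases alternate)")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("phase_transition rows must sum to 1")
        for name in ("p_grooming_after_expulsion", "p_burrow_in_exploration",
                     "p_buried", "p_buried_unknown"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fps <= 0 or self.recording_length_s <= 0:
            raise ValueError("fps and recording_length_s must be positive")
        if self.n_flies < 1:
            raise ValueError(f"n_flies must be >= 1, got {self.n_flies}")
        if self.proboscis_rate_per_s < 0:
            raise ValueError("proboscis_rate_per_s must be >= 0")
        missing = set(_default_template()) - set(self.deposition_template)
        if missing:
            raise ValueError(f"deposition_template missing elements: {sorted(missing)}")

    @property
    def n_frames(self) -> int:
        return int(round(self.recording_length_s * self.fps))


@dataclass(frozen=True)
class ResponseModel:
    """Optogenetic response overlay: which behaviour, how often, how fast."""

    behaviour: str
    p_respond: float
    latency: DurationDist = DurationDist(1.0, 0.5)
    clip_to_stimulus: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_respond <= 1.0:
            raise ValueError(f"p_respond must be in [0, 1], got {self.p_respond}")


@dataclass
class GroundTruth:
    """What the simulator actually did, keyed to the emitted tables.

    ``phase_sequences`` maps fly → the emitted (run-length-collapsed)
    phase sequence; ``egg_buried`` maps fly → list of burial statuses in
    expulsion order; ``responses`` holds (fly_id, stimulus_index,
    responded, onset_frame) tuples planted by the stimulation overlay.
    """

    phase_sequences: dict = field(default_factory=dict)
    egg_buried: dict = field(default_factory=dict)
    responses: list = field(default_factory=list)


class _FlyBuilder:
    """Accumulates one fly's bouts in seconds, emitting frames at the end."""

    def __init__(self, fly_id: str, config: SimulatorConfig):
        self.fly_id = fly_id
        self.config = config
        self.raw: list = []  # (behaviour, start_s, duration_s, attributes)

    def add(self, behaviour: str, start_s: float, duration_s: float, **attributes) -> bool:
        """Queue a bout, clipped to the recording; False when nothing fits."""
        fps, n_frames = self.config.fps, self.config.n_frames
        start = int(round(start_s * fps))
        if start >= n_frames:
            return False
        end = start + max(1, int(round(duration_s * fps))) - 1
        end = min(end, n_frames - 1)
        self.raw.append((behaviour, start, end, attributes))
        return True

    def bouts(self) -> list:
        return [
            Bout(self.fly_id, behaviour, start, end, attrs)
            for behaviour, start, end, attrs in self.raw
        ]


def _emit_deposition(builder: _FlyBuilder, rng: np.random.Generator, t: float):
    """Lay out one deposition template starting at time t.

    Returns ``(end_time_s, expulsion_start_s, buried_status)`` or ``None``
    when the full template does not fit before the recording end — a
    partial template is never emitted (it would read as a spurious
    exploration contact downstream).
    """
    cfg = builder.config
    order = ("ovipositor_contact", "burrowing", "egg_pushing", "egg_expulsion",
             "abdomen_curling")
    durations = [cfg.deposition_template[name].sample(rng) for name in order]
    gaps = [min(cfg.template_gap.sample(rng), _MAX_TEMPLATE_GAP_S) for _ in order]
    groom = rng.random() < cfg.p_grooming_after_expulsion
    groom_dur = cfg.deposition_template["grooming_terminalia"].sample(rng)
    if rng.random() < cfg.p_buried_unknown:
        buried = "unknown"
    elif rng.random() < cfg.p_buried:
        buried = "yes"
    else:
        buried = "no"

    total = sum(durations) + sum(gaps[:-1]) + ((gaps[-1] + groom_dur) if groom else 0.0)
    if t + total > cfg.recording_length_s:
        return None

    cursor = t
    expulsion_start = None
    for name, dur, gap in zip(order, durations, gaps):
        attrs = {"buried": buried} if name == "egg_expulsion" else {}
        if name == "egg_expulsion":
            expulsion_start = cursor
        builder.add(name, cursor, dur, **attrs)
        cursor += dur + gap
    if groom:
        builder.add("grooming_terminalia", cursor, groom_dur)
        cursor += groom_dur
    else:
        cursor -= gaps[-1]
    return cursor, expulsion_start, buried


def _emit_exploration(builder: _FlyBuilder, rng: np.random.Generator, t: float, dwell: float):
    """Contact (± burrowing) bouts inside an exploration dwell window.

    Returns the onset (s) of the first contact, or ``None`` when no
    contact fits.  A trailing margin keeps the last probing bout more
    than one chain-gap away from whatever follows the phase.
    """
    cfg = builder.config
    window_end = min(t + dwell, cfg.recording_length_s) - _EXPLORATION_TRAIL_S
    cursor = t + _EXPLORATION_LEAD_S
    first_onset = None
    while cursor < window_end:
        dur = cfg.exploration_contact.sample(rng)
        dur = min(dur, window_end - cursor)
        if dur * cfg.fps < 1.0:
            break
        if not builder.add("ovipositor_contact", cursor, dur):
            break
        if first_onset is None:
            first_onset = cursor
        if rng.random() < cfg.p_burrow_in_exploration:
            b_start = cursor + 0.5 * dur
            # burrowing accompanies the contact; cap it so it cannot reach
            # the next probing bout regardless of the sampled pause
            b_dur = min(cfg.exploration_burrow.sample(rng), window_end - b_start,
                        0.5 * dur + 2.0)
            if b_dur * cfg.fps >= 1.0:
                builder.add("burrowing", b_start, b_dur)
        # pauses never drop below 3 s, keeping successive probing bouts
        # (and their burrows) disjoint and non-adjacent after rounding
        cursor += dur + max(3.0, cfg.exploration_pause.sample(rng))
    return first_onset


def _emit_proboscis(builder: _FlyBuilder, rng: np.random.Generator) -> None:
    """Background proboscis-extension renewal process over the recording."""
    cfg = builder.config
    if cfg.proboscis_rate_per_s <= 0:
        return
    t = float(rng.exponential(1.0 / cfg.proboscis_rate_per_s))
    while t < cfg.recording_length_s:
        dur = cfg.proboscis_duration.sample(rng)
        builder.add("proboscis_extension", t, dur)
        # renewal gap keeps successive bouts non-adjacent
        t += dur + 0.2 + float(rng.exponential(1.0 / cfg.proboscis_rate_per_s))


def simulate_fly(config: SimulatorConfig, fly_seed: int, fly_id: str = "fly"):
    """Simulate one fly; returns ``(bouts, phase_sequence, egg_buried)``.

    Phases alternate by sampling the transition matrix; dwell times and
    element durations come from the configured distributions; the
    recording truncates the process.  Identical ``(config, fly_seed)``
    yield identical output.
    """
    config.validate()
    rng = np.random.default_rng(fly_seed)
    builder = _FlyBuilder(fly_id, config)
    transition = np.asarray(config.phase_transition, dtype=float)

    entries: list = []  # (Phase, onset_frame)
    buried_statuses: list = []

    def record_phase(phase: Phase, onset_s: float) -> None:
        onset = int(round(onset_s * config.fps))
        if not entries or entries[-1][0] != phase:
            entries.append((phase, onset))

    phase = Phase.EXPLORATION
    t = _INTER_PHASE_GAP_S
    while t < config.recording_length_s:
        if phase == Phase.DEPOSITION:
            emitted = _emit_deposition(builder, rng, t)
            if emitted is None:
                break
            t_end, expulsion_start, buried = emitted
            record_phase(Phase.DEPOSITION, expulsion_start)
            buried_statuses.append(buried)
            t = t_end + _INTER_PHASE_GAP_S
        elif phase == Phase.CONTORTIONS:
            dwell = config.contortions_dwell.sample(rng)
            if not builder.add("abdominal_contortions", t,
                               min(dwell, config.recording_length_s - t)):
                break
            record_phase(Phase.CONTORTIONS, t)
            t += dwell + _INTER_PHASE_GAP_S
        else:
            dwell = config.exploration_dwell.sample(rng)
            first_onset = _emit_exploration(builder, rng, t, dwell)
            if first_onset is None:
                break
            record_phase(Phase.EXPLORATION, first_onset)
            t += dwell + _INTER_PHASE_GAP_S
        phase = PHASES[rng.choice(3, p=transition[PHASES.index(phase)])]

    _emit_proboscis(builder, rng)
    return builder.bouts(), PhaseSequence(fly_id, entries), buried_statuses


def simulate_dataset(config: SimulatorConfig, n_flies: Optional[int] = None):
    """Simulate a whole dataset; returns ``(EthogramDataset, GroundTruth)``.

    Per-fly seeds derive deterministically from ``config.seed`` via a
    seed sequence, so the dataset is reproducible fly-by-fly and the
    result always passes validation.
    """
    config.validate()
    if n_flies is None:
        n_flies = config.n_flies
    if n_flies < 1:
        raise ValueError(f"n_flies must be >= 1, got {n_flies}")

    truth = GroundTruth()
    recordings, bouts = {}, []
    width = len(str(n_flies))
    for i in range(n_flies):
        fly_id = f"fly{i + 1:0{width}d}"
        fly_seed = int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31))
        fly_bouts, phase_seq, buried = simulate_fly(config, fly_seed, fly_id)
        bouts.extend(fly_bouts)
        recordings[fly_id] = Recording(fly_id, config.fps, config.n_frames, config.group)
        truth.phase_sequences[fly_id] = phase_seq
        truth.egg_buried[fly_id] = buried
    return EthogramDataset(recordings, bouts), truth


def overlay_stimulation(
    dataset: EthogramDataset,
    truth: GroundTruth,
    protocol: StimulationProtocol,
    response_model: ResponseModel,
    *,
    seed: int = 0,
) -> EthogramDataset:
    """Plant stimulus-locked response bouts into a simulated dataset.

    For every fly and light-ON window, with probability ``p_respond`` a
    bout of the response behaviour is inserted at onset + sampled latency
    and lasts to the end of the window.  A latency falling beyond the
    window is clipped to the final window frame when
    ``clip_to_stimulus``, otherwise the planted response is dropped (and
    recorded as a non-response).  Planted outcomes are appended to
    ``truth.responses``; a new dataset is returned, with same-behaviour
    overlaps merged so the result stays valid.
    """
    rng = np.random.default_rng(seed)
    new_bouts = list(dataset.bouts)
    recordings = {}
    for fly_id in dataset.fly_ids():
        rec = dataset.recordings[fly_id]
        recordings[fly_id] = replace(rec, protocol_id=protocol.protocol_id)
        for idx, (on, off) in enumerate(protocol.stim_windows(rec.fps), start=1):
            if rng.random() >= response_model.p_respond:
                truth.responses.append((fly_id, idx, False, None))
                continue
            latency_frames = int(round(response_model.latency.sample(rng) * rec.fps))
            onset = on + latency_frames
            if onset >= off:
                if response_model.clip_to_stimulus:
                    onset = off - 1
                else:
                    truth.responses.append((fly_id, idx, False, None))
                    continue
            end = min(off - 1, rec.n_frames - 1)
            if onset > end:
                truth.responses.append((fly_id, idx, False, None))
                continue
            new_bouts.append(Bout(fly_id, response_model.behaviour, onset, end))
            truth.responses.append((fly_id, idx, True, onset))
    protocols = dict(dataset.protocols)
    protocols[protocol.protocol_id] = protocol
    return EthogramDataset(
        recordings, merge_same_behaviour_overlaps(new_bouts), protocols
    )
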