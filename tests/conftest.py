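"""Shared fixtures: hand-built tiny ethograms and a random-dataset factory.

The random factory is deliberately independent of the package's own
simulator: it lays out non-overlapping bouts per (fly, behaviour) track
by walking a cursor with positive gaps, so oracle tests exercise the
analysis code on data the analysis code had no hand in generating.
"""

import numpy as np
import pytest

from ovibout.io import Bout, EthogramDataset, Recording

BEHAVIOURS = [
    "egg_expulsion",
    "ovipositor_contact",
    "burrowing",
    "egg_pushing",
    "abdominal_contortions",
    "grooming_terminalia",
    "proboscis_extension",
]


def make_dataset(bouts, n_frames=54000, fps=20.0, group="g", protocols=None):
    """Dataset from raw bout tuples (fly, behaviour, start, end[, attrs])."""
    built = []
    flies = set()
    for spec in bouts:
        fly, behaviour, start, end = spec[:4]
        attrs = spec[4] if len(spec) > 4 else {}
        built.append(Bout(fly, behaviour, start, end, attrs))
        flies.add(fly)
    recordings = {f: Recording(f, fps, n_frames, group) for f in sorted(flies) or {"fly1"}}
    return EthogramDataset(recordings, built, protocols or {})


def random_dataset(rng, n_flies=3, n_frames_range=(2000, 6000), max_bouts_per_track=8):
    """A random valid dataset: disjoint, non-adjacent bouts per track."""
    recordings, bouts = {}, []
    for i in range(n_flies):
        fly = f"f{i}"
        n_frames = int(rng.integers(*n_frames_range))
        fps = float(rng.choice([15.0, 20.0]))
        recordings[fly] = Recording(fly, fps, n_frames, group=rng.choice(["ctrl", "test"]))
        for behaviour in BEHAVIOURS:
            n_bouts = int(rng.integers(0, max_bouts_per_track + 1))
            cursor = int(rng.integers(0, 50))
            for _ in range(n_bouts):
                start = cursor + int(rng.integers(2, 80))
                end = start + int(rng.integers(0, 60))
                if end >= n_frames:
                    break
                attrs = {}
                if behaviour == "egg_expulsion":
                    attrs["buried"] = str(rng.choice(["yes", "no", "unknown"]))
                bouts.append(Bout(fly, behaviour, start, end, attrs))
                cursor = end
    return EthogramDataset(recordings, bouts)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def simple_dataset():
    """One fly, three expulsions and a few accompanying bouts at 20 fps."""
    return make_dataset(
        [
            ("fly1", "egg_expulsion", 100, 105, {"buried": "yes"}),
            ("fly1", "egg_expulsion", 2500, 2510, {"buried": "no"}),
            ("fly1", "egg_expulsion", 5000, 5004, {"buried": "yes"}),
            ("fly1", "ovipositor_contact", 60, 80),
            ("fly1", "ovipositor_contact", 1200, 1220),
            ("fly1", "abdominal_contortions", 300, 900),
        ]
    )
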