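"""Per-fly bout metrics against hand arithmetic and brute-force oracles."""

import math

import numpy as np
import pytest

from ovibout.metrics import (
    TimeBinSpec,
    bouts_per_egg,
    counts_per_bin,
    inter_egg_intervals,
    mean_bout_duration,
    metric_table,
    proportion_eggs_not_buried,
    proportion_with_flag,
)

from conftest import BEHAVIOURS, make_dataset, random_dataset


class TestInterEggIntervals:
    def test_direct_formula(self, simple_dataset):
        # expulsions (100,105), (2500,2510), (5000,5004) at 20 fps
        assert inter_egg_intervals(simple_dataset, "fly1") == [2395, 2490]
        assert inter_egg_intervals(simple_dataset, "fly1", unit="seconds") == [119.75, 124.5]

    def test_single_expulsion_yields_empty(self):
        dataset = make_dataset([("fly1", "egg_expulsion", 100, 105)])
        assert inter_egg_intervals(dataset, "fly1") == []

    def test_matches_pairwise_difference_oracle(self, rng):
        # 50 random expulsion bouts, disjoint by construction
        cursor, bouts = 0, []
        for _ in range(50):
            start = cursor + int(rng.integers(2, 500))
            end = start + int(rng.integers(0, 100))
            bouts.append(("fly1", "egg_expulsion", start, end))
            cursor = end
        dataset = make_dataset(bouts, n_frames=cursor + 1)
        starts = sorted(b[2] for b in bouts)
        ends = sorted(b[3] for b in bouts)
        expected = [starts[i + 1] - ends[i] for i in range(49)]
        assert inter_egg_intervals(dataset, "fly1") == expected


class TestCountsPerBin:
    def test_counts_land_in_start_bins(self):
        # 15-min recording at 20 fps, 300-s bins -> 3 complete bins
        dataset = make_dataset(
            [
                ("fly1", "egg_expulsion", 100, 105),
                ("fly1", "egg_expulsion", 3000, 3004),
                ("fly1", "egg_expulsion", 5900, 5904),
            ],
            n_frames=18000,
        )
        assert counts_per_bin(dataset, "fly1", "egg_expulsion") == [3, 0, 0]

    def test_straddling_bout_counts_once_in_start_bin(self):
        dataset = make_dataset([("fly1", "burrowing", 5990, 6020)], n_frames=18000)
        assert counts_per_bin(dataset, "fly1", "burrowing") == [1, 0, 0]

    def test_bin_longer_than_recording_errors(self):
        dataset = make_dataset([("fly1", "burrowing", 0, 5)], n_frames=100)
        with pytest.raises(ValueError, match="exceeds"):
            counts_per_bin(dataset, "fly1", "burrowing", TimeBinSpec(300.0))

    def test_matches_histogram_oracle(self, rng):
        for _ in range(30):
            dataset = random_dataset(rng, n_flies=2)
            for fly in dataset.fly_ids():
                rec = dataset.recordings[fly]
                spec = TimeBinSpec(30.0)
                n_bins = int(rec.n_frames / (30.0 * rec.fps))
                if n_bins == 0:
                    continue
                for behaviour in BEHAVIOURS:
                    starts = [b.start_frame for b in dataset.bouts_for(fly, behaviour)]
                    width = 30.0 * rec.fps
                    expected = [
                        sum(1 for s in starts if i * width <= s < (i + 1) * width)
                        for i in range(n_bins)
                    ]
                    assert counts_per_bin(dataset, fly, behaviour, spec) == expected


class TestBoutsPerEgg:
    def test_direct_ratio(self):
        bouts = [("fly1", "ovipositor_contact", 100 * i, 100 * i + 10) for i in range(6)]
        bouts += [("fly1", "egg_expulsion", 1000 + 100 * i, 1000 + 100 * i + 5) for i in range(3)]
        dataset = make_dataset(bouts)
        assert bouts_per_egg(dataset, "fly1", "ovipositor_contact") == 2.0

    def test_zero_eggs_is_undefined(self, caplog):
        dataset = make_dataset([("fly1", "ovipositor_contact", 0, 10)])
        with caplog.at_level("WARNING"):
            assert bouts_per_egg(dataset, "fly1", "ovipositor_contact") is None
        assert "no eggs" in caplog.text

    def test_frames_reading_sums_bout_lengths(self):
        dataset = make_dataset(
            [
                ("fly1", "burrowing", 0, 19),  # 20 frames
                ("fly1", "burrowing", 100, 129),  # 30 frames
                ("fly1", "egg_expulsion", 500, 505),
            ]
        )
        assert bouts_per_egg(dataset, "fly1", "burrowing") == 2.0
        assert bouts_per_egg(dataset, "fly1", "burrowing", count_frames=True) == 50.0


class TestMeanBoutDuration:
    def test_last_minus_first_frame_convention(self):
        dataset = make_dataset([("fly1", "burrowing", 0, 20), ("fly1", "burrowing", 100, 140)])
        assert mean_bout_duration(dataset, "fly1", "burrowing") == 1.5

    def test_one_frame_bout_lasts_zero_seconds(self):
        dataset = make_dataset([("fly1", "burrowing", 5, 5)])
        assert mean_bout_duration(dataset, "fly1", "burrowing") == 0.0

    def test_no_bouts_is_undefined(self):
        dataset = make_dataset([("fly1", "burrowing", 5, 5)])
        assert mean_bout_duration(dataset, "fly1", "egg_pushing") is None


class TestProportions:
    def test_unknown_status_excluded(self):
        dataset = make_dataset(
            [
                ("fly1", "egg_expulsion", 100, 105, {"buried": "no"}),
                ("fly1", "egg_expulsion", 300, 305, {"buried": "yes"}),
                ("fly1", "egg_expulsion", 500, 505, {"buried": "yes"}),
                ("fly1", "egg_expulsion", 700, 705, {"buried": "unknown"}),
            ]
        )
        assert proportion_eggs_not_buried(dataset, "fly1") == pytest.approx(1 / 3)

    def test_all_unknown_is_undefined(self):
        dataset = make_dataset([("fly1", "egg_expulsion", 100, 105, {"buried": "unknown"})])
        assert proportion_eggs_not_buried(dataset, "fly1") is None

    def test_population_proportion(self):
        assert proportion_with_flag(17, 17) == 1.0
        assert proportion_with_flag(0, 24) == 0.0
        with pytest.raises(ValueError):
            proportion_with_flag(0, 0)

    def test_random_ratios_match_division(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 100))
            k = int(rng.integers(0, n + 1))
            assert proportion_with_flag(k, n) == k / n


def test_all_metrics_match_brute_force_enumeration(rng):
    """Every formula equals an independently coded enumeration, 200 datasets."""
    for _ in range(200):
        dataset = random_dataset(rng, n_flies=2, max_bouts_per_track=5)
        for fly in dataset.fly_ids():
            fps = dataset.recordings[fly].fps
            tracks = {
                beh: sorted(
                    [(b.start_frame, b.end_frame) for b in dataset.bouts if
                     b.fly_id == fly and b.behaviour == beh]
                )
                for beh in BEHAVIOURS
            }
            eggs = tracks["egg_expulsion"]
            # inter-egg intervals by explicit pairwise difference
            expected_iei = [eggs[i + 1][0] - eggs[i][1] for i in range(len(eggs) - 1)]
            assert inter_egg_intervals(dataset, fly) == expected_iei
            for beh in BEHAVIOURS:
                n_bouts = len(tracks[beh])
                # bouts per egg
                got = bouts_per_egg(dataset, fly, beh)
                if not eggs:
                    assert got is None
                else:
                    assert got == pytest.approx(n_bouts / len(eggs))
                # mean duration
                got = mean_bout_duration(dataset, fly, beh)
                if n_bouts == 0:
                    assert got is None
                else:
                    durations = [(e - s) / fps for s, e in tracks[beh]]
                    assert got == pytest.approx(sum(durations) / n_bouts)
            # burial proportion by filter-then-ratio
            statuses = [
                b.attributes.get("buried", "unknown")
                for b in sorted(
                    (b for b in dataset.bouts if b.fly_id == fly and b.behaviour == "egg_expulsion"),
                    key=lambda b: b.start_frame,
                )
            ]
            determined = [s for s in statuses if s != "unknown"]
            got = proportion_eggs_not_buried(dataset, fly)
            if not determined:
                assert got is None
            else:
                assert got == pytest.approx(determined.count("no") / len(determined))


def test_metric_table_keeps_undefined_rows_explicit(rng):
    dataset = random_dataset(rng, n_flies=3)
    table = metric_table(dataset)
    undefined = table[~table["defined"]]
    assert undefined["value"].isna().all()
    # one row per (fly, metric, window)
    assert not table.duplicated(["fly_id", "metric", "window"]).any()
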