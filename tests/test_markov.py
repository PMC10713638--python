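"""Phase extraction, contact classification and transition estimation."""

import numpy as np
import pytest

from ovibout.markov import (
    CHAIN_BEHAVIOURS,
    PHASES,
    Phase,
    PhaseSequence,
    classify_ovipositor_contact,
    per_fly_average_matrix,
    transition_matrix,
    extract_phase_sequence,
)

from conftest import make_dataset


def get_contact(dataset, fly="fly1", index=0):
    return dataset.bouts_for(fly, "ovipositor_contact")[index]


class TestClassifyContact:
    def test_canonical_deposition_chain_progresses(self):
        # contact -> burrowing (gap 5) -> egg_pushing (gap 3) -> expulsion (gap 0)
        dataset = make_dataset(
            [
                ("fly1", "ovipositor_contact", 100, 140),
                ("fly1", "burrowing", 146, 240),
                ("fly1", "egg_pushing", 244, 300),
                ("fly1", "egg_expulsion", 301, 320),
            ]
        )
        assert classify_ovipositor_contact(dataset, "fly1", get_contact(dataset)) == "progressing"

    def test_contortions_break_the_chain(self):
        dataset = make_dataset(
            [
                ("fly1", "ovipositor_contact", 100, 140),
                ("fly1", "abdominal_contortions", 150, 400),
                ("fly1", "egg_expulsion", 160, 180),
            ]
        )
        assert (
            classify_ovipositor_contact(dataset, "fly1", get_contact(dataset))
            == "non_progressing"
        )

    def test_gap_beyond_linkage_breaks_the_chain(self):
        dataset = make_dataset(
            [
                ("fly1", "ovipositor_contact", 100, 140),
                ("fly1", "egg_expulsion", 300, 320),  # gap 159 frames > 40 (2 s @ 20 fps)
            ]
        )
        assert (
            classify_ovipositor_contact(dataset, "fly1", get_contact(dataset))
            == "non_progressing"
        )
        assert (
            classify_ovipositor_contact(dataset, "fly1", get_contact(dataset), linkage_gap=200)
            == "progressing"
        )

    def test_matches_graph_reachability_oracle(self, rng):
        """Greedy chain walk equals BFS over the bout adjacency relation."""
        linkage = 40
        for _ in range(100):
            cursor, bouts = 0, []
            for _ in range(int(rng.integers(3, 12))):
                behaviour = str(rng.choice(list(CHAIN_BEHAVIOURS)))
                start = cursor + int(rng.integers(1, 80))
                end = start + int(rng.integers(0, 30))
                bouts.append(("fly1", behaviour, start, end))
                cursor = end
            for _ in range(int(rng.integers(0, 3))):
                onset = int(rng.integers(0, max(cursor, 1)))
                bouts.append(("fly1", "abdominal_contortions", onset, onset + 2))
            # contortion bouts may collide; keep only valid layouts
            contortion = sorted(
                [(s, e) for f, b, s, e in bouts if b == "abdominal_contortions"]
            )
            if any(b[0] <= a[1] + 1 for a, b in zip(contortion, contortion[1:])):
                continue
            dataset = make_dataset(bouts, n_frames=cursor + 100)

            chain = sorted(
                (b for b in dataset.bouts_for("fly1") if b.behaviour in CHAIN_BEHAVIOURS),
                key=lambda b: (b.start_frame, b.end_frame),
            )
            onsets = [s for s, _ in contortion]

            def reachable(i):
                seen, frontier = {i}, [i]
                while frontier:
                    u = frontier.pop()
                    if chain[u].behaviour == "egg_expulsion":
                        return True
                    for v in range(u + 1, len(chain)):
                        if v in seen:
                            continue
                        gap = chain[v].start_frame - chain[u].end_frame - 1
                        if gap > linkage:
                            continue
                        if any(chain[u].end_frame < t <= chain[v].start_frame for t in onsets):
                            continue
                        seen.add(v)
                        frontier.append(v)
                return False

            for i, b in enumerate(chain):
                if b.behaviour != "ovipositor_contact":
                    continue
                expected = "progressing" if reachable(i) else "non_progressing"
                got = classify_ovipositor_contact(dataset, "fly1", b, linkage_gap=linkage)
                assert got == expected, (chain, onsets, i)


class TestExtractPhaseSequence:
    def test_direct_mapping(self):
        dataset = make_dataset(
            [
                ("fly1", "abdominal_contortions", 0, 100),
                ("fly1", "ovipositor_contact", 500, 520),  # isolated -> exploration
                ("fly1", "abdominal_contortions", 900, 1000),
                ("fly1", "egg_expulsion", 1500, 1505),
            ]
        )
        seq = extract_phase_sequence(dataset, "fly1")
        assert seq.phases() == [
            Phase.CONTORTIONS,
            Phase.EXPLORATION,
            Phase.CONTORTIONS,
            Phase.DEPOSITION,
        ]

    def test_consecutive_expulsions_collapse_keeping_earliest_onset(self):
        dataset = make_dataset(
            [
                ("fly1", "egg_expulsion", 100, 105),
                ("fly1", "egg_expulsion", 4000, 4005),
                ("fly1", "egg_expulsion", 8000, 8005),
            ]
        )
        seq = extract_phase_sequence(dataset, "fly1")
        assert seq.entries == [(Phase.DEPOSITION, 100)]

    def test_progressing_contact_is_not_exploration(self):
        dataset = make_dataset(
            [
                ("fly1", "ovipositor_contact", 100, 140),
                ("fly1", "egg_expulsion", 150, 160),
            ]
        )
        seq = extract_phase_sequence(dataset, "fly1")
        assert seq.phases() == [Phase.DEPOSITION]

    def test_proboscis_and_burrowing_contribute_no_phase(self):
        dataset = make_dataset(
            [
                ("fly1", "proboscis_extension", 100, 110),
                ("fly1", "burrowing", 300, 400),
            ]
        )
        assert extract_phase_sequence(dataset, "fly1").entries == []


class TestTransitionMatrix:
    def test_hand_counted_single_sequence(self):
        # D,C,D,C,E,D
        phases = [
            Phase.DEPOSITION, Phase.CONTORTIONS, Phase.DEPOSITION,
            Phase.CONTORTIONS, Phase.EXPLORATION, Phase.DEPOSITION,
        ]
        seq = PhaseSequence("fly1", [(p, 100 * i) for i, p in enumerate(phases)])
        tm = transition_matrix([seq])
        assert tm.n_transitions == 5
        assert tm.counts[0, 1] == 2  # D -> C
        assert tm.counts[1, 0] == 1  # C -> D
        assert tm.counts[1, 2] == 1  # C -> E
        assert tm.counts[2, 0] == 1  # E -> D
        assert tm.probability(Phase.DEPOSITION, Phase.CONTORTIONS) == 1.0
        assert tm.probability(Phase.CONTORTIONS, Phase.DEPOSITION) == 0.5
        assert tm.probability(Phase.CONTORTIONS, Phase.EXPLORATION) == 0.5
        assert tm.probability(Phase.EXPLORATION, Phase.DEPOSITION) == 1.0

    def test_no_transitions_across_fly_boundaries(self):
        a = PhaseSequence("a", [(Phase.DEPOSITION, 0), (Phase.CONTORTIONS, 10)])
        b = PhaseSequence("b", [(Phase.CONTORTIONS, 0), (Phase.DEPOSITION, 10)])
        tm = transition_matrix([a, b])
        assert tm.n_transitions == 2
        assert tm.counts[1, 1] == 0  # no spurious C -> C

    def test_rows_without_outgoing_transitions_are_nan(self):
        seq = PhaseSequence("a", [(Phase.DEPOSITION, 0), (Phase.CONTORTIONS, 10)])
        probs = transition_matrix([seq]).probabilities
        assert np.isnan(probs[1]).all() and np.isnan(probs[2]).all()
        assert probs[0, 1] == 1.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="no phase transitions"):
            transition_matrix([PhaseSequence("a", [(Phase.DEPOSITION, 0)])])

    def test_rows_are_stochastic_and_diagonal_zero(self, rng):
        for _ in range(20):
            entries, phase = [], None
            for i in range(int(rng.integers(2, 30))):
                nxt = rng.choice([p for p in PHASES if p != phase])
                entries.append((nxt, i * 10))
                phase = nxt
            tm = transition_matrix([PhaseSequence("a", entries)])
            assert np.all(np.diag(tm.counts) == 0)
            probs = tm.probabilities
            for row in range(3):
                if tm.counts[row].sum() > 0:
                    assert probs[row].sum() == pytest.approx(1.0, abs=1e-12)

    def test_estimator_recovers_known_matrix(self):
        """2000+ sampled transitions land within 0.05 of the true matrix."""
        true = np.array([[0.0, 0.8, 0.2], [0.6, 0.0, 0.4], [0.3, 0.7, 0.0]])
        rng = np.random.default_rng(42)
        seqs = []
        for fly in range(20):
            phase_idx = int(rng.integers(3))
            entries = [(PHASES[phase_idx], 0)]
            for i in range(120):
                phase_idx = int(rng.choice(3, p=true[phase_idx]))
                entries.append((PHASES[phase_idx], 10 * (i + 1)))
            seqs.append(PhaseSequence(f"f{fly}", entries))
        tm = transition_matrix(seqs)
        assert tm.n_transitions >= 2000
        assert np.nanmax(np.abs(tm.probabilities - true)) < 0.05

    def test_per_fly_average_matches_pooled_for_identical_flies(self):
        phases = [Phase.DEPOSITION, Phase.CONTORTIONS, Phase.EXPLORATION, Phase.DEPOSITION]
        seqs = [
            PhaseSequence(f, [(p, 10 * i) for i, p in enumerate(phases)]) for f in "ab"
        ]
        pooled = transition_matrix(seqs).probabilities
        averaged = per_fly_average_matrix(seqs)
        np.testing.assert_allclose(averaged, pooled)
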