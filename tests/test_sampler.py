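import math

import numpy as np
import pytest

import motifgrammar as mg
from motifgrammar.errors import ConfigurationError, PlacementError


def one_hot_motif(seq, mid="m"):
    m = np.zeros((len(seq), 4))
    for i, c in enumerate(seq):
        m[i, "ACGT".index(c)] = 1.0
    return mg.Motif(mid, m)


class TestCounts:
    def test_fixed(self, rng):
        policy = mg.InsertionPolicy(count_dist=("fixed", 3))
        assert all(mg.sample_num_instances(policy, rng) == 3 for _ in range(20))

    def test_poisson_zero(self, rng):
        policy = mg.InsertionPolicy(count_dist=("poisson", 0.0))
        assert all(mg.sample_num_instances(policy, rng) == 0 for _ in range(20))

    def test_poisson_mean(self, rng):
        policy = mg.InsertionPolicy(count_dist=("poisson", 2.0))
        n = 10_000
        draws = [mg.sample_num_instances(policy, rng) for _ in range(n)]
        assert abs(np.mean(draws) - 2.0) < 3 * math.sqrt(2.0 / n)

    def test_invalid(self):
        with pytest.raises(ConfigurationError):
            mg.InsertionPolicy(count_dist=("poisson", -1.0))
        with pytest.raises(ConfigurationError):
            mg.InsertionPolicy(count_dist=("negbin", 2))


class TestSampleInstance:
    def test_one_hot_gives_consensus(self, rng):
        m = one_hot_motif("GATTACA")
        assert all(
            mg.sample_instance(m, mg.DNA, rng) == "GATTACA" for _ in range(10)
        )

    def test_half_half_column(self, rng):
        m = mg.Motif("m", np.array([[0.5, 0.5, 0.0, 0.0]]))
        n = 10_000
        hits = sum(mg.sample_instance(m, mg.DNA, rng) == "A" for _ in range(n))
        se = math.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) < 3 * se

    def test_column_frequency_recovery(self, rng):
        m = mg.Motif("m", np.random.default_rng(3).dirichlet([1] * 4, size=5))
        n = 50_000
        counts = np.zeros((5, 4))
        for _ in range(n):
            s = mg.sample_instance(m, mg.DNA, rng)
            for i, c in enumerate(s):
                counts[i, "ACGT".index(c)] += 1
        assert np.abs(counts / n - m.matrix).max() < 0.02


class TestSamplePosition:
    def test_center(self, rng):
        policy = mg.InsertionPolicy(position_dist=("center",))
        assert mg.sample_position(policy, 10, 4, rng) == 3

    def test_gaussian_sd0_is_center(self, rng):
        policy = mg.InsertionPolicy(position_dist=("gaussian", 0.0, 0.0))
        assert all(mg.sample_position(policy, 10, 4, rng) == 3 for _ in range(5))

    def test_uniform_multinomial(self, rng):
        policy = mg.InsertionPolicy(position_dist=("uniform",))
        n = 70_000
        draws = np.array([mg.sample_position(policy, 10, 4, rng) for _ in range(n)])
        se = math.sqrt((1 / 7) * (6 / 7) / n)
        for s in range(7):
            assert abs((draws == s).mean() - 1 / 7) < 3 * se
        assert draws.min() == 0 and draws.max() == 6

    def test_motif_longer_than_sequence(self, rng):
        policy = mg.InsertionPolicy()
        with pytest.raises(PlacementError):
            mg.sample_position(policy, 5, 6, rng)

    def test_gaussian_clip_boundary(self, rng):
        policy = mg.InsertionPolicy(
            position_dist=("gaussian", 1000.0, 0.1), boundary_policy="clip"
        )
        assert mg.sample_position(policy, 10, 4, rng) == 6


class TestPlaceInstance:
    def test_replacement(self):
        assert mg.place_instance("AAAAAAAA", "CGT", 2) == "AACGTAAA"

    def test_idempotent_on_existing_slice(self):
        s = "ACGTACGT"
        assert mg.place_instance(s, s[3:6], 3) == s

    def test_out_of_range(self):
        with pytest.raises(PlacementError):
            mg.place_instance("AAAAAAAA", "CGT", 7)


class TestSimulateRound:
    def _setup(self, count, p_forward=1.0, position=("center",), seq="A" * 20,
               overlap="resample"):
        ms = mg.MotifSet(alphabet=mg.DNA)
        ms.add(one_hot_motif("CGTCG", "m0"))
        grammar = mg.build_grammar({"g": ["m0"]})
        policy = mg.InsertionPolicy(
            count_dist=count, p_forward=p_forward, position_dist=position,
            overlap_policy=overlap,
        )
        track = np.tile([0.25] * 4, (len(seq), 1))
        return ("bg", seq), track, grammar, ms, policy

    def test_zero_instances_leaves_background(self, rng):
        bg, track, grammar, ms, policy = self._setup(("fixed", 0))
        seq, records, out_track, dropped = mg.simulate_round(
            bg, track, grammar, ms, policy, mg.DNA, rng, "s0"
        )
        assert seq == bg[1] and records == [] and dropped == 0
        np.testing.assert_array_equal(out_track, track)

    def test_fully_deterministic_round(self, rng):
        bg, track, grammar, ms, policy = self._setup(("fixed", 1))
        seq, records, out_track, _ = mg.simulate_round(
            bg, track, grammar, ms, policy, mg.DNA, rng, "s0"
        )
        start = (20 - 5) // 2
        assert seq == "A" * start + "CGTCG" + "A" * (20 - start - 5)
        rec = records[0]
        assert (rec.start, rec.end, rec.strand, rec.instance) == (
            start, start + 5, "+", "CGTCG",
        )
        np.testing.assert_allclose(
            out_track[start : start + 5], ms["m0"].matrix
        )
        np.testing.assert_allclose(out_track[:start], 0.25)

    def test_reverse_strand_track_and_sequence(self, rng):
        bg, track, grammar, ms, policy = self._setup(("fixed", 1), p_forward=0.0)
        seq, records, out_track, _ = mg.simulate_round(
            bg, track, grammar, ms, policy, mg.DNA, rng, "s0"
        )
        rec = records[0]
        assert rec.strand == "-"
        written = seq[rec.start : rec.end]
        assert mg.reverse_complement(written, mg.DNA) == rec.instance == "CGTCG"
        # track rows are the reversed, complemented motif columns
        perm = mg.DNA.complement_permutation()
        np.testing.assert_allclose(
            out_track[rec.start : rec.end], ms["m0"].matrix[::-1, perm]
        )

    def test_resample_policy_drops_when_no_room(self, rng):
        # motif as long as the sequence: a second instance can never fit
        bg, track, grammar, ms, policy = self._setup(
            ("fixed", 2), seq="A" * 5, position=("uniform",)
        )
        with pytest.warns(UserWarning, match="dropped"):
            seq, records, _, dropped = mg.simulate_round(
                bg, track, grammar, ms, policy, mg.DNA, rng, "s0"
            )
        assert len(records) == 1 and dropped == 1

    def test_allow_policy_flags_occluded(self, rng):
        bg, track, grammar, ms, policy = self._setup(
            ("fixed", 2), seq="A" * 5, position=("center",), overlap="allow"
        )
        _, records, _, dropped = mg.simulate_round(
            bg, track, grammar, ms, policy, mg.DNA, rng, "s0"
        )
        assert dropped == 0 and len(records) == 2
        assert records[0].occluded and not records[1].occluded


class TestRunSimulation:
    @pytest.fixture
    def small_run(self, simulated_motifs, overlapping_grammar, rng):
        pool = mg.simulate_iid(100, 80, 120, mg.DNA, rng)
        policy = mg.InsertionPolicy(
            count_dist=("poisson", 2.0), p_forward=0.5,
            position_dist=("uniform",),
        )
        return mg.run_simulation(
            pool, simulated_motifs, overlapping_grammar, policy, 500, 11
        )

    def test_shape_and_ids(self, small_run):
        assert len(small_run.sequences) == 500
        assert small_run.sequences[0][0] == "sequence_0"
        assert small_run.sequences[-1][0] == "sequence_499"

    def test_ground_truth_consistency(self, small_run):
        seqs = dict(small_run.sequences)
        for rec in small_run.records:
            window = seqs[rec.sequence_id][rec.start : rec.end]
            expect = (
                rec.instance if rec.strand == "+"
                else mg.reverse_complement(rec.instance, mg.DNA)
            )
            if not rec.occluded:
                assert window == expect

    def test_probability_tracks_valid_and_background_elsewhere(self, small_run):
        covered = {}
        for rec in small_run.records:
            covered.setdefault(rec.sequence_id, set()).update(
                range(rec.start, rec.end)
            )
        for (sid, seq), track in zip(
            small_run.sequences, small_run.probability_tracks
        ):
            assert track.shape == (len(seq), 4)
            np.testing.assert_allclose(track.sum(axis=1), 1.0, atol=1e-9)
            free = sorted(set(range(len(seq))) - covered.get(sid, set()))
            if free:
                np.testing.assert_allclose(track[free], 0.25)

    def test_counts_tally_consistency(self, small_run):
        counts = small_run.counts
        total = sum(counts["motifs"].values())
        assert total == len(small_run.records)
        assert sum(counts["orientations"].values()) == total
        assert sum(counts["instances_per_sequence"].values()) == 500
        assert sum(counts["backgrounds"].values()) == 500
        assert counts["dropped_instances"] == 0

    def test_determinism_same_seed(self, simulated_motifs, overlapping_grammar, rng):
        pool = mg.simulate_iid(20, 60, 60, mg.DNA, rng)
        policy = mg.InsertionPolicy(count_dist=("fixed", 2))
        a = mg.run_simulation(pool, simulated_motifs, overlapping_grammar, policy, 50, 7)
        b = mg.run_simulation(pool, simulated_motifs, overlapping_grammar, policy, 50, 7)
        assert a.sequences == b.sequences
        assert a.records == b.records

    def test_empty_run(self, simulated_motifs, overlapping_grammar, rng):
        pool = mg.simulate_iid(5, 60, 60, mg.DNA, rng)
        policy = mg.InsertionPolicy()
        res = mg.run_simulation(
            pool, simulated_motifs, overlapping_grammar, policy, 0, 1
        )
        assert res.sequences == [] and res.records == []

    def test_orientation_fraction(self, simulated_motifs, overlapping_grammar, rng):
        pool = mg.simulate_iid(50, 100, 100, mg.DNA, rng)
        policy = mg.InsertionPolicy(
            count_dist=("fixed", 2), p_forward=0.5, position_dist=("uniform",)
        )
        res = mg.run_simulation(
            pool, simulated_motifs, overlapping_grammar, policy, 10_000, 13
        )
        n = len(res.records)
        frac = sum(r.strand == "+" for r in res.records) / n
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_linear_runtime_scaling(self, simulated_motifs, overlapping_grammar, rng):
        import time

        pool = mg.simulate_iid(50, 100, 100, mg.DNA, rng)
        policy = mg.InsertionPolicy(count_dist=("fixed", 2))
        times = []
        for n in (1000, 2000, 4000):
            t0 = time.perf_counter()
            mg.run_simulation(
                pool, simulated_motifs, overlapping_grammar, policy, n, 3
            )
            times.append(time.perf_counter() - t0)
        # per-sequence cost stable within 3x across doublings (qualitative O(n))
        per_seq = [t / n for t, n in zip(times, (1000, 2000, 4000))]
        assert max(per_seq) < 3 * min(per_seq)
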