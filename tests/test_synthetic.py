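"""Fixture generator: determinism, divergence calibration, truth bookkeeping."""

import numpy as np
import pytest

from synscaf.io_formats import revcomp
from synscaf.synthetic import (
    EvolutionParams,
    FixtureParams,
    NoiseParams,
    emit_alignments,
    evolve_query,
    fragment_into_scaffolds,
    generate_fixture,
    generate_reference,
    read_truth_tsv,
    write_truth_tsv,
)


class TestGenerateReference:
    def test_deterministic_per_seed(self):
        a = generate_reference(1, (10_000, 10_000), 0.5, seed=4)
        b = generate_reference(1, (10_000, 10_000), 0.5, seed=4)
        assert a[0].sequence == b[0].sequence and a[0].length == 10_000

    def test_gc_one_yields_only_gc(self):
        (rec,) = generate_reference(1, (10_000, 10_000), 1.0, seed=1)
        assert set(rec.sequence) <= {"G", "C"}

    def test_gc_fraction_concentrates(self):
        (rec,) = generate_reference(1, (1_000_000, 1_000_000), 0.42, seed=2)
        gc = (rec.sequence.count("G") + rec.sequence.count("C")) / rec.length
        assert abs(gc - 0.42) < 0.01

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_reference(0, (10_000, 10_000))
        with pytest.raises(ValueError):
            generate_reference(1, (100, 200))
        with pytest.raises(ValueError):
            generate_reference(1, (10_000, 10_000), gc=1.5)


class TestEvolveQuery:
    def test_zero_rates_is_identity(self):
        ref = generate_reference(2, (20_000, 30_000), seed=3)
        params = EvolutionParams(substitution_rate=0, indel_rate=0, seed=5)
        query, qmap, events = evolve_query(ref, params)
        assert events == []
        assert [q.sequence for q in query] == [r.sequence for r in ref]
        # identity projection
        (piece,) = qmap.project(query[0].id, 100, 5_000)
        assert piece == (100, 5_000, ref[0].id, 100, 5_000, "+")

    def test_substitution_fraction_concentrates(self):
        ref = generate_reference(1, (1_000_000, 1_000_000), seed=6)
        params = EvolutionParams(substitution_rate=0.05, indel_rate=0, seed=7)
        (q,), _, _ = evolve_query(ref, params)
        mismatch = sum(a != b for a, b in zip(ref[0].sequence, q.sequence)) / q.length
        assert abs(mismatch - 0.05) < 0.002

    def test_event_log_counts_and_coordinates(self):
        ref = generate_reference(2, (500_000, 600_000), seed=8)
        params = EvolutionParams(
            substitution_rate=0, indel_rate=0, n_inversions=3, n_translocations=2,
            inversion_len_range=(10_000, 50_000), translocation_len_range=(10_000, 30_000),
            seed=9,
        )
        _, _, events = evolve_query(ref, params)
        kinds = [e["kind"] for e in events]
        assert kinds.count("inversion") == 3 and kinds.count("translocation") == 2
        for e in events:
            assert e["length"] > 0

    def test_planted_inversion_projects_with_minus_strand(self):
        ref = generate_reference(1, (200_000, 200_000), seed=10)
        params = EvolutionParams(
            substitution_rate=0, indel_rate=0, n_inversions=1,
            inversion_len_range=(50_000, 50_000), seed=11,
        )
        (q,), qmap, (ev,) = evolve_query(ref, params)
        a, b = ev["start"], ev["end"]
        # inside the inversion the query is the reverse complement of the reference
        assert q.sequence[a:b] == revcomp(ref[0].sequence[a:b])
        (piece,) = qmap.project(q.id, a, b)
        assert piece[5] == "-" and (piece[3], piece[4]) == (a, b)

    def test_indels_keep_projection_consistent(self):
        ref = generate_reference(1, (100_000, 100_000), seed=12)
        params = EvolutionParams(substitution_rate=0, indel_rate=0.01, mean_indel_len=5, seed=13)
        (q,), qmap, _ = evolve_query(ref, params)
        assert q.length != ref[0].length
        pieces = qmap.project(q.id, 0, q.length)
        assert pieces
        covered = sum(p[1] - p[0] for p in pieces)
        assert covered >= 0.95 * q.length
        for q0, q1, rchrom, r0, r1, strand in pieces:
            # projected spans agree up to the accumulated indel drift
            assert abs((q1 - q0) - (r1 - r0)) <= 0.1 * (q1 - q0) + 50


class TestFragmentation:
    def test_zero_breaks_scaffolds_equal_chromosomes(self):
        ref = generate_reference(2, (20_000, 20_000), seed=14)
        query, qmap, ev = evolve_query(ref, EvolutionParams(substitution_rate=0, indel_rate=0, seed=1))
        scaffolds, truth = fragment_into_scaffolds(query, 0, (500, 1_000), seed=15, query_map=qmap)
        assert len(scaffolds) == 2
        assert all(len(parts) == 1 for parts in truth.chromosomes.values())

    def test_length_bookkeeping(self):
        ref = generate_reference(1, (1_000_000, 1_000_000), seed=16)
        query, qmap, _ = evolve_query(ref, EvolutionParams(substitution_rate=0, indel_rate=0, seed=1))
        scaffolds, truth = fragment_into_scaffolds(query, 4, (1_000, 1_000), seed=17, query_map=qmap)
        assert len(scaffolds) == 5
        total_gap = sum(g for _, _, g in truth.chromosomes[query[0].id][:-1])
        assert sum(s.length for s in scaffolds) + total_gap == 1_000_000

    def test_deterministic_per_seed(self):
        ref = generate_reference(1, (100_000, 100_000), seed=18)
        query, qmap, _ = evolve_query(ref, EvolutionParams(substitution_rate=0, indel_rate=0, seed=1))
        a, _ = fragment_into_scaffolds(query, 5, (500, 2_000), seed=19, query_map=qmap)
        b, _ = fragment_into_scaffolds(query, 5, (500, 2_000), seed=19, query_map=qmap)
        assert [(s.id, s.sequence) for s in a] == [(s.id, s.sequence) for s in b]

    def test_truth_origins_slice_the_query(self):
        ref = generate_reference(1, (100_000, 100_000), seed=20)
        query, qmap, _ = evolve_query(ref, EvolutionParams(substitution_rate=0.05, indel_rate=0, seed=2))
        scaffolds, truth = fragment_into_scaffolds(query, 5, (500, 2_000), seed=21, query_map=qmap)
        seqs = {q.id: q.sequence for q in query}
        for s in scaffolds:
            chrom, b, e = truth.origins[s.id]
            assert s.sequence == seqs[chrom][b:e]


class TestEmitAlignments:
    def _fixture(self, noise, seed=22):
        ref = generate_reference(2, (200_000, 250_000), seed=seed)
        query, qmap, ev = evolve_query(
            ref, EvolutionParams(substitution_rate=0.05, indel_rate=0, seed=seed + 1)
        )
        scaffolds, truth = fragment_into_scaffolds(
            query, 9, (500, 2_000), seed=seed + 2, query_map=qmap, events=ev
        )
        return ref, scaffolds, truth, emit_alignments(truth, ref, noise, seed=seed + 3)

    def test_zero_noise_one_record_per_truth_segment(self):
        _, scaffolds, truth, alns = self._fixture(NoiseParams())
        assert len(alns) == len(scaffolds)  # no rearrangements: one segment each
        by_q = {a.query_id: a for a in alns}
        for s in scaffolds:
            a = by_q[s.id]
            assert (a.q_start, a.q_end) == (0, s.length)

    def test_dropout_binomially_thins_records(self):
        counts = []
        for seed in range(30, 40):
            _, _, _, alns = self._fixture(NoiseParams(dropout_rate=0.3), seed=seed)
            counts.append(len(alns))
        assert 0.55 * 200 < np.mean(counts) * 10 < 0.85 * 200  # ~0.7 of 20 per fixture

    def test_spurious_records_top_up_count(self):
        _, scaffolds, _, alns = self._fixture(NoiseParams(spurious_rate=0.2))
        assert len(alns) == round(1.2 * len(scaffolds))

    def test_jitter_moves_but_preserves_validity(self):
        _, scaffolds, _, alns = self._fixture(NoiseParams(jitter_bp=100))
        lengths = {s.id: s.length for s in scaffolds}
        for a in alns:
            assert 0 <= a.q_start < a.q_end <= lengths[a.query_id]


class TestTruthTsv:
    def test_round_trip(self, tmp_path, zero_noise_fixture):
        truth = zero_noise_fixture.truth
        path = tmp_path / "truth.tsv"
        write_truth_tsv(truth, path)
        back = read_truth_tsv(path)
        assert back.chromosomes == truth.chromosomes
        assert back.origins == truth.origins
        assert back.chromosome_lengths == truth.chromosome_lengths


def test_whole_fixture_is_deterministic_per_seed():
    params = FixtureParams(
        n_chromosomes=1, chromosome_length_range=(150_000, 160_000),
        evolution=EvolutionParams(n_inversions=1, n_translocations=1,
                                  inversion_len_range=(5_000, 10_000),
                                  translocation_len_range=(5_000, 10_000)),
        n_breaks_per_chrom=4, seed=33,
        noise=NoiseParams(dropout_rate=0.1, spurious_rate=0.1, jitter_bp=100),
    )
    a = generate_fixture(params)
    b = generate_fixture(params)
    assert [(s.id, s.sequence) for s in a.scaffolds] == [(s.id, s.sequence) for s in b.scaffolds]
    assert [(x.query_id, x.q_start, x.r_start) for x in a.alignments] == [
        (x.query_id, x.q_start, x.r_start) for x in b.alignments
    ]
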