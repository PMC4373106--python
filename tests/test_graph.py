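"""Link creation, conflict resolution and superscaffold assembly."""

import pytest

from synscaf.graph import (
    LinkEdge,
    assemble_superscaffolds,
    assign_unplaced,
    links_from_mate_pairs,
    links_from_placements,
    resolve_conflicts,
)
from synscaf.io_formats import SequenceRecord
from synscaf.collinearity import chain_collinear_blocks
from synscaf.placement import LEFT, RIGHT, EndPlacement, MappedPair, default_insert_specs
from conftest import aln


SPECS = default_insert_specs(scale=0.001)


def placement(scf, end, ref, pos, orient, anchor=10_000):
    return EndPlacement(scf, end, ref, pos, orient, anchor, 0)


class TestLinksFromPlacements:
    def test_facing_ends_link_under_smallest_containing_window(self):
        ps = [
            placement("A", RIGHT, "chr1", 1_000_000, "+"),
            placement("B", LEFT, "chr1", 1_030_000, "+"),
        ]
        (e,) = links_from_placements(ps, SPECS)
        assert e.insert_class == "40k" and e.gap_estimate == 30_000
        assert {e.a, e.b} == {("A", RIGHT), ("B", LEFT)}

    def test_separation_between_windows_does_not_link(self):
        ps = [
            placement("A", RIGHT, "chr1", 1_000_000, "+"),
            placement("B", LEFT, "chr1", 1_090_000, "+"),  # 90 kb: 40k tops at 60k, 200k starts at 100k
        ]
        assert links_from_placements(ps, SPECS) == []

    def test_different_chromosomes_do_not_link(self):
        ps = [
            placement("A", RIGHT, "chr1", 1_000_000, "+"),
            placement("B", LEFT, "chr2", 1_030_000, "+"),
        ]
        assert links_from_placements(ps, SPECS) == []

    def test_sub_window_separation_links_only_when_allowed(self):
        ps = [
            placement("A", RIGHT, "chr1", 1_000_000, "+"),
            placement("B", LEFT, "chr1", 1_005_000, "+"),  # 5 kb < 20 kb lower bound
        ]
        (e,) = links_from_placements(ps, SPECS, allow_sub_window=True)
        assert e.insert_class == "40k" and e.gap_estimate == 5_000
        assert links_from_placements(ps, SPECS, allow_sub_window=False) == []

    def test_non_facing_orientations_do_not_link(self):
        # both termini point high: parallel, not facing
        ps = [
            placement("A", RIGHT, "chr1", 1_000_000, "+"),
            placement("B", RIGHT, "chr1", 1_030_000, "+"),
        ]
        assert links_from_placements(ps, SPECS) == []

    def test_minus_oriented_scaffold_faces_with_its_left_end(self):
        ps = [
            placement("A", RIGHT, "chr1", 1_000_000, "+"),
            placement("B", RIGHT, "chr1", 1_030_000, "-"),  # '-' RIGHT end is the low side
        ]
        (e,) = links_from_placements(ps, SPECS)
        assert {e.a, e.b} == {("A", RIGHT), ("B", RIGHT)}


def mapped(pair_id, cls, sa, pa, sta, sb, pb, stb):
    return MappedPair(pair_id, sa, pa, sta, sb, pb, stb, cls)


class TestLinksFromMatePairs:
    lengths = {"A": 50_000, "B": 50_000}

    def _concordant(self, n, gap=2_000):
        # A.RIGHT faces B.LEFT: read1 '+' near A's right end, read2 '-' near B's left end
        out = []
        for i in range(n):
            tail_a = 20_000 + 137 * i  # distance from read start to A's right end
            tail_b = 40_000 - gap - tail_a - 100  # so insert 40k implies the gap
            out.append(
                mapped(f"40k:{i}", "40k", "A", 50_000 - tail_a, "+", "B", tail_b - 100, "-")
            )
        return out

    def test_concordant_bucket_becomes_edge_with_median_gap(self):
        edges = links_from_mate_pairs(self._concordant(10), SPECS, self.lengths, min_links=5)
        (e,) = edges
        assert e.weight == 10
        assert {e.a, e.b} == {("A", RIGHT), ("B", LEFT)}
        assert abs(e.gap_estimate - 2_000) <= 100

    def test_below_min_links_no_edge(self):
        assert links_from_mate_pairs(self._concordant(3), SPECS, self.lengths, min_links=5) == []

    def test_inconsistent_orientations_split_buckets(self):
        pairs = self._concordant(3)
        # three more pairs implying A.RIGHT-B.RIGHT instead
        for i in range(3, 6):
            tail_a = 20_000
            tail_b = 40_000 - 2_000 - tail_a
            pairs.append(mapped(f"40k:{i}", "40k", "A", 50_000 - tail_a, "+", "B", 50_000 - tail_b, "+"))
        assert links_from_mate_pairs(pairs, SPECS, self.lengths, min_links=5) == []

    def test_discordant_gap_pairs_are_dropped(self):
        # implied gap ~ -30 kb, far outside +/-20 kb tolerance
        pairs = [
            mapped(f"40k:{i}", "40k", "A", 50_000 - 35_000, "+", "B", 35_000 - 100, "-")
            for i in range(10)
        ]
        assert links_from_mate_pairs(pairs, SPECS, self.lengths, min_links=5) == []

    def test_same_scaffold_pairs_are_internal(self):
        pairs = [mapped(f"40k:{i}", "40k", "A", 0, "+", "A", 39_900, "-") for i in range(10)]
        assert links_from_mate_pairs(pairs, SPECS, self.lengths, min_links=5) == []


def edge(a, b, weight, cls="40k", gap=100):
    return LinkEdge(a, b, cls, gap, weight, "direct")


class TestResolveConflicts:
    def test_clear_winner_kept(self):
        es = [
            edge(("A", RIGHT), ("B", LEFT), 10),
            edge(("A", RIGHT), ("C", LEFT), 2),
        ]
        kept = resolve_conflicts(es, ambiguity_ratio=0.7)
        assert len(kept) == 1 and {kept[0].a, kept[0].b} == {("A", RIGHT), ("B", LEFT)}

    def test_ambiguous_end_drops_all(self):
        es = [
            edge(("A", RIGHT), ("B", LEFT), 10),
            edge(("A", RIGHT), ("C", LEFT), 9),
        ]
        assert resolve_conflicts(es, ambiguity_ratio=0.7) == []

    def test_degree_one_graph_is_identity(self):
        es = [
            edge(("A", RIGHT), ("B", LEFT), 10),
            edge(("B", RIGHT), ("C", LEFT), 3),
        ]
        assert len(resolve_conflicts(es, ambiguity_ratio=0.7)) == 2

    def test_smaller_insert_class_takes_precedence(self):
        es = [
            edge(("A", RIGHT), ("B", LEFT), 5, cls="40k"),
            edge(("A", RIGHT), ("C", LEFT), 50, cls="200k"),
        ]
        kept = resolve_conflicts(es, ambiguity_ratio=0.7, insert_specs=SPECS)
        assert len(kept) == 1 and kept[0].insert_class == "40k"


class TestAssemble:
    scaffolds = [SequenceRecord(x, "A" * 100) for x in "ABCD"]

    def test_linear_chain_all_plus(self):
        es = [
            edge(("A", RIGHT), ("B", LEFT), 10),
            edge(("B", RIGHT), ("C", LEFT), 10),
        ]
        sss = assemble_superscaffolds(es, self.scaffolds, min_gap=10)
        chain = next(s for s in sss if len(s.parts) > 1)
        assert [(p[0], p[1]) for p in chain.parts] == [("A", "+"), ("B", "+"), ("C", "+")]

    def test_right_right_link_flips_second_scaffold(self):
        es = [edge(("A", RIGHT), ("B", RIGHT), 10)]
        sss = assemble_superscaffolds(es, self.scaffolds, min_gap=10)
        chain = next(s for s in sss if len(s.parts) > 1)
        assert [(p[0], p[1]) for p in chain.parts] == [("A", "+"), ("B", "-")]

    def test_negative_gap_estimate_clamped(self):
        es = [edge(("A", RIGHT), ("B", LEFT), 10, gap=-500)]
        sss = assemble_superscaffolds(es, self.scaffolds, min_gap=10)
        chain = next(s for s in sss if len(s.parts) > 1)
        assert chain.parts[0][2] == 10

    def test_every_scaffold_in_exactly_one_superscaffold(self):
        es = [edge(("A", RIGHT), ("B", LEFT), 10)]
        sss = assemble_superscaffolds(es, self.scaffolds, min_gap=10)
        seen = [p[0] for s in sss for p in s.parts]
        assert sorted(seen) == ["A", "B", "C", "D"]

    def test_cycle_broken_at_lightest_edge(self):
        es = [
            edge(("A", RIGHT), ("B", LEFT), 10),
            edge(("B", RIGHT), ("C", LEFT), 2),
            edge(("C", RIGHT), ("A", LEFT), 10),
        ]
        sss = assemble_superscaffolds(es, self.scaffolds, min_gap=10)
        chain = next(s for s in sss if len(s.parts) > 1)
        assert len(chain.parts) == 3
        ids = [p[0] for p in chain.parts]
        adjacent = set(zip(ids, ids[1:])) | set(zip(ids[1:], ids))
        assert ("B", "C") not in adjacent  # the lightest (B-C) edge was removed

    def test_degree_violation_rejected(self):
        es = [
            edge(("A", RIGHT), ("B", LEFT), 10),
            edge(("A", RIGHT), ("C", LEFT), 10),
        ]
        with pytest.raises(ValueError):
            assemble_superscaffolds(es, self.scaffolds, min_gap=10)

    def test_n50_never_decreases(self, zero_noise_fixture):
        from synscaf.evaluation import compute_assembly_stats
        from synscaf.pipeline import RunConfig, run_scaffold

        fx = zero_noise_fixture
        res = run_scaffold(fx.scaffolds, fx.alignments, RunConfig(mode="direct"))
        lengths = {s.id: s.length for s in res.scaffolds}
        before = compute_assembly_stats([s.length for s in res.scaffolds]).n50
        after = compute_assembly_stats([s.length(lengths) for s in res.superscaffolds]).n50
        assert after >= before


class TestAssignUnplaced:
    def test_dominant_chromosome_assignment(self):
        blocks = chain_collinear_blocks(
            [
                aln("s1", 0, 80_000, 100_000, "chr5", 0, 80_000, 10**6),
                aln("s1", 80_000, 100_000, 100_000, "chr2", 0, 20_000, 10**6),
            ],
            min_block_bp=0,
        )
        assert assign_unplaced(blocks, set(), min_fraction=0.6) == {"s1": "chr5"}

    def test_even_split_stays_unassigned(self):
        blocks = chain_collinear_blocks(
            [
                aln("s1", 0, 50_000, 100_000, "chr1", 0, 50_000, 10**6),
                aln("s1", 50_000, 100_000, 100_000, "chr2", 0, 50_000, 10**6),
            ],
            min_block_bp=0,
        )
        assert assign_unplaced(blocks, set(), min_fraction=0.6) == {}

    def test_no_alignments_unassigned(self):
        assert assign_unplaced([], set(), min_fraction=0.6) == {}

    def test_already_placed_ids_skipped(self):
        blocks = chain_collinear_blocks(
            [aln("s1", 0, 80_000, 100_000, "chr5", 0, 80_000, 10**6)], min_block_bp=0
        )
        assert assign_unplaced(blocks, {"s1"}, min_fraction=0.6) == {}
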