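"""From raw pairwise alignments to single-coverage collinear blocks.

Whole-genome aligners emit overlapping, partly redundant local alignments.
Superscaffolding needs at most one alignment covering any position of either
genome, chained into blocks that are collinear (consistently ordered and
stranded) in both genomes.  This module also flags putative inter-chromosomal
mis-assemblies: scaffolds whose alignments jump between reference
chromosomes with strong support on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .io_formats import PairwiseAlignment, SequenceRecord

__all__ = [
    "CollinearBlock",
    "BreakCall",
    "single_coverage_filter",
    "chain_collinear_blocks",
    "detect_interchromosomal_breaks",
    "split_scaffolds",
]

DEFAULT_MAX_GAP = 100_000
DEFAULT_MIN_BLOCK_BP = 5_000
DEFAULT_MIN_KEEP_LEN = 200
DEFAULT_MIN_SUPPORT_BP = 50_000


@dataclass
class CollinearBlock:
    """A chained, single-coverage run of alignments collinear in both genomes."""

    query_id: str
    ref_id: str
    strand: str
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    aligned_bp: int
    members: list[PairwiseAlignment]

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def r_span(self) -> int:
        return self.r_end - self.r_start


@dataclass
class BreakCall:
    """A putative inter-chromosomal mis-join inside one query scaffold."""

    query_id: str
    break_pos: int
    left_ref_id: str
    right_ref_id: str
    support_left_bp: int
    support_right_bp: int


def _sort_key(a: PairwiseAlignment):
    # Descending score, then longer span, then lexicographic ids/coords.
    return (-a.score, -(a.q_span + a.r_span), a.query_id, a.ref_id, a.q_start, a.r_start)


def _largest_free_subinterval(start: int, end: int, tree: IntervalTree) -> tuple[int, int] | None:
    """Largest sub-interval of [start, end) not covered by ``tree``.

    Ties broken toward the lower coordinate.  Returns None if fully covered.
    """
    hits = sorted(tree.overlap(start, end))
    if not hits:
        return (start, end)
    best: tuple[int, int] | None = None
    cursor = start
    for iv in hits:
        if iv.begin > cursor:
            cand = (cursor, iv.begin)
            if best is None or cand[1] - cand[0] > best[1] - best[0]:
                best = cand
        cursor = max(cursor, iv.end)
    if cursor < end:
        cand = (cursor, end)
        if best is None or cand[1] - cand[0] > best[1] - best[0]:
            best = cand
    return best


def _trim_to_ref(a: PairwiseAlignment, rs: int, re_: int) -> PairwiseAlignment | None:
    """Trim ``a`` to reference interval [rs, re_) with proportional query trim."""
    if rs <= a.r_start and re_ >= a.r_end:
        return a
    span = a.r_span
    cut_low = rs - a.r_start
    cut_high = a.r_end - re_
    dq_low = cut_low * a.q_span // span
    dq_high = cut_high * a.q_span // span
    if a.strand == "+":
        qs, qe = a.q_start + dq_low, a.q_end - dq_high
    else:
        qs, qe = a.q_start + dq_high, a.q_end - dq_low
    if qe <= qs or re_ <= rs:
        return None
    frac_kept = (re_ - rs) / span
    matches = min(int(a.matches * frac_kept), qe - qs, re_ - rs)
    return PairwiseAlignment(
        a.query_id, qs, qe, a.query_len, a.ref_id, rs, re_, a.ref_len,
        a.strand, matches, a.score,
    )


def _trim_to_query(a: PairwiseAlignment, qs: int, qe: int) -> PairwiseAlignment | None:
    """Trim ``a`` to query interval [qs, qe) with proportional reference trim."""
    if qs <= a.q_start and qe >= a.q_end:
        return a
    span = a.q_span
    cut_low = qs - a.q_start
    cut_high = a.q_end - qe
    dr_low = cut_low * a.r_span // span
    dr_high = cut_high * a.r_span // span
    if a.strand == "+":
        rs, re_ = a.r_start + dr_low, a.r_end - dr_high
    else:
        rs, re_ = a.r_start + dr_high, a.r_end - dr_low
    if qe <= qs or re_ <= rs:
        return None
    frac_kept = (qe - qs) / span
    matches = min(int(a.matches * frac_kept), qe - qs, re_ - rs)
    return PairwiseAlignment(
        a.query_id, qs, qe, a.query_len, a.ref_id, rs, re_, a.ref_len,
        a.strand, matches, a.score,
    )


def single_coverage_filter(
    alignments: Iterable[PairwiseAlignment],
    min_keep_len: int = DEFAULT_MIN_KEEP_LEN,
) -> list[PairwiseAlignment]:
    """Greedily enforce at most 1x alignment coverage on both genomes.

    Alignments are processed in descending score order (ties: longer span,
    then lexicographic ids).  A candidate overlapping already-accepted
    alignments is trimmed to its largest conflict-free sub-interval on the
    overlapping axis, with proportional trimming of the paired axis; remnants
    shorter than ``min_keep_len`` on either axis are dropped.
    """
    ref_trees: dict[str, IntervalTree] = {}
    query_trees: dict[str, IntervalTree] = {}
    kept: list[PairwiseAlignment] = []
    for a in sorted(alignments, key=_sort_key):
        cand: PairwiseAlignment | None = a
        # Alternate axes until conflict-free; each pass strictly shrinks.
        for _ in range(64):
            if cand is None:
                break
            rtree = ref_trees.setdefault(cand.ref_id, IntervalTree())
            qtree = query_trees.setdefault(cand.query_id, IntervalTree())
            free_r = _largest_free_subinterval(cand.r_start, cand.r_end, rtree)
            if free_r is None:
                cand = None
                break
            if free_r != (cand.r_start, cand.r_end):
                cand = _trim_to_ref(cand, *free_r)
                if cand is None:
                    break
                continue
            free_q = _largest_free_subinterval(cand.q_start, cand.q_end, qtree)
            if free_q is None:
                cand = None
                break
            if free_q != (cand.q_start, cand.q_end):
                cand = _trim_to_query(cand, *free_q)
                if cand is None:
                    break
                continue
            break  # conflict-free on both axes
        if cand is None or min(cand.q_span, cand.r_span) < min_keep_len:
            continue
        kept.append(cand)
        ref_trees[cand.ref_id].addi(cand.r_start, cand.r_end)
        query_trees[cand.query_id].addi(cand.q_start, cand.q_end)
    kept.sort(key=lambda x: (x.query_id, x.q_start, x.ref_id, x.r_start))
    return kept


def _members_to_block(members: list[PairwiseAlignment]) -> CollinearBlock:
    first = members[0]
    return CollinearBlock(
        query_id=first.query_id,
        ref_id=first.ref_id,
        strand=first.strand,
        q_start=min(m.q_start for m in members),
        q_end=max(m.q_end for m in members),
        r_start=min(m.r_start for m in members),
        r_end=max(m.r_end for m in members),
        aligned_bp=sum(m.q_span for m in members),
        members=members,
    )


def chain_collinear_blocks(
    alignments: Iterable[PairwiseAlignment],
    max_gap: int = DEFAULT_MAX_GAP,
    min_block_bp: int = DEFAULT_MIN_BLOCK_BP,
) -> list[CollinearBlock]:
    """Chain single-coverage alignments into collinear blocks.

    Alignments sharing (query, reference, strand) are chained greedily in
    query order while consecutive members keep the diagonal direction and
    have gaps <= ``max_gap`` on both genomes.  Blocks with fewer than
    ``min_block_bp`` aligned bp are discarded.
    """
    groups: dict[tuple[str, str, str], list[PairwiseAlignment]] = {}
    for a in alignments:
        groups.setdefault((a.query_id, a.ref_id, a.strand), []).append(a)

    blocks: list[CollinearBlock] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda x: (x.q_start, x.r_start))
        chain: list[PairwiseAlignment] = []
        strand = key[2]
        for a in members:
            if chain:
                prev = chain[-1]
                q_gap = a.q_start - prev.q_end
                if strand == "+":
                    r_gap = a.r_start - prev.r_end
                else:
                    r_gap = prev.r_start - a.r_end
                if 0 <= q_gap <= max_gap and 0 <= r_gap <= max_gap:
                    chain.append(a)
                    continue
                blocks.append(_members_to_block(chain))
                chain = []
            chain.append(a)
        if chain:
            blocks.append(_members_to_block(chain))
    blocks = [b for b in blocks if b.aligned_bp >= min_block_bp]
    blocks.sort(key=lambda b: (b.query_id, b.q_start, b.ref_id, b.r_start))
    return blocks


def detect_interchromosomal_breaks(
    blocks: Iterable[CollinearBlock],
    min_support_bp: int = DEFAULT_MIN_SUPPORT_BP,
) -> list[BreakCall]:
    """Flag transitions between reference chromosomes inside one scaffold.

    Blocks of each scaffold are ordered along the query; maximal runs on the
    same reference chromosome are formed, and a break is called at every
    transition whose flanking runs both carry at least ``min_support_bp``
    aligned bp.  The break position is the midpoint of the uncovered query
    interval between the two runs.
    """
    by_query: dict[str, list[CollinearBlock]] = {}
    for b in blocks:
        by_query.setdefault(b.query_id, []).append(b)

    calls: list[BreakCall] = []
    for qid in sorted(by_query):
        bs = sorted(by_query[qid], key=lambda b: b.q_start)
        # maximal same-ref runs: (ref_id, q_start, q_end, support)
        runs: list[list] = []
        for b in bs:
            if runs and runs[-1][0] == b.ref_id:
                runs[-1][2] = max(runs[-1][2], b.q_end)
                runs[-1][3] += b.aligned_bp
            else:
                runs.append([b.ref_id, b.q_start, b.q_end, b.aligned_bp])
        for left, right in zip(runs, runs[1:]):
            if left[3] >= min_support_bp and right[3] >= min_support_bp:
                calls.append(
                    BreakCall(
                        query_id=qid,
                        break_pos=(left[2] + right[1]) // 2,
                        left_ref_id=left[0],
                        right_ref_id=right[0],
                        support_left_bp=left[3],
                        support_right_bp=right[3],
                    )
                )
    return calls


def split_scaffolds(
    scaffolds: Sequence[SequenceRecord],
    break_calls: Iterable[BreakCall],
) -> tuple[list[SequenceRecord], dict[str, list[tuple[str, int, int]]]]:
    """Split scaffolds at break positions.

    Returns the new records plus an id map ``old_id -> [(new_id, start, end)]``
    in old coordinates, for lifting block/alignment coordinates over.
    Scaffolds without breaks are passed through unchanged (mapped to
    themselves over their full span).
    """
    breaks: dict[str, list[int]] = {}
    for call in break_calls:
        breaks.setdefault(call.query_id, []).append(call.break_pos)

    out: list[SequenceRecord] = []
    id_map: dict[str, list[tuple[str, int, int]]] = {}
    for scf in scaffolds:
        positions = sorted(set(breaks.get(scf.id, [])))
        if not positions:
            out.append(scf)
            id_map[scf.id] = [(scf.id, 0, scf.length)]
            continue
        for pos in positions:
            if not (0 < pos < scf.length):
                raise ValueError(f"break position {pos} outside scaffold {scf.id}")
        bounds = [0, *positions, scf.length]
        parts: list[tuple[str, int, int]] = []
        for i, (s, e) in enumerate(zip(bounds, bounds[1:]), 1):
            new_id = f"{scf.id}.part{i}"
            out.append(SequenceRecord(new_id, scf.sequence[s:e]))
            parts.append((new_id, s, e))
        id_map[scf.id] = parts
    return out, id_map
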