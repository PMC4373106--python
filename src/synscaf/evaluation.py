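"""Assembly statistics, truth-based link accuracy, rearrangement flags.

The evaluator scores a superscaffold set against a known truth layout: a
junction (adjacent pair inside a superscaffold) is correct when the two
scaffolds sit on the same truth chromosome, are consecutive in truth order,
and their relative orientation matches; a scaffold is correctly linked when
every junction it participates in is correct.  Consecutiveness is computed
among the scaffolds that were actually linked, so pieces the scaffolder left
unordered do not turn otherwise correct joins into errors; a strict variant
that counts every input scaffold is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .collinearity import CollinearBlock

__all__ = [
    "AssemblyStats",
    "EvaluationReport",
    "RearrangementEvent",
    "compute_assembly_stats",
    "evaluate_against_truth",
    "detect_intrachromosomal_rearrangements",
]


@dataclass
class AssemblyStats:
    n_sequences: int
    total_length: int
    n50: int
    mean_length: float
    max_length: int


@dataclass
class EvaluationReport:
    n_junctions: int
    n_correct_junctions: int
    n_scaffolds_linked: int
    n_scaffolds_correctly_linked: int
    correct_link_rate: float | None
    junction_rate: float | None
    n50_before: int
    n50_after: int
    n50_ratio: float
    # strict accounting: consecutiveness computed over every input scaffold,
    # i.e. unordered singletons count against skipped joins
    n_correct_junctions_strict: int = 0
    correct_link_rate_strict: float | None = None


@dataclass
class RearrangementEvent:
    query_id: str
    ref_id: str
    kind: str  # inversion | transposition
    block_indices: list[int]


def compute_assembly_stats(lengths: Sequence[int]) -> AssemblyStats:
    """Standard assembly statistics; N50 by descending cumulative sum."""
    if not lengths:
        raise ValueError("no sequence lengths given")
    if any(l <= 0 for l in lengths):
        raise ValueError("sequence lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    half = total / 2
    acc = 0
    n50 = ordered[-1]
    for l in ordered:
        acc += l
        if acc >= half:
            n50 = l
            break
    return AssemblyStats(
        n_sequences=len(ordered),
        total_length=total,
        n50=n50,
        mean_length=total / len(ordered),
        max_length=ordered[0],
    )


def _junction_correct(
    x: str, ox: str, y: str, oy: str,
    truth_pos: dict[str, tuple[str, int, str]],
    rank: dict[str, int],
) -> bool:
    """Is the emitted adjacency x(ox) -> y(oy) a truth adjacency?

    Correct directly (same flip state, x immediately before y in truth) or
    fully reversed (both flipped, y immediately before x); this makes the
    check symmetric and invariant under reversing a superscaffold.
    """
    cx, _, tx = truth_pos[x]
    cy, _, ty = truth_pos[y]
    if cx != cy:
        return False
    if x not in rank or y not in rank:
        return False
    fx = ox != tx
    fy = oy != ty
    if fx != fy:
        return False
    if not fx:
        return rank[y] == rank[x] + 1
    return rank[x] == rank[y] + 1


def evaluate_against_truth(
    superscaffolds,
    truth,
    scaffold_lengths: dict[str, int],
) -> EvaluationReport:
    """Score superscaffold junctions and scaffolds against the truth layout.

    ``truth`` provides per-chromosome ordered (scaffold_id, orientation, gap)
    lists.  Reports per-junction and per-scaffold correct-link rates (both
    the linked-only and the strict all-scaffolds accounting) plus the N50 of
    the input scaffolds and of the emitted superscaffolds.
    """
    truth_pos: dict[str, tuple[str, int, str]] = {}
    for chrom, parts in truth.chromosomes.items():
        for idx, (scf, orient, _gap) in enumerate(parts):
            truth_pos[scf] = (chrom, idx, orient)

    junctions: list[tuple[str, str, str, str]] = []
    linked: set[str] = set()
    present: set[str] = set()
    for ss in superscaffolds:
        for scf, _, _ in ss.parts:
            if scf not in truth_pos:
                raise KeyError(f"scaffold {scf} not in truth")
            present.add(scf)
        for (x, ox, _), (y, oy, _) in zip(ss.parts, ss.parts[1:]):
            junctions.append((x, ox, y, oy))
            linked.add(x)
            linked.add(y)

    def ranks_among(members: set[str]) -> dict[str, int]:
        out: dict[str, int] = {}
        for chrom, parts in truth.chromosomes.items():
            pos = 0
            for scf, _, _ in parts:
                if scf in members:
                    out[scf] = pos
                    pos += 1
        return out

    rank_linked = ranks_among(linked)
    rank_all = ranks_among(present)

    bad_scaffolds: set[str] = set()
    bad_scaffolds_strict: set[str] = set()
    n_correct = 0
    n_correct_strict = 0
    for x, ox, y, oy in junctions:
        if _junction_correct(x, ox, y, oy, truth_pos, rank_linked):
            n_correct += 1
        else:
            bad_scaffolds.update((x, y))
        if _junction_correct(x, ox, y, oy, truth_pos, rank_all):
            n_correct_strict += 1
        else:
            bad_scaffolds_strict.update((x, y))

    n_junctions = len(junctions)
    n_linked = len(linked)
    n_good = len(linked - bad_scaffolds)
    n_good_strict = len(linked - bad_scaffolds_strict)

    lengths_before = [scaffold_lengths[s] for s in sorted(present)]
    lengths_after = [ss.length(scaffold_lengths) for ss in superscaffolds]
    n50_before = compute_assembly_stats(lengths_before).n50 if lengths_before else 0
    n50_after = compute_assembly_stats(lengths_after).n50 if lengths_after else 0

    return EvaluationReport(
        n_junctions=n_junctions,
        n_correct_junctions=n_correct,
        n_scaffolds_linked=n_linked,
        n_scaffolds_correctly_linked=n_good,
        correct_link_rate=(n_good / n_linked) if n_linked else None,
        junction_rate=(n_correct / n_junctions) if n_junctions else None,
        n50_before=n50_before,
        n50_after=n50_after,
        n50_ratio=(n50_after / n50_before) if n50_before else 0.0,
        n_correct_junctions_strict=n_correct_strict,
        correct_link_rate_strict=(n_good_strict / n_linked) if n_linked else None,
    )


def _longest_increasing_subsequence(values: Sequence[int]) -> list[int]:
    """Indices of one longest strictly increasing subsequence (O(n^2) DP).

    Deterministic: among equally long subsequences the lexicographically
    smallest index set reached by the left-to-right DP is returned.
    """
    n = len(values)
    if n == 0:
        return []
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if values[j] < values[i] and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = max(range(n), key=lambda i: (best_len[i], -i))
    out = []
    while end != -1:
        out.append(end)
        end = prev[end]
    return out[::-1]


def detect_intrachromosomal_rearrangements(
    blocks: Sequence[CollinearBlock],
) -> list[RearrangementEvent]:
    """Flag inversions and transpositions of one scaffold on one chromosome.

    Blocks are taken in query order.  Runs of blocks on the minority strand
    are inversion events; among majority-strand blocks, consecutive runs
    outside the longest increasing subsequence of reference order are
    transposition events.
    """
    if not blocks:
        return []
    qid = blocks[0].query_id
    rid = blocks[0].ref_id
    for b in blocks:
        if b.query_id != qid or b.ref_id != rid:
            raise ValueError("blocks must share one query and one reference sequence")
    bs = sorted(range(len(blocks)), key=lambda i: blocks[i].q_start)

    plus_bp = sum(blocks[i].aligned_bp for i in bs if blocks[i].strand == "+")
    minus_bp = sum(blocks[i].aligned_bp for i in bs if blocks[i].strand == "-")
    majority = "+" if plus_bp >= minus_bp else "-"

    events: list[RearrangementEvent] = []
    run: list[int] = []
    for i in bs:
        if blocks[i].strand != majority:
            run.append(i)
        elif run:
            events.append(RearrangementEvent(qid, rid, "inversion", run))
            run = []
    if run:
        events.append(RearrangementEvent(qid, rid, "inversion", run))

    maj = [i for i in bs if blocks[i].strand == majority]
    refs = [blocks[i].r_start for i in maj]
    if majority == "-":
        refs = [-r for r in refs]
    keep = set(_longest_increasing_subsequence(refs))
    run = []
    for pos, i in enumerate(maj):
        if pos not in keep:
            run.append(i)
        elif run:
            events.append(RearrangementEvent(qid, rid, "transposition", run))
            run = []
    if run:
        events.append(RearrangementEvent(qid, rid, "transposition", run))
    events.sort(key=lambda e: e.block_indices[0])
    return events
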