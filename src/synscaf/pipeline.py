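"""End-to-end composition: alignments in, superscaffolds out.

Two modes mirror the two ways collinearity can order scaffolds:

* ``direct`` — scaffold termini are projected onto the reference and linked
  when facing termini fall within an insert window of each other.
* ``matepair`` — a reference-ordered mosaic of query sequence is rebuilt,
  long-insert mate pairs are simulated from it at the three insert classes,
  mapped back to the scaffolds, and linked like a mate-pair scaffolder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import collinearity as coll
from . import graph as sg
from .io_formats import PairwiseAlignment, SequenceRecord
from .placement import (
    InsertSpec,
    _ExactMatchIndex,
    build_reference_ordered_mosaic,
    default_insert_specs,
    map_mate_pairs,
    place_scaffold_ends,
    simulate_long_mate_pairs,
)

__all__ = ["RunConfig", "ScaffoldResult", "run_scaffold", "lift_alignments"]


@dataclass
class RunConfig:
    """All thresholds of one scaffolding run."""

    mode: str = "direct"  # direct | matepair
    scale: float = 0.001  # divides the full-scale pair counts
    strict_windows: bool = False
    split_misjoins: bool = False
    min_keep_len: int = coll.DEFAULT_MIN_KEEP_LEN
    max_gap: int = coll.DEFAULT_MAX_GAP
    min_block_bp: int = coll.DEFAULT_MIN_BLOCK_BP
    min_support_bp: int = coll.DEFAULT_MIN_SUPPORT_BP
    min_links: int = sg.DEFAULT_MIN_LINKS
    ambiguity_ratio: float = sg.DEFAULT_AMBIGUITY_RATIO
    min_gap: int = sg.DEFAULT_MIN_GAP
    max_overlap: int = sg.DEFAULT_MAX_OVERLAP
    min_fraction: float = sg.DEFAULT_MIN_FRACTION
    read_length: int = 100
    mapping_k: int = 31
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("direct", "matepair"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def insert_specs(self) -> list[InsertSpec]:
        return default_insert_specs(scale=self.scale, read_length=self.read_length)


@dataclass
class ScaffoldResult:
    scaffolds: list[SequenceRecord]  # possibly split
    filtered: list[PairwiseAlignment]
    blocks: list
    break_calls: list
    edges: list
    superscaffolds: list
    chromosome_assignment: dict[str, str]
    log: dict = field(default_factory=dict)


def lift_alignments(
    alignments: Sequence[PairwiseAlignment],
    id_map: dict[str, list[tuple[str, int, int]]],
) -> list[PairwiseAlignment]:
    """Re-express alignments on split scaffold parts (clipping at cut sites)."""
    out: list[PairwiseAlignment] = []
    for a in alignments:
        parts = id_map.get(a.query_id)
        if parts is None or (len(parts) == 1 and parts[0][0] == a.query_id):
            out.append(a)
            continue
        for new_id, s, e in parts:
            qs, qe = max(a.q_start, s), min(a.q_end, e)
            if qe <= qs:
                continue
            clipped = coll._trim_to_query(a, qs, qe)
            if clipped is None:
                continue
            out.append(
                PairwiseAlignment(
                    new_id, clipped.q_start - s, clipped.q_end - s, e - s,
                    clipped.ref_id, clipped.r_start, clipped.r_end, clipped.ref_len,
                    clipped.strand, clipped.matches, clipped.score,
                )
            )
    return out


def run_scaffold(
    scaffolds: Sequence[SequenceRecord],
    alignments: Sequence[PairwiseAlignment],
    config: RunConfig,
) -> ScaffoldResult:
    """Run filter -> chain -> (optional split) -> link -> resolve -> assemble."""
    log: dict = {"n_scaffolds_in": len(scaffolds), "n_alignments_in": len(alignments)}
    scaffolds = list(scaffolds)

    filtered = coll.single_coverage_filter(alignments, min_keep_len=config.min_keep_len)
    log["n_alignments_filtered"] = len(filtered)

    blocks = coll.chain_collinear_blocks(
        filtered, max_gap=config.max_gap, min_block_bp=config.min_block_bp
    )
    log["n_blocks"] = len(blocks)

    break_calls = coll.detect_interchromosomal_breaks(
        blocks, min_support_bp=config.min_support_bp
    )
    log["n_break_calls"] = len(break_calls)
    if config.split_misjoins and break_calls:
        scaffolds, id_map = coll.split_scaffolds(scaffolds, break_calls)
        filtered = lift_alignments(filtered, id_map)
        blocks = coll.chain_collinear_blocks(
            filtered, max_gap=config.max_gap, min_block_bp=config.min_block_bp
        )
        log["n_scaffolds_after_split"] = len(scaffolds)
        log["n_blocks_after_split"] = len(blocks)

    specs = config.insert_specs()
    scaffold_lengths = {s.id: s.length for s in scaffolds}

    if not blocks:
        log["note"] = "no blocks after filtering; emitting singletons"
        superscaffolds = sg.assemble_superscaffolds([], scaffolds, min_gap=config.min_gap)
        return ScaffoldResult(scaffolds, filtered, [], break_calls, [], superscaffolds, {}, log)

    if config.mode == "direct":
        placements = place_scaffold_ends(blocks, specs)
        log["n_placements"] = len(placements)
        edges = sg.links_from_placements(
            placements, specs,
            allow_sub_window=not config.strict_windows,
            max_overlap=config.max_overlap,
        )
    else:
        query_seqs = {s.id: s.sequence for s in scaffolds}
        ref_lengths: dict[str, int] = {}
        for a in filtered:
            ref_lengths[a.ref_id] = a.ref_len
        mosaics, segments = build_reference_ordered_mosaic(blocks, query_seqs, ref_lengths)
        log["n_mosaic_chromosomes"] = len(mosaics)
        log["mosaic_bp"] = sum(m.length for m in mosaics)
        seeds = np.random.SeedSequence(config.seed).generate_state(len(specs))
        index = _ExactMatchIndex(scaffolds, k=config.mapping_k)
        mapped = []
        n_pairs = 0
        for spec, s in zip(specs, seeds):
            pairs = simulate_long_mate_pairs(mosaics, spec, seed=int(s))
            n_pairs += len(pairs)
            mapped.extend(map_mate_pairs(pairs, scaffolds, k=config.mapping_k, index=index))
        log["n_pairs_simulated"] = n_pairs
        log["n_pairs_mapped"] = len(mapped)
        edges = sg.links_from_mate_pairs(
            mapped, specs, scaffold_lengths, min_links=config.min_links
        )
        if config.strict_windows:
            smallest_lo = min(s.window[0] for s in specs)
            edges = [e for e in edges if e.gap_estimate >= smallest_lo]
    log["n_edges_raw"] = len(edges)

    edges = sg.resolve_conflicts(edges, ambiguity_ratio=config.ambiguity_ratio, insert_specs=specs)
    log["n_edges_resolved"] = len(edges)

    superscaffolds = sg.assemble_superscaffolds(edges, scaffolds, min_gap=config.min_gap)
    log["n_superscaffolds"] = len(superscaffolds)
    log["n_singletons"] = sum(1 for s in superscaffolds if len(s.parts) == 1)

    placed = {scf for ss in superscaffolds for scf in ss.scaffold_ids if len(ss.parts) > 1}
    assignment = sg.assign_unplaced(blocks, placed, min_fraction=config.min_fraction)
    log["n_assigned_unplaced"] = len(assignment)

    return ScaffoldResult(
        scaffolds, filtered, blocks, break_calls, edges, superscaffolds, assignment, log
    )
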