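"""Scaffold adjacency graph: linking, conflict resolution, assembly.

A link joins two scaffold *ends* and thereby fixes the relative orientation
of the two scaffolds (linked ends face each other).  Links come either from
direct end placements on the reference (within the insert windows) or from
simulated long-insert mate pairs.  Conflicts are resolved per insert class,
smallest class first, with a weight-ratio ambiguity rule; the surviving
degree-<=1 graph decomposes into chains that become superscaffolds.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .collinearity import CollinearBlock
from .io_formats import SequenceRecord
from .placement import LEFT, RIGHT, EndPlacement, InsertSpec, MappedPair

__all__ = [
    "LinkEdge",
    "Superscaffold",
    "links_from_placements",
    "links_from_mate_pairs",
    "resolve_conflicts",
    "assemble_superscaffolds",
    "assign_unplaced",
]

DEFAULT_MIN_LINKS = 5
DEFAULT_AMBIGUITY_RATIO = 0.7
DEFAULT_MIN_GAP = 10
DEFAULT_MAX_OVERLAP = 2_000
DEFAULT_MIN_FRACTION = 0.6

End = tuple[str, str]  # (scaffold_id, LEFT|RIGHT)


@dataclass
class LinkEdge:
    """A reference-supported adjacency between two scaffold ends."""

    a: End
    b: End
    insert_class: str
    gap_estimate: int
    weight: int
    source: str  # direct | matepair
    ref_id: str | None = None

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("self-link")

    @property
    def key(self) -> tuple[End, End]:
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)


@dataclass
class Superscaffold:
    """An ordered, oriented list of scaffolds with inter-scaffold gaps.

    ``parts`` entries are (scaffold_id, orientation, gap_after); gap_after is
    None for the last part.
    """

    id: str
    parts: list[tuple[str, str, int | None]]

    @property
    def scaffold_ids(self) -> list[str]:
        return [p[0] for p in self.parts]

    def length(self, scaffold_lengths: dict[str, int]) -> int:
        total = sum(scaffold_lengths[s] for s, _, _ in self.parts)
        total += sum(g for _, _, g in self.parts[:-1])
        return total


def _points_high(p: EndPlacement) -> bool:
    """True if this terminus is the high-reference-coordinate side of its scaffold."""
    return (p.end == RIGHT) == (p.orientation == "+")


def _class_for_separation(
    d: int,
    specs: Sequence[InsertSpec],
    allow_sub_window: bool,
    max_overlap: int,
) -> InsertSpec | None:
    for spec in sorted(specs, key=lambda s: s.insert):
        lo, hi = spec.window
        if lo <= d <= hi:
            return spec
    if allow_sub_window:
        smallest = min(specs, key=lambda s: s.insert)
        if -max_overlap <= d < smallest.window[0]:
            return smallest
    return None


def links_from_placements(
    placements: Iterable[EndPlacement],
    insert_specs: Sequence[InsertSpec],
    allow_sub_window: bool = True,
    max_overlap: int = DEFAULT_MAX_OVERLAP,
) -> list[LinkEdge]:
    """Link facing scaffold termini whose separation fits an insert window.

    On each reference chromosome every terminus is paired with its *nearest*
    facing terminus of another scaffold; the pair links under the smallest
    insert class whose window contains the separation.  With
    ``allow_sub_window`` (default) separations below the smallest window's
    lower bound still link under the smallest class down to ``-max_overlap``.
    """
    by_ref: dict[str, list[EndPlacement]] = {}
    for p in placements:
        by_ref.setdefault(p.ref_id, []).append(p)

    edges: dict[tuple[End, End], LinkEdge] = {}
    for ref_id in sorted(by_ref):
        ps = sorted(by_ref[ref_id], key=lambda p: (p.ref_pos, p.scaffold_id, p.end))
        highs = [p for p in ps if _points_high(p)]
        lows = [p for p in ps if not _points_high(p)]

        candidates: set[tuple[int, int]] = set()
        for hi_idx, p in enumerate(highs):
            best = None
            for lo_idx, q in enumerate(lows):
                if q.scaffold_id == p.scaffold_id:
                    continue
                d = q.ref_pos - p.ref_pos
                if d < -max_overlap:
                    continue
                if best is None or d < best[0]:
                    best = (d, lo_idx)
            if best is not None:
                candidates.add((hi_idx, best[1]))
        for lo_idx, q in enumerate(lows):
            best = None
            for hi_idx, p in enumerate(highs):
                if p.scaffold_id == q.scaffold_id:
                    continue
                d = q.ref_pos - p.ref_pos
                if d < -max_overlap:
                    continue
                if best is None or d < best[0]:
                    best = (d, hi_idx)
            if best is not None:
                candidates.add((best[1], lo_idx))

        for hi_idx, lo_idx in sorted(candidates):
            p, q = highs[hi_idx], lows[lo_idx]
            d = q.ref_pos - p.ref_pos
            spec = _class_for_separation(d, insert_specs, allow_sub_window, max_overlap)
            if spec is None:
                continue
            edge = LinkEdge(
                a=(p.scaffold_id, p.end),
                b=(q.scaffold_id, q.end),
                insert_class=spec.label,
                gap_estimate=d,
                weight=min(p.anchor_bp, q.anchor_bp),
                source="direct",
                ref_id=ref_id,
            )
            prev = edges.get(edge.key)
            if prev is None or edge.weight > prev.weight:
                edges[edge.key] = edge
    return [edges[k] for k in sorted(edges)]


def links_from_mate_pairs(
    mapped_pairs: Iterable[MappedPair],
    insert_specs: Sequence[InsertSpec],
    scaffold_lengths: dict[str, int],
    min_links: int = DEFAULT_MIN_LINKS,
) -> list[LinkEdge]:
    """Bucket cross-scaffold mate pairs into weighted link edges.

    Each mapped read implicates the scaffold end its mate points past; the
    implied inter-scaffold gap of a pair is insert - tail_a - tail_b.  Pairs
    whose implied gap falls outside +/- tolerance of zero are discarded as
    discordant; a bucket of >= ``min_links`` concordant pairs becomes an
    edge with the median implied gap.
    """
    specs = {s.label: s for s in insert_specs}
    buckets: dict[tuple[End, End, str], list[int]] = {}
    n_internal = 0
    for mp in mapped_pairs:
        if mp.scaffold_a == mp.scaffold_b:
            n_internal += 1
            continue
        spec = specs[mp.insert_class]
        rl = spec.read_length
        ends: list[End] = []
        tails: list[int] = []
        for scf, pos, strand in (
            (mp.scaffold_a, mp.pos_a, mp.strand_a),
            (mp.scaffold_b, mp.pos_b, mp.strand_b),
        ):
            if strand == "+":
                ends.append((scf, RIGHT))
                tails.append(scaffold_lengths[scf] - pos)
            else:
                ends.append((scf, LEFT))
                tails.append(pos + rl)
        gap = spec.insert - tails[0] - tails[1]
        if abs(gap) > spec.tolerance:
            continue
        a, b = sorted(ends)
        buckets.setdefault((a, b, mp.insert_class), []).append(gap)

    edges = []
    for (a, b, label), gaps in sorted(buckets.items()):
        if len(gaps) < min_links:
            continue
        edges.append(
            LinkEdge(
                a=a,
                b=b,
                insert_class=label,
                gap_estimate=int(statistics.median(gaps)),
                weight=len(gaps),
                source="matepair",
            )
        )
    return edges


def resolve_conflicts(
    edges: Iterable[LinkEdge],
    ambiguity_ratio: float = DEFAULT_AMBIGUITY_RATIO,
    insert_specs: Sequence[InsertSpec] | None = None,
) -> list[LinkEdge]:
    """Reduce the link graph so every scaffold end has degree <= 1.

    Edges are resolved per insert class, smallest insert first (the way an
    iterative mate-pair scaffolder consumes its libraries): ends already
    linked by a smaller class are closed to larger classes.  Within a class,
    an end with several incident edges keeps the heaviest only when the
    second-heaviest weighs less than ``ambiguity_ratio`` times it; otherwise
    all edges at that end are dropped as ambiguous.
    """
    edges = list(edges)
    if insert_specs is not None:
        class_rank = {s.label: s.insert for s in insert_specs}
    else:
        labels = sorted({e.insert_class for e in edges})
        class_rank = {lab: i for i, lab in enumerate(labels)}

    by_class: dict[str, list[LinkEdge]] = {}
    for e in edges:
        by_class.setdefault(e.insert_class, []).append(e)

    kept: list[LinkEdge] = []
    used_ends: set[End] = set()
    for label in sorted(by_class, key=lambda l: class_rank.get(l, 1 << 60)):
        pool = {
            e.key: e
            for e in by_class[label]
            if e.a not in used_ends and e.b not in used_ends
        }
        changed = True
        while changed:
            changed = False
            incident: dict[End, list[LinkEdge]] = {}
            for e in pool.values():
                incident.setdefault(e.a, []).append(e)
                incident.setdefault(e.b, []).append(e)
            for end in sorted(incident):
                es = incident[end]
                if len(es) <= 1:
                    continue
                es.sort(key=lambda e: (-e.weight, e.key))
                if es[1].weight < ambiguity_ratio * es[0].weight:
                    doomed = es[1:]
                else:
                    doomed = es
                for e in doomed:
                    pool.pop(e.key, None)
                changed = True
                break
        for key in sorted(pool):
            e = pool[key]
            kept.append(e)
            used_ends.add(e.a)
            used_ends.add(e.b)
    kept.sort(key=lambda e: e.key)
    return kept


def assemble_superscaffolds(
    edges: Sequence[LinkEdge],
    scaffolds: Sequence[SequenceRecord],
    min_gap: int = DEFAULT_MIN_GAP,
) -> list[Superscaffold]:
    """Walk degree-<=1 chains into ordered, oriented superscaffolds.

    Chains are emitted from their lexicographically smaller terminus; any
    residual cycle is broken at its lightest edge first.  Gaps are clamped
    to at least ``min_gap``.  Unlinked scaffolds come out as singletons.
    """
    edge_at: dict[End, LinkEdge] = {}
    for e in edges:
        for end in (e.a, e.b):
            if end in edge_at:
                raise ValueError(f"scaffold end {end} has degree > 1")
            edge_at[end] = e

    graph = nx.Graph()
    graph.add_nodes_from(s.id for s in scaffolds)
    known = set(graph.nodes)
    for e in edges:
        for scf, _ in (e.a, e.b):
            if scf not in known:
                raise KeyError(f"edge references unknown scaffold {scf}")
        graph.add_edge(e.a[0], e.b[0], link=e)

    # break residual cycles at their lightest edge
    for cycle in nx.cycle_basis(graph):
        cyc_edges = [
            graph.edges[u, v]["link"]
            for u, v in zip(cycle, cycle[1:] + cycle[:1])
            if graph.has_edge(u, v)
        ]
        victim = min(cyc_edges, key=lambda e: (e.weight, e.key))
        graph.remove_edge(victim.a[0], victim.b[0])
        for end in (victim.a, victim.b):
            edge_at.pop(end, None)

    superscaffolds: list[Superscaffold] = []
    chains: list[list[tuple[str, str, int | None]]] = []
    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        if len(comp) == 1:
            chains.append([(comp[0], "+", None)])
            continue
        termini = [
            s
            for s in comp
            if ((s, LEFT) not in edge_at) or ((s, RIGHT) not in edge_at)
        ]
        start = min(termini)
        free_end = LEFT if (start, LEFT) not in edge_at else RIGHT
        parts: list[tuple[str, str, int | None]] = []
        scf, entry = start, free_end
        while True:
            orient = "+" if entry == LEFT else "-"
            exit_end = RIGHT if entry == LEFT else LEFT
            e = edge_at.get((scf, exit_end))
            if e is None:
                parts.append((scf, orient, None))
                break
            parts.append((scf, orient, max(e.gap_estimate, min_gap)))
            other = e.b if e.a == (scf, exit_end) else e.a
            scf, entry = other
        chains.append(parts)

    chains.sort(key=lambda parts: parts[0][0])
    for i, parts in enumerate(chains, 1):
        superscaffolds.append(Superscaffold(f"ss{i}", parts))
    return superscaffolds


def assign_unplaced(
    blocks: Iterable[CollinearBlock],
    assigned_ids: set[str],
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> dict[str, str]:
    """Assign leftover scaffolds to the chromosome holding most of their alignment.

    A scaffold not in ``assigned_ids`` maps to the reference chromosome
    carrying at least ``min_fraction`` of its aligned bp; otherwise it stays
    unassigned.
    """
    per_scaffold: dict[str, dict[str, int]] = {}
    for b in blocks:
        if b.query_id in assigned_ids:
            continue
        per_scaffold.setdefault(b.query_id, {}).setdefault(b.ref_id, 0)
        per_scaffold[b.query_id][b.ref_id] += b.aligned_bp

    assignment: dict[str, str] = {}
    for qid in sorted(per_scaffold):
        by_ref = per_scaffold[qid]
        total = sum(by_ref.values())
        ref_id, top = max(by_ref.items(), key=lambda kv: (kv[1], kv[0]))
        if total > 0 and top >= min_fraction * total:
            assignment[qid] = ref_id
    return assignment
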